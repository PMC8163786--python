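import numpy as np
import pytest

from invascreen.synthetic import (ConditionEffect, SyntheticPlateSpec,
                                  generate_plate)


def small_plate_spec(seed: int = 7) -> SyntheticPlateSpec:
    """A compact plate: one planted invasion target, one null, full control set."""
    return SyntheticPlateSpec(
        plate_id="P1",
        targets={"siINV": ConditionEffect(amplitude_shift=0.3),
                 "siNULL": ConditionEffect()},
        n_mock=1, n_tumor_alone=1, n_control_tox=1,
        seed=seed)


def recovery_screen_spec(seed: int) -> SyntheticPlateSpec:
    """One control + four targets: a planted invasion effect, a planted
    lethal effect (which also releases invasion), and two nulls."""
    return SyntheticPlateSpec(
        plate_id="S",
        targets={"siINV": ConditionEffect(amplitude_shift=0.3),
                 "siLETHAL": ConditionEffect(amplitude_shift=0.3,
                                             viability_factor=0.15),
                 "siNULL1": ConditionEffect(),
                 "siNULL2": ConditionEffect()},
        n_mock=0, n_tumor_alone=0, n_control_tox=0,
        seed=seed)


@pytest.fixture(scope="session")
def plate_dir(tmp_path_factory):
    """A generated synthetic plate on disk, shared across tests."""
    out = tmp_path_factory.mktemp("plate")
    res = generate_plate(small_plate_spec(), out)
    return res["out_dir"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def disc_mask(radius: int, pad: int = 10) -> np.ndarray:
    n = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
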