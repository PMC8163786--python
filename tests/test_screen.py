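"""Per-plate normalization, hit-calling, and phenotype classification."""
import numpy as np
import pandas as pd
import pytest

from conftest import recovery_screen_spec

from invascreen.pipeline import run_synthetic_screen
from invascreen.screen import (PlateLayout, ScreenParams, classify_phenotype,
                               dunnett_hits, normalize_to_control,
                               normalize_viability, screen_report)


def colonies_frame(spec: dict[str, tuple[str, list[float]]],
                   plate="P1") -> pd.DataFrame:
    rows = []
    for cond, (role, ratios) in spec.items():
        for r in ratios:
            rows.append(dict(plate_id=plate, well="w", condition=cond,
                             role=role, ratio=r))
    return pd.DataFrame(rows)


class TestNormalizeRatios:
    def test_control_self_normalizes_to_one(self):
        df = colonies_frame({"siOTP-NT": ("control_nt", [0.8, 0.9, 1.0])})
        out = normalize_to_control(df)
        assert out["ratio_norm"].mean() == pytest.approx(1.0)

    def test_target_scaled_by_control_mean(self):
        df = colonies_frame({"siOTP-NT": ("control_nt", [0.85, 0.85]),
                             "GENE": ("target", [0.68])})
        out = normalize_to_control(df)
        assert out.loc[out.condition == "GENE", "ratio_norm"].iloc[0] == \
            pytest.approx(0.8)

    def test_rank_order_preserved(self, rng):
        ratios = list(rng.uniform(0.4, 1.0, 20))
        df = colonies_frame({"siOTP-NT": ("control_nt", [0.9, 0.95]),
                             "GENE": ("target", ratios)})
        out = normalize_to_control(df)
        sub = out[out.condition == "GENE"]
        assert np.array_equal(np.argsort(sub["ratio"]), np.argsort(sub["ratio_norm"]))

    def test_idempotent_on_normalized_data(self):
        df = colonies_frame({"siOTP-NT": ("control_nt", [0.8, 1.0]),
                             "GENE": ("target", [0.6, 0.7])})
        once = normalize_to_control(df)
        again = normalize_to_control(
            once.drop(columns="ratio").rename(columns={"ratio_norm": "ratio"}))
        assert np.allclose(again["ratio"], again["ratio_norm"])

    def test_missing_control_names_plate(self):
        df = colonies_frame({"GENE": ("target", [0.6, 0.7])}, plate="P9")
        with pytest.raises(ValueError, match="P9"):
            normalize_to_control(df)


class TestNormalizeViability:
    def make(self, counts):
        rows = [dict(plate_id="P1", well=f"w{i}", condition=c, role=r,
                     well_count=n) for i, (c, r, n) in enumerate(counts)]
        return pd.DataFrame(rows)

    def test_half_of_control(self):
        via = self.make([("siOTP-NT", "control_nt", 2000),
                         ("siOTP-NT", "control_nt", 2200),
                         ("GENE", "target", 1050)])
        out = normalize_viability(via)
        assert out.loc[out.condition == "GENE", "viability"].iloc[0] == \
            pytest.approx(0.5)
        assert out.loc[out.role == "control_nt", "viability"].mean() == \
            pytest.approx(1.0)

    def test_lethal_control_near_zero(self):
        via = self.make([("siOTP-NT", "control_nt", 2000),
                         ("siTOX", "control_tox", 15)])
        out = normalize_viability(via)
        assert out.loc[out.condition == "siTOX", "viability"].iloc[0] <= 0.01

    def test_missing_control_rejected(self):
        via = self.make([("GENE", "target", 500)])
        with pytest.raises(ValueError, match="control_nt"):
            normalize_viability(via)


class TestClassification:
    def test_impairment_boundary_at_half_control(self):
        p = ScreenParams()
        assert classify_phenotype("target", True, "decrease", 0.49, p) == \
            "viability_impaired"
        assert classify_phenotype("target", True, "decrease", 0.51, p) == \
            "suppressor_candidate"

    def test_increase_with_viability_is_promoter(self):
        assert classify_phenotype("target", True, "increase", 0.95) == \
            "promoter_candidate"

    def test_non_significant_is_no_hit(self):
        assert classify_phenotype("target", False, "none", 0.9) == "no_hit"

    def test_roles_short_circuit(self):
        assert classify_phenotype("control_nt", False, "none", 1.0) == "control"
        assert classify_phenotype("tumor_alone", False, "none", None) == \
            "tumor_alone"

    def test_hit_without_viability_rejected(self):
        with pytest.raises(ValueError, match="viability"):
            classify_phenotype("target", True, "decrease", None)


class TestDunnettHits:
    def test_hits_and_directions(self, rng):
        groups = {"down": rng.normal(0.7, 0.05, 12),
                  "same": rng.normal(0.95, 0.05, 12),
                  "up_tiny": rng.normal(0.96, 0.05, 2)}
        ctl = rng.normal(0.95, 0.05, 10)
        out = dunnett_hits(groups, ctl).set_index("condition")
        assert bool(out.loc["down", "hit"]) and out.loc["down", "direction"] == "decrease"
        assert not out.loc["same", "hit"]
        assert not bool(out.loc["up_tiny", "testable"])  # n=2 < min group size
        assert out.attrs["anova_p"] < 0.05

    def test_raw_and_normalized_hits_agree_within_plate(self, rng):
        # dividing every colony by the plate control mean is a positive
        # scalar: within-plate t statistics are unchanged
        groups = {"a": rng.normal(0.8, 0.05, 10), "b": rng.normal(0.95, 0.05, 10)}
        ctl = rng.normal(0.95, 0.05, 10)
        scale = ctl.mean()
        raw = dunnett_hits(groups, ctl)
        norm = dunnett_hits({k: v / scale for k, v in groups.items()}, ctl / scale)
        assert np.allclose(raw["p_value"], norm["p_value"], atol=1e-9)
        assert list(raw["hit"]) == list(norm["hit"])


class TestScreenReport:
    def test_two_plates_normalized_separately(self, rng):
        dfs = []
        for plate, ctl_level in [("R1", 0.9), ("R2", 0.7)]:
            dfs.append(colonies_frame(
                {"siOTP-NT": ("control_nt", list(rng.normal(ctl_level, 0.03, 8))),
                 "GENE": ("target", list(rng.normal(ctl_level, 0.03, 8)))},
                plate=plate))
        rep = screen_report(pd.concat(dfs, ignore_index=True), None)
        gene = rep[rep.condition == "GENE"]
        assert len(gene) == 2  # one row per run
        assert np.allclose(gene["ratio_norm_mean"], 1.0, atol=0.05)
        assert not gene["hit"].any()

    def test_empty_condition_reported_untestable(self, rng):
        df = colonies_frame({"siOTP-NT": ("control_nt", list(rng.normal(0.9, 0.03, 6)))})
        via = pd.DataFrame([
            dict(plate_id="P1", well="w1", condition="siOTP-NT",
                 role="control_nt", well_count=1000),
            dict(plate_id="P1", well="w2", condition="GHOST", role="target",
                 well_count=900)])
        rep = screen_report(df, via)
        ghost = rep[rep.condition == "GHOST"]
        assert len(ghost) == 1
        assert ghost["n_colonies"].iloc[0] == 0
        assert not ghost["testable"].iloc[0]

    def test_end_to_end_synthetic_screen(self):
        res = run_synthetic_screen(recovery_screen_spec(seed=0))
        s = res["summary"].set_index("condition")
        assert s.loc["siINV", "phenotype_class"] == "suppressor_candidate"
        assert s.loc["siLETHAL", "phenotype_class"] == "viability_impaired"
        assert s.loc["siNULL1", "phenotype_class"] == "no_hit"
        assert s.loc["siNULL2", "phenotype_class"] == "no_hit"
        assert s.loc["siOTP-NT", "ratio_norm_mean"] == pytest.approx(1.0)
        # measured colony ratios track the generator's exact polygon truth
        truth = res["ground_truth"].groupby("condition")["true_ratio"].mean()
        meas = res["summary"]["ratio_raw_mean"]
        assert s.loc["siINV", "ratio_raw_mean"] == pytest.approx(
            truth["siINV"], abs=0.08)


class TestPlateLayout:
    def test_valid_layout_roundtrip(self, plate_dir):
        layout = PlateLayout.from_csv(plate_dir / "plate_map.csv")
        assert layout.plates == ["P1"]
        assert (layout.for_plate("P1")["role"] == "control_nt").any()

    def test_missing_control_rejected(self):
        df = pd.DataFrame({"plate_id": ["P1"], "well": ["A01"],
                           "condition": ["g"], "role": ["target"]})
        with pytest.raises(ValueError, match="control_nt"):
            PlateLayout(df)

    def test_duplicate_well_rejected(self):
        df = pd.DataFrame({"plate_id": ["P1", "P1"], "well": ["A01", "A01"],
                           "condition": ["g", "h"],
                           "role": ["control_nt", "target"]})
        with pytest.raises(ValueError, match="duplicate"):
            PlateLayout(df)

    def test_unknown_role_rejected(self):
        df = pd.DataFrame({"plate_id": ["P1"], "well": ["A01"],
                           "condition": ["g"], "role": ["wildcard"]})
        with pytest.raises(ValueError, match="role"):
            PlateLayout(df)


class TestScreenParams:
    @pytest.mark.parametrize("kw", [dict(alpha=0), dict(alpha=1),
                                    dict(viability_min=1.5),
                                    dict(min_colonies_per_group=1)])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            ScreenParams(**kw)
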