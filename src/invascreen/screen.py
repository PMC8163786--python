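"""Per-plate aggregation, normalization, hit-calling and phenotype
classification for the siRNA screen.

Every quantity is normalized to the same plate's non-targeting-control
(siOTP-NT) wells: colony ratios to the mean control colony ratio, well
nuclei counts to the mean control well count.  Hypothesis tests (one-way
ANOVA followed by Dunnett's many-to-one comparisons) always run on raw
colony ratios, never on normalized values; individual colonies are the
observations, which is a pseudo-replication caveat inherited from the
screen design (wells are not independent biological replicates).

Phenotype classes for target conditions:

* ``suppressor_candidate`` — ratio significantly decreased (more invasive
  growth) with viability ≥ 50% of control: the knocked-down gene is a
  candidate suppressor of tumour-cell invasion.
* ``viability_impaired``  — ratio significantly decreased but viability
  < 50% of control: loss of tumour control confounded by myoepithelial
  death.
* ``promoter_candidate``  — ratio significantly increased (smoother
  colonies) with intact viability: the gene normally promotes invasion.
* ``no_hit``              — anything else.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import dunnett_pvalues, one_way_anova_pvalue

ROLES = ("target", "control_nt", "control_tox", "mock", "tumor_alone")


@dataclass(frozen=True)
class ScreenParams:
    """Hit-calling thresholds.

    ``alpha`` is the two-sided Dunnett significance level; ``viability_min``
    the impairment boundary as a fraction of control (viability strictly
    below it counts as impaired); ``min_colonies_per_group`` the smallest
    group testable by the many-to-one comparison.  ``require_omnibus`` gates
    Dunnett calls on a significant one-way ANOVA when set (off by default;
    the omnibus p is always reported either way).
    """

    alpha: float = 0.05
    viability_min: float = 0.5
    min_colonies_per_group: int = 3
    require_omnibus: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.viability_min < 1:
            raise ValueError(
                f"viability_min must be in (0, 1), got {self.viability_min}")
        if self.min_colonies_per_group < 2:
            raise ValueError("min_colonies_per_group must be >= 2")


class PlateLayout:
    """Well → (condition, role) map for one or more plates.

    Wraps a DataFrame with columns plate_id, well, condition, role.  Each
    (plate_id, well) appears once and every plate carries at least one
    control_nt well (the normalizer).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"plate_id", "well", "condition", "role"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"plate map is missing columns: {sorted(missing)}")
        bad_roles = set(table["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(
                f"unknown roles {sorted(bad_roles)}; expected one of {ROLES}")
        dup = table.duplicated(subset=["plate_id", "well"])
        if dup.any():
            wells = table.loc[dup, ["plate_id", "well"]].values.tolist()
            raise ValueError(f"duplicate wells in plate map: {wells}")
        for plate, sub in table.groupby("plate_id"):
            if not (sub["role"] == "control_nt").any():
                raise ValueError(
                    f"plate {plate!r} has no control_nt well; a non-targeting "
                    f"control is required as the per-plate normalizer")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        return cls(pd.read_csv(path, dtype=str))

    @property
    def plates(self) -> list[str]:
        return list(dict.fromkeys(self.table["plate_id"]))

    def for_plate(self, plate_id: str) -> pd.DataFrame:
        return self.table[self.table["plate_id"] == plate_id]


def normalize_to_control(colonies: pd.DataFrame) -> pd.DataFrame:
    """Add a ``ratio_norm`` column: each colony's ratio divided by the mean
    ratio of its plate's control_nt colonies.  Raw ratios are retained.

    ``colonies`` needs columns plate_id, role, ratio.
    """
    out = colonies.copy()
    out["ratio_norm"] = np.nan
    for plate, sub in out.groupby("plate_id"):
        ctl = sub.loc[sub["role"] == "control_nt", "ratio"]
        if ctl.empty:
            raise ValueError(
                f"plate {plate!r} has no control_nt colonies passing the size "
                f"filter; cannot normalize")
        out.loc[sub.index, "ratio_norm"] = sub["ratio"] / ctl.mean()
    return out


def normalize_viability(viability: pd.DataFrame) -> pd.DataFrame:
    """Add a ``viability`` column: well_count divided by the mean control_nt
    well_count of the same plate.

    ``viability`` needs columns plate_id, well, condition, role, well_count.
    Duplicate wells of one condition stay separate rows; condition-level
    averaging (after normalization) happens in :func:`screen_report`.
    """
    out = viability.copy()
    out["viability"] = np.nan
    for plate, sub in out.groupby("plate_id"):
        ctl = sub.loc[sub["role"] == "control_nt", "well_count"]
        if ctl.empty:
            raise ValueError(
                f"plate {plate!r} has no control_nt viability record; cannot "
                f"normalize viability")
        out.loc[sub.index, "viability"] = sub["well_count"] / ctl.mean()
    return out


def dunnett_hits(groups: dict[str, np.ndarray], control: np.ndarray,
                 params: ScreenParams | None = None) -> pd.DataFrame:
    """ANOVA + Dunnett hit calls of raw per-colony ratios vs the control.

    Groups (or a control) smaller than ``min_colonies_per_group`` are
    flagged untestable rather than silently dropped.  Returns one row per
    condition with columns condition, n_colonies, raw statistics, p-value,
    direction, hit, testable; the omnibus ANOVA p is stored in
    ``result.attrs['anova_p']``.
    """
    if params is None:
        params = ScreenParams()
    control = np.asarray(control, dtype=float)
    names = list(groups)
    arrays = {c: np.asarray(v, dtype=float) for c, v in groups.items()}
    testable = {c: (arrays[c].size >= params.min_colonies_per_group
                    and control.size >= params.min_colonies_per_group)
                for c in names}
    tested = [c for c in names if testable[c]]

    anova_p = np.nan
    pvals: dict[str, float] = {}
    stats_: dict[str, float] = {}
    if tested:
        res = dunnett_pvalues([arrays[c] for c in tested], control)
        anova_p = one_way_anova_pvalue([arrays[c] for c in tested] + [control])
        for c, p, t in zip(tested, res.pvalue, res.statistic):
            pvals[c] = float(p)
            stats_[c] = float(t)

    rows = []
    for c in names:
        g = arrays[c]
        p = pvals.get(c, np.nan)
        gate_ok = (not params.require_omnibus) or (anova_p < params.alpha)
        hit = bool(testable[c] and gate_ok and p < params.alpha)
        if hit:
            direction = "decrease" if g.mean() < control.mean() else "increase"
        else:
            direction = "none"
        rows.append(dict(
            condition=c, n_colonies=int(g.size),
            ratio_raw_mean=float(g.mean()) if g.size else np.nan,
            ratio_raw_sem=float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else np.nan,
            statistic=stats_.get(c, np.nan), p_value=p,
            direction=direction, hit=hit, testable=bool(testable[c])))
    out = pd.DataFrame(rows)
    out.attrs["anova_p"] = anova_p
    return out


def classify_phenotype(role: str, hit: bool, direction: str,
                       viability: float | None,
                       params: ScreenParams | None = None) -> str:
    """Phenotype class of one condition (see module docstring for classes)."""
    if params is None:
        params = ScreenParams()
    if role in ("control_nt", "control_tox", "mock"):
        return "control"
    if role == "tumor_alone":
        return "tumor_alone"
    if not hit:
        return "no_hit"
    if viability is None or not np.isfinite(viability):
        raise ValueError(
            "viability is required to classify a hit target condition")
    if direction == "decrease":
        return ("viability_impaired" if viability < params.viability_min
                else "suppressor_candidate")
    if direction == "increase" and viability >= params.viability_min:
        return "promoter_candidate"
    return "no_hit"


def screen_report(colonies: pd.DataFrame, viability: pd.DataFrame | None,
                  params: ScreenParams | None = None) -> pd.DataFrame:
    """Full per-plate screen summary: one row per condition per plate.

    ``colonies``: per-colony table with plate_id, well, condition, role,
    ratio (the shape module's output joined with the plate map).
    ``viability``: per-well table with plate_id, well, condition, role,
    well_count, or None if no 2-D companion data exist.

    Normalization is strictly per plate — a condition screened on two plates
    yields two rows, each normalized to its own plate's control.  Conditions
    with no surviving colonies are reported untestable, not dropped.
    """
    if params is None:
        params = ScreenParams()
    colonies = normalize_to_control(colonies)
    via = normalize_viability(viability) if viability is not None and len(viability) else None

    reports = []
    for plate, sub in colonies.groupby("plate_id", sort=False):
        ctl_raw = sub.loc[sub["role"] == "control_nt", "ratio"].to_numpy()
        target_groups = {c: g["ratio"].to_numpy()
                         for c, g in sub[sub["role"] == "target"].groupby("condition", sort=False)}
        hits = dunnett_hits(target_groups, ctl_raw, params) if target_groups \
            else pd.DataFrame(columns=["condition"])
        hits_ix = hits.set_index("condition") if len(hits) else hits

        # Condition-level viability (duplicate wells averaged after
        # normalization).
        via_mean: dict[str, float] = {}
        if via is not None:
            vp = via[via["plate_id"] == plate]
            via_mean = vp.groupby("condition")["viability"].mean().to_dict()

        # Union of conditions present in colonies or viability for the plate.
        conds = list(dict.fromkeys(
            list(sub[["condition", "role"]].itertuples(index=False, name=None))
            + ([(c, r) for c, r, in vp[["condition", "role"]].drop_duplicates()
                .itertuples(index=False, name=None)] if via is not None else [])))
        for cond, role in conds:
            g = sub[sub["condition"] == cond]
            raw = g["ratio"].to_numpy()
            norm = g["ratio_norm"].to_numpy()
            n = raw.size
            v = via_mean.get(cond, np.nan)
            if role == "target" and cond in getattr(hits_ix, "index", []):
                h = hits_ix.loc[cond]
                p, hit, direction, testable = (float(h["p_value"]), bool(h["hit"]),
                                               str(h["direction"]), bool(h["testable"]))
                stat = float(h["statistic"])
            else:
                p, hit, direction, testable, stat = np.nan, False, "none", False, np.nan
            phen = classify_phenotype(role, hit, direction,
                                      None if not np.isfinite(v) else v, params)
            reports.append(dict(
                plate_id=plate, condition=cond, role=role, n_colonies=int(n),
                ratio_raw_mean=float(raw.mean()) if n else np.nan,
                ratio_raw_sem=float(raw.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                ratio_norm_mean=float(norm.mean()) if n else np.nan,
                viability=v,
                anova_p=hits.attrs.get("anova_p", np.nan) if role == "target" else np.nan,
                p_value=p, statistic=stat, direction=direction, hit=hit,
                testable=testable, phenotype_class=phen))
    cols = ["plate_id", "condition", "role", "n_colonies", "ratio_raw_mean",
            "ratio_raw_sem", "ratio_norm_mean", "viability", "anova_p",
            "p_value", "statistic", "direction", "hit", "testable",
            "phenotype_class"]
    return pd.DataFrame(reports, columns=cols)
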