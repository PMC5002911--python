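"""Cohort-level statistics: test-retest repeatability, group/muscle ANOVA,
and correlation of the hyperemic response with jump performance.

The study design has three subject groups (two athlete groups and sedentary
controls); controls are imaged twice for test-retest repeatability.
Repeatability is summarized per muscle and parameter by the between-subject
coefficient of variation at each visit plus a paired two-sided comparison
across visits.  Group and muscle effects are assessed with one-way ANOVA
(D'Agostino-Pearson omnibus normality per cell, Tukey HSD post hoc when the
omnibus test rejects), and the link to lower-extremity function with
Pearson correlation between per-muscle PHV and maximal jump distances.

TTR is undefined for series that never returned to baseline; all statistics
here average TTR over recovered cases only and report the pair/cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError
from .indices import BoldIndices
from .io import MUSCLES

GROUPS = ("linemen", "backs_receivers", "controls")
PARAMETERS = ("phv", "ttp", "miv", "ttr")


@dataclass
class SubjectRecord:
    """One subject at one visit: per-muscle indices plus jump distances."""

    subject_id: str
    group: str
    visit: int
    indices: dict[str, BoldIndices]
    vertical_jump: float | None = None  # cm
    broad_jump: float | None = None  # cm
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise StatsError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.visit not in (1, 2):
            raise StatsError(f"visit must be 1 or 2, got {self.visit}")
        if self.visit == 2 and self.group != "controls":
            raise StatsError("visit 2 exists only for the control group")
        if self.excluded and not self.exclusion_reason:
            raise StatsError(f"{self.subject_id}: excluded subjects need a reason")

    def value(self, muscle: str, parameter: str) -> float:
        """Parameter value for one muscle; NaN for TTR of a non-recovered series."""
        idx = self.indices[muscle]
        if parameter == "ttr":
            return float(idx.ttr) if idx.recovered else math.nan
        return float(getattr(idx, parameter))


@dataclass(frozen=True)
class RepeatabilityResult:
    muscle: str
    parameter: str
    visit1_mean: float
    visit1_sd: float
    visit1_cv: float
    visit2_mean: float
    visit2_sd: float
    visit2_cv: float
    paired_p: float  # NaN when the paired test is undefined (zero variance)
    n_pairs: int


@dataclass(frozen=True)
class CellSummary:
    n: int
    mean: float
    sd: float
    normality_p: float  # NaN when not assessable (n < 8)


@dataclass(frozen=True)
class GroupStatResult:
    factor: str  # "group" (compared within one muscle) or "muscle" (within one group)
    stratum: str  # the muscle or group the comparison is made within
    parameter: str
    anova_f: float
    anova_p: float
    cells: dict[str, CellSummary] = field(default_factory=dict)
    posthoc: dict[tuple[str, str], float] | None = None  # only when omnibus p < alpha


@dataclass(frozen=True)
class CorrelationResult:
    muscle: str
    functional_measure: str  # "vertical" | "broad"
    r: float
    p: float
    n: int


def coefficient_of_variation(mean: float, sd: float) -> float:
    """Between-subject CV in percent: ``100 * sd / |mean|``.

    The absolute mean makes the CV of a negative-valued parameter (MIV)
    positive, matching the convention of repeatability tables.
    """
    if mean == 0:
        raise StatsError("CV undefined for zero mean")
    if sd < 0:
        raise StatsError("negative SD")
    return 100.0 * sd / abs(mean)


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Long table: one row per subject x visit x muscle."""
    rows = []
    for rec in records:
        for muscle, idx in rec.indices.items():
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "visit": rec.visit,
                    "muscle": muscle,
                    "phv": idx.phv,
                    "ttp": idx.ttp,
                    "miv": idx.miv,
                    "ttr": idx.ttr if idx.recovered else math.nan,
                    "recovered": idx.recovered,
                    "vertical_jump": rec.vertical_jump,
                    "broad_jump": rec.broad_jump,
                    "excluded": rec.excluded,
                    "exclusion_reason": rec.exclusion_reason or "",
                }
            )
    return pd.DataFrame(rows)


def records_from_frame(
    df: pd.DataFrame, exclusions: dict[str, str] | None = None
) -> list[SubjectRecord]:
    """Inverse of :func:`records_to_frame`; ``exclusions`` maps subject_id -> reason."""
    exclusions = exclusions or {}
    records = []
    for (sid, visit), sub in df.groupby(["subject_id", "visit"], sort=True):
        indices = {}
        for row in sub.itertuples():
            recovered = bool(row.recovered) and not (
                isinstance(row.ttr, float) and math.isnan(row.ttr)
            )
            indices[row.muscle] = BoldIndices(
                phv=float(row.phv),
                ttp=float(row.ttp),
                miv=float(row.miv),
                ttr=float(row.ttr) if recovered else None,
                recovered=recovered,
                muscle=str(row.muscle),
            )
        first = sub.iloc[0]
        vertical = None if pd.isna(first.get("vertical_jump")) else float(first["vertical_jump"])
        broad = None if pd.isna(first.get("broad_jump")) else float(first["broad_jump"])
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                group=str(first["group"]),
                visit=int(visit),
                indices=indices,
                vertical_jump=vertical,
                broad_jump=broad,
                excluded=str(sid) in exclusions,
                exclusion_reason=exclusions.get(str(sid)),
            )
        )
    return records


def _paired_p(v1: np.ndarray, v2: np.ndarray, method: str) -> float:
    diff = v1 - v2
    if np.allclose(diff.std(ddof=1) if diff.size > 1 else 0.0, 0.0):
        return math.nan  # zero-variance differences: paired test undefined
    if method == "wilcoxon":
        return float(sps.wilcoxon(v1, v2).pvalue)
    return float(sps.ttest_rel(v1, v2).pvalue)


def repeatability_table(
    records: list[SubjectRecord],
    parameters: tuple[str, ...] = PARAMETERS,
    muscles: tuple[str, ...] | None = None,
    paired_method: str = "ttest",
) -> list[RepeatabilityResult]:
    """Test-retest repeatability over control subjects seen at both visits.

    For each muscle x parameter: per-visit mean, sample SD (n-1), CV, and a
    two-sided paired p-value across visits (paired t-test by default,
    Wilcoxon signed-rank with ``paired_method="wilcoxon"``).  TTR pairs where
    either visit did not recover are dropped; ``n_pairs`` reports the count
    actually used.
    """
    by_visit: dict[int, dict[str, SubjectRecord]] = {1: {}, 2: {}}
    for rec in records:
        if rec.group == "controls" and not rec.excluded:
            by_visit[rec.visit][rec.subject_id] = rec
    paired_ids = sorted(set(by_visit[1]) & set(by_visit[2]))
    if len(paired_ids) < 2:
        raise StatsError(
            f"repeatability needs >= 2 control subjects with both visits, got {len(paired_ids)}"
        )
    if muscles is None:
        muscles = tuple(
            m for m in MUSCLES if m in next(iter(by_visit[1].values())).indices
        ) or tuple(next(iter(by_visit[1].values())).indices)
    out = []
    for muscle in muscles:
        for param in parameters:
            v1 = np.array([by_visit[1][s].value(muscle, param) for s in paired_ids])
            v2 = np.array([by_visit[2][s].value(muscle, param) for s in paired_ids])
            ok = ~(np.isnan(v1) | np.isnan(v2))
            v1, v2 = v1[ok], v2[ok]
            if v1.size < 2:
                raise StatsError(f"{muscle}/{param}: fewer than 2 usable pairs")
            out.append(
                RepeatabilityResult(
                    muscle=muscle,
                    parameter=param,
                    visit1_mean=float(v1.mean()),
                    visit1_sd=float(v1.std(ddof=1)),
                    visit1_cv=coefficient_of_variation(v1.mean(), v1.std(ddof=1)),
                    visit2_mean=float(v2.mean()),
                    visit2_sd=float(v2.std(ddof=1)),
                    visit2_cv=coefficient_of_variation(v2.mean(), v2.std(ddof=1)),
                    paired_p=_paired_p(v1, v2, paired_method),
                    n_pairs=int(v1.size),
                )
            )
    return out


def _normality_p(values: np.ndarray) -> float:
    # D'Agostino-Pearson omnibus test; requires n >= 8 to be assessable.
    if values.size < 8:
        return math.nan
    return float(sps.normaltest(values).pvalue)


def _posthoc(cells: dict[str, np.ndarray], method: str) -> dict[tuple[str, str], float]:
    names = list(cells)
    pairs: dict[tuple[str, str], float] = {}
    if method == "bonferroni":
        m = len(names) * (len(names) - 1) // 2
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                p = float(sps.ttest_ind(cells[a], cells[b]).pvalue)
                pairs[(a, b)] = min(1.0, p * m)
    else:  # Tukey HSD
        res = sps.tukey_hsd(*cells.values())
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    pairs[(a, b)] = float(res.pvalue[i, j])
    return pairs


def _one_way(
    cells: dict[str, np.ndarray],
    factor: str,
    stratum: str,
    parameter: str,
    alpha: float,
    posthoc: str,
) -> GroupStatResult:
    for name, vals in cells.items():
        if vals.size < 2:
            raise StatsError(f"{factor} ANOVA cell {name!r} has n < 2")
        if np.allclose(vals.std(ddof=1), 0.0):
            raise StatsError(f"{factor} ANOVA cell {name!r} has zero variance")
    f, p = sps.f_oneway(*cells.values())
    if math.isnan(p):
        # exact ties can produce a tiny negative F and a NaN p; clamp
        f = max(float(f), 0.0)
        k = len(cells)
        n_total = sum(v.size for v in cells.values())
        p = float(sps.f.sf(f, k - 1, n_total - k))
    summaries = {
        name: CellSummary(
            n=int(v.size),
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)),
            normality_p=_normality_p(v),
        )
        for name, v in cells.items()
    }
    pairs = _posthoc(cells, posthoc) if (p < alpha and len(cells) > 1) else None
    return GroupStatResult(
        factor=factor,
        stratum=stratum,
        parameter=parameter,
        anova_f=float(f),
        anova_p=float(p),
        cells=summaries,
        posthoc=pairs,
    )


def group_muscle_anova(
    records: list[SubjectRecord],
    parameter: str,
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> list[GroupStatResult]:
    """One-way ANOVAs across groups (within each muscle) and across muscles
    (within each group), on visit-1, non-excluded subjects.

    Post-hoc pairwise p-values (Tukey HSD by default, Bonferroni-corrected
    t-tests with ``posthoc="bonferroni"``) are attached only when the
    omnibus p is below ``alpha``.  TTR uses recovered cases only.
    """
    if parameter not in PARAMETERS:
        raise StatsError(f"unknown parameter {parameter!r}")
    usable = [r for r in records if r.visit == 1 and not r.excluded]
    if not usable:
        raise StatsError("no usable visit-1 records")
    muscles = sorted({m for r in usable for m in r.indices})
    groups = [g for g in GROUPS if any(r.group == g for r in usable)]

    def cell(group: str, muscle: str) -> np.ndarray:
        vals = np.array(
            [r.value(muscle, parameter) for r in usable if r.group == group and muscle in r.indices]
        )
        return vals[~np.isnan(vals)]

    results = []
    if len(groups) > 1:
        for muscle in muscles:
            cells = {g: cell(g, muscle) for g in groups}
            results.append(_one_way(cells, "group", muscle, parameter, alpha, posthoc))
    if len(muscles) > 1:
        for group in groups:
            cells = {m: cell(group, m) for m in muscles}
            results.append(_one_way(cells, "muscle", group, parameter, alpha, posthoc))
    if not results:
        raise StatsError("need at least two groups or two muscles to compare")
    return results


def jump_correlation(
    records: list[SubjectRecord],
    muscle: str,
    functional_measure: str,
) -> CorrelationResult:
    """Pearson correlation of per-muscle PHV with a jump distance.

    Pools visit-1, non-excluded subjects across groups that have both the
    PHV and the requested jump measure.
    """
    if functional_measure not in ("vertical", "broad"):
        raise StatsError(f"functional_measure must be 'vertical' or 'broad', got {functional_measure!r}")
    attr = f"{functional_measure}_jump"
    xs, ys = [], []
    for rec in records:
        if rec.visit != 1 or rec.excluded or muscle not in rec.indices:
            continue
        jump = getattr(rec, attr)
        if jump is None:
            continue
        xs.append(rec.indices[muscle].phv)
        ys.append(float(jump))
    x, y = np.asarray(xs), np.asarray(ys)
    if x.size < 3:
        raise StatsError(f"correlation needs >= 3 usable subjects, got {x.size}")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        raise StatsError("zero variance in PHV or jump values")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        muscle=muscle, functional_measure=functional_measure, r=float(r), p=float(p), n=int(x.size)
    )
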