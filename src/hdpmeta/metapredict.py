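"""Meta-prediction over ordinal air-pollution levels.

Study-level outcomes (genotype percentages per arm and per-study risk
ratios) are partitioned over the ordinal pollution levels by a
single-depth binary split judged with the small-sample-corrected Akaike
criterion (AICc); group differences are additionally screened with
Tukey-Kramer simultaneous comparisons, a polynomial trend fit, and a 2-D
density binning for heat maps.  No rendering happens here: every
operation returns coordinates, counts or tabulated statistics.

Candidate splits respect ordinal contiguity — with analysed levels
{2, 3, 4} the only binary candidates are {2}|{3,4} and {2,3}|{4}, each
compared against the no-split model.  The model for a candidate is
"one normal mean per group, common variance", so a candidate with g
groups has g + 1 parameters; AICc(sse, n, k) =
n*ln(sse/n) + 2k + 2k(k+1)/(n-k-1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genetics import contrast_table
from .pooling import study_effect
from .types import (
    Contrast,
    DegenerateInputError,
    DoubleZeroError,
    EffectMeasure,
    StudyRecord,
)

log = logging.getLogger(__name__)

#: Outcome variables: arm percentages for the four contrasts of interest
#: and per-study risk ratios.  "carrier" is the dominant TT+CT grouping.
OUTCOME_VARIABLES = (
    "pct_variant_case",
    "pct_variant_ctrl",
    "pct_het_case",
    "pct_het_ctrl",
    "pct_wild_case",
    "pct_wild_ctrl",
    "pct_carrier_case",
    "pct_carrier_ctrl",
    "rr_variant",
    "rr_het",
    "rr_wild",
    "rr_carrier",
)

_PCT_CONTRASTS = {
    "variant": Contrast.HOMO_VARIANT,
    "het": Contrast.HET,
    "wild": Contrast.WILD,
    "carrier": Contrast.DOMINANT,
}


@dataclass(frozen=True)
class StudyOutcome:
    study_id: str
    variable: str
    value: float
    pollution_level: int


def compute_outcomes(
    studies: Sequence[StudyRecord], correction: float = 0.5
) -> list[StudyOutcome]:
    """Study-level outcomes for the pollution analysis.

    Percentages are full precision (rounding is a reporting concern);
    risk ratios come from the same estimator as the pooled analysis.
    Outcomes whose effect is undefined (zero exposed in both arms) are
    omitted with a log entry.
    """
    out: list[StudyOutcome] = []
    for s in studies:
        level = s.air_pollution_level
        for name, contrast in _PCT_CONTRASTS.items():
            out.append(
                StudyOutcome(
                    s.study_id,
                    f"pct_{name}_case",
                    100.0 * contrast.exposed(s.cases) / s.cases.total,
                    level,
                )
            )
            out.append(
                StudyOutcome(
                    s.study_id,
                    f"pct_{name}_ctrl",
                    100.0 * contrast.exposed(s.controls) / s.controls.total,
                    level,
                )
            )
            table = contrast_table(s.cases, s.controls, contrast)
            try:
                est = study_effect(table, EffectMeasure.RR, correction)
            except DoubleZeroError:
                log.info(
                    "study %s: rr_%s undefined (zero exposed in both arms); omitted",
                    s.study_id,
                    name,
                )
                continue
            out.append(StudyOutcome(s.study_id, f"rr_{name}", est.effect, level))
    return out


def outcomes_by_level(
    outcomes: Iterable[StudyOutcome], variable: str
) -> dict[int, np.ndarray]:
    """Values of one outcome variable grouped by pollution level,
    levels in ascending order."""
    grouped: dict[int, list[float]] = {}
    for o in outcomes:
        if o.variable == variable:
            grouped.setdefault(o.pollution_level, []).append(o.value)
    return {lvl: np.asarray(grouped[lvl], dtype=float) for lvl in sorted(grouped)}


def aicc(sse: float, n: int, n_params: int) -> float:
    """Small-sample-corrected AIC for a Gaussian model summarised by its
    residual sum of squares: n*ln(sse/n) + 2k + 2k(k+1)/(n-k-1).

    Undefined (raises) when n <= k + 1.  A perfect fit (sse = 0) maps to
    -inf, which compares correctly against any finite candidate.
    """
    if sse < 0:
        raise ValueError("sse must be non-negative")
    if n <= n_params + 1:
        raise DegenerateInputError(
            f"AICc undefined for n={n}, k={n_params} (needs n > k+1)"
        )
    k = n_params
    penalty = 2 * k + 2 * k * (k + 1) / (n - k - 1)
    if sse / n == 0.0:  # exact or underflowed perfect fit
        return float("-inf")
    return n * math.log(sse / n) + penalty


@dataclass(frozen=True)
class GroupStats:
    levels: tuple[int, ...]
    count: int
    mean: float
    sd: float


@dataclass(frozen=True)
class CandidateSplit:
    groups: tuple[tuple[int, ...], ...]  # contiguous level sets
    sse: float
    n_params: int
    aicc: float


@dataclass(frozen=True)
class PartitionResult:
    variable: str
    candidates: tuple[CandidateSplit, ...]  # includes the no-split model
    chosen: CandidateSplit
    group_stats: tuple[GroupStats, ...]

    @property
    def is_split(self) -> bool:
        return len(self.chosen.groups) > 1


def _group_sse(groups: Sequence[np.ndarray]) -> float:
    return float(sum(np.sum((g - g.mean()) ** 2) for g in groups))


def partition_split(
    outcomes: Sequence[StudyOutcome],
    variable: str | None = None,
    min_leaf: int = 5,
) -> PartitionResult:
    """Best single binary split of one outcome over pollution levels.

    Enumerates the no-split model and every contiguous binary cut of the
    observed levels, scores each by AICc of the group-means model, and
    returns the argmin with all candidates' AICc values as a ledger.
    Candidates with a group smaller than ``min_leaf`` are excluded; if
    every split candidate is excluded the no-split model is returned.
    Ties in AICc break toward fewer groups.
    """
    if variable is None:
        variables = {o.variable for o in outcomes}
        if len(variables) != 1:
            raise ValueError(f"outcomes mix variables {sorted(variables)}")
        variable = variables.pop()
    by_level = outcomes_by_level(outcomes, variable)
    levels = sorted(by_level)
    if len(levels) < 2:
        raise DegenerateInputError("partition needs at least two distinct levels")
    n = sum(len(v) for v in by_level.values())

    def candidate(level_groups: Sequence[Sequence[int]]) -> CandidateSplit | None:
        arrays = [np.concatenate([by_level[l] for l in grp]) for grp in level_groups]
        if len(arrays) > 1 and any(len(a) < min_leaf for a in arrays):
            return None
        k = len(arrays) + 1  # group means + common variance
        if n <= k + 1:
            return None
        sse = _group_sse(arrays)
        return CandidateSplit(
            groups=tuple(tuple(grp) for grp in level_groups),
            sse=sse,
            n_params=k,
            aicc=aicc(sse, n, k),
        )

    candidates: list[CandidateSplit] = []
    no_split = candidate([levels])
    if no_split is None:
        raise DegenerateInputError("too few observations for the no-split model")
    candidates.append(no_split)
    for cut in range(1, len(levels)):
        c = candidate([levels[:cut], levels[cut:]])
        if c is not None:
            candidates.append(c)
    # argmin AICc; ties break toward fewer groups (candidates are listed
    # simplest-first, so a stable min on (aicc, n_groups) suffices)
    chosen = min(candidates, key=lambda c: (c.aicc, len(c.groups)))
    group_stats = tuple(
        GroupStats(
            levels=grp,
            count=int(sum(len(by_level[l]) for l in grp)),
            mean=float(np.mean(np.concatenate([by_level[l] for l in grp]))),
            sd=float(np.std(np.concatenate([by_level[l] for l in grp]), ddof=1))
            if sum(len(by_level[l]) for l in grp) > 1
            else float("nan"),
        )
        for grp in chosen.groups
    )
    return PartitionResult(
        variable=variable,
        candidates=tuple(candidates),
        chosen=chosen,
        group_stats=group_stats,
    )


@dataclass(frozen=True)
class PairComparison:
    level_a: int
    level_b: int
    difference: float  # mean(level_a) - mean(level_b), ordered so >= 0
    se: float
    ci_low: float
    ci_high: float
    p_adjusted: float


@dataclass(frozen=True)
class TukeyResult:
    n_groups: int
    df_error: int
    mse: float
    comparisons: tuple[PairComparison, ...]

    def difference(self, level_i: int, level_j: int) -> float:
        """Signed mean difference mean(i) - mean(j)."""
        for c in self.comparisons:
            if (c.level_a, c.level_b) == (level_i, level_j):
                return c.difference
            if (c.level_a, c.level_b) == (level_j, level_i):
                return -c.difference
        raise KeyError((level_i, level_j))


def tukey_hsd(
    groups: Mapping[int, Sequence[float]], conf_level: float = 0.95
) -> TukeyResult:
    """Tukey-Kramer simultaneous pairwise comparisons of group means.

    MSE is the pooled within-group variance with N - g error df; for the
    pair (i, j) the SE of the mean difference is
    sqrt(MSE * (1/n_i + 1/n_j)) and the adjusted p-value comes from the
    studentized-range distribution with (g, N - g) parameters evaluated
    at q = |diff| * sqrt(2) / SE.  Simultaneous CIs use the same
    critical value.  Pairs involving an empty group are omitted.
    """
    data = {lvl: np.asarray(v, dtype=float) for lvl, v in groups.items() if len(v) > 0}
    if len(data) < 2:
        raise DegenerateInputError("Tukey comparison needs at least two groups")
    g = len(data)
    ns = {lvl: len(v) for lvl, v in data.items()}
    n_total = sum(ns.values())
    df = n_total - g
    if df < 1:
        raise DegenerateInputError("no error degrees of freedom")
    means = {lvl: float(v.mean()) for lvl, v in data.items()}
    mse = float(sum(np.sum((v - v.mean()) ** 2) for v in data.values()) / df)
    q_crit = float(stats.studentized_range.ppf(conf_level, g, df))
    comparisons = []
    levels = sorted(data)
    for i, li in enumerate(levels):
        for lj in levels[i + 1 :]:
            hi, lo = (li, lj) if means[li] >= means[lj] else (lj, li)
            diff = means[hi] - means[lo]
            se = math.sqrt(mse * (1.0 / ns[li] + 1.0 / ns[lj]))
            if se == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
                half = 0.0
            else:
                q = diff * math.sqrt(2.0) / se
                p = float(stats.studentized_range.sf(q, g, df))
                half = q_crit * se / math.sqrt(2.0)
            comparisons.append(
                PairComparison(
                    level_a=hi,
                    level_b=lo,
                    difference=diff,
                    se=se,
                    ci_low=diff - half,
                    ci_high=diff + half,
                    p_adjusted=min(max(p, 0.0), 1.0),
                )
            )
    comparisons.sort(key=lambda c: (-c.difference, c.level_a, c.level_b))
    return TukeyResult(
        n_groups=g, df_error=df, mse=mse, comparisons=tuple(comparisons)
    )


@dataclass(frozen=True)
class TrendFit:
    """Polynomial trend of an outcome on the numeric pollution level.

    ``coefficients`` are ascending (constant first); ``fitted`` maps each
    observed level to its fitted value.
    """

    variable: str
    degree: int
    coefficients: tuple[float, ...]
    fitted: dict[int, float]
    residual_ss: float


def nonlinear_fit(
    outcomes: Sequence[StudyOutcome],
    variable: str | None = None,
    degree: int = 2,
) -> TrendFit:
    """Least-squares polynomial (default quadratic) of outcome value on
    the ordinal level treated as numeric.  The degree is reduced when
    fewer distinct levels are observed than the polynomial needs."""
    if variable is None:
        variables = {o.variable for o in outcomes}
        if len(variables) != 1:
            raise ValueError(f"outcomes mix variables {sorted(variables)}")
        variable = variables.pop()
    pts = [(o.pollution_level, o.value) for o in outcomes if o.variable == variable]
    if len(pts) < 2:
        raise DegenerateInputError("trend fit needs at least two points")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    n_levels = len(np.unique(x))
    deg = min(degree, n_levels - 1)
    coeffs = np.polynomial.polynomial.polyfit(x, y, deg)
    fitted_all = np.polynomial.polynomial.polyval(x, coeffs)
    fitted = {
        int(lvl): float(np.polynomial.polynomial.polyval(float(lvl), coeffs))
        for lvl in np.unique(x)
    }
    return TrendFit(
        variable=variable,
        degree=int(deg),
        coefficients=tuple(float(c) for c in coeffs),
        fitted=fitted,
        residual_ss=float(np.sum((y - fitted_all) ** 2)),
    )


@dataclass(frozen=True)
class HeatmapGrid:
    """Frequency counts of outcome values per (level, value-bin) cell.

    Bins are half-open [low, high) with the last bin closed; values
    outside the grid are clipped into the edge bins and counted in
    ``n_clipped``.
    """

    levels: tuple[int, ...]
    y_edges: tuple[float, ...]
    counts: np.ndarray  # shape (n_levels, n_bins)
    n_clipped: int


def heatmap_bins(
    outcomes: Sequence[StudyOutcome],
    y_edges: Sequence[float],
    variable: str | None = None,
) -> HeatmapGrid:
    if variable is None:
        variables = {o.variable for o in outcomes}
        if len(variables) != 1:
            raise ValueError(f"outcomes mix variables {sorted(variables)}")
        variable = variables.pop()
    edges = np.asarray(y_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("y_edges must be a strictly increasing grid")
    pts = [(o.pollution_level, o.value) for o in outcomes if o.variable == variable]
    levels = tuple(sorted({p[0] for p in pts}))
    counts = np.zeros((len(levels), len(edges) - 1), dtype=int)
    level_index = {lvl: i for i, lvl in enumerate(levels)}
    n_clipped = 0
    for lvl, value in pts:
        if value < edges[0] or value > edges[-1]:
            n_clipped += 1
            log.info("heatmap: value %.4g clipped into edge bin", value)
        # digitize with right-open bins; the last bin is closed on top
        j = int(np.clip(np.searchsorted(edges, value, side="right") - 1, 0, len(edges) - 2))
        counts[level_index[lvl], j] += 1
    return HeatmapGrid(
        levels=levels,
        y_edges=tuple(float(e) for e in edges),
        counts=counts,
        n_clipped=n_clipped,
    )
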