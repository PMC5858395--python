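"""Per-study effect estimation and inverse-variance meta-analysis.

Effects are risk ratios (RR) or odds ratios (OR) on the log scale with
Wald standard errors.  Pooling is inverse-variance fixed-effect or
DerSimonian-Laird random-effects; the model is chosen by the Cochran Q
heterogeneity test (random when Q's p-value is below the heterogeneity
alpha, fixed otherwise).  Publication-bias diagnostics are the Egger
regression of standardized effect on precision and funnel-plot
coordinates.

The RR here is the "standardized" ratio of exposed-genotype proportions
with the full arm total as denominator: RR = (a/n1) / (c/n2).  Its log
variance is 1/a - 1/n1 + 1/c - 1/n2.  The OR from the same 2x2 is
a(n2-c) / (c(n1-a)) with log variance 1/a + 1/(n1-a) + 1/c + 1/(n2-c).
When any of the four cells {a, n1-a, c, n2-c} is zero, a
Haldane-Anscombe continuity constant (default 0.5) is added to all four
cells (raising n1 and n2 accordingly) before computing either measure.
Studies with zero exposed in both arms carry no information about the
ratio and are excluded from pooling with a logged reason.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .genetics import contrast_table
from .types import (
    Contrast,
    DoubleZeroError,
    EffectMeasure,
    InsufficientStudiesError,
    PoolingModel,
    StudyRecord,
    TwoByTwo,
)

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EffectEstimate:
    study_id: str
    measure: EffectMeasure
    log_effect: float
    se: float
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")

    @property
    def effect(self) -> float:
        return math.exp(self.log_effect)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_effect - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_effect + Z_95 * self.se)


@dataclass(frozen=True)
class PooledResult:
    model: PoolingModel
    measure: EffectMeasure
    k: int
    log_effect: float
    se: float
    z: float
    p_value: float
    Q: float
    Q_df: int
    Q_p: float
    I2: float
    tau2: float
    excluded: tuple[tuple[str, str], ...] = ()

    @property
    def effect(self) -> float:
        return math.exp(self.log_effect)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_effect - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_effect + Z_95 * self.se)


def study_effect(
    table: TwoByTwo,
    measure: EffectMeasure = EffectMeasure.RR,
    correction: float = 0.5,
) -> EffectEstimate:
    """Log RR or OR with Wald SE from one 2x2; Haldane-Anscombe corrected
    when any cell is zero.  Raises DoubleZeroError when both arms have
    zero exposed."""
    if correction < 0:
        raise ValueError("continuity correction must be >= 0")
    a, n1, c, n2 = float(table.a), float(table.n1), float(table.c), float(table.n2)
    if table.a == 0 and table.c == 0:
        raise DoubleZeroError("zero exposed in both arms")
    corrected = False
    cells = (a, n1 - a, c, n2 - c)
    if any(x == 0 for x in cells) and correction > 0:
        a += correction
        c += correction
        n1 += 2 * correction
        n2 += 2 * correction
        corrected = True
    if measure is EffectMeasure.RR:
        log_effect = math.log((a / n1) / (c / n2))
        var = 1 / a - 1 / n1 + 1 / c - 1 / n2
    else:
        b, d = n1 - a, n2 - c
        log_effect = math.log(a * d / (c * b))
        var = 1 / a + 1 / b + 1 / c + 1 / d
    return EffectEstimate(
        study_id="",
        measure=measure,
        log_effect=log_effect,
        se=math.sqrt(var),
        continuity_corrected=corrected,
    )


def _check_estimates(estimates: Sequence[EffectEstimate]) -> None:
    if not estimates:
        raise InsufficientStudiesError("no estimates to pool")
    measures = {e.measure for e in estimates}
    if len(measures) > 1:
        raise ValueError(f"mixed effect measures: {measures}")


def heterogeneity(
    estimates: Sequence[EffectEstimate],
) -> tuple[float, int, float, float, float]:
    """Cochran Q, its df and p, I^2 (%) and DerSimonian-Laird tau^2.

    Q = sum w_i (theta_i - theta_fixed)^2 with fixed-effect weights
    w_i = 1/se_i^2; I2 = max(0, 100 (Q - df) / Q);
    tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)).
    Single-study input returns (0, 0, 1, 0, 0) by convention.
    """
    _check_estimates(estimates)
    k = len(estimates)
    if k == 1:
        return 0.0, 0, 1.0, 0.0, 0.0
    theta = np.array([e.log_effect for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    mean = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - mean) ** 2))
    df = k - 1
    q_p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return q, df, q_p, i2, tau2


def _pool(
    estimates: Sequence[EffectEstimate],
    model: PoolingModel,
    tau2: float,
    het: tuple[float, int, float, float, float],
) -> PooledResult:
    if len(estimates) == 1:
        # the exact identity: no weight round-trip
        pooled = estimates[0].log_effect
        se = math.sqrt(estimates[0].se ** 2 + tau2) if tau2 else estimates[0].se
    else:
        theta = np.array([e.log_effect for e in estimates])
        w = np.array([1.0 / (e.se**2 + tau2) for e in estimates])
        pooled = float(np.sum(w * theta) / np.sum(w))
        se = float(1.0 / math.sqrt(np.sum(w)))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q, df, q_p, i2, tau2_dl = het
    return PooledResult(
        model=model,
        measure=estimates[0].measure,
        k=len(estimates),
        log_effect=pooled,
        se=se,
        z=z,
        p_value=p,
        Q=q,
        Q_df=df,
        Q_p=q_p,
        I2=i2,
        tau2=tau2_dl,
    )


def pool_fixed(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling on the log scale."""
    _check_estimates(estimates)
    het = heterogeneity(estimates)
    return _pool(estimates, PoolingModel.FIXED, 0.0, het)


def pool_random(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling: weights 1/(se^2 + tau2).

    Reduces exactly to the fixed-effect result when tau2 truncates to 0.
    """
    _check_estimates(estimates)
    het = heterogeneity(estimates)
    tau2 = het[4]
    return _pool(estimates, PoolingModel.RANDOM, tau2, het)


def select_model(q_p: float, alpha: float = 0.05) -> PoolingModel:
    """Random effects iff the heterogeneity p-value is strictly below
    alpha; fixed otherwise (including exactly at the boundary)."""
    if not 0.0 <= q_p <= 1.0:
        raise ValueError(f"Q_p must be a probability, got {q_p}")
    return PoolingModel.RANDOM if q_p < alpha else PoolingModel.FIXED


def study_estimates(
    studies: Iterable[StudyRecord],
    contrast: Contrast,
    measure: EffectMeasure = EffectMeasure.RR,
    correction: float = 0.5,
) -> tuple[list[EffectEstimate], list[tuple[str, str]]]:
    """Per-study effects for one contrast; double-zero studies go to the
    exclusion log instead of the estimate list."""
    estimates: list[EffectEstimate] = []
    excluded: list[tuple[str, str]] = []
    for s in studies:
        table = contrast_table(s.cases, s.controls, contrast)
        try:
            est = study_effect(table, measure, correction)
        except DoubleZeroError:
            excluded.append((s.study_id, f"{contrast}: zero exposed in both arms"))
            continue
        estimates.append(
            EffectEstimate(
                study_id=s.study_id,
                measure=est.measure,
                log_effect=est.log_effect,
                se=est.se,
                continuity_corrected=est.continuity_corrected,
            )
        )
    return estimates, excluded


def meta_analyze(
    studies: Sequence[StudyRecord],
    contrast: Contrast,
    measure: EffectMeasure = EffectMeasure.RR,
    alpha: float = 0.05,
    correction: float = 0.5,
) -> PooledResult:
    """Estimate, test heterogeneity, select fixed/random, pool.

    Single-study input pools as fixed (the identity).  Raises if every
    study is excluded for the contrast.
    """
    estimates, excluded = study_estimates(studies, contrast, measure, correction)
    if not estimates:
        raise InsufficientStudiesError(
            f"all studies excluded for contrast {contrast}"
        )
    het = heterogeneity(estimates)
    if len(estimates) == 1:
        model = PoolingModel.FIXED
    else:
        model = select_model(het[2], alpha)
    tau2 = het[4] if model is PoolingModel.RANDOM else 0.0
    result = _pool(estimates, model, tau2, het)
    return dataclasses.replace(result, excluded=tuple(excluded))


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    t: float
    df: int
    p_value: float
    slope: float


def egger_test(estimates: Sequence[EffectEstimate]) -> EggerResult:
    """Egger regression test for funnel-plot asymmetry.

    Unweighted OLS of the standardized effect y_i = theta_i / se_i on the
    precision x_i = 1/se_i.  The intercept estimates small-study bias;
    its t statistic has k-2 df.
    """
    if len(estimates) < 3:
        raise InsufficientStudiesError("Egger's test needs at least 3 studies")
    y = np.array([e.log_effect / e.se for e in estimates])
    x = np.array([1.0 / e.se for e in estimates])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return EggerResult(
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        t=float(fit.tvalues[0]),
        df=int(fit.df_resid),
        p_value=float(fit.pvalues[0]),
        slope=float(fit.params[1]),
    )


@dataclass(frozen=True)
class FunnelData:
    """Funnel-plot coordinates: one (effect, se) point per study plus the
    fixed-effect pooled center line.  No rendering."""

    points: tuple[tuple[str, float, float], ...]  # (study_id, effect, se)
    center_effect: float


def funnel_data(estimates: Sequence[EffectEstimate]) -> FunnelData:
    _check_estimates(estimates)
    center = pool_fixed(estimates).effect
    points = tuple((e.study_id, e.effect, e.se) for e in estimates)
    return FunnelData(points=points, center_effect=center)
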