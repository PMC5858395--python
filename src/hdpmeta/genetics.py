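"""Genotype arithmetic: allele frequencies, Hardy-Weinberg screening,
contrast 2x2 construction and reporting percentages.

Hardy-Weinberg equilibrium (HWE) is screened on the control arm with the
1-df Pearson chi-square: under random mating the three genotypes occur at
(1-p)^2, 2p(1-p), p^2 where p is the variant-allele frequency.  Departure
in controls flags possible genotyping error or population stratification;
studies are flagged, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

from .types import Contrast, DegenerateInputError, GenotypeCounts, TwoByTwo


def allele_frequency(counts: GenotypeCounts) -> float:
    """Variant-allele frequency: (2*n_variant + n_het) / (2*total)."""
    if counts.total < 1:
        raise DegenerateInputError("allele_frequency: empty arm")
    return (2 * counts.n_variant + counts.n_het) / (2 * counts.total)


@dataclass(frozen=True)
class HWEResult:
    allele_frequency_variant: float
    expected: tuple[float, float, float]  # (wild, het, variant)
    chi_square: float
    p_value: float
    in_equilibrium: bool
    monomorphic: bool


def hwe_test(controls: GenotypeCounts, alpha: float = 0.05) -> HWEResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    Expected counts come from the observed variant-allele frequency p:
    (1-p)^2*N wild, 2p(1-p)*N het, p^2*N variant.  A monomorphic sample
    (p = 0 or 1) is trivially in equilibrium and flagged as such.
    """
    p = allele_frequency(controls)
    n = controls.total
    expected = ((1 - p) ** 2 * n, 2 * p * (1 - p) * n, p**2 * n)
    if p == 0.0 or p == 1.0:
        return HWEResult(p, expected, 0.0, 1.0, True, True)
    observed = (controls.n_wild, controls.n_het, controls.n_variant)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(p, expected, chi2, p_value, p_value >= alpha, False)


def contrast_table(
    cases: GenotypeCounts, controls: GenotypeCounts, contrast: Contrast
) -> TwoByTwo:
    """Build the exposed-vs-total 2x2 for a genetic contrast.

    The denominator is always the full arm total (all three genotypes), so
    exposed proportions across TT / CT / CC partition to one.
    """
    return TwoByTwo(
        a=contrast.exposed(cases),
        n1=cases.total,
        c=contrast.exposed(controls),
        n2=controls.total,
    )


def genotype_percentage(exposed: int, total: int) -> float:
    """Reporting percentage 100*exposed/total, rounded half-up to 2 dp.

    Rounding is half-up (not banker's) to match conventional table style;
    compute on full precision and round only here.
    """
    if total < 1:
        raise DegenerateInputError("genotype_percentage: zero total")
    if not (0 <= exposed <= total):
        raise ValueError(f"exposed {exposed} outside [0, {total}]")
    frac = Decimal(100 * exposed) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
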