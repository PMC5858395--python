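"""Core domain types for case-control genotype meta-analysis.

A study contributes genotype counts (homozygous wild-type, heterozygote,
homozygous variant) for a case arm and a control arm at one MTHFR locus,
plus covariates used for stratification: country, ethnic group, subtype of
hypertensive disorder in pregnancy (HDP), an ordinal country-level
air-pollution band, a methodological quality score and publication year.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Locus(enum.StrEnum):
    """Polymorphism locus. Genotype slots map to CC/CT/TT for C677T and
    AA/AC/CC for A1298C (wild / heterozygous / homozygous variant)."""

    C677T = "C677T"
    A1298C = "A1298C"


class EthnicGroup(enum.StrEnum):
    CAUCASIAN = "Caucasian"
    HISPANIC = "Hispanic"
    SOUTH_AMERICAN = "SouthAmerican"
    EAST_ASIAN = "EastAsian"
    SOUTH_ASIAN = "SouthAsian"
    MIDDLE_EAST = "MiddleEast"
    AFRICAN = "African"


class HdpSubtype(enum.StrEnum):
    """HDP subtype: preeclampsia-eclampsia (with or without HELLP),
    gestational hypertension, or a mixture of both."""

    PE_E = "PE_E"
    GH = "GH"
    MIXED = "Mixed"


#: Air-pollution death-rate bands (deaths per million) accepted on input.
#: Band 1 (<=50) is merged into band 2 before analysis; band 5 (>=401) is
#: retained with a warning because it is essentially unpopulated in the
#: literature this pipeline targets.
POLLUTION_LEVELS = (1, 2, 3, 4, 5)

#: Levels actually analysed after the 1->2 merge.
ANALYSIS_LEVELS = (2, 3, 4)

QUALITY_SCORE_RANGE = (0, 28)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one study arm.

    ``n_wild`` is the homozygous wild-type count (CC at 677, AA at 1298),
    ``n_het`` the heterozygote (CT / AC) and ``n_variant`` the homozygous
    variant (TT at 677, CC at 1298).  ``total`` must equal their sum.
    """

    n_wild: int
    n_het: int
    n_variant: int
    total: int

    @classmethod
    def of(cls, n_wild: int, n_het: int, n_variant: int) -> "GenotypeCounts":
        return cls(n_wild, n_het, n_variant, n_wild + n_het + n_variant)

    def violations(self, prefix: str = "") -> list[str]:
        out = []
        for name in ("n_wild", "n_het", "n_variant", "total"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                out.append(f"{prefix}{name}: not an integer ({v!r})")
            elif v < 0:
                out.append(f"{prefix}{name}: negative count ({v})")
        if not out and self.total != self.n_wild + self.n_het + self.n_variant:
            out.append(
                f"{prefix}total: {self.total} != sum of genotype counts "
                f"{self.n_wild + self.n_het + self.n_variant}"
            )
        return out


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study's genotype counts plus covariates."""

    study_id: str
    country: str
    ethnic_group: EthnicGroup
    hdp_subtype: HdpSubtype
    locus: Locus
    cases: GenotypeCounts
    controls: GenotypeCounts
    air_pollution_level: int
    quality_score: int
    year: int

    def violations(self) -> list[str]:
        out = []
        out.extend(self.cases.violations("cases."))
        out.extend(self.controls.violations("controls."))
        if not out:
            if self.cases.total < 1:
                out.append("cases.total: must be >= 1")
            if self.controls.total < 1:
                out.append("controls.total: must be >= 1")
        if self.air_pollution_level not in POLLUTION_LEVELS:
            out.append(
                f"air_pollution_level: {self.air_pollution_level} not in "
                f"{POLLUTION_LEVELS}"
            )
        lo, hi = QUALITY_SCORE_RANGE
        if not (lo <= self.quality_score <= hi):
            out.append(f"quality_score: {self.quality_score} outside {lo}-{hi}")
        return out


class Contrast(enum.StrEnum):
    """Genetic contrast: which genotypes count as 'exposed'.

    The exposed proportion always uses the arm *total* as denominator, so
    the five contrasts are: homozygous variant (TT), heterozygote (CT),
    wild-type (CC), variant carrier / dominant (TT+CT) and non-recessive
    (CC+CT).
    """

    HOMO_VARIANT = "TT"
    HET = "CT"
    WILD = "CC"
    DOMINANT = "TT+CT"
    NON_RECESSIVE = "CC+CT"

    def exposed(self, counts: GenotypeCounts) -> int:
        match self:
            case Contrast.HOMO_VARIANT:
                return counts.n_variant
            case Contrast.HET:
                return counts.n_het
            case Contrast.WILD:
                return counts.n_wild
            case Contrast.DOMINANT:
                return counts.n_variant + counts.n_het
            case Contrast.NON_RECESSIVE:
                return counts.n_wild + counts.n_het
        raise AssertionError(self)


ALL_CONTRASTS = (
    Contrast.HOMO_VARIANT,
    Contrast.HET,
    Contrast.WILD,
    Contrast.DOMINANT,
    Contrast.NON_RECESSIVE,
)


class EffectMeasure(enum.StrEnum):
    RR = "RR"
    OR = "OR"


class PoolingModel(enum.StrEnum):
    FIXED = "Fixed"
    RANDOM = "Random"


@dataclass(frozen=True)
class TwoByTwo:
    """Exposed-genotype 2x2 margins: ``a`` exposed among ``n1`` cases,
    ``c`` exposed among ``n2`` controls."""

    a: int
    n1: int
    c: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n1 and 0 <= self.c <= self.n2):
            raise ValueError(f"inconsistent 2x2 margins: {self}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("each arm needs at least one subject")


class SchemaError(ValueError):
    """Input table is missing a required column."""


class ParseError(ValueError):
    """A row could not be parsed; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class ValidationError(ValueError):
    """A StudyRecord violates a structural invariant."""


class DegenerateInputError(ValueError):
    """Operation undefined on this input (e.g. zero total)."""


class DoubleZeroError(DegenerateInputError):
    """Effect undefined: zero exposed in both arms."""


class InsufficientStudiesError(ValueError):
    """Fewer studies than the method requires."""


class ConfigError(ValueError):
    """Invalid run or generator configuration."""
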