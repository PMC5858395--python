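"""Stratified meta-analysis and assembly of summary report tables.

Strata: ethnic group, HDP subtype, country (case-insensitive match),
pollution level, and the direction of the homozygous-variant risk ratio
per country (all study RRs above 1 / all below 1 / straddling 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genetics import genotype_percentage
from .pooling import meta_analyze, study_estimates
from .types import Contrast, EffectMeasure, InsufficientStudiesError, StudyRecord

STRATIFICATION_KEYS = (
    "ethnic_group",
    "hdp_subtype",
    "country",
    "pollution_level",
    "tt_risk_direction",
)


@dataclass(frozen=True)
class Stratification:
    key: str
    groups: dict[str, tuple[str, ...]]  # label -> study ids (input order)


def stratify(studies: Sequence[StudyRecord], key: str) -> Stratification:
    """Partition studies by a covariate; labels sorted for stable output.

    Country labels are canonicalized case-insensitively: the first
    spelling seen is kept as the display label.
    """
    if key not in ("ethnic_group", "hdp_subtype", "country", "pollution_level"):
        raise ValueError(f"unknown stratification key {key!r}")
    groups: dict[str, list[str]] = {}
    canonical: dict[str, str] = {}
    for s in studies:
        if key == "ethnic_group":
            label = str(s.ethnic_group)
        elif key == "hdp_subtype":
            label = str(s.hdp_subtype)
        elif key == "pollution_level":
            label = str(s.air_pollution_level)
        else:
            label = canonical.setdefault(s.country.casefold(), s.country)
        groups.setdefault(label, []).append(s.study_id)
    ordered = {label: tuple(groups[label]) for label in sorted(groups)}
    return Stratification(key=key, groups=ordered)


@dataclass(frozen=True)
class DirectionClass:
    label: str  # RiskAbove1 | ProtectiveBelow1 | Varied
    countries: tuple[str, ...]


def classify_tt_direction(
    per_country: Mapping[str, Sequence[float]],
) -> list[DirectionClass]:
    """Classify countries by the direction of their study-level
    homozygous-variant risk ratios.

    RiskAbove1 when every study RR in the country exceeds 1,
    ProtectiveBelow1 when every RR is below 1, Varied when study RRs
    straddle (or touch) 1 or when no RR is defined.  Classes are mutually
    exclusive and exhaustive over the country set.
    """
    buckets: dict[str, list[str]] = {
        "RiskAbove1": [],
        "ProtectiveBelow1": [],
        "Varied": [],
    }
    for country in sorted(per_country):
        rrs = [r for r in per_country[country] if r is not None]
        if not rrs:
            buckets["Varied"].append(country)
        elif all(r > 1.0 for r in rrs):
            buckets["RiskAbove1"].append(country)
        elif all(r < 1.0 for r in rrs):
            buckets["ProtectiveBelow1"].append(country)
        else:
            buckets["Varied"].append(country)
    return [DirectionClass(label, tuple(cs)) for label, cs in buckets.items()]


SUMMARY_COLUMNS = (
    "contrast",
    "subgroup",
    "n_studies",
    "case_exposed",
    "case_total",
    "case_pct",
    "ctrl_exposed",
    "ctrl_total",
    "ctrl_pct",
    "model",
    "effect",
    "ci_low",
    "ci_high",
    "p_value",
)


def _summary_row(
    studies: Sequence[StudyRecord],
    contrast: Contrast,
    label: str,
    measure: EffectMeasure,
    alpha: float,
    correction: float,
) -> dict:
    case_exposed = sum(contrast.exposed(s.cases) for s in studies)
    case_total = sum(s.cases.total for s in studies)
    ctrl_exposed = sum(contrast.exposed(s.controls) for s in studies)
    ctrl_total = sum(s.controls.total for s in studies)
    row = {
        "contrast": str(contrast),
        "subgroup": label,
        "n_studies": len(studies),
        "case_exposed": case_exposed,
        "case_total": case_total,
        "case_pct": genotype_percentage(case_exposed, case_total),
        "ctrl_exposed": ctrl_exposed,
        "ctrl_total": ctrl_total,
        "ctrl_pct": genotype_percentage(ctrl_exposed, ctrl_total),
        "model": "",
        "effect": float("nan"),
        "ci_low": float("nan"),
        "ci_high": float("nan"),
        "p_value": float("nan"),
    }
    try:
        pooled = meta_analyze(studies, contrast, measure, alpha, correction)
    except InsufficientStudiesError:
        row["model"] = "Excluded"
        return row
    # k=1 strata carry the study's own effect, flagged as single-study
    row["model"] = "SingleStudy" if pooled.k == 1 else str(pooled.model)
    row["effect"] = round(pooled.effect, 2)
    row["ci_low"] = round(pooled.ci_low, 2)
    row["ci_high"] = round(pooled.ci_high, 2)
    row["p_value"] = pooled.p_value
    return row


def build_summary_table(
    studies: Sequence[StudyRecord],
    contrasts: Sequence[Contrast],
    measure: EffectMeasure = EffectMeasure.RR,
    alpha: float = 0.05,
    correction: float = 0.5,
    subgroup_key: str = "ethnic_group",
) -> pd.DataFrame:
    """Pooled-analysis summary table: per contrast, an Overall row over
    all studies then one row per subgroup, each with exposed counts,
    percentages, the selected model, the pooled effect with 95% CI and
    its p-value.  Effects and CI bounds are rounded to 2 decimals for
    report style; percentages use the half-up 2-dp reporting rule.
    Empty strata are simply absent (never printed as zeros).

    Deterministic: repeated calls on the same input are identical.
    """
    if not studies:
        raise InsufficientStudiesError("no studies")
    strat = stratify(studies, subgroup_key)
    by_id = {s.study_id: s for s in studies}
    rows = []
    for contrast in contrasts:
        rows.append(
            _summary_row(studies, contrast, "Overall", measure, alpha, correction)
        )
        for label, ids in strat.groups.items():
            members = [by_id[i] for i in ids]
            rows.append(
                _summary_row(members, contrast, label, measure, alpha, correction)
            )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def country_tt_rrs(
    studies: Sequence[StudyRecord],
    measure: EffectMeasure = EffectMeasure.RR,
    correction: float = 0.5,
) -> dict[str, list[float]]:
    """Per-country study-level homozygous-variant effect estimates
    (input for classify_tt_direction); undefined effects contribute
    None."""
    strat = stratify(studies, "country")
    by_id = {s.study_id: s for s in studies}
    out: dict[str, list[float]] = {}
    for country, ids in strat.groups.items():
        members = [by_id[i] for i in ids]
        estimates, excluded = study_estimates(
            members, Contrast.HOMO_VARIANT, measure, correction
        )
        vals: list[float] = [e.effect for e in estimates]
        vals.extend([None] * len(excluded))  # type: ignore[list-item]
        out[country] = vals
    return out


def significant_findings_table(
    summary: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Schema of significant findings: per subgroup, which contrasts come
    out as risk (effect > 1) or protective (effect < 1) at the given
    alpha — the compact overview companion to the full summary table."""
    rows = []
    for subgroup, block in summary.groupby("subgroup", sort=True):
        risk, protective = [], []
        for _, r in block.iterrows():
            if r["model"] in ("", "Excluded", "SingleStudy"):
                continue
            if pd.notna(r["p_value"]) and r["p_value"] < alpha:
                (risk if r["effect"] > 1.0 else protective).append(r["contrast"])
        rows.append(
            {
                "subgroup": subgroup,
                "n_studies": int(block["n_studies"].max()),
                "risk_contrasts": "; ".join(risk) if risk else "NS",
                "protective_contrasts": "; ".join(protective) if protective else "NS",
            }
        )
    return pd.DataFrame(
        rows, columns=["subgroup", "n_studies", "risk_contrasts", "protective_contrasts"]
    )
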