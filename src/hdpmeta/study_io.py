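"""Reading, validating and writing per-study genotype-count tables.

The on-disk format is a delimited text table (comma by default, tab via
``delimiter="\\t"``) with a required header.  Genotype columns are named
by role rather than by nucleotide so one schema serves both loci:
``case_wild / case_het / case_var`` and ``ctrl_wild / ctrl_het /
ctrl_var`` (wild = CC at 677 or AA at 1298, var = TT at 677 or CC at
1298).  Country names are stored verbatim (UTF-8) and matched
case-insensitively downstream; unknown ethnic-group labels are rejected
rather than coerced to avoid silent subgroup misassignment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .types import (
    ALL_CONTRASTS,
    Contrast,
    EffectMeasure,
    EthnicGroup,
    GenotypeCounts,
    HdpSubtype,
    Locus,
    ParseError,
    SchemaError,
    StudyRecord,
    ValidationError,
    ConfigError,
)

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "study_id",
    "country",
    "ethnic_group",
    "hdp_subtype",
    "locus",
    "case_wild",
    "case_het",
    "case_var",
    "ctrl_wild",
    "ctrl_het",
    "ctrl_var",
    "air_pollution_level",
    "quality_score",
    "year",
)

_INT_COLUMNS = (
    "case_wild",
    "case_het",
    "case_var",
    "ctrl_wild",
    "ctrl_het",
    "ctrl_var",
    "air_pollution_level",
    "quality_score",
    "year",
)


def _parse_int(value, column: str, row: int) -> int:
    try:
        text = str(value).strip()
        as_float = float(text)
        as_int = int(as_float)
        if as_int != as_float:
            raise ValueError
        return as_int
    except (TypeError, ValueError):
        raise ParseError(row, f"column {column!r}: non-integer value {value!r}")


def _parse_enum(enum_cls, value, column: str, row: int):
    try:
        return enum_cls(str(value).strip())
    except ValueError:
        valid = ", ".join(m.value for m in enum_cls)
        raise ParseError(
            row, f"column {column!r}: unknown value {value!r} (expected one of {valid})"
        )


def read_studies(path: str | Path, delimiter: str = ",") -> list[StudyRecord]:
    """Read a study table; one validated StudyRecord per row, row order
    preserved.  Missing columns raise SchemaError; malformed or invalid
    rows raise ParseError/ValidationError with the 1-based data row."""
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[StudyRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        rec = _row_to_record(row._asdict(), i)
        problems = rec.violations()
        if problems:
            raise ValidationError(f"row {i}: " + "; ".join(problems))
        records.append(rec)
    return records


def _row_to_record(row: Mapping[str, object], rownum: int) -> StudyRecord:
    ints = {c: _parse_int(row[c], c, rownum) for c in _INT_COLUMNS}
    for c in ("case_wild", "case_het", "case_var", "ctrl_wild", "ctrl_het", "ctrl_var"):
        if ints[c] < 0:
            raise ParseError(rownum, f"column {c!r}: negative count {ints[c]}")
    if ints["air_pollution_level"] == 5:
        log.warning(
            "row %d (%s): air pollution level 5 is unusual but retained",
            rownum,
            row["study_id"],
        )
    return StudyRecord(
        study_id=str(row["study_id"]).strip(),
        country=str(row["country"]).strip(),
        ethnic_group=_parse_enum(EthnicGroup, row["ethnic_group"], "ethnic_group", rownum),
        hdp_subtype=_parse_enum(HdpSubtype, row["hdp_subtype"], "hdp_subtype", rownum),
        locus=_parse_enum(Locus, row["locus"], "locus", rownum),
        cases=GenotypeCounts.of(ints["case_wild"], ints["case_het"], ints["case_var"]),
        controls=GenotypeCounts.of(ints["ctrl_wild"], ints["ctrl_het"], ints["ctrl_var"]),
        air_pollution_level=ints["air_pollution_level"],
        quality_score=ints["quality_score"],
        year=ints["year"],
    )


def validate_study(record: StudyRecord) -> list[str]:
    """All invariant violations of a record, empty when valid.  Violations
    are data, not exceptions: callers decide what is fatal."""
    return record.violations()


def merge_pollution_levels(records: Sequence[StudyRecord]) -> list[StudyRecord]:
    """Recode pollution band 1 to band 2 (the analysis merge); all other
    bands pass through.  Idempotent, order- and count-preserving."""
    out = []
    for r in records:
        if r.air_pollution_level == 1:
            out.append(dataclasses.replace(r, air_pollution_level=2))
        else:
            out.append(r)
    return out


def studies_to_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "country": r.country,
                "ethnic_group": str(r.ethnic_group),
                "hdp_subtype": str(r.hdp_subtype),
                "locus": str(r.locus),
                "case_wild": r.cases.n_wild,
                "case_het": r.cases.n_het,
                "case_var": r.cases.n_variant,
                "ctrl_wild": r.controls.n_wild,
                "ctrl_het": r.controls.n_het,
                "ctrl_var": r.controls.n_variant,
                "air_pollution_level": r.air_pollution_level,
                "quality_score": r.quality_score,
                "year": r.year,
            }
        )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_studies(
    records: Iterable[StudyRecord], path: str | Path, delimiter: str = ","
) -> Path:
    """Write a study table that read_studies round-trips exactly."""
    path = Path(path)
    studies_to_frame(records).to_csv(path, sep=delimiter, index=False, lineterminator="\n")
    return path


def write_report(
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    run_log: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write report tables as CSV plus a machine-readable JSON run log.

    Output is deterministic: column order as given, UNIX newlines, JSON
    keys sorted — the same input and config produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        target = outdir / f"{name}.csv"
        table.to_csv(target, index=False, lineterminator="\n")
        written.append(target)
    if run_log is not None:
        target = outdir / "run_log.json"
        target.write_text(json.dumps(run_log, indent=2, sort_keys=True, default=str) + "\n")
        written.append(target)
    return written


@dataclass
class RunConfig:
    """Pipeline run configuration (mirrors the YAML config file)."""

    input: str | None = None
    outdir: str = "hdpmeta_out"
    locus: Locus = Locus.C677T
    contrasts: tuple[Contrast, ...] = ALL_CONTRASTS
    measure: EffectMeasure = EffectMeasure.RR
    heterogeneity_alpha: float = 0.05
    hwe_alpha: float = 0.05
    continuity_correction: float = 0.5
    delimiter: str = ","
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.heterogeneity_alpha < 1.0:
            raise ConfigError("heterogeneity_alpha must lie in (0, 1)")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ConfigError("hwe_alpha must lie in (0, 1)")
        if self.continuity_correction < 0:
            raise ConfigError("continuity_correction must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "locus" in kwargs:
            kwargs["locus"] = Locus(kwargs["locus"])
        if "measure" in kwargs:
            kwargs["measure"] = EffectMeasure(str(kwargs["measure"]).upper())
        if "contrasts" in kwargs:
            kwargs["contrasts"] = tuple(Contrast(c) for c in kwargs["contrasts"])
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "outdir": self.outdir,
            "locus": str(self.locus),
            "contrasts": [str(c) for c in self.contrasts],
            "measure": str(self.measure),
            "heterogeneity_alpha": self.heterogeneity_alpha,
            "hwe_alpha": self.hwe_alpha,
            "continuity_correction": self.continuity_correction,
            "delimiter": self.delimiter,
            "seed": self.seed,
        }
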