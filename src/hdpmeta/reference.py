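"""Published pooled genotype counts for MTHFR C677T and HDP.

Aggregate case/control genotype counts from the worldwide case-control
literature on the C677T polymorphism and hypertensive disorders in
pregnancy (71 study groups; 8064 cases, 13232 controls), broken down by
ethnic subgroup.  These pooled margins are the standard cross-check for
the counting and percentage arithmetic in this package: subgroup counts
must sum to the overall counts, and exposed percentages recompute from
counts alone.

Counts are exposed per contrast label ("TT", "CT", "CC", "TT+CT",
"CC+CT") as (exposed, total) pairs per arm.
"""

from __future__ import annotations

#: (case_exposed, case_total, ctrl_exposed, ctrl_total) per contrast,
#: overall pooled over all 71 study groups.
C677T_OVERALL: dict[str, tuple[int, int, int, int]] = {
    "TT": (1087, 8064, 1410, 13232),
    "CT": (3142, 8064, 5166, 13232),
    "CC": (3835, 8064, 6656, 13232),
    "TT+CT": (4229, 8064, 6576, 13232),
    "CC+CT": (6977, 8064, 11822, 13232),
}

#: Homozygous-variant (TT) exposed counts per ethnic subgroup:
#: (n_studies, case_exposed, case_total, ctrl_exposed, ctrl_total).
C677T_TT_BY_ETHNICITY: dict[str, tuple[int, int, int, int, int]] = {
    "Caucasian": (27, 425, 3648, 700, 7138),
    "Hispanic": (7, 215, 765, 325, 1115),
    "SouthAmerican": (4, 62, 378, 66, 555),
    "EastAsian": (17, 296, 1255, 240, 2030),
    "SouthAsian": (4, 15, 561, 31, 991),
    "MiddleEast": (7, 54, 744, 46, 628),
    "African": (5, 20, 713, 2, 775),
}

#: Hispanic pooled case genotype counts (CC, CT, TT) — a worked example
#: for contrast construction.
HISPANIC_CASES: tuple[int, int, int] = (190, 360, 215)
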