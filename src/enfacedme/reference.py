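"""Published per-type cohort summaries used as worked-example inputs.

Summary statistics (counts, means ± sd) of a published 128-eye cohort of
center-involving DME classified into the five observed en face types.
Only group-level summaries are available; the pooled Segment-2 comparisons
are recomputed from these by :mod:`enfacedme.stats`.
"""

from __future__ import annotations

from .stats import GroupSummary

__all__ = [
    "TYPE_ORDER",
    "PUBLISHED_COHORT",
    "SEGMENT2_DRY_TYPES",
    "SEGMENT2_WET_TYPES",
    "N_TOTAL",
]

TYPE_ORDER = ("FC/NF", "PC/NF", "PC/DF", "DF/DF", "DF/DF+SF")

#: types without / with diffuse fluid in Segment 2
SEGMENT2_DRY_TYPES = ("FC/NF", "PC/NF")
SEGMENT2_WET_TYPES = ("PC/DF", "DF/DF", "DF/DF+SF")

#: per-type group summaries: n, demographics, biomarkers (mean, sd) and
#: event counts. ``mdrf`` summarises eyes with ERM only.
PUBLISHED_COHORT = {
    "FC/NF": {
        "n": 24,
        "age_years": (64.4, 12.2),
        "n_female": 6,
        "hba1c_pct": (7.2, 1.4),
        "bcva_logmar": (0.17, 0.20),
        "n_pvd_incomplete": 10,
        "n_ez_disrupted": 0,
        "cst_um": (304.4, 42.7),
        "n_erm": 9,
        "mdrf_um": (49.7, 33.8),
    },
    "PC/NF": {
        "n": 25,
        "age_years": (62.3, 11.5),
        "n_female": 12,
        "hba1c_pct": (6.9, 1.0),
        "bcva_logmar": (0.27, 0.26),
        "n_pvd_incomplete": 8,
        "n_ez_disrupted": 5,
        "cst_um": (385.2, 80.4),
        "n_erm": 12,
        "mdrf_um": (41.4, 26.0),
    },
    "PC/DF": {
        "n": 16,
        "age_years": (70.3, 8.3),
        "n_female": 8,
        "hba1c_pct": (7.3, 1.6),
        "bcva_logmar": (0.47, 0.40),
        "n_pvd_incomplete": 7,
        "n_ez_disrupted": 5,
        "cst_um": (420.8, 82.4),
        "n_erm": 8,
        "mdrf_um": (57.9, 16.0),
    },
    "DF/DF": {
        "n": 37,
        "age_years": (63.9, 8.8),
        "n_female": 16,
        "hba1c_pct": (8.2, 1.9),
        "bcva_logmar": (0.46, 0.30),
        "n_pvd_incomplete": 16,
        "n_ez_disrupted": 25,
        "cst_um": (407.9, 129.0),
        "n_erm": 19,
        "mdrf_um": (54.3, 44.2),
    },
    "DF/DF+SF": {
        "n": 26,
        "age_years": (60.2, 11.6),
        "n_female": 8,
        "hba1c_pct": (8.1, 2.1),
        "bcva_logmar": (0.50, 0.35),
        "n_pvd_incomplete": 17,
        "n_ez_disrupted": 25,
        "cst_um": (493.5, 106.0),
        "n_erm": 12,
        "mdrf_um": (57.2, 46.5),
    },
}

N_TOTAL = sum(v["n"] for v in PUBLISHED_COHORT.values())


def type_counts() -> dict[str, int]:
    return {k: v["n"] for k, v in PUBLISHED_COHORT.items()}


def cst_summary(type_label: str) -> GroupSummary:
    n = PUBLISHED_COHORT[type_label]["n"]
    mean, sd = PUBLISHED_COHORT[type_label]["cst_um"]
    return GroupSummary(n=n, mean=mean, sd=sd)


def ez_counts(type_label: str) -> tuple[int, int]:
    """(events, n) of EZ disruption for one type."""
    v = PUBLISHED_COHORT[type_label]
    return v["n_ez_disrupted"], v["n"]
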