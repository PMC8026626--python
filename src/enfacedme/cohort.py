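"""Per-eye records and cohort tables (CSV-backed)."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import parse_label

__all__ = ["EyeRecord", "CohortTable", "read_cohort", "write_cohort", "COLUMNS"]

COLUMNS = [
    "eye_id",
    "age_years",
    "sex",
    "hba1c_pct",
    "bcva_logmar",
    "type_label",
    "cst_um",
    "ez_disrupted",
    "erm_present",
    "mdrf_um",
    "pvd_incomplete",
]

_BOOL_COLUMNS = ("ez_disrupted", "erm_present", "pvd_incomplete")


@dataclass
class EyeRecord:
    """One eye: demographics, taxonomy label and structural biomarkers.

    ``mdrf_um`` is defined for eyes with ERM only (None otherwise).
    """

    eye_id: str
    age_years: float
    sex: str
    hba1c_pct: float
    bcva_logmar: float
    type_label: str
    cst_um: float
    ez_disrupted: bool
    erm_present: bool
    mdrf_um: float | None
    pvd_incomplete: bool

    def __post_init__(self):
        parse_label(self.type_label)  # raises on unknown labels
        if self.cst_um <= 0:
            raise ValueError("cst_um must be positive")
        if self.erm_present:
            if self.mdrf_um is None or self.mdrf_um < 0:
                raise ValueError("eyes with ERM need mdrf_um >= 0")
        elif self.mdrf_um is not None:
            raise ValueError("mdrf_um must be null when no ERM is present")


class CohortTable:
    """A validated cohort of :class:`EyeRecord`, with derived groupings."""

    def __init__(self, records: list[EyeRecord]):
        self.records = list(records)
        frame = pd.DataFrame([asdict(r) for r in self.records], columns=COLUMNS)
        findings = [parse_label(l) for l in frame["type_label"]]
        frame["segment2_fluid"] = [f.segment2_state == "DF" for f in findings]
        frame["srf_present"] = [f.srf_present for f in findings]
        self.frame = frame

    def __len__(self):
        return len(self.records)

    def by_type(self) -> dict[str, pd.DataFrame]:
        return {k: v for k, v in self.frame.groupby("type_label")}

    def by_segment2_fluid(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(without, with) diffuse fluid in Segment 2."""
        f = self.frame
        return f[~f["segment2_fluid"]], f[f["segment2_fluid"]]


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.frame[COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV; unknown taxonomy labels raise a validation error."""
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        mdrf = row["mdrf_um"]
        records.append(
            EyeRecord(
                eye_id=str(row["eye_id"]),
                age_years=float(row["age_years"]),
                sex=str(row["sex"]),
                hba1c_pct=float(row["hba1c_pct"]),
                bcva_logmar=float(row["bcva_logmar"]),
                type_label=str(row["type_label"]),
                cst_um=float(row["cst_um"]),
                ez_disrupted=bool(row["ez_disrupted"]),
                erm_present=bool(row["erm_present"]),
                mdrf_um=None if pd.isna(mdrf) else float(mdrf),
                pvd_incomplete=bool(row["pvd_incomplete"]),
            )
        )
    return CohortTable(records)
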