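"""Per-patient records and the cohort table layout.

Column dictionary for cohort CSVs (one row per patient):

====================  =====================================================
column                meaning
====================  =====================================================
id                    patient identifier
mtv0, mtv2            metabolic tumour volume, baseline / interim (cm^3)
tlg0, tlg2            total lesion glycolysis, baseline / interim (cm^3·SUV)
suvmax0, suvmax2      tumour SUVmax, baseline / interim
ds                    interim Deauville score, 1-5
delta_mtv             % change in MTV (negative = reduction)
delta_tlg             % change in TLG
delta_suvmax          % change in SUVmax
ipi                   International Prognostic Index, 0-5
mtd                   maximum tumour dimension, cm
stage                 Ann Arbor stage, 1-4
time_years            progression-free survival time from diagnosis, years
event                 True if progression/death observed, False if censored
true_group            (simulated cohorts) generating prognostic group
true_log_hr           (simulated cohorts) generating log hazard ratio
====================  =====================================================
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

__all__ = ["PatientRecord", "records_to_dataframe", "dataframe_to_records", "COHORT_COLUMNS"]


@dataclass
class PatientRecord:
    """All per-patient PET parameters plus the PFS outcome."""

    id: str
    mtv0: float
    tlg0: float
    suvmax0: float
    mtv2: float
    tlg2: float
    suvmax2: float
    ds: int
    delta_mtv: float
    delta_tlg: float
    delta_suvmax: float
    ipi: int
    mtd: float
    stage: int
    time_years: float
    event: bool
    true_group: str | None = None
    true_log_hr: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.ds <= 5:
            raise ValueError(f"Deauville score must be 1-5, got {self.ds}")
        if not 0 <= self.ipi <= 5:
            raise ValueError(f"IPI must be 0-5, got {self.ipi}")
        if self.time_years <= 0:
            raise ValueError("PFS time must be positive")
        for name in ("mtv0", "tlg0", "suvmax0", "mtv2", "tlg2", "suvmax2", "mtd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


COHORT_COLUMNS = [f.name for f in PatientRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]


def records_to_dataframe(records: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=COHORT_COLUMNS)


def dataframe_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    out = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in COHORT_COLUMNS if k in row.index}
        kwargs["ds"] = int(kwargs["ds"])
        kwargs["ipi"] = int(kwargs["ipi"])
        kwargs["stage"] = int(kwargs["stage"])
        kwargs["event"] = bool(kwargs["event"])
        kwargs["id"] = str(kwargs["id"])
        out.append(PatientRecord(**kwargs))
    return out
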