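"""Long-format concentration CSV reader/writer.

Header: subject_id, group, dose_mmol, time_h, conc_uM, matrix, below_loq.
Times are decimal hours from injection (injection = 0). One row per sample;
dose and group are repeated on every row of a subject.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from csfclear.model import DoseEvent, Observation, SubjectRecord

__all__ = [
    "CONCENTRATION_COLUMNS",
    "frame_to_subjects",
    "read_subjects",
    "subjects_to_frame",
    "write_subjects",
]

CONCENTRATION_COLUMNS = (
    "subject_id",
    "group",
    "dose_mmol",
    "time_h",
    "conc_uM",
    "matrix",
    "below_loq",
)

_COVARIATE_COLUMNS = ("age", "sex", "height", "weight", "bmi", "gfr")


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        cov = {k: s.covariates.get(k) for k in _COVARIATE_COLUMNS if k in s.covariates}
        for o in s.observations:
            rows.append(
                {
                    "subject_id": s.id,
                    "group": s.group,
                    "dose_mmol": s.dose.dose_mmol,
                    "time_h": o.time,
                    "conc_uM": o.concentration,
                    "matrix": o.matrix,
                    "below_loq": o.below_loq,
                    **cov,
                }
            )
    return pd.DataFrame(rows)


def frame_to_subjects(df: pd.DataFrame) -> list[SubjectRecord]:
    missing = set(CONCENTRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    subjects = []
    for sid, block in df.groupby("subject_id", sort=False):
        block = block.sort_values("time_h")
        dose_vals = block["dose_mmol"].unique()
        if len(dose_vals) != 1:
            raise ValueError(f"subject {sid} has inconsistent dose rows")
        group_vals = block["group"].unique()
        if len(group_vals) != 1:
            raise ValueError(f"subject {sid} has inconsistent group labels")
        obs = tuple(
            Observation(
                time=float(r.time_h),
                concentration=float(r.conc_uM),
                matrix=str(r.matrix),
                below_loq=bool(r.below_loq),
            )
            for r in block.itertuples()
        )
        cov = {}
        for k in _COVARIATE_COLUMNS:
            if k in block.columns and pd.notna(block[k].iloc[0]):
                cov[k] = block[k].iloc[0]
        subjects.append(
            SubjectRecord(
                id=str(sid),
                group=str(group_vals[0]),
                dose=DoseEvent(amount=float(dose_vals[0]) * 1000.0),
                observations=obs,
                covariates=cov,
            )
        )
    return subjects


def write_subjects(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False)


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    return frame_to_subjects(pd.read_csv(path))
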