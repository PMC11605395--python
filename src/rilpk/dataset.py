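"""Event-record datasets (NONMEM-convention CSV) and the ObservationTable.

One row per event.  Columns:

==========  =============================================================
ID          subject identifier (int)
TIME        hours since the subject's first dose
EVID        1 = dose, 0 = observation
AMT         dose amount, mg (0 for observations)
ROUTE       'oral' or 'im'; for observations, the route of the most
            recent preceding dose (decides the residual-error model)
DUR         zero-order input duration, h (0 → model default for oral)
DV          observed concentration, ng/mL (empty for doses)
MDV         1 = missing/ignore DV (doses), 0 = usable observation
OCC         injection occasion, 1..6 for IM doses, else 0; observations
            carry the occasion of the last IM dose
BLQ         1 = below the quantification limit (censored), else 0
SEX         1 = female, 0 = male
AGE         years
WT          kg
BMI         kg/m²
==========  =============================================================

Times must be non-decreasing within a subject and every observation must
be preceded by at least one dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pk_core import DoseEvent

__all__ = ["ObservationTable", "SubjectData", "read_dataset", "write_dataset",
           "DatasetError", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = [
    "ID", "TIME", "EVID", "AMT", "ROUTE", "DUR", "DV", "MDV", "OCC", "BLQ",
    "SEX", "AGE", "WT", "BMI",
]


class DatasetError(ValueError):
    """Raised when an event-record table violates the format contract."""


@dataclass
class SubjectData:
    """All events of one subject, unpacked for the model machinery."""

    id: int
    doses: list = field(default_factory=list)          # DoseEvent
    obs_time: np.ndarray = None                        # h
    obs_dv: np.ndarray = None                          # ng/mL
    obs_route_oral: np.ndarray = None                  # bool per observation
    obs_occ: np.ndarray = None                         # occasion per observation
    obs_blq: np.ndarray = None                         # censored flag
    female: bool = False
    age: float = np.nan
    weight: float = np.nan
    bmi: float = np.nan


class ObservationTable:
    """Validated event-record table with convenient per-subject access."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = _validate(frame.copy())

    @property
    def n_subjects(self) -> int:
        return self.frame["ID"].nunique()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["ID"].unique()

    @property
    def n_observations(self) -> int:
        return int((self.frame["EVID"] == 0).sum())

    def n_observations_by_route(self) -> dict:
        obs = self.frame[self.frame["EVID"] == 0]
        return obs.groupby("ROUTE").size().to_dict()

    def subjects(self) -> list[SubjectData]:
        out = []
        for sid, grp in self.frame.groupby("ID", sort=True):
            doses = grp[grp["EVID"] == 1]
            obs = grp[grp["EVID"] == 0]
            out.append(
                SubjectData(
                    id=int(sid),
                    doses=[
                        DoseEvent(
                            time=float(r.TIME), amount=float(r.AMT), route=str(r.ROUTE),
                            duration=float(r.DUR), occasion=int(r.OCC),
                        )
                        for r in doses.itertuples()
                    ],
                    obs_time=obs["TIME"].to_numpy(float),
                    obs_dv=obs["DV"].to_numpy(float),
                    obs_route_oral=(obs["ROUTE"] == "oral").to_numpy(),
                    obs_occ=obs["OCC"].to_numpy(int),
                    obs_blq=obs["BLQ"].to_numpy(int).astype(bool),
                    female=bool(grp["SEX"].iloc[0]),
                    age=float(grp["AGE"].iloc[0]),
                    weight=float(grp["WT"].iloc[0]),
                    bmi=float(grp["BMI"].iloc[0]),
                )
            )
        return out

    def covariate_frame(self) -> pd.DataFrame:
        """One row per subject with SEX/AGE/WT/BMI."""
        return (
            self.frame.groupby("ID", sort=True)[["SEX", "AGE", "WT", "BMI"]]
            .first()
            .reset_index()
        )

    def subset(self, subject_ids) -> "ObservationTable":
        """Table restricted to the given subjects (order preserved, IDs kept)."""
        keep = self.frame[self.frame["ID"].isin(set(subject_ids))]
        return ObservationTable(keep.reset_index(drop=True))

    def resample(self, subject_ids) -> "ObservationTable":
        """Bootstrap-style table: one copy per listed ID (repeats allowed),
        re-indexed 1..n so duplicated subjects stay distinct."""
        parts = []
        for new_id, sid in enumerate(subject_ids, start=1):
            part = self.frame[self.frame["ID"] == sid].copy()
            part["ID"] = new_id
            parts.append(part)
        return ObservationTable(pd.concat(parts, ignore_index=True))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    df["DV"] = pd.to_numeric(df["DV"], errors="coerce")
    for sid, grp in df.groupby("ID"):
        t = grp["TIME"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            raise DatasetError(f"subject {sid}: times are not non-decreasing")
        evid = grp["EVID"].to_numpy(int)
        if (evid == 0).any():
            first_obs = t[evid == 0].min()
            if not (evid == 1).any() or t[evid == 1].min() > first_obs:
                raise DatasetError(
                    f"subject {sid}: observation at t={first_obs} precedes any dose"
                )
        doses = grp[grp["EVID"] == 1]
        if (doses["AMT"].to_numpy(float) <= 0).any():
            raise DatasetError(f"subject {sid}: dose record with AMT <= 0")
        obs = grp[grp["EVID"] == 0]
        if obs["DV"].isna().any():
            raise DatasetError(f"subject {sid}: observation record without DV")
    return df


def read_dataset(path) -> ObservationTable:
    """Read and validate a NONMEM-convention CSV event table."""
    df = pd.read_csv(path)
    return ObservationTable(df)


def write_dataset(table: ObservationTable, path) -> None:
    """Write an event table as CSV (round-trips bit-identically through
    :func:`read_dataset` for tables produced by this package)."""
    df = table.frame.copy()
    df.to_csv(path, index=False, float_format="%.10g")
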