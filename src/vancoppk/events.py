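"""Long-format event tables (doses + concentration observations).

The on-disk dialect is a plain CSV with one row per event and columns
``ID, TIME, EVID, AMT, RATE, DV, WT, PMA, PNA, GA, SCR, SEX``:
``EVID=1`` rows are doses (``AMT`` mg infused at ``RATE`` mg/h), ``EVID=0``
rows are observations (``DV`` ug/ml).  Times are hours from the subject's
first dose.  Missing numeric fields are written as ``"."``.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["EVENT_COLUMNS", "EventTable"]

EVENT_COLUMNS = [
    "ID", "TIME", "EVID", "AMT", "RATE", "DV",
    "WT", "PMA", "PNA", "GA", "SCR", "SEX",
]
_NUMERIC_COLUMNS = [c for c in EVENT_COLUMNS if c not in ("ID", "SEX")]


class EventTable:
    """Validated container for a dosing/observation event table.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format events in the documented dialect.
    truth : pandas.DataFrame, optional
        Simulation ground truth (one row per subject: ``ID, ETA_CL, ETA_V,
        CL, V``); carried alongside synthetic datasets for recovery tests,
        never written into the event CSV.
    """

    def __init__(self, data: pd.DataFrame, truth: pd.DataFrame | None = None,
                 validate: bool = True):
        df = data.copy()
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"missing required column(s): {', '.join(missing)}")
        for col in _NUMERIC_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df = df[EVENT_COLUMNS + [c for c in df.columns if c not in EVENT_COLUMNS]]
        df = df.reset_index(drop=True)
        self.data = df
        self.truth = truth.reset_index(drop=True) if truth is not None else None
        if validate:
            self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if df["TIME"].isna().any():
            row = int(df.index[df["TIME"].isna()][0])
            raise DataError(f"row {row}: column TIME is missing or non-numeric")
        if (df["TIME"] < 0).any():
            row = int(df.index[df["TIME"] < 0][0])
            raise DataError(f"row {row}: column TIME is negative")
        bad_evid = ~df["EVID"].isin([0, 1])
        if bad_evid.any():
            row = int(df.index[bad_evid][0])
            raise DataError(f"row {row}: column EVID must be 0 or 1")
        for sid, sub in df.groupby("ID", sort=False):
            times = sub["TIME"].to_numpy()
            if np.any(np.diff(times) < 0):
                row = int(sub.index[1:][np.diff(times) < 0][0])
                raise DataError(
                    f"row {row}: column TIME decreases within subject {sid}"
                )
            obs = sub[sub["EVID"] == 0]
            doses = sub[sub["EVID"] == 1]
            if len(obs) == 0:
                raise DataError(f"subject {sid}: no observations")
            if len(doses) == 0 or obs["TIME"].min() < doses["TIME"].min():
                row = int(obs.index[0])
                raise DataError(
                    f"row {row}: observation for subject {sid} precedes any dose"
                )
            if obs["DV"].isna().any():
                row = int(obs.index[obs["DV"].isna()][0])
                raise DataError(f"row {row}: column DV missing on observation row")
            if doses["AMT"].isna().any() or (doses["AMT"] <= 0).any():
                row = int(doses.index[(doses["AMT"].isna()) | (doses["AMT"] <= 0)][0])
                raise DataError(f"row {row}: column AMT must be positive on dose row")
            if doses["RATE"].isna().any() or (doses["RATE"] <= 0).any():
                row = int(doses.index[(doses["RATE"].isna()) | (doses["RATE"] <= 0)][0])
                raise DataError(f"row {row}: column RATE must be positive on dose row")

    # -- accessors -----------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(pd.unique(self.data["ID"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return int((self.data["EVID"] == 0).sum())

    def observations(self) -> pd.DataFrame:
        return self.data[self.data["EVID"] == 0]

    def doses(self) -> pd.DataFrame:
        return self.data[self.data["EVID"] == 1]

    def iter_subjects(self) -> Iterator[tuple]:
        for sid, sub in self.data.groupby("ID", sort=False):
            yield sid, sub

    def subset(self, ids: Iterable) -> "EventTable":
        ids = list(ids)
        data = self.data[self.data["ID"].isin(ids)]
        truth = None
        if self.truth is not None:
            truth = self.truth[self.truth["ID"].isin(ids)]
        return EventTable(data, truth=truth)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.data, other.data, check_dtype=False, check_exact=False
            )
        except AssertionError:
            return False
        return True

    # -- IO --------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the table in the documented CSV dialect ("." for missing)."""
        self.data.to_csv(path, index=False, na_rep=".")

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        df = pd.read_csv(path, na_values=["."], keep_default_na=True)
        return cls(df)
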