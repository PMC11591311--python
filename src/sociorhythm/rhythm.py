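"""Dense per-person body-rhythm storage.

All timestamps in the pipeline are integer minutes since the study
epoch; day d spans minutes [d*1440, (d+1)*1440).  ``RhythmStore`` keeps
one row of per-minute BR values per person over the whole observation
span, with NaN for minutes where the badge produced no data (not worn,
or the minute was lost).  Wear time is exactly the set of non-NaN
minutes.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440


class RhythmStore:
    """Per-person, per-minute BR values over [0, n_minutes)."""

    def __init__(self, person_ids: Iterable[int], n_minutes: int):
        self.person_ids = list(person_ids)
        self.index = {pid: k for k, pid in enumerate(self.person_ids)}
        self.n_minutes = int(n_minutes)
        self.values = np.full((len(self.person_ids), self.n_minutes), np.nan,
                              dtype=np.float64)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RhythmStore":
        """Build from a long (person_id, minute, br_hz) table."""
        pids = sorted(df["person_id"].unique())
        n_minutes = int(df["minute"].max()) + 1 if len(df) else 0
        store = cls(pids, n_minutes)
        rows = df["person_id"].map(store.index).to_numpy()
        store.values[rows, df["minute"].to_numpy(dtype=np.int64)] = \
            df["br_hz"].to_numpy(dtype=np.float64)
        return store

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(~np.isnan(self.values))
        return pd.DataFrame({
            "person_id": np.asarray(self.person_ids)[rows],
            "minute": cols,
            "br_hz": self.values[rows, cols],
        })

    def row(self, person_id: int) -> np.ndarray:
        return self.values[self.index[person_id]]

    def wear_minutes(self) -> dict[int, int]:
        """Number of minutes with data, per person."""
        counts = np.count_nonzero(~np.isnan(self.values), axis=1)
        return {pid: int(c) for pid, c in zip(self.person_ids, counts)}

    def person_mean(self, person_id: int) -> float:
        return float(np.nanmean(self.row(person_id)))


def day_of(minute: int) -> int:
    return int(minute) // MINUTES_PER_DAY


def day_bounds(minute: int) -> tuple[int, int]:
    """Half-open [start, end) minute span of the day containing ``minute``."""
    d = day_of(minute)
    return d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY
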