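"""Face-to-face interaction episodes from minute-level infrared detections.

Badges detect each other once per minute when roughly facing within a
couple of metres, emitting directed records (observer, detected,
minute).  Misalignment from posture or movement causes short missed
runs, so same-pair records separated by less than five minutes are
treated as one continuous episode (gap merging).  Participants with
less than five hours of wear or less than one hour of total interaction
time are excluded outright.

An episode keeps only the *observed* active minutes (merged gaps are
not back-filled) unless ``fill_gaps`` is requested; episode identity is
what merging decides, the minutes are what the sensors saw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MERGE_THRESHOLD = 5  # minutes; gaps < this join two events
DEFAULT_MIN_WEAR_HOURS = 5.0
DEFAULT_MIN_INTERACTION_HOURS = 1.0


@dataclass(frozen=True)
class InteractionEpisode:
    """A merged face-to-face episode between two persons.

    ``minutes`` is the sorted tuple of observed active minutes (possibly
    non-contiguous after gap merging); ``start``/``end`` are its extremes.
    """
    pair: tuple[int, int]
    minutes: tuple[int, ...]
    episode_id: int = -1

    @property
    def start(self) -> int:
        return self.minutes[0]

    @property
    def end(self) -> int:
        return self.minutes[-1]

    @property
    def n_minutes(self) -> int:
        return len(self.minutes)


def _pair_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


def records_to_minutes(records: pd.DataFrame) -> dict[tuple[int, int], np.ndarray]:
    """Collapse directed detection records into per-pair active minute sets.

    A minute is active for pair {i, j} iff at least one directed record
    (i->j or j->i) exists for that minute (union rule).  Self-detections
    are dropped with a warning.
    """
    if len(records) == 0:
        return {}
    required = {"observer", "detected", "minute"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"detection records missing columns {sorted(missing)}")
    self_mask = records["observer"] == records["detected"]
    if self_mask.any():
        logger.warning("dropping %d self-detection records", int(self_mask.sum()))
        records = records[~self_mask]
    a = records["observer"].to_numpy()
    b = records["detected"].to_numpy()
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    df = pd.DataFrame({"lo": lo, "hi": hi, "minute": records["minute"].to_numpy()})
    out: dict[tuple[int, int], np.ndarray] = {}
    for (plo, phi), grp in df.groupby(["lo", "hi"], sort=True):
        out[(int(plo), int(phi))] = np.unique(grp["minute"].to_numpy(dtype=np.int64))
    return out


def merge_gaps(pair_minutes: Mapping[tuple[int, int], np.ndarray],
               merge_threshold: int = DEFAULT_MERGE_THRESHOLD) -> list[InteractionEpisode]:
    """Join same-pair active minutes separated by gaps < ``merge_threshold``.

    Episode minutes retain only the observed active minutes.  Output is
    sorted by (start, pair) and episode ids are assigned sequentially.
    """
    if merge_threshold <= 0:
        raise ValueError("merge_threshold must be a positive number of minutes")
    episodes: list[InteractionEpisode] = []
    for pair, minutes in pair_minutes.items():
        m = np.unique(np.asarray(minutes, dtype=np.int64))
        if m.size == 0:
            continue
        # split where the jump between consecutive active minutes >= threshold
        cuts = np.nonzero(np.diff(m) >= merge_threshold)[0] + 1
        for chunk in np.split(m, cuts):
            episodes.append(InteractionEpisode(pair=pair, minutes=tuple(int(x) for x in chunk)))
    episodes.sort(key=lambda e: (e.start, e.pair))
    return [InteractionEpisode(pair=e.pair, minutes=e.minutes, episode_id=k)
            for k, e in enumerate(episodes)]


def interaction_minutes_per_person(episodes: Iterable[InteractionEpisode]) -> dict[int, int]:
    """Total face-to-face minutes per person, summed over their episodes."""
    totals: dict[int, int] = {}
    for ep in episodes:
        for pid in ep.pair:
            totals[pid] = totals.get(pid, 0) + ep.n_minutes
    return totals


def exclusion_filter(wear_minutes: Mapping[int, int],
                     interaction_minutes: Mapping[int, int],
                     min_wear_hours: float = DEFAULT_MIN_WEAR_HOURS,
                     min_interaction_hours: float = DEFAULT_MIN_INTERACTION_HOURS,
                     ) -> set[int]:
    """Retain persons with >= 5 h wear AND >= 1 h total interaction time.

    Thresholds are strict on the exclusion side: 4.9 h wear or 59 min of
    interaction are excluded.
    """
    keep: set[int] = set()
    for pid, wear in wear_minutes.items():
        inter = interaction_minutes.get(pid, 0)
        if wear >= min_wear_hours * 60 and inter >= min_interaction_hours * 60:
            keep.add(pid)
    return keep


def drop_excluded_episodes(episodes: Iterable[InteractionEpisode],
                           retained: set[int]) -> list[InteractionEpisode]:
    """Drop every episode involving an excluded person."""
    return [e for e in episodes if e.pair[0] in retained and e.pair[1] in retained]


def merge_fraction_report(pair_minutes: Mapping[tuple[int, int], np.ndarray],
                          threshold: int = DEFAULT_MERGE_THRESHOLD) -> float:
    """Fraction of within-pair adjacent interaction events separated by < threshold.

    An *event* is a maximal run of consecutive active minutes before any
    merging; the separating interval between adjacent events is the
    minute-index difference between one event's last minute and the next
    event's first minute (the same quantity the merge rule thresholds).
    Returns 0.0 when no adjacent event pairs exist.
    """
    short = 0
    total = 0
    for minutes in pair_minutes.values():
        m = np.unique(np.asarray(minutes, dtype=np.int64))
        if m.size < 2:
            continue
        gaps = np.diff(m)
        event_gaps = gaps[gaps > 1]  # jumps between maximal consecutive runs
        total += event_gaps.size
        short += int(np.count_nonzero(event_gaps < threshold))
    return short / total if total else 0.0


def episodes_to_frame(episodes: Iterable[InteractionEpisode]) -> pd.DataFrame:
    rows = [(e.episode_id, e.pair[0], e.pair[1], e.start, e.end, e.n_minutes)
            for e in episodes]
    return pd.DataFrame(rows, columns=["episode_id", "person_a", "person_b",
                                       "start", "end", "n_minutes"])
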