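"""Physical engagement: the interaction-induced rise in body rhythm.

For participant i of episode k, physical engagement is

    PE_i(k) = mean BR_i over T_k  -  mean BR_i over T-hat_k

where T_k is the episode's minute set extended by 10 minutes on each
side (body rhythm already rises around interactions, partly greeting
and approach, partly sensors acquiring each other late) and T-hat_k is
a 30-minute baseline window shifted 10 minutes before the extension,
i.e. [start-40, start-10) by default.  Both means run over minutes with
BR present; windows are clipped to the day of the episode so that a
baseline never reaches across an overnight gap.

If the same pair already interacted inside a baseline window the
baseline is compromised, so such episodes are first integrated into a
single episode (fixpoint of pairwise merging).  Interactions with
*other* partners are left in the baseline — they cannot be excluded
without discarding most baselines — and are only counted and reported
as a contamination diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interactions import InteractionEpisode
from .rhythm import RhythmStore, day_bounds

DEFAULT_EXTENSION = 10   # minutes added before and after the episode
DEFAULT_BASELINE_SPAN = 30   # minutes
DEFAULT_MIN_BASELINE_MINUTES = 5
DEFAULT_MIN_INTERACTION_MINUTES = 1


@dataclass(frozen=True)
class EngagementParams:
    extension: int = DEFAULT_EXTENSION
    baseline_span: int = DEFAULT_BASELINE_SPAN
    min_baseline_minutes: int = DEFAULT_MIN_BASELINE_MINUTES
    min_interaction_minutes: int = DEFAULT_MIN_INTERACTION_MINUTES
    #: back-fill merged-gap minutes into T_k (off: only observed minutes count)
    fill_gaps: bool = False


def baseline_bounds(start: int, extension: int = DEFAULT_EXTENSION,
                    span: int = DEFAULT_BASELINE_SPAN) -> tuple[int, int]:
    """Half-open [lo, hi) bounds of the shifted baseline window."""
    return start - extension - span, start - extension


def _episode_minutes_in(episode: InteractionEpisode, lo: int, hi: int) -> bool:
    m = np.asarray(episode.minutes)
    return bool(np.any((m >= lo) & (m < hi)))


def integrate_baseline_partner(episodes: Iterable[InteractionEpisode],
                               extension: int = DEFAULT_EXTENSION,
                               span: int = DEFAULT_BASELINE_SPAN,
                               ) -> list[InteractionEpisode]:
    """Merge same-pair episodes until no baseline contains the focal partner.

    Fixpoint rule: while any episode's baseline window [start-ext-span,
    start-ext) contains minutes of an earlier episode with the same
    partner, union the two into one episode.  Episode ids are reassigned
    on the merged, globally sorted result.
    """
    by_pair: dict[tuple[int, int], list[InteractionEpisode]] = {}
    for ep in episodes:
        by_pair.setdefault(ep.pair, []).append(ep)
    merged_all: list[InteractionEpisode] = []
    for pair, eps in by_pair.items():
        eps = sorted(eps, key=lambda e: e.start)
        changed = True
        while changed:
            changed = False
            for idx in range(1, len(eps)):
                lo, hi = baseline_bounds(eps[idx].start, extension, span)
                for jdx in range(idx):
                    if _episode_minutes_in(eps[jdx], lo, hi):
                        union = tuple(sorted(set(eps[jdx].minutes) | set(eps[idx].minutes)))
                        keep = [e for k, e in enumerate(eps) if k not in (jdx, idx)]
                        keep.append(InteractionEpisode(pair=pair, minutes=union))
                        eps = sorted(keep, key=lambda e: e.start)
                        changed = True
                        break
                if changed:
                    break
        merged_all.extend(eps)
    merged_all.sort(key=lambda e: (e.start, e.pair))
    return [InteractionEpisode(pair=e.pair, minutes=e.minutes, episode_id=k)
            for k, e in enumerate(merged_all)]


def build_windows(episode: InteractionEpisode,
                  extension: int = DEFAULT_EXTENSION,
                  span: int = DEFAULT_BASELINE_SPAN,
                  fill_gaps: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Extended interaction window T_k and shifted baseline window T-hat_k.

    T_k = episode minutes plus [start-ext, start) and (end, end+ext];
    T-hat_k = [start-ext-span, start-ext).  Both are clipped to the day
    of the episode start (minutes outside wear simply carry no BR and
    drop out of the means later).
    """
    day_lo, day_hi = day_bounds(episode.start)
    start, end = episode.start, episode.end
    core = (np.arange(start, end + 1, dtype=np.int64) if fill_gaps
            else np.asarray(episode.minutes, dtype=np.int64))
    pre = np.arange(max(start - extension, day_lo), start, dtype=np.int64)
    post = np.arange(end + 1, min(end + extension, day_hi - 1) + 1, dtype=np.int64)
    tk = np.concatenate([pre, core, post])
    b_lo, b_hi = baseline_bounds(start, extension, span)
    that = np.arange(max(b_lo, day_lo), max(b_hi, day_lo), dtype=np.int64)
    return tk, that


def physical_engagement(br_row: np.ndarray,
                        tk: np.ndarray,
                        that: np.ndarray,
                        min_baseline_minutes: int = DEFAULT_MIN_BASELINE_MINUTES,
                        min_interaction_minutes: int = DEFAULT_MIN_INTERACTION_MINUTES,
                        ):
    """PE for one person and one episode, or None if data are insufficient.

    Returns (pe, mean_tk, mean_that, n_tk, n_that) with means over the
    minutes where BR is present.
    """
    tk_vals = br_row[tk] if tk.size else np.empty(0)
    that_vals = br_row[that] if that.size else np.empty(0)
    tk_ok = tk_vals[np.isfinite(tk_vals)]
    that_ok = that_vals[np.isfinite(that_vals)]
    if tk_ok.size < min_interaction_minutes or that_ok.size < min_baseline_minutes:
        return None
    mean_tk = float(tk_ok.mean())
    mean_that = float(that_ok.mean())
    return mean_tk - mean_that, mean_tk, mean_that, int(tk_ok.size), int(that_ok.size)


def activity_counts(store: RhythmStore,
                    episodes: Iterable[InteractionEpisode]) -> np.ndarray:
    """Per-person, per-minute count of interaction records (partner-minutes)."""
    counts = np.zeros_like(store.values, dtype=np.int32)
    for ep in episodes:
        idx = np.asarray(ep.minutes, dtype=np.int64)
        idx = idx[idx < store.n_minutes]
        for pid in ep.pair:
            counts[store.index[pid], idx] += 1
    return counts


def compute_engagement(store: RhythmStore,
                       episodes: Sequence[InteractionEpisode],
                       params: EngagementParams = EngagementParams(),
                       activity: np.ndarray | None = None) -> pd.DataFrame:
    """Engagement records for both participants of every episode.

    Episodes whose windows carry too little BR (fewer than the minimum
    minutes in either window) are omitted for that participant.  When an
    ``activity`` count array is given, the number of other-partner
    interaction records inside each baseline is reported per record.
    """
    rows = []
    for ep in episodes:
        tk, that = build_windows(ep, params.extension, params.baseline_span,
                                 params.fill_gaps)
        tk = tk[(tk >= 0) & (tk < store.n_minutes)]
        that = that[(that >= 0) & (that < store.n_minutes)]
        for pid, partner in ((ep.pair[0], ep.pair[1]), (ep.pair[1], ep.pair[0])):
            res = physical_engagement(store.row(pid), tk, that,
                                      params.min_baseline_minutes,
                                      params.min_interaction_minutes)
            if res is None:
                continue
            pe, mean_tk, mean_that, n_tk, n_that = res
            contamination = (int(activity[store.index[pid], that].sum())
                             if activity is not None and that.size else 0)
            rows.append((ep.episode_id, pid, partner, pe, mean_tk, mean_that,
                         n_tk, n_that, contamination))
    return pd.DataFrame(rows, columns=[
        "episode_id", "person", "partner", "pe_hz",
        "mean_interaction_br", "mean_baseline_br",
        "n_interaction_minutes_used", "n_baseline_minutes_used",
        "n_baseline_other_partner_records",
    ])


def baseline_contamination_report(records: pd.DataFrame) -> dict[str, float]:
    """Mean and median other-partner records inside baseline windows."""
    col = records["n_baseline_other_partner_records"]
    if len(col) == 0:
        return {"mean": float("nan"), "median": float("nan")}
    return {"mean": float(col.mean()), "median": float(col.median())}


def baseline_span_sweep(store: RhythmStore,
                        merged_episodes: Sequence[InteractionEpisode],
                        ds: Mapping[int, float],
                        episode_minutes: Mapping[int, int] | None = None,
                        spans: Sequence[int] = (10, 20, 30, 40, 50, 60),
                        params: EngagementParams = EngagementParams(),
                        ) -> pd.DataFrame:
    """Recompute PE and the four headline correlations per baseline span.

    ``merged_episodes`` are gap-merged (pre-integration) episodes; the
    partner-integration step depends on the span and is redone for each.
    Returns a long frame (span, correlation, r, p, n).
    """
    from . import features, stats
    rows = []
    for span in spans:
        integrated = integrate_baseline_partner(merged_episodes,
                                                params.extension, span)
        p = EngagementParams(extension=params.extension, baseline_span=span,
                             min_baseline_minutes=params.min_baseline_minutes,
                             min_interaction_minutes=params.min_interaction_minutes,
                             fill_gaps=params.fill_gaps)
        records = compute_engagement(store, integrated, p)
        feats = features.interaction_features(records, ds, integrated)
        emp = features.employee_features(feats)
        for name, res in stats.four_correlations(emp).items():
            rows.append((span, name, res.r, res.p, res.n))
    return pd.DataFrame(rows, columns=["span", "correlation", "r", "p", "n"])
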