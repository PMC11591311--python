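"""Dyadic interaction features and per-employee aggregation.

Each usable episode k between employees i and j yields a feature
4-vector (PE_i(k), PE_j(k), DS_i, DS_j): both participants' physical
engagement in that episode and both CES-D depression totals.  Per
employee, the feature vectors of all their interactions I_i are
averaged *episode-weighted* — each episode contributes once, so
frequent partners weigh more — giving the 4-vector

    (mean PE_self, mean PE_partner, DS_self, mean DS_partner).

For robustness analyses the episode set can be restricted, per focal
employee, to episodes with that employee's top-N partners ranked by
interaction frequency (episode count; ties broken by total interaction
minutes, then by smaller partner id).  Employees with fewer than N
partners keep all their partners.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interactions import InteractionEpisode

logger = logging.getLogger(__name__)

EGO_COLUMNS = ["ego", "partner", "episode_id", "pe_self", "pe_partner",
               "ds_self", "ds_partner", "n_minutes"]


def interaction_features(records: pd.DataFrame,
                         ds: Mapping[int, float],
                         episodes: Sequence[InteractionEpisode] | None = None,
                         ) -> pd.DataFrame:
    """One row per episode with both PE values and both DS totals.

    Episodes where either side lacks an engagement record or a DS total
    are dropped (counts logged).  ``episodes`` supplies the per-episode
    minute counts used later for tie-breaking; without it the focal
    side's used interaction minutes stand in.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["episode_id", "i", "j", "pe_i", "pe_j",
                                     "ds_i", "ds_j", "n_minutes"])
    rec = records.sort_values(["episode_id", "person"], kind="mergesort")
    sizes = rec.groupby("episode_id")["person"].transform("size")
    n_missing_side = int((sizes != 2).sum())
    rec = rec[sizes == 2]
    # after the sort each episode occupies two adjacent rows with i < j
    a = rec.iloc[0::2].reset_index(drop=True)
    b = rec.iloc[1::2].reset_index(drop=True)
    ds_series = pd.Series(dict(ds), dtype=float)
    ds_i = a["person"].map(ds_series)
    ds_j = b["person"].map(ds_series)
    have_ds = ds_i.notna() & ds_j.notna()
    n_missing_ds = int((~have_ds).sum())
    out = pd.DataFrame({
        "episode_id": a["episode_id"].astype(int),
        "i": a["person"].astype(int),
        "j": b["person"].astype(int),
        "pe_i": a["pe_hz"].astype(float),
        "pe_j": b["pe_hz"].astype(float),
        "ds_i": ds_i,
        "ds_j": ds_j,
        "n_minutes": a["n_interaction_minutes_used"].astype(int),
    })[have_ds].reset_index(drop=True)
    if episodes is not None:
        n_by_ep = {e.episode_id: e.n_minutes for e in episodes}
        out["n_minutes"] = out["episode_id"].map(n_by_ep).astype(int)
    if n_missing_side or n_missing_ds:
        logger.info("dropped %d one-sided rows and %d DS-missing episodes",
                    n_missing_side, n_missing_ds)
    return out


def to_ego_long(feats: pd.DataFrame) -> pd.DataFrame:
    """Duplicate each episode row into two ego-centric rows (i's and j's view)."""
    if len(feats) == 0:
        return pd.DataFrame(columns=EGO_COLUMNS)
    a = pd.DataFrame({
        "ego": feats["i"], "partner": feats["j"], "episode_id": feats["episode_id"],
        "pe_self": feats["pe_i"], "pe_partner": feats["pe_j"],
        "ds_self": feats["ds_i"], "ds_partner": feats["ds_j"],
        "n_minutes": feats["n_minutes"],
    })
    b = pd.DataFrame({
        "ego": feats["j"], "partner": feats["i"], "episode_id": feats["episode_id"],
        "pe_self": feats["pe_j"], "pe_partner": feats["pe_i"],
        "ds_self": feats["ds_j"], "ds_partner": feats["ds_i"],
        "n_minutes": feats["n_minutes"],
    })
    return pd.concat([a, b], ignore_index=True)


def _as_ego_long(feats_or_ego: pd.DataFrame) -> pd.DataFrame:
    if "ego" in feats_or_ego.columns:
        return feats_or_ego
    return to_ego_long(feats_or_ego)


def rank_partners(ego_long: pd.DataFrame) -> pd.DataFrame:
    """Per (ego, partner): episode count and total minutes, sorted by rank.

    Rank order: more episodes first, then more total minutes, then the
    smaller partner id — a deterministic total order.
    """
    stats = (ego_long.groupby(["ego", "partner"])
             .agg(n_episodes=("episode_id", "size"),
                  total_minutes=("n_minutes", "sum"))
             .reset_index())
    return stats.sort_values(["ego", "n_episodes", "total_minutes", "partner"],
                             ascending=[True, False, False, True],
                             kind="mergesort").reset_index(drop=True)


def restrict_to_top_partners(feats_or_ego: pd.DataFrame, n_partners: int) -> pd.DataFrame:
    """Ego-long rows restricted to each ego's top-N partners by frequency.

    The restriction is ego-relative: episode k between i and j may
    survive in i's view and not in j's.  Egos with fewer than N partners
    keep all of them.
    """
    if n_partners < 1:
        raise ValueError("n_partners must be >= 1")
    ego_long = _as_ego_long(feats_or_ego)
    if len(ego_long) == 0:
        return ego_long
    ranked = rank_partners(ego_long)
    top = ranked.groupby("ego").head(n_partners)[["ego", "partner"]]
    return ego_long.merge(top, on=["ego", "partner"], how="inner")


def employee_features(feats_or_ego: pd.DataFrame,
                      org: Mapping[int, int] | None = None) -> pd.DataFrame:
    """Episode-weighted per-employee means of the interaction features."""
    ego_long = _as_ego_long(feats_or_ego)
    if len(ego_long) == 0:
        return pd.DataFrame(columns=["person_id", "mean_pe_self", "mean_pe_partner",
                                     "ds_self", "mean_ds_partner", "n_interactions",
                                     "n_distinct_partners", "org_id"])
    agg = (ego_long.groupby("ego")
           .agg(mean_pe_self=("pe_self", "mean"),
                mean_pe_partner=("pe_partner", "mean"),
                ds_self=("ds_self", "first"),
                mean_ds_partner=("ds_partner", "mean"),
                n_interactions=("episode_id", "size"),
                n_distinct_partners=("partner", "nunique"))
           .reset_index()
           .rename(columns={"ego": "person_id"}))
    agg["org_id"] = (agg["person_id"].map(org) if org is not None else np.nan)
    return agg
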