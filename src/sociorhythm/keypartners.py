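"""Key interaction partners: top-3 nominations and tertile grouping.

Each employee nominates their top-k (default 3) most frequent
interaction partners; an employee's *selection count* is the number of
times colleagues in the same workplace nominated them.  Employees are
then split into high / middle / low groups at the tertile points of the
pooled selection-count distribution: high strictly above the upper
tertile, middle strictly above the lower tertile, low otherwise.  The
strict inequalities push ties at a cut into the lower group, which is
what makes unequal group sizes (high smallest) possible on heavily tied
counts.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .features import rank_partners, _as_ego_long

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 3
GROUPS = ("high", "middle", "low")


def top_k_selection_counts(feats_or_ego: pd.DataFrame,
                           org: Mapping[int, int],
                           k: int = DEFAULT_TOP_K) -> pd.Series:
    """Selection counts: times each person appears in colleagues' top-k lists.

    Nominations only count within the nominator's organization (episodes
    are within-organization anyway, but the constraint is enforced).
    Persons never nominated get a count of 0.  Ties at rank k use the
    deterministic partner ranking (episodes, minutes, id).
    """
    ego_long = _as_ego_long(feats_or_ego)
    persons = sorted(set(ego_long["ego"]).union(ego_long["partner"]))
    counts = pd.Series(0, index=pd.Index(persons, name="person_id"), dtype=int)
    ranked = rank_partners(ego_long)
    nominations = ranked.groupby("ego").head(k)
    for _, row in nominations.iterrows():
        ego, partner = int(row["ego"]), int(row["partner"])
        if org.get(ego) != org.get(partner):
            continue
        counts.loc[partner] += 1
    counts.name = "selection_count"
    return counts


def tertile_grouping(counts: pd.Series) -> pd.DataFrame:
    """Assign high/middle/low by pooled tertile points of selection counts.

    Cut points are the 1/3 and 2/3 empirical quantiles (lower-value-at-
    ties convention); membership is strict: high iff count > upper cut,
    middle iff count > lower cut, else low.
    """
    if len(counts) < 3:
        raise ValueError("tertile grouping needs at least 3 persons")
    values = counts.to_numpy()
    if np.all(values == values[0]):
        logger.warning("all selection counts identical; everyone grouped low")
        group = np.full(len(counts), "low", dtype=object)
    else:
        lower = np.quantile(values, 1 / 3, method="inverted_cdf")
        upper = np.quantile(values, 2 / 3, method="inverted_cdf")
        group = np.where(values > upper, "high",
                         np.where(values > lower, "middle", "low"))
    return pd.DataFrame({
        "person_id": counts.index,
        "selection_count": values,
        "group": group,
    }).reset_index(drop=True)


def group_sizes(grouping: pd.DataFrame) -> dict[str, int]:
    sizes = grouping["group"].value_counts().to_dict()
    return {g: int(sizes.get(g, 0)) for g in GROUPS}
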