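"""Hypergeometric over-representation analysis of DE feature lists.

For a universe of N genes containing a K-gene annotated set and an n-gene
selection with overlap k, the enrichment p-value is the upper hypergeometric
tail P(X >= k).  Significance defaults to raw p < 0.05 (the rule attached to
the reported enrichments); a BH-adjusted rule is exposed because raw-p ORA is
anticonservative over large collections.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger("mirlink")

__all__ = ["hypergeom_ora", "enrich_collection"]

_ORA_COLUMNS = ["set_name", "N", "K", "n", "k", "ratio", "p", "q", "significant"]


def hypergeom_ora(
    selected: set[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    use_q: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each set against the selection.

    Selected features outside the universe are dropped with a logged count.
    Returns one row per set with columns (set_name, N, K, n, k, ratio, p, q,
    significant), sorted by p ascending with ties broken by set name.
    """
    universe = collection.universe
    if not universe:
        raise ValueError("empty universe")
    inside = set(selected) & universe
    dropped = len(set(selected)) - len(inside)
    if dropped:
        logger.warning("ORA: dropped %d selected feature(s) outside the universe", dropped)
    if not inside:
        raise ValueError("no selected features inside the universe")
    N, n = len(universe), len(inside)
    rows = []
    for name in collection.set_names:
        members = collection.sets[name] & universe
        K = len(members)
        k = len(members & inside)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        ratio = (k / n) / (K / N) if K else np.nan
        rows.append((name, N, K, n, k, ratio, min(p, 1.0)))
    frame = pd.DataFrame(rows, columns=_ORA_COLUMNS[:7])
    frame["q"] = bh_adjust(frame["p"].to_numpy())
    frame["significant"] = (frame["q"] if use_q else frame["p"]) < alpha
    return frame.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)


def enrich_collection(
    de_results: pd.DataFrame,
    collections: dict[str, GeneSetCollection],
    alpha: float = 0.05,
    use_q: bool = False,
) -> dict[str, pd.DataFrame]:
    """ORA of the called DE features against each named collection.

    The selection is ``de_results`` rows with ``called`` true.  An empty call
    set returns empty result frames with a warning rather than an error.
    """
    called = set(de_results.loc[de_results["called"].astype(bool), "feature"])
    out: dict[str, pd.DataFrame] = {}
    for name, collection in collections.items():
        if not called or not (called & collection.universe):
            logger.warning("ORA: no called features usable against collection %r", name)
            out[name] = pd.DataFrame(columns=_ORA_COLUMNS)
            continue
        out[name] = hypergeom_ora(called, collection, alpha=alpha, use_q=use_q)
    return out
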