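"""miRNA-mRNA interactome construction by a four-stage filter cascade.

Candidate (miRNA, gene) pairs drawn from the differentially expressed miRNAs
(DEMs) and genes (DEGs) survive, in order:

1. consensus   — predicted by at least k distinct target-prediction tools,
2. validation  — present in an experimental-validation table (optional),
3. shared target — the gene is paired with at least m distinct DEMs in the
   surviving candidate list,
4. anti-correlation — Pearson r of the configured expression transform across
   all samples below r_max with two-sided p below p_max, and (optionally)
   opposite DE log2FC signs for the miRNA and the gene.

Each surviving edge carries its full evidence: tool count and names,
validation sources, r, p, n and the DE directions of both partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import normalize_counts
from .io import CountMatrix

logger = logging.getLogger("mirlink")

__all__ = [
    "InteractomeConfig",
    "pearson_with_p",
    "correlation_threshold",
    "consensus_pairs",
    "pearson_pair_correlations",
    "apply_validation_filter",
    "apply_shared_target_filter",
    "select_final_pairs",
    "export_network",
    "read_edge_tsv",
]

EDGE_COLUMNS = [
    "mirna", "gene", "tool_count", "tools", "validated", "sources",
    "r", "p_corr", "n", "mirna_log2fc", "gene_log2fc",
]


@dataclass
class InteractomeConfig:
    """Filter thresholds for the interactome cascade.

    min_tools (k), min_sharing (m) follow the published criteria (>=3 tools,
    gene shared by >=2 DEMs); the anti-correlation screen keeps pairs with
    r < r_max and p < p_max (defaults -0.7 and 0.05).  correlation_input picks
    the values fed to Pearson: log2(normalized + 1) (default), normalized, or
    raw counts.
    """

    min_tools: int = 3
    min_sharing: int = 2
    r_max: float = -0.7
    p_max: float = 0.05
    require_validated: bool = True
    require_anticorrelation_sign: bool = True
    correlation_input: str = "log2_normalized"

    def __post_init__(self):
        if not 1 <= self.min_tools <= 8:
            raise ValueError("min_tools must lie in [1, 8]")
        if self.min_sharing < 1:
            raise ValueError("min_sharing must be >= 1")
        if not -1.0 < self.r_max < 0.0:
            raise ValueError("r_max must lie in (-1, 0)")
        if not 0.0 < self.p_max < 1.0:
            raise ValueError("p_max must lie in (0, 1)")
        if self.correlation_input not in ("log2_normalized", "normalized", "raw"):
            raise ValueError("correlation_input must be log2_normalized, normalized or raw")


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p from t = r*sqrt((n-2)/(1-r^2)), df = n-2.

    Returns (nan, nan) for zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Pearson screen needs at least 3 paired samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def correlation_threshold(n: int, p_max: float = 0.05) -> float:
    """|r| above which the two-sided correlation p falls below p_max at n samples.

    Inverts the t quantile at df = n-2: the joint rule (r < r_max and
    p < p_max) is equivalent to r < -max(|r_max|, this threshold).
    """
    df = n - 2
    t_crit = stats.t.ppf(1.0 - p_max / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def consensus_pairs(
    dems: list[str],
    degs: list[str],
    predictions: pd.DataFrame,
    k: int = 3,
    tool_vocabulary: list[str] | None = None,
) -> pd.DataFrame:
    """Candidate (DEM, DEG) pairs predicted by at least k distinct tools.

    Returns columns (mirna, gene, tool_count, tools) with tools a sorted
    comma-joined string.  Tools outside ``tool_vocabulary`` (if given) trigger
    a warning but still count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tool_vocabulary is not None:
        unknown = set(predictions["tool"]) - set(tool_vocabulary)
        if unknown:
            logger.warning("predictions contain tools outside the vocabulary: %s", sorted(unknown))
    sub = predictions[
        predictions["mirna"].isin(set(dems)) & predictions["gene"].isin(set(degs))
    ].drop_duplicates(["mirna", "gene", "tool"])
    if sub.empty:
        return pd.DataFrame(columns=["mirna", "gene", "tool_count", "tools"])
    grouped = (
        sub.groupby(["mirna", "gene"])["tool"]
        .agg(tool_count="nunique", tools=lambda t: ",".join(sorted(set(t))))
        .reset_index()
    )
    keep = grouped[grouped["tool_count"] >= k].sort_values(["mirna", "gene"], kind="mergesort")
    return keep.reset_index(drop=True)


def _correlation_values(counts: CountMatrix, s: pd.Series, mode: str) -> pd.DataFrame:
    if mode == "raw":
        return counts.frame.astype(float)
    norm = normalize_counts(counts, s)
    if mode == "normalized":
        return norm
    return np.log2(norm + 1.0)


def pearson_pair_correlations(
    pairs: pd.DataFrame,
    mirna_counts: CountMatrix,
    mrna_counts: CountMatrix,
    s_mirna: pd.Series,
    s_mrna: pd.Series,
    cfg: InteractomeConfig | None = None,
) -> pd.DataFrame:
    """Pearson screen of each candidate pair across all shared samples.

    Returns columns (mirna, gene, r, p_corr, n, status); status is ``ok``,
    ``missing`` (feature absent from a matrix) or ``degenerate``
    (zero-variance expression, r undefined).  Both matrices must carry an
    identical sample set; order is reconciled by id.
    """
    cfg = cfg or InteractomeConfig()
    if set(mirna_counts.sample_ids) != set(mrna_counts.sample_ids):
        raise ValueError("miRNA and mRNA matrices must share an identical sample set")
    sample_order = mirna_counts.sample_ids
    n = len(sample_order)
    if n < 3:
        raise ValueError("Pearson screen needs at least 3 shared samples")
    vals_mirna = _correlation_values(mirna_counts, s_mirna, cfg.correlation_input)
    vals_mrna = _correlation_values(mrna_counts, s_mrna, cfg.correlation_input)[sample_order]
    rows = []
    for mirna, gene in pairs[["mirna", "gene"]].itertuples(index=False):
        if mirna not in vals_mirna.index or gene not in vals_mrna.index:
            rows.append((mirna, gene, np.nan, np.nan, n, "missing"))
            continue
        r, p = pearson_with_p(vals_mirna.loc[mirna].to_numpy(), vals_mrna.loc[gene].to_numpy())
        if np.isnan(r):
            logger.warning("zero-variance expression for pair (%s, %s)", mirna, gene)
            rows.append((mirna, gene, np.nan, np.nan, n, "degenerate"))
        else:
            rows.append((mirna, gene, r, p, n, "ok"))
    return pd.DataFrame(rows, columns=["mirna", "gene", "r", "p_corr", "n", "status"])


def apply_validation_filter(
    pairs: pd.DataFrame, validated: pd.DataFrame, require: bool = True
) -> pd.DataFrame:
    """Annotate pairs with validation evidence; drop unvalidated ones if required."""
    if validated.empty:
        ann = pairs.copy()
        ann["validated"] = False
        ann["sources"] = ""
    else:
        src = (
            validated.groupby(["mirna", "gene"])["source"]
            .agg(lambda s: ",".join(sorted(set(s))))
            .rename("sources")
            .reset_index()
        )
        ann = pairs.merge(src, on=["mirna", "gene"], how="left")
        ann["validated"] = ann["sources"].notna()
        ann["sources"] = ann["sources"].fillna("")
    if require:
        ann = ann[ann["validated"]]
    return ann.reset_index(drop=True)


def apply_shared_target_filter(pairs: pd.DataFrame, m: int = 2) -> pd.DataFrame:
    """Keep pairs whose gene is paired with >= m distinct miRNAs in this list."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if pairs.empty:
        return pairs.reset_index(drop=True)
    sharing = pairs.groupby("gene")["mirna"].nunique()
    keep = pairs["gene"].map(sharing) >= m
    return pairs[keep].reset_index(drop=True)


def select_final_pairs(
    pairs: pd.DataFrame,
    correlations: pd.DataFrame,
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    cfg: InteractomeConfig | None = None,
    validated: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full cascade on consensus pairs and return the surviving edges.

    ``pairs`` is a consensus table (mirna, gene, tool_count, tools);
    ``correlations`` the Pearson screen output; ``de_mirna``/``de_mrna`` DE
    result frames supplying log2FC signs.  Returns (edges, stage_counts) with
    edges sorted by (r ascending, mirna, gene) and stage_counts recording the
    pair count after each filter stage.
    """
    cfg = cfg or InteractomeConfig()
    counts: dict[str, int] = {"consensus": len(pairs)}
    current = pairs.copy()

    if validated is not None:
        current = apply_validation_filter(current, validated, require=cfg.require_validated)
    else:
        current["validated"] = current.get("validated", False)
        current["sources"] = current.get("sources", "")
        if cfg.require_validated:
            current = current[current["validated"].astype(bool)]
    counts["validated"] = len(current)

    current = apply_shared_target_filter(current, cfg.min_sharing)
    counts["shared"] = len(current)

    merged = current.merge(correlations, on=["mirna", "gene"], how="left")
    ok = merged["status"].eq("ok")
    passing = ok & (merged["r"] < cfg.r_max) & (merged["p_corr"] < cfg.p_max)
    merged = merged[passing]
    counts["correlation"] = len(merged)

    lfc_mirna = de_mirna.set_index("feature")["log2fc"]
    lfc_gene = de_mrna.set_index("feature")["log2fc"]
    merged = merged.assign(
        mirna_log2fc=merged["mirna"].map(lfc_mirna), gene_log2fc=merged["gene"].map(lfc_gene)
    )
    if cfg.require_anticorrelation_sign:
        opposite = (merged["mirna_log2fc"] * merged["gene_log2fc"]) < 0
        merged = merged[opposite.fillna(False)]
    counts["final"] = len(merged)

    merged = merged.rename(columns={})[
        [c for c in EDGE_COLUMNS if c in merged.columns] + ["status"]
    ]
    edges = merged.drop(columns=["status"]).sort_values(
        ["r", "mirna", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    return edges, counts


def export_network(edges: pd.DataFrame, path: str | Path, format: str = "graphml") -> None:
    """Write the bipartite miRNA-gene network (node attribute ``type``).

    ``graphml`` via networkx, or ``edge_tsv`` carrying all evidence columns.
    Node and edge ordering is deterministic: miRNAs then genes, each sorted;
    edges as provided (already sorted by the cascade).
    """
    path = Path(path)
    if format == "edge_tsv":
        cols = [c for c in EDGE_COLUMNS if c in edges.columns]
        edges[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")
        return
    if format != "graphml":
        raise ValueError("format must be graphml or edge_tsv")
    graph = nx.Graph()
    for m in sorted(edges["mirna"].unique()) if len(edges) else []:
        graph.add_node(m, type="mirna")
    for g in sorted(edges["gene"].unique()) if len(edges) else []:
        graph.add_node(g, type="gene")
    for row in edges.itertuples(index=False):
        attrs = {}
        for key in ("tool_count", "validated", "r"):
            if hasattr(row, key):
                attrs[key] = getattr(row, key)
        if hasattr(row, "p_corr"):
            attrs["p"] = row.p_corr
        graph.add_edge(row.mirna, row.gene, **attrs)
    nx.write_graphml(graph, path)


def read_edge_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "sources" in frame.columns:
        frame["sources"] = frame["sources"].fillna("")
    if "tools" in frame.columns:
        frame["tools"] = frame["tools"].fillna("")
    return frame
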