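"""Per-cluster GO over-representation analysis.

One-sided hypergeometric tail test per (cluster, term), with BH adjustment
scoped within each (cluster, namespace), following clusterProfiler's output
conventions (GeneRatio k/n, BgRatio K/N). The default universe is the set of
analyzed genes that appear in at least one gene set; term sizes are filtered
to 10..500 after intersecting with the universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .gapstat import ClusterAssignment
from .io import GeneSetCollection, ValidationError

MIN_SET = 10
MAX_SET = 500

COLUMNS = ["cluster", "term_id", "name", "namespace", "k", "n", "K", "N",
           "gene_ratio", "bg_ratio", "pvalue", "padj", "top10", "genes"]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): drawing n genes from a
    universe of N of which K are annotated, seeing k or more annotated."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require K <= N and n <= N; got K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_cluster(cluster_genes, universe, sets: GeneSetCollection,
                   min_set: int = MIN_SET, max_set: int = MAX_SET) -> pd.DataFrame:
    """Over-representation rows for one gene cluster against the universe.

    Terms are intersected with the universe and filtered to
    min_set <= K <= max_set; BH adjustment is applied within each namespace.
    Rows are sorted by padj then pvalue.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    cluster = sorted(set(cluster_genes))  # dedupe; deterministic order
    outside = [g for g in cluster if g not in universe]
    if outside:
        raise ValidationError(f"cluster gene(s) absent from universe: {outside[:5]}")
    n = len(cluster)
    N = len(universe)
    cluster_set = set(cluster)

    rows = []
    for gs in sets.values():
        members = gs.genes & universe
        K = len(members)
        if not (min_set <= K <= max_set):
            continue
        overlap = sorted(cluster_set & members)
        k = len(overlap)
        rows.append({
            "term_id": gs.term_id, "name": gs.name, "namespace": gs.namespace,
            "k": k, "n": n, "K": K, "N": N,
            "gene_ratio": f"{k}/{n}", "bg_ratio": f"{K}/{N}",
            "pvalue": hypergeom_tail(k, K, n, N),
            "genes": ",".join(overlap),
        })
    if not rows:
        return pd.DataFrame(columns=[c for c in COLUMNS if c not in ("cluster", "top10")])
    df = pd.DataFrame(rows)
    df["padj"] = np.nan
    for ns in df["namespace"].unique():
        mask = df["namespace"] == ns
        df.loc[mask, "padj"] = bh_adjust(df.loc[mask, "pvalue"].to_numpy())
    return df.sort_values(["padj", "pvalue", "term_id"]).reset_index(drop=True)


def enrich_clusters(assignment: ClusterAssignment, universe,
                    sets: GeneSetCollection, min_set: int = MIN_SET,
                    max_set: int = MAX_SET) -> pd.DataFrame:
    """Map :func:`enrich_cluster` over every cluster; one table with a cluster
    column and the top-10 terms per (cluster, namespace) flagged (by padj,
    then pvalue). BH scoping stays within each cluster. Cluster members
    outside the universe (e.g. unannotated genes under the default universe)
    are dropped from the tested gene list, mirroring clusterProfiler."""
    universe = set(universe)
    frames = []
    for c in range(1, assignment.K + 1):
        members = [g for g in assignment.members(c) if g in universe]
        if not members:
            continue
        df = enrich_cluster(members, universe, sets, min_set, max_set)
        if df.empty:
            continue
        df.insert(0, "cluster", c)
        df["top10"] = False
        for ns in df["namespace"].unique():
            idx = df.index[df["namespace"] == ns][:10]
            df.loc[idx, "top10"] = True
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=COLUMNS)
    return pd.concat(frames, ignore_index=True)[COLUMNS]


def default_universe(analyzed_genes, sets: GeneSetCollection) -> set:
    """Genes of the analyzed set that appear in >= 1 gene set (the default
    conditioning); alternatives are all matrix genes or all annotated genes."""
    annotated = sets.annotated_genes()
    return set(analyzed_genes) & annotated
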