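"""t-SNE embedding and kNN-Louvain clustering of single-cell intensities.

The workflow: balanced subsampling per case-type/region subgroup, natural-log
transform of the five marker intensities (equal weighting), Barnes-Hut t-SNE
to 2D with learning rate N/EE and early exaggeration EE for the first 250 of
1000 iterations, a k-nearest-neighbour graph on the embedding with
k = floor(sqrt(N)), Louvain community detection on that graph, and the
cluster composition/phenotyping tables: group contribution per cluster,
per-case cluster percentages, and the relative MOI^high percentage (a
cluster's MOI^high percentage for a case minus that case's overall
percentage, so positive values mark enrichment).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from .config import MARKERS, ConfigError, EmbeddingConfig

__all__ = [
    "ClusterResult",
    "subsample_balanced",
    "log_transform",
    "tsne_embed",
    "knn_graph",
    "louvain_cluster",
    "run_clustering",
    "cluster_group_contribution",
    "cluster_case_percentages",
    "relative_moi_high",
]


class SubsampleError(ValueError):
    pass


@dataclass
class ClusterResult:
    """Embedding + cluster labels for the subsampled cells.

    ``cells`` carries the subsampled cell table joined with columns
    tsne_x, tsne_y and cluster (labels contiguous from 1).
    """

    cells: pd.DataFrame
    k: int
    n_clusters: int
    modularity: float


def subsample_balanced(
    cells: pd.DataFrame,
    n_per_group: int,
    by: tuple[str, ...] = ("group", "region"),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw exactly ``n_per_group`` cells without replacement from every
    case-type/region subgroup, so each subgroup contributes equally to the
    embedding. Raises naming the subgroup when one is undersized."""
    rng = np.random.default_rng(seed)
    parts = []
    for key, grp in cells.groupby(list(by), sort=True, observed=True):
        if len(grp) < n_per_group:
            raise SubsampleError(
                f"subgroup {key} has {len(grp)} cells, fewer than the "
                f"requested {n_per_group}"
            )
        take = rng.choice(len(grp), size=n_per_group, replace=False)
        parts.append(grp.iloc[np.sort(take)])
    return pd.concat(parts, ignore_index=True)


def log_transform(
    cells: pd.DataFrame, markers: tuple[str, ...] = MARKERS
) -> np.ndarray:
    """Natural-log feature matrix (N x 5) in fixed marker order.

    Zero intensities get a pseudocount of 1 (warned); negatives are an
    error. No per-column scaling is applied — the log itself provides the
    equal weighting across markers.
    """
    x = cells[list(markers)].to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("negative marker intensity in cell table")
    if np.any(x == 0):
        warnings.warn("zero intensities present; adding pseudocount 1 before log")
        x = x + 1.0
    return np.log(x)


def tsne_embed(features: np.ndarray, config: EmbeddingConfig) -> np.ndarray:
    """Barnes-Hut t-SNE to 2D with the tied learning-rate rule.

    learning_rate = N / EE_factor; early exaggeration EE_factor during the
    first 250 iterations of ``max_iterations``; PCA initialisation for
    reproducible global geometry; seed fixes the run.
    """
    features = np.asarray(features, dtype=float)
    if np.any(~np.isfinite(features)):
        raise ValueError("features contain NaN or infinities")
    n = features.shape[0]
    perplexity = config.perplexity
    if n <= 3 * perplexity:
        perplexity = max((n - 1) / 3.0, 2.0)
        warnings.warn(
            f"perplexity reduced to {perplexity:.1f} for N={n} (requires N > 3*perplexity)"
        )
    if config.ee_iterations != 250:
        warnings.warn(
            "the Barnes-Hut backend applies early exaggeration for a fixed "
            "250 iterations; ee_iterations ignored"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=config.learning_rate(n),
        early_exaggeration=config.ee_factor,
        max_iter=config.max_iterations,
        init="pca",
        method="barnes_hut",
        random_state=config.seed,
    )
    emb = tsne.fit_transform(features)
    return np.asarray(emb, dtype=float)


def knn_graph(embedding: np.ndarray, k: int | None = None, chunk: int = 2048) -> ig.Graph:
    """Undirected kNN graph on the 2D embedding, k = floor(sqrt(N)) by
    default. Edge (i, j) exists iff j is among i's k nearest Euclidean
    neighbours (union-symmetrised, unweighted); distance ties break in
    index order."""
    pts = np.asarray(embedding, dtype=float)
    n = pts.shape[0]
    if k is None:
        k = int(np.floor(np.sqrt(n)))
    if k <= 0:
        raise ConfigError("k must be positive")
    if k >= n:
        raise ConfigError(f"k={k} must be smaller than N={n}")
    edges: set[tuple[int, int]] = set()
    for start in range(0, n, chunk):
        block = pts[start : start + chunk]
        d = cdist(block, pts)
        for i in range(block.shape[0]):
            gi = start + i
            row = d[i].copy()
            row[gi] = np.inf  # exclude self
            # argpartition narrows candidates; stable sort on (distance,
            # index) enforces the index-order tie rule
            cand = np.argpartition(row, min(2 * k, n - 1))[: min(2 * k + 1, n)]
            cand = cand[np.lexsort((cand, row[cand]))][:k]
            for j in cand:
                edges.add((min(gi, int(j)), max(gi, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def louvain_cluster(graph: ig.Graph, seed: int = 0) -> tuple[np.ndarray, float]:
    """Louvain (multilevel modularity) communities on the kNN graph.

    Returns (labels contiguous from 1, modularity). The label order is made
    deterministic given the seed by renumbering communities by their first
    member's index.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    random.seed(seed)
    part = graph.community_multilevel()
    membership = np.asarray(part.membership)
    # renumber by first occurrence so labels are stable and 1-based
    _, first_idx = np.unique(membership, return_index=True)
    order = membership[np.sort(first_idx)]
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.asarray([remap[m] for m in membership], dtype=int)
    return labels, float(graph.modularity(part.membership))


def run_clustering(
    cells: pd.DataFrame,
    config: EmbeddingConfig,
    markers: tuple[str, ...] = MARKERS,
    cluster_on: str = "embedding",
) -> ClusterResult:
    """Subsample -> log -> t-SNE -> kNN -> Louvain, returning a ClusterResult.

    ``cluster_on='embedding'`` builds the kNN graph on the 2D t-SNE
    coordinates (the reference procedure); ``'features'`` clusters the 5D
    log-intensity space directly, offered only as a sensitivity analysis.
    """
    sub = subsample_balanced(cells, config.n_per_group, seed=config.seed)
    feats = log_transform(sub, markers)
    emb = tsne_embed(feats, config)
    space = emb if cluster_on == "embedding" else feats
    g = knn_graph(space)
    labels, q = louvain_cluster(g, seed=config.seed)
    out = sub.copy()
    out["tsne_x"] = emb[:, 0]
    out["tsne_y"] = emb[:, 1]
    out["cluster"] = labels
    return ClusterResult(
        cells=out,
        k=int(np.floor(np.sqrt(len(out)))),
        n_clusters=int(labels.max()),
        modularity=q,
    )


def cluster_group_contribution(cells: pd.DataFrame) -> pd.DataFrame:
    """Percentage of each cluster's cells contributed by each case group.

    Wide table indexed by cluster with one column per group; rows sum to
    100 (the paper's per-cluster control-vs-disease contribution bars).
    """
    counts = cells.groupby(["cluster", "group"], observed=True).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def cluster_case_percentages(cells: pd.DataFrame) -> pd.DataFrame:
    """Per case: the percentage of that case's cells falling in each
    cluster (long format: case_id, group, region, cluster, pct). Sums to
    100 across clusters within each case."""
    counts = (
        cells.groupby(["case_id", "group", "region", "cluster"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby("case_id")["n"].transform("sum")
    counts["pct"] = 100.0 * counts["n"] / totals
    return counts.drop(columns="n")


def relative_moi_high(
    cells: pd.DataFrame, markers: tuple[str, ...] = MARKERS
) -> pd.DataFrame:
    """Relative MOI^high percentage per (cluster, case, marker).

    rel = pct_high(marker | cluster, case) - pct_high(marker | case overall),
    in percentage points; > 0 means the cluster is enriched for that
    marker's high-expressing cells relative to the case baseline.
    Cluster-case pairs with no cells do not appear (they are null).
    """
    flag_cols = [f"{m}_high" for m in markers]
    missing = [c for c in flag_cols if c not in cells.columns]
    if missing:
        raise ValueError(f"missing MOI^high flags: {missing}")
    overall = cells.groupby("case_id", observed=True)[flag_cols].mean() * 100.0
    per_cluster = (
        cells.groupby(["cluster", "case_id"], observed=True)[flag_cols].mean() * 100.0
    )
    sizes = cells.groupby(["cluster", "case_id"], observed=True).size().rename("n_cells")
    rows = []
    for (cluster, case_id), vals in per_cluster.iterrows():
        for m in markers:
            rows.append(
                {
                    "cluster": cluster,
                    "case_id": case_id,
                    "marker": m,
                    "rel_pct_high": vals[f"{m}_high"] - overall.loc[case_id, f"{m}_high"],
                    "n_cells": int(sizes.loc[(cluster, case_id)]),
                }
            )
    return pd.DataFrame(rows)
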