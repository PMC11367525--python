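"""Hierarchical clustering of logFC profiles, Fisher-exact GO enrichment,
top-variable PCA, and per-gene z-score trajectories."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact

from .data_model_io import MODALITY_PROTEIN, ExpressionMatrix, validate_samples
from .transcript_de import DEResult

DEFAULT_LINKAGE = "ward"
DEFAULT_N_TOP_RNA = 500
DEFAULT_N_TOP_PROTEIN = 300


@dataclass
class ClusterResult:
    """Partition of DE genes by their logFC trajectories.

    ``assignments`` maps gene_id -> cluster id in 1..k, with cluster 1 the
    most upregulated at the final time point.
    """

    assignments: pd.Series
    k: int
    linkage: str
    quartiles: pd.DataFrame  # cluster, time column, q25/q50/q75

    def genes_in(self, cluster_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])


@dataclass
class EnrichmentResult:
    """Fisher-exact enrichment table (one row per term x cluster)."""

    table: pd.DataFrame  # term, cluster, a, b, c, d, p, fold_enrichment

    def top_terms(self, cluster_id: int, n: int = 4) -> pd.DataFrame:
        sub = self.table[self.table["cluster"] == cluster_id]
        return sub.sort_values(["p", "fold_enrichment"], ascending=[True, False]).head(n)


def cluster_logfc(
    deresult: DEResult, k: int, linkage: str = DEFAULT_LINKAGE
) -> ClusterResult:
    """Agglomerative clustering of DE genes on Euclidean logFC distance.

    The tree is cut into k clusters which are relabeled by descending mean
    logFC at the final time point (cluster 1 = most upregulated). The
    procedure is fully deterministic; gene order does not affect the
    partition.
    """
    logfc = deresult.logfc_matrix().loc[deresult.table["is_DE"]]
    n = len(logfc)
    if k > n:
        raise ValueError(f"k={k} exceeds number of DE genes ({n})")
    if n == 0:
        raise ValueError("no DE genes to cluster")
    # sort genes by id so the partition is invariant to input row order
    logfc = logfc.sort_index()
    X = logfc.to_numpy(dtype=float)
    if n == 1:
        raw = np.array([1])
    else:
        Z = hierarchy.linkage(X, method=linkage)
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    final_col = logfc.columns[-1]
    means = pd.Series(X[:, -1], index=logfc.index).groupby(raw).mean()
    order = means.sort_values(ascending=False).index.tolist()
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignments = pd.Series([relabel[c] for c in raw], index=logfc.index, name="cluster")

    rows = []
    for cid in range(1, k + 1):
        sub = logfc.loc[assignments == cid]
        for col in logfc.columns:
            q25, q50, q75 = np.percentile(sub[col], [25, 50, 75]) if len(sub) else (np.nan,) * 3
            rows.append({"cluster": cid, "timepoint": col, "q25": q25, "q50": q50, "q75": q75})
    return ClusterResult(assignments, k, linkage, pd.DataFrame(rows))


def go_fisher(
    cluster_genes: Sequence[str],
    background_genes: Sequence[str],
    gene_sets: Mapping[str, set[str]],
    min_term_size: int = 3,
    cluster_id: int = 1,
) -> EnrichmentResult:
    """One-sided Fisher exact enrichment of each term in one cluster.

    2x2 table: a = term members in the cluster, b = cluster non-members,
    c = term members outside the cluster, d = the rest of the background.
    fold_enrichment = (a/cluster size)/(term size/background size). Terms
    with fewer than ``min_term_size`` annotated background genes are
    skipped; results are sorted by p (ties by larger fold enrichment).
    """
    background = set(background_genes)
    cluster = set(cluster_genes) & background
    n_bg = len(background)
    n_cl = len(cluster)
    rows = []
    for term, members in gene_sets.items():
        in_bg = members & background
        if len(in_bg) < min_term_size:
            continue
        a = len(in_bg & cluster)
        b = n_cl - a
        c = len(in_bg) - a
        d = n_bg - n_cl - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        fold = (a / n_cl) / (len(in_bg) / n_bg) if n_cl and in_bg else 0.0
        rows.append(
            {
                "term": term,
                "cluster": cluster_id,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p": float(p),
                "fold_enrichment": fold,
            }
        )
    table = pd.DataFrame(
        rows, columns=["term", "cluster", "a", "b", "c", "d", "p", "fold_enrichment"]
    )
    table = table.sort_values(["p", "fold_enrichment"], ascending=[True, False]).reset_index(
        drop=True
    )
    return EnrichmentResult(table)


def enrich_clusters(
    clusters: ClusterResult,
    background_genes: Sequence[str],
    gene_sets: Mapping[str, set[str]],
    min_term_size: int = 3,
) -> EnrichmentResult:
    """Fisher enrichment for every cluster, concatenated."""
    tables = []
    for cid in range(1, clusters.k + 1):
        res = go_fisher(
            clusters.genes_in(cid), background_genes, gene_sets, min_term_size, cluster_id=cid
        )
        tables.append(res.table)
    return EnrichmentResult(pd.concat(tables, ignore_index=True))


def pca_top_variable(
    matrix: ExpressionMatrix | pd.DataFrame, n_top: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the n_top most variable genes.

    Genes are ranked by variance across samples, centered (per gene), and
    decomposed by SVD. Returns (sample scores with PC columns,
    variance-explained percentages summing to 100 over all PCs).
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    variances = values.var(axis=1)
    top = variances.sort_values(ascending=False, kind="mergesort").index[:n_top]
    X = values.loc[top].to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    # samples x genes for sample scores
    U, S, Vt = np.linalg.svd(X.T, full_matrices=False)
    scores = U * S
    total = (S**2).sum()
    var_explained = 100.0 * S**2 / total if total > 0 else np.zeros_like(S)
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=values.columns, columns=cols), var_explained


def milestone_zscores(
    matrix: ExpressionMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    gene_sets: Optional[Mapping[str, set[str]]] = None,
    modality: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene z-score trajectories over time-point means.

    For each gene the replicate mean is taken per time point, then
    standardized over time points. Constant genes get an all-zero
    trajectory and are flagged. If ``gene_sets`` is given, only member
    genes are returned.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    samples = validate_samples(samples)
    sub = samples[samples["sample_id"].isin(values.columns)]
    if modality is not None:
        sub = sub[sub["modality"] == modality]
    timepoints = sorted(sub["time_h"].unique())
    means = pd.DataFrame(index=values.index, dtype=float)
    for t in timepoints:
        cols = sub.loc[sub["time_h"] == t, "sample_id"].tolist()
        means[f"{t:g}"] = values[cols].mean(axis=1)
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    constant = sd <= 0
    z = means.sub(mu, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    if gene_sets is not None:
        keep = set().union(*gene_sets.values()) & set(z.index)
        z = z.loc[[g for g in z.index if g in keep]]
        constant = constant.loc[z.index]
    return z, constant.rename("constant")
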