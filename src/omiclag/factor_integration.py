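"""Multi-view factor decomposition of the paired dataset.

A deterministic truncated SVD of the gene-wise stacked, per-gene centered,
equal-total-variance-scaled views, with per-factor per-view variance
explained, max-|loading| scaling, the both-view loading threshold gene
classification, and permutation GSEA on factor weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .concordance import _replicate_means
from .data_model_io import MODALITY_PROTEIN, MODALITY_TRANSCRIPT, ExpressionMatrix

DEFAULT_LOADING_THRESHOLD = 0.45

VIEW_RNA = "rna"
VIEW_PROTEIN = "protein"


@dataclass
class FactorModel:
    """K-factor multi-view decomposition.

    ``loadings`` maps view -> gene x factor DataFrame scaled so the largest
    absolute loading per factor per view is 1; ``factors`` is sample/time x
    factor; ``variance_explained`` is factor x view in percent.
    """

    loadings: dict[str, pd.DataFrame]
    factors: pd.DataFrame
    variance_explained: pd.DataFrame
    loading_threshold: float = DEFAULT_LOADING_THRESHOLD
    raw_loadings: Optional[dict[str, pd.DataFrame]] = None

    @property
    def k(self) -> int:
        return self.factors.shape[1]


def fit_multiview_factors(
    rna_matrix: ExpressionMatrix | pd.DataFrame,
    prot_matrix: ExpressionMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    k: int,
    loading_threshold: float = DEFAULT_LOADING_THRESHOLD,
    average_replicates: bool = True,
) -> FactorModel:
    """Fit a K-factor multi-view SVD on the common genes of both views.

    Views are replicate-averaged per time point (default) or aligned on
    per-plate samples, centered per gene, scaled so both views carry equal
    total variance, stacked gene-wise, and decomposed by truncated SVD.
    Factor values are the right singular vectors scaled by the singular
    values; variance_explained[k, view] = 100 * s_k^2 ||u_k,view||^2 /
    ||Y_view||^2. Factor signs are fixed so the value at the last time
    point (column) is non-negative.
    """
    rna_values = rna_matrix.values if isinstance(rna_matrix, ExpressionMatrix) else rna_matrix
    prot_values = prot_matrix.values if isinstance(prot_matrix, ExpressionMatrix) else prot_matrix
    if average_replicates:
        rna = _replicate_means(ExpressionMatrix(rna_values, "log_intensity"), samples, MODALITY_TRANSCRIPT)
        prot = _replicate_means(ExpressionMatrix(prot_values, "log_intensity"), samples, MODALITY_PROTEIN)
        shared = [t for t in rna.columns if t in set(prot.columns)]
        rna = rna[shared]
        prot = prot[shared]
        columns = [f"{t:g}" for t in shared]
    else:
        from .concordance import _paired_columns

        pairs = _paired_columns(samples)
        rna = rna_values[pairs["sample_id_rna"].tolist()]
        prot = prot_values[pairs["sample_id_prot"].tolist()]
        columns = pairs["plate"].tolist()
    common = [g for g in rna.index if g in set(prot.index)]
    if len(common) == 0:
        raise ValueError("no common genes between views")
    n_cols = len(columns)
    if k > min(n_cols, 2 * len(common)):
        raise ValueError(f"k={k} exceeds the rank bound")

    views = {}
    norms = {}
    for name, df in ((VIEW_RNA, rna.loc[common]), (VIEW_PROTEIN, prot.loc[common])):
        X = df.to_numpy(dtype=float)
        X = X - X.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(X)
        if norm > 0:
            X = X / norm  # equal total variance per view
        views[name] = X
        norms[name] = norm

    stacked = np.vstack([views[VIEW_RNA], views[VIEW_PROTEIN]])
    U, S, Vt = np.linalg.svd(stacked, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]

    # deterministic signs: factor value at the last column non-negative
    signs = np.where(Vt[:, -1] < 0, -1.0, 1.0)
    U = U * signs[None, :]
    Vt = Vt * signs[:, None]

    factors = pd.DataFrame(
        (Vt.T * S[None, :]), index=columns, columns=[f"Factor{i+1}" for i in range(k)]
    )
    n_genes = len(common)
    raw_loadings = {}
    loadings = {}
    ve = pd.DataFrame(
        index=[f"Factor{i+1}" for i in range(k)], columns=[VIEW_RNA, VIEW_PROTEIN], dtype=float
    )
    slices = {VIEW_RNA: slice(0, n_genes), VIEW_PROTEIN: slice(n_genes, 2 * n_genes)}
    for name in (VIEW_RNA, VIEW_PROTEIN):
        u_view = U[slices[name]]
        raw = pd.DataFrame(u_view, index=common, columns=factors.columns)
        raw_loadings[name] = raw
        maxabs = np.abs(u_view).max(axis=0)
        scaled = u_view / np.where(maxabs > 0, maxabs, 1.0)[None, :]
        loadings[name] = pd.DataFrame(scaled, index=common, columns=factors.columns)
        total = np.sum(views[name] ** 2)
        for i in range(k):
            captured = S[i] ** 2 * np.sum(u_view[:, i] ** 2)
            ve.loc[f"Factor{i+1}", name] = 100.0 * captured / total if total > 0 else 0.0
    return FactorModel(loadings, factors, ve, loading_threshold, raw_loadings)


def select_factor_genes(model: FactorModel, factor_index: int = 1) -> pd.DataFrame:
    """Genes whose scaled loading exceeds the threshold in BOTH views.

    Returns a DataFrame with the two loadings and a class column:
    concordant-up (both positive), concordant-down (both negative),
    discordant (opposite signs).
    """
    col = f"Factor{factor_index}"
    lr = model.loadings[VIEW_RNA][col]
    lp = model.loadings[VIEW_PROTEIN][col]
    thr = model.loading_threshold
    keep = (lr.abs() >= thr) & (lp.abs() >= thr)
    out = pd.DataFrame({"loading_rna": lr[keep], "loading_protein": lp[keep]})
    both_up = (out["loading_rna"] > 0) & (out["loading_protein"] > 0)
    both_down = (out["loading_rna"] < 0) & (out["loading_protein"] < 0)
    out["class"] = np.where(both_up, "concordant-up", np.where(both_down, "concordant-down", "discordant"))
    return out


def gsea_factor_weights(
    model: FactorModel,
    view: str,
    factor_index: int,
    gene_sets: Mapping[str, set[str]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation GSEA on one factor's loadings in one view.

    Statistic: mean loading of the set members. Null: ``n_perm`` random
    same-size draws from the view's gene universe. Two-sided
    p = (1 + #{|null - mean| >= |obs - mean|}) / (n_perm + 1), where the
    overall mean loading centers both sides so that the p-value is
    invariant to affine rescaling of the loadings.
    """
    col = f"Factor{factor_index}"
    weights = model.loadings[view][col]
    universe = weights.index.to_numpy()
    w = weights.to_numpy(dtype=float)
    overall = w.mean()
    rng = np.random.default_rng(seed)
    rows = []
    by_size: dict[int, np.ndarray] = {}
    for term, members in gene_sets.items():
        idx = [i for i, g in enumerate(universe) if g in members]
        if not idx:
            continue
        m = len(idx)
        obs = w[idx].mean()
        if m == w.size:
            rows.append({"term": term, "n_genes": m, "mean_weight": obs, "p": 1.0})
            continue
        if m not in by_size:
            null = np.empty(n_perm)
            for b in range(n_perm):
                null[b] = w[rng.choice(w.size, size=m, replace=False)].mean()
            by_size[m] = null
        null = by_size[m]
        p = (1.0 + np.sum(np.abs(null - overall) >= np.abs(obs - overall))) / (n_perm + 1.0)
        rows.append({"term": term, "n_genes": m, "mean_weight": obs, "p": float(p)})
    out = pd.DataFrame(rows, columns=["term", "n_genes", "mean_weight", "p"])
    out["neg_log10_p"] = -np.log10(out["p"]) if len(out) else pd.Series(dtype=float)
    return out.sort_values("p").reset_index(drop=True)
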