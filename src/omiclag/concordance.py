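"""mRNA-protein concordance statistics.

Fraction-of-total scaling, across-gene Spearman correlation at and across
time points (the lag matrix and the offset maximizing it), ranged-major-axis
regression, per-gene Pearson correlations over plate-paired samples, the
matched-versus-mismatched plate permutation test, and top-k abundance
shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import (
    MODALITY_PROTEIN,
    MODALITY_TRANSCRIPT,
    ExpressionMatrix,
    validate_samples,
)

PSEUDO_FRACTION = 1e-12  # guards log of zero fractions


@dataclass
class ConcordanceResult:
    """Bundle of concordance outputs (see module docstring)."""

    per_timepoint_rho: pd.Series  # index: shared time points
    lag_matrix: pd.DataFrame  # rows: RNA times, cols: protein times
    estimated_lag_h: float
    per_gene_r: Optional[pd.Series] = None
    rma: Optional[pd.DataFrame] = None  # per time point slope/intercept
    matched_median_r: Optional[float] = None
    mismatched_median_r: Optional[float] = None
    permutation_p: Optional[float] = None


def fraction_of_total(matrix: ExpressionMatrix | pd.DataFrame, delog: bool = False) -> ExpressionMatrix:
    """Scale each sample so its values sum to 1.

    ``delog=True`` first maps log2 intensities back to the linear scale.
    Requires a complete, non-negative matrix.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    X = values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("fraction_of_total requires a complete matrix")
    if delog:
        X = np.exp2(X)
    if (X < 0).any():
        raise ValueError("fraction_of_total requires non-negative values")
    totals = X.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("a sample column sums to zero")
    out = pd.DataFrame(X / totals[None, :], index=values.index, columns=values.columns)
    return ExpressionMatrix(out, "fraction")


def _replicate_means(
    fractions: ExpressionMatrix, samples: pd.DataFrame, modality: str
) -> pd.DataFrame:
    """Per-gene replicate means at each time point (columns = time points)."""
    samples = validate_samples(samples)
    sub = samples[
        (samples["modality"] == modality)
        & samples["sample_id"].isin(fractions.values.columns)
    ]
    out = pd.DataFrame(index=fractions.values.index, dtype=float)
    for t in sorted(sub["time_h"].unique()):
        cols = sub.loc[sub["time_h"] == t, "sample_id"].tolist()
        out[t] = fractions.values[cols].mean(axis=1)
    return out


def across_gene_correlation(
    rna_fractions: ExpressionMatrix,
    prot_fractions: ExpressionMatrix,
    samples: pd.DataFrame,
    t_rna: float,
    t_prot: float,
) -> float:
    """Across-gene Spearman rho of replicate-mean fractions at a time pair.

    Genes are intersected between modalities; ties get average ranks.
    """
    rna_means = _replicate_means(rna_fractions, samples, MODALITY_TRANSCRIPT)
    prot_means = _replicate_means(prot_fractions, samples, MODALITY_PROTEIN)
    common = [g for g in rna_means.index if g in set(prot_means.index)]
    if len(common) < 3:
        raise ValueError("need >=3 common genes")
    x = rna_means.loc[common, t_rna].to_numpy()
    y = prot_means.loc[common, t_prot].to_numpy()
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def lag_matrix(
    rna_fractions: ExpressionMatrix,
    prot_fractions: ExpressionMatrix,
    samples: pd.DataFrame,
    genes: Optional[list[str]] = None,
) -> ConcordanceResult:
    """Spearman rho for every (RNA time, protein time) pair, plus the
    protein-minus-RNA offset that maximizes the mean rho.

    Only offsets represented by at least two time-point pairs enter the
    lag estimate (a single shared time point degenerates to lag 0).
    ``genes`` optionally restricts the universe (e.g. to both-DE genes).
    """
    if genes is not None:
        rna_fractions = rna_fractions.subset_genes(genes)
        prot_fractions = prot_fractions.subset_genes(genes)
    rna_means = _replicate_means(rna_fractions, samples, MODALITY_TRANSCRIPT)
    prot_means = _replicate_means(prot_fractions, samples, MODALITY_PROTEIN)
    common = [g for g in rna_means.index if g in set(prot_means.index)]
    if len(common) < 3:
        raise ValueError("need >=3 common genes")
    rna_means = rna_means.loc[common]
    prot_means = prot_means.loc[common]
    t_rna = list(rna_means.columns)
    t_prot = list(prot_means.columns)
    mat = pd.DataFrame(index=t_rna, columns=t_prot, dtype=float)
    for tr in t_rna:
        for tp in t_prot:
            rho, _ = stats.spearmanr(rna_means[tr].to_numpy(), prot_means[tp].to_numpy())
            mat.loc[tr, tp] = float(rho)

    shared = [t for t in t_rna if t in set(t_prot)]
    per_tp = pd.Series({t: mat.loc[t, t] for t in shared})

    offsets: dict[float, list[float]] = {}
    for tr in t_rna:
        for tp in t_prot:
            offsets.setdefault(round(tp - tr, 9), []).append(mat.loc[tr, tp])
    eligible = {d: np.mean(v) for d, v in offsets.items() if len(v) >= 2}
    if eligible:
        estimated = max(eligible, key=lambda d: eligible[d])
    else:
        estimated = 0.0
    return ConcordanceResult(
        per_timepoint_rho=per_tp, lag_matrix=mat, estimated_lag_h=float(estimated)
    )


def rma_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ranged major axis (model-II) regression slope and intercept.

    Both variables are scaled by their ranges, the major-axis (orthogonal)
    slope is computed on the scaled data, back-transformed, and the
    intercept taken through the means. The method is symmetric: swapping x
    and y inverts the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >=3 points")
    rx = x.max() - x.min()
    ry = y.max() - y.min()
    if rx <= 0 or ry <= 0:
        raise ValueError("zero range in x or y")
    u = x / rx
    v = y / ry
    s_uu = np.var(u, ddof=1)
    s_vv = np.var(v, ddof=1)
    s_uv = np.cov(u, v, ddof=1)[0, 1]
    if s_uv == 0:
        b_scaled = 1.0 if s_vv >= s_uu else 0.0
    else:
        b_scaled = (s_vv - s_uu + np.sqrt((s_vv - s_uu) ** 2 + 4 * s_uv**2)) / (2 * s_uv)
    slope = b_scaled * ry / rx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def rma_per_timepoint(
    rna_fractions: ExpressionMatrix,
    prot_fractions: ExpressionMatrix,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """RMA slope/intercept of log10 mean protein on log10 mean mRNA
    fractions at every shared time point."""
    rna_means = _replicate_means(rna_fractions, samples, MODALITY_TRANSCRIPT)
    prot_means = _replicate_means(prot_fractions, samples, MODALITY_PROTEIN)
    common = [g for g in rna_means.index if g in set(prot_means.index)]
    shared = [t for t in rna_means.columns if t in set(prot_means.columns)]
    rows = []
    for t in shared:
        x = np.log10(rna_means.loc[common, t].to_numpy() + PSEUDO_FRACTION)
        y = np.log10(prot_means.loc[common, t].to_numpy() + PSEUDO_FRACTION)
        slope, intercept = rma_regression(x, y)
        rows.append({"time_h": t, "slope": slope, "intercept": intercept})
    return pd.DataFrame(rows)


def _paired_columns(samples: pd.DataFrame) -> pd.DataFrame:
    """Plate-paired (rna_sample, prot_sample, time_h) rows."""
    samples = validate_samples(samples)
    plated = samples[samples["plate"].notna() & (samples["plate"].astype(str) != "")]
    rna = plated[plated["modality"] == MODALITY_TRANSCRIPT]
    prot = plated[plated["modality"] == MODALITY_PROTEIN]
    merged = rna.merge(prot, on="plate", suffixes=("_rna", "_prot"))
    return merged[["plate", "sample_id_rna", "sample_id_prot", "time_h_rna"]].rename(
        columns={"time_h_rna": "time_h"}
    )


def per_gene_correlations(
    rna_fractions: ExpressionMatrix,
    prot_fractions: ExpressionMatrix,
    samples: pd.DataFrame,
    pairs: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Pearson r per gene over the plate-paired samples.

    Genes with zero variance in either modality are returned as NaN.
    """
    if pairs is None:
        pairs = _paired_columns(samples)
    if pairs.empty:
        raise ValueError("no plate-paired samples")
    common = [g for g in rna_fractions.values.index if g in set(prot_fractions.values.index)]
    X = rna_fractions.values.loc[common, pairs["sample_id_rna"].tolist()].to_numpy(dtype=float)
    Y = prot_fractions.values.loc[common, pairs["sample_id_prot"].tolist()].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * Yc).sum(axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return pd.Series(r, index=common, name="pearson_r")


def matched_vs_mismatched(
    rna_fractions: ExpressionMatrix,
    prot_fractions: ExpressionMatrix,
    samples: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Compare the matched-plate median per-gene r against a permutation
    null where protein plates are shuffled within each time point.

    The identity permutation is excluded. Returns
    (matched_median, mean mismatched median, permutation p) with
    p = fraction of permuted medians >= the matched median.
    """
    pairs = _paired_columns(samples)
    if pairs.empty:
        raise ValueError("no plate-paired samples")
    if pairs.groupby("time_h").size().max() < 2:
        raise ValueError("need >=2 replicates at some time point to permute")
    matched = float(np.nanmedian(per_gene_correlations(rna_fractions, prot_fractions, samples, pairs)))

    rng = np.random.default_rng(seed)
    groups = [grp.index.to_numpy() for _, grp in pairs.groupby("time_h")]
    perm_medians = np.empty(n_perm)
    for b in range(n_perm):
        while True:
            perm = pairs.copy()
            for idx in groups:
                shuffled = rng.permutation(idx)
                perm.loc[idx, "sample_id_prot"] = pairs.loc[shuffled, "sample_id_prot"].to_numpy()
            if not perm["sample_id_prot"].equals(pairs["sample_id_prot"]):
                break
        perm_medians[b] = np.nanmedian(
            per_gene_correlations(rna_fractions, prot_fractions, samples, perm)
        )
    p = float(np.mean(perm_medians >= matched))
    return matched, float(np.mean(perm_medians)), p


def top_k_share(fractions: ExpressionMatrix | pd.DataFrame, k: int) -> float:
    """Sum of the k largest per-gene mean fractions."""
    values = fractions.values if isinstance(fractions, ExpressionMatrix) else fractions
    means = values.mean(axis=1).to_numpy(dtype=float)
    if k <= 0:
        return 0.0
    k = min(k, means.size)
    return float(np.sort(means)[::-1][:k].sum())
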