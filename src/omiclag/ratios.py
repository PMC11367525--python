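"""Protein:mRNA ratio trajectories, up/down classification by 10h fold
change, and Dunnett many-to-one contrasts versus the baseline time point."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import PSEUDO_FRACTION, _replicate_means
from .data_model_io import MODALITY_PROTEIN, MODALITY_TRANSCRIPT, ExpressionMatrix
from .transcript_de import DEResult

FC_UP = 2.0
FC_DOWN = 0.5
REPORT_THRESHOLD = 0.1
DEFAULT_N_MC = 20_000


@dataclass
class RatioResult:
    """Protein:mRNA ratios and per-class Dunnett contrasts."""

    ratios: pd.DataFrame  # gene x time point, linear scale
    log2_ratios: pd.DataFrame
    classes: Optional[pd.Series] = None  # gene -> {up, down, other}
    dunnett: Optional[pd.DataFrame] = None  # class, time_h, median_ratio, dunnett_p


def ratio_matrix(
    rna_fractions: ExpressionMatrix,
    prot_fractions: ExpressionMatrix,
    samples: pd.DataFrame,
) -> RatioResult:
    """Per-gene, per-time-point protein fraction divided by mRNA fraction.

    Both modalities are replicate-averaged per time point first; a
    pseudo-fraction guards zero denominators so ratios stay positive.
    """
    rna_means = _replicate_means(rna_fractions, samples, MODALITY_TRANSCRIPT)
    prot_means = _replicate_means(prot_fractions, samples, MODALITY_PROTEIN)
    common = [g for g in rna_means.index if g in set(prot_means.index)]
    shared = [t for t in rna_means.columns if t in set(prot_means.columns)]
    num = prot_means.loc[common, shared] + PSEUDO_FRACTION
    den = rna_means.loc[common, shared] + PSEUDO_FRACTION
    ratios = num / den
    return RatioResult(ratios=ratios, log2_ratios=np.log2(ratios))


def classify_regulation(
    de_rna: DEResult, final_time: Optional[float] = None
) -> pd.Series:
    """Classify genes as up/down/other from the RNA DE result.

    up: DE and fold change at the final time point (vs baseline) > 2;
    down: DE and fold change < 0.5; other: everything else.
    """
    if final_time is None:
        final_time = max(de_rna.timepoints)
    col = f"logFC_{final_time:g}"
    if col not in de_rna.table.columns:
        raise ValueError(f"missing column {col!r} in DE result")
    fc = np.exp2(de_rna.table[col].to_numpy(dtype=float))
    is_de = de_rna.table["is_DE"].to_numpy(dtype=bool)
    cls = np.where(is_de & (fc > FC_UP), "up", np.where(is_de & (fc < FC_DOWN), "down", "other"))
    return pd.Series(cls, index=de_rna.table.index, name="class")


def _mc_max_t_pvalues(
    t_obs: np.ndarray,
    ns: np.ndarray,
    n0: int,
    df: int,
    n_mc: int,
    seed: int,
) -> np.ndarray:
    """Family-wise p from the Monte-Carlo max-|t| null.

    Contrast statistics sharing the baseline group have correlation
    sqrt(n_i n_j / ((n_i+n0)(n_j+n0))); draws are correlated standard
    normals divided by a shared sqrt(chi2_df/df), i.e. multivariate t.
    """
    lam = np.sqrt(ns / (ns + n0))
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n_mc, len(ns))) @ L.T
    chi = np.sqrt(rng.chisquare(df, size=n_mc) / df)
    max_abs = np.abs(Z / chi[:, None]).max(axis=1)
    return np.array([(max_abs >= abs(t)).mean() for t in t_obs])


def dunnett_vs_baseline(
    log_ratios: pd.DataFrame,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> pd.DataFrame:
    """Many-to-one Dunnett contrasts of each time point against baseline.

    ``log_ratios`` is observations x time-point columns (the first column
    is the baseline); each column's non-NaN values form one group. Per
    contrast t_i = (mean_i - mean_0) / (s_p * sqrt(1/n_i + 1/n_0)) with the
    pooled variance; the family-wise adjusted two-sided p is estimated by
    Monte Carlo from the max-|t| distribution: correlated standard-normal
    contrast draws divided by a shared chi/df factor, which for a single
    contrast reproduces the pooled t-test exactly (up to MC error).

    Time points with fewer than 2 observations are excluded with a warning.
    Returns a DataFrame with time_h, n, mean_diff, t, p_unadj, p_adj.
    """
    cols = list(log_ratios.columns)
    if len(cols) < 2:
        raise ValueError("need >=2 time points")
    groups = []
    kept_cols = []
    for c in cols:
        vals = log_ratios[c].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            warnings.warn(f"time point {c!r} has <2 observations; excluded", stacklevel=2)
            continue
        groups.append(vals)
        kept_cols.append(c)
    if len(groups) < 2:
        raise ValueError("need >=2 usable time points")
    base = groups[0]
    others = groups[1:]
    n0 = base.size
    ns = np.array([g.size for g in others])
    df = int(sum(g.size for g in groups) - len(groups))
    s2p = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    sp = np.sqrt(s2p)
    diffs = np.array([g.mean() - base.mean() for g in others])
    se = sp * np.sqrt(1.0 / ns + 1.0 / n0)
    t_obs = diffs / se

    k = len(others)
    p_unadj = 2.0 * stats.t.sf(np.abs(t_obs), df)
    if k == 1:
        # no multiplicity: the contrast is the two-sample pooled t-test
        p_adj = p_unadj.copy()
    else:
        p_adj = _mc_max_t_pvalues(t_obs, ns, n0, df, n_mc, seed)
        p_adj = np.maximum(p_adj, p_unadj)
    rows = []
    for i, c in enumerate(kept_cols[1:]):
        rows.append(
            {
                "time_h": c,
                "n": int(ns[i]),
                "mean_diff": float(diffs[i]),
                "t": float(t_obs[i]),
                "p_unadj": float(p_unadj[i]),
                "p_adj": float(p_adj[i]),
            }
        )
    return pd.DataFrame(rows)


def ratio_analysis(
    rna_fractions: ExpressionMatrix,
    prot_fractions: ExpressionMatrix,
    samples: pd.DataFrame,
    de_rna: DEResult,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> RatioResult:
    """Full ratio pipeline: ratio matrix, class assignment, per-class
    Dunnett contrasts versus baseline (classes: all, up, down)."""
    result = ratio_matrix(rna_fractions, prot_fractions, samples)
    classes = classify_regulation(de_rna).reindex(result.ratios.index).fillna("other")
    rows = []
    for label, genes in (
        ("all", result.ratios.index),
        ("up", classes.index[classes == "up"]),
        ("down", classes.index[classes == "down"]),
    ):
        sub = result.log2_ratios.loc[genes]
        if len(sub) < 2:
            continue
        contrasts = dunnett_vs_baseline(sub, n_mc=n_mc, seed=seed)
        medians = result.ratios.loc[genes].median(axis=0)
        base_t = result.ratios.columns[0]
        rows.append(
            {
                "class": label,
                "time_h": base_t,
                "median_ratio": float(medians[base_t]),
                "dunnett_p": np.nan,
            }
        )
        for _, row in contrasts.iterrows():
            rows.append(
                {
                    "class": label,
                    "time_h": row["time_h"],
                    "median_ratio": float(medians[row["time_h"]]),
                    "dunnett_p": row["p_adj"],
                }
            )
    result.classes = classes
    result.dunnett = pd.DataFrame(rows)
    return result
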