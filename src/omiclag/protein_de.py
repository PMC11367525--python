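"""MNAR imputation by probabilistic minimum and empirical-Bayes moderated
F-tests on protein log-intensities.

Imputation draws missing cells of qualifying proteins from a Gaussian
centered at a low quantile of each sample's observed values. The moderated
F-test fits per-gene one-way linear models and shrinks residual variances
toward a prior variance; hyperparameters (d0, s0^2) are estimated by
matching the mean and variance of log s^2 to their digamma/trigamma
expressions under the scaled-F hierarchical model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_model_io import (
    MODALITY_PROTEIN,
    ExpressionMatrix,
    validate_samples,
)
from .transcript_de import DEFAULT_ALPHA, DEResult, bh_adjust

MIN_OBSERVED_PER_SAMPLE = 10


@dataclass
class ImputationParams:
    """MinProb tuning: quantile center, s.d. multiplier, per-sample flag."""

    q: float = 0.01
    sigma_scale: float = 1.0
    per_sample: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q < 0.5:
            raise ValueError("q must be in (0, 0.5)")
        if self.sigma_scale <= 0:
            raise ValueError("sigma_scale must be > 0")


@dataclass
class EBHyperparams:
    """Empirical-Bayes variance moderation hyperparameters.

    s_tilde^2 = (d0*s0_sq + d*s^2) / (d0 + d); d0 = inf collapses every
    moderated variance to s0_sq.
    """

    d0: float
    s0_sq: float

    def moderate(self, s_sq: np.ndarray, d: float) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s_sq, dtype=float), self.s0_sq)
        return (self.d0 * self.s0_sq + d * np.asarray(s_sq, dtype=float)) / (self.d0 + d)


def impute_minprob(
    intensities: ExpressionMatrix,
    quantified: set[str],
    imputable: set[str],
    params: Optional[ImputationParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionMatrix:
    """Impute missing cells of imputable proteins by a probabilistic minimum.

    For each missing cell of an imputable protein, draw from
    Normal(mu_s, (sigma_scale*sigma_s)^2) where mu_s is the q-quantile and
    sigma_s the standard deviation of the sample's observed values. Proteins
    outside ``quantified | imputable`` are dropped; the output is complete.
    """
    if params is None:
        params = ImputationParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    keep = [g for g in intensities.gene_ids if g in quantified or g in imputable]
    values = intensities.values.loc[keep].copy()
    obs_all = values.to_numpy(dtype=float)
    pooled = obs_all[~np.isnan(obs_all)]
    global_mu = np.nanquantile(pooled, params.q) if pooled.size else 0.0
    global_sigma = np.nanstd(pooled, ddof=1) if pooled.size > 1 else 1.0
    for col in values.columns:
        colvals = values[col].to_numpy(dtype=float)
        missing = np.isnan(colvals)
        if not missing.any():
            continue
        observed = colvals[~missing]
        if params.per_sample and observed.size >= MIN_OBSERVED_PER_SAMPLE:
            mu = np.quantile(observed, params.q)
            sigma = observed.std(ddof=1)
        else:
            if params.per_sample:
                warnings.warn(
                    f"sample {col!r} has <{MIN_OBSERVED_PER_SAMPLE} observed values; "
                    "using pooled imputation parameters",
                    stacklevel=2,
                )
            mu, sigma = global_mu, global_sigma
        draws = rng.normal(mu, params.sigma_scale * max(sigma, 1e-12), size=missing.sum())
        colvals[missing] = draws
        values[col] = colvals
    return ExpressionMatrix(values, "log_intensity")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, cf. limma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)


def estimate_eb_hyperparams(s_sq: np.ndarray, d: float) -> EBHyperparams:
    """Moment-match d0 and s0^2 from the spread of log sample variances.

    Under the hierarchical model s^2 ~ s0^2 * F(d, d0):
    Var(log s^2) = trigamma(d/2) + trigamma(d0/2) and
    E(log s^2) = log s0^2 + digamma(d/2) - log(d/2)
                 - digamma(d0/2) + log(d0/2).
    A non-positive excess variance yields the d0 = inf branch.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0)
    z = np.log(s_sq[ok])
    if z.size < 2:
        return EBHyperparams(np.inf, float(np.exp(np.mean(z))) if z.size else 1.0)
    e_mean = float(np.mean(z))
    e_var = float(np.var(z, ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if not np.isfinite(excess) or excess <= 0:
        s0_sq = np.exp(e_mean - special.digamma(d / 2.0) + np.log(d / 2.0))
        return EBHyperparams(np.inf, float(s0_sq))
    d0 = 2.0 * _trigamma_inverse(excess)
    log_s0 = (
        e_mean
        - special.digamma(d / 2.0)
        + np.log(d / 2.0)
        + special.digamma(d0 / 2.0)
        - np.log(d0 / 2.0)
    )
    return EBHyperparams(float(d0), float(np.exp(log_s0)))


def moderated_f_test(
    intensities: ExpressionMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    hyperparams: Optional[EBHyperparams] = None,
    n_imputed: Optional[pd.Series] = None,
) -> DEResult:
    """Empirical-Bayes moderated F-test of time-point means on a complete
    log-intensity matrix.

    Per gene: one-way OLS (group means), residual variance s^2 on d = n - T
    degrees of freedom, moderated variance s_tilde^2, moderated
    F = between-group mean square / s_tilde^2 with p from F(T-1, d0+d);
    BH across genes; logFC vs baseline = difference of fitted group means
    (values are already log2).

    ``hyperparams`` overrides estimation (used by the d0=0 / d0=inf limit
    tests). ``n_imputed`` is carried into the output table if given.
    """
    values = intensities.values if isinstance(intensities, ExpressionMatrix) else intensities
    if values.isna().to_numpy().any():
        raise ValueError("moderated_f_test requires a complete (post-imputation) matrix")
    samples = validate_samples(samples)
    prot = samples[samples["modality"] == MODALITY_PROTEIN]
    cols = [c for c in values.columns if c in set(prot["sample_id"])]
    if not cols:
        cols = list(values.columns)
        prot = samples[samples["sample_id"].isin(cols)]
    times = prot.set_index("sample_id").loc[cols, "time_h"].to_numpy(dtype=float)
    timepoints = sorted(set(times))
    n, T = len(cols), len(timepoints)
    if T < 2:
        raise ValueError("need >=2 time points")
    counts_per_tp = [int((times == t).sum()) for t in timepoints]
    if min(counts_per_tp) < 2:
        raise ValueError("need >=2 replicates per time point")
    baseline = timepoints[0]
    y = values[cols].to_numpy(dtype=float)

    group_idx = [np.flatnonzero(times == t) for t in timepoints]
    means = np.column_stack([y[:, idx].mean(axis=1) for idx in group_idx])
    fitted = np.empty_like(y)
    for t_i, idx in enumerate(group_idx):
        fitted[:, idx] = means[:, [t_i]]
    d = n - T
    rss = ((y - fitted) ** 2).sum(axis=1)
    s_sq = rss / d
    grand = y.mean(axis=1)
    ss_between = sum(
        len(idx) * (means[:, t_i] - grand) ** 2 for t_i, idx in enumerate(group_idx)
    )
    ms_between = ss_between / (T - 1)

    if hyperparams is None:
        hyperparams = estimate_eb_hyperparams(s_sq, d)
    s_tilde_sq = hyperparams.moderate(s_sq, d)
    f_mod = ms_between / np.maximum(s_tilde_sq, 1e-300)
    if np.isinf(hyperparams.d0):
        # F(T-1, inf) is chi2_{T-1}/(T-1)
        p = stats.chi2.sf(f_mod * (T - 1), T - 1)
    else:
        p = stats.f.sf(f_mod, T - 1, hyperparams.d0 + d)
    p_adj = bh_adjust(p)

    table = pd.DataFrame(index=values.index.copy())
    table["stat"] = f_mod
    table["p"] = p
    table["p_adj"] = p_adj
    for t_i, t in enumerate(timepoints):
        if t == baseline:
            continue
        table[f"logFC_{t:g}"] = means[:, t_i] - means[:, 0]
    table["is_DE"] = table["p_adj"] < alpha
    table["s_sq"] = s_sq
    table["s_tilde_sq"] = s_tilde_sq
    if n_imputed is not None:
        table["n_imputed"] = n_imputed.reindex(table.index).fillna(0).astype(int)
    table.attrs["d0"] = hyperparams.d0
    table.attrs["s0_sq"] = hyperparams.s0_sq
    table.attrs["residual_df"] = d
    return DEResult(table, MODALITY_PROTEIN, timepoints, baseline, alpha)
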