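"""Synthetic paired transcriptomics/proteomics generator.

Genes follow archetypal developmental mRNA trajectories; protein levels are
obtained by integrating a first-order synthesis/degradation kinetic

    dP/dt = alpha * M(t) - delta * P(t),

which induces an effective translation lag of roughly ``1/delta`` hours.
Counts are negative-binomial around library-scaled mRNA fractions,
log-intensities are Gaussian around log protein fractions, and protein
values are censored missing-not-at-random with a logistic dependence on
intensity. A shared per-plate, per-gene noise term couples the RNA and
protein samples taken from the same plate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model_io import (
    MODALITY_PROTEIN,
    MODALITY_TRANSCRIPT,
    ExpressionMatrix,
    GeneAnnotation,
    PairedOmicsDataset,
    ValidationError,
)

ARCHETYPES = ("linear_up", "linear_down", "dip_recover", "spike_decay", "flat")


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters fully determining one synthetic dataset."""

    n_genes: int = 500
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: {
            "linear_up": 0.25,
            "linear_down": 0.25,
            "dip_recover": 0.1,
            "spike_decay": 0.1,
            "flat": 0.3,
        }
    )
    time_grid_rna: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    time_grid_protein: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 10.0)
    n_reps_rna: int = 4
    n_reps_protein: int = 3
    nb_dispersion: float = 0.05
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    alpha_range: tuple[float, float] = (0.5, 2.0)
    delta_range: tuple[float, float] = (1.0 / 6.0, 1.0 / 2.0)
    intensity_noise_sd: float = 0.25
    intensity_scale: float = 1e6
    mnar_midpoint: float = 7.0
    mnar_slope: float = 1.5
    # per-hour increase of the noise s.d. / censoring midpoint, to model
    # measurements degrading as development proceeds (0 = time-constant)
    intensity_noise_gradient: float = 0.0
    mnar_midpoint_gradient: float = 0.0
    plate_effect_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ConfigurationError(f"unknown archetype name(s): {sorted(unknown)}")
        total = sum(self.archetype_mix.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError(f"archetype_mix sums to {total}, expected 1")
        for name, rng in (("alpha_range", self.alpha_range), ("delta_range", self.delta_range)):
            lo, hi = rng
            if lo <= 0 or hi <= 0 or hi < lo:
                raise ConfigurationError(f"{name} must be positive with lo <= hi")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        for name, grid in (
            ("time_grid_rna", self.time_grid_rna),
            ("time_grid_protein", self.time_grid_protein),
        ):
            g = list(grid)
            if g != sorted(g) or len(set(g)) != len(g):
                raise ConfigurationError(f"{name} must be strictly ascending")
            if not g or g[0] != 0:
                raise ConfigurationError(f"{name} must start at 0")
        if not set(self.time_grid_protein) <= set(self.time_grid_rna):
            raise ConfigurationError("protein time points must be a subset of the RNA grid")

    def to_yaml(self, path: str) -> None:
        doc = dataclasses.asdict(self)
        doc["time_grid_rna"] = list(self.time_grid_rna)
        doc["time_grid_protein"] = list(self.time_grid_protein)
        doc["lib_size_range"] = list(self.lib_size_range)
        doc["alpha_range"] = list(self.alpha_range)
        doc["delta_range"] = list(self.delta_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("time_grid_rna", "time_grid_protein", "lib_size_range", "alpha_range", "delta_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


# ---------------------------------------------------------------------------
# True trajectories
# ---------------------------------------------------------------------------

ODE_STEP_H = 0.1  # fixed RK4 step; sufficient for the smooth archetypes


def _archetype_mrna(
    archetype: str, m0: float, params: dict[str, float]
) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form mRNA trajectory for one gene; all archetypes are smooth."""
    if archetype == "flat":
        return lambda t: np.full_like(np.asarray(t, dtype=float), m0)
    if archetype in ("linear_up", "linear_down"):
        k = params["k"]
        return lambda t: m0 * np.exp(k * np.asarray(t, dtype=float))
    if archetype == "dip_recover":
        depth, tmid, width = params["depth"], params["tmid"], params["width"]
        return lambda t: m0 * np.exp(
            -depth * np.exp(-((np.asarray(t, dtype=float) - tmid) ** 2) / (2 * width**2))
        )
    if archetype == "spike_decay":
        # alpha-function pulse peaking at t_peak (within 0-2h), then relaxing
        amp, t_peak = params["amp"], params["t_peak"]
        return lambda t: m0 * np.exp(
            amp * (np.asarray(t, dtype=float) / t_peak) * np.exp(1 - np.asarray(t, dtype=float) / t_peak)
        )
    raise ConfigurationError(f"unknown archetype name: {archetype!r}")


@dataclass
class TrueTrajectories:
    """Per-gene continuous mRNA and protein levels on a dense hour grid."""

    gene_ids: list[str]
    archetypes: np.ndarray  # dtype object/str, one label per gene
    params: pd.DataFrame  # per-gene M0, k, depth, ..., alpha, delta
    grid: np.ndarray  # dense hour grid
    M: np.ndarray  # genes x grid
    P: Optional[np.ndarray] = None  # genes x grid, filled by protein_from_mrna
    _mrna_funcs: Optional[list] = None

    def mrna_at(self, t: float | np.ndarray) -> np.ndarray:
        """Exact mRNA level at arbitrary times (closed forms), genes x t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if not self.gene_ids:
            return np.empty((0, t.size))
        if self._mrna_funcs is not None:
            return np.vstack([f(t) for f in self._mrna_funcs])
        out = np.empty((self.M.shape[0], t.size))
        for j, tj in enumerate(t):
            out[:, j] = _interp_columns(self.grid, self.M, tj)
        return out

    def protein_at(self, t: float | np.ndarray) -> np.ndarray:
        if self.P is None:
            raise ValueError("protein trajectories not yet integrated")
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((self.P.shape[0], t.size))
        for j, tj in enumerate(t):
            out[:, j] = _interp_columns(self.grid, self.P, tj)
        return out


def _interp_columns(grid: np.ndarray, mat: np.ndarray, t: float) -> np.ndarray:
    idx = np.searchsorted(grid, t)
    if idx < len(grid) and grid[idx] == t:
        return mat[:, idx]
    if idx == 0:
        return mat[:, 0]
    if idx >= len(grid):
        return mat[:, -1]
    w = (t - grid[idx - 1]) / (grid[idx] - grid[idx - 1])
    return (1 - w) * mat[:, idx - 1] + w * mat[:, idx]


def simulate_mrna_profiles(config: SimulationConfig) -> TrueTrajectories:
    """Assign archetypes and draw per-gene mRNA trajectories.

    Baseline abundances M0 are log-normal; archetype shape parameters are
    drawn uniformly within fixed, visually plausible ranges.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    names = [a for a in ARCHETYPES if config.archetype_mix.get(a, 0.0) > 0]
    probs = np.array([config.archetype_mix[a] for a in names], dtype=float)
    probs = probs / probs.sum()
    labels = rng.choice(names, size=n, p=probs) if n else np.array([], dtype=object)
    m0 = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n)
    t_max = max(config.time_grid_rna) if config.time_grid_rna else 10.0
    grid = np.round(np.arange(0.0, t_max + ODE_STEP_H / 2, ODE_STEP_H), 10)

    rows = []
    funcs = []
    for g in range(n):
        arch = str(labels[g])
        p: dict[str, float] = {"M0": m0[g]}
        if arch == "linear_up":
            p["k"] = rng.uniform(0.15, 0.35)
        elif arch == "linear_down":
            p["k"] = -rng.uniform(0.15, 0.35)
        elif arch == "dip_recover":
            p.update(depth=rng.uniform(1.0, 2.0), tmid=t_max / 2, width=t_max / 5)
        elif arch == "spike_decay":
            p.update(amp=rng.uniform(1.0, 2.0) * rng.choice([-1.0, 1.0]), t_peak=1.5)
        rows.append(p)
        funcs.append(_archetype_mrna(arch, m0[g], p))

    params = pd.DataFrame(rows, index=[f"gene{g:05d}" for g in range(n)])
    params["archetype"] = labels
    M = (
        np.vstack([f(grid) for f in funcs])
        if n
        else np.empty((0, grid.size))
    )
    return TrueTrajectories(
        gene_ids=list(params.index),
        archetypes=np.asarray(labels, dtype=object),
        params=params,
        grid=grid,
        M=M,
        _mrna_funcs=funcs,
    )


def protein_from_mrna(
    traj: TrueTrajectories,
    alpha: float | np.ndarray,
    delta: float | np.ndarray,
    grid: Optional[np.ndarray] = None,
) -> TrueTrajectories:
    """Integrate dP/dt = alpha*M(t) - delta*P with fixed-step RK4.

    P(0) is the pre-starvation steady state alpha*M(0)/delta. Returns a new
    TrueTrajectories with P filled and alpha/delta recorded per gene.
    """
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (len(traj.gene_ids),)).copy()
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (len(traj.gene_ids),)).copy()
    if np.any(delta <= 0):
        raise ConfigurationError("delta must be > 0")
    if np.any(alpha < 0):
        raise ConfigurationError("alpha must be >= 0")
    if grid is None:
        grid = traj.grid
    grid = np.asarray(grid, dtype=float)

    n = len(traj.gene_ids)
    P = np.empty((n, grid.size))
    if n:
        P[:, 0] = alpha * traj.mrna_at(grid[0])[:, 0] / delta
        for j in range(grid.size - 1):
            h = grid[j + 1] - grid[j]
            t = grid[j]
            m_t = traj.mrna_at(t)[:, 0]
            m_mid = traj.mrna_at(t + h / 2)[:, 0]
            m_next = traj.mrna_at(t + h)[:, 0]
            p = P[:, j]
            k1 = alpha * m_t - delta * p
            k2 = alpha * m_mid - delta * (p + h / 2 * k1)
            k3 = alpha * m_mid - delta * (p + h / 2 * k2)
            k4 = alpha * m_next - delta * (p + h * k3)
            P[:, j + 1] = p + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    params = traj.params.copy()
    params["alpha"] = alpha
    params["delta"] = delta
    return TrueTrajectories(
        gene_ids=traj.gene_ids,
        archetypes=traj.archetypes,
        params=params,
        grid=grid,
        M=traj.mrna_at(grid),
        P=P,
        _mrna_funcs=traj._mrna_funcs,
    )


# ---------------------------------------------------------------------------
# Sampling layers
# ---------------------------------------------------------------------------

def _rna_sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in config.time_grid_rna:
        for r in range(1, config.n_reps_rna + 1):
            paired = t in config.time_grid_protein and r <= config.n_reps_protein
            rows.append(
                {
                    "sample_id": f"rna_t{t:g}_r{r}",
                    "modality": MODALITY_TRANSCRIPT,
                    "time_h": float(t),
                    "replicate": str(r),
                    "plate": f"plate_t{t:g}_r{r}" if paired else "",
                }
            )
    return pd.DataFrame(rows)


def _protein_sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in config.time_grid_protein:
        for r in range(1, config.n_reps_protein + 1):
            rows.append(
                {
                    "sample_id": f"prot_t{t:g}_r{r}",
                    "modality": MODALITY_PROTEIN,
                    "time_h": float(t),
                    "replicate": str(r),
                    "plate": f"plate_t{t:g}_r{r}",
                }
            )
    return pd.DataFrame(rows)


def sample_counts(
    traj: TrueTrajectories,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    samples: Optional[pd.DataFrame] = None,
    plate_effects: Optional[dict[str, np.ndarray]] = None,
) -> ExpressionMatrix:
    """Draw NB counts around library-scaled mRNA fractions.

    count[g, s] ~ NB(mean = libsize_s * f_g(t_s), dispersion phi) with
    var = mu + phi*mu^2; phi -> 0 falls back to Poisson. ``plate_effects``
    maps sample_id to a per-gene log2-scale perturbation shared with the
    paired protein sample.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if samples is None:
        samples = _rna_sample_table(config)
    n = len(traj.gene_ids)
    phi = float(config.nb_dispersion)
    cols = {}
    for _, row in samples.iterrows():
        m = traj.mrna_at(row["time_h"])[:, 0]
        if plate_effects is not None and row["sample_id"] in plate_effects:
            m = m * np.exp2(plate_effects[row["sample_id"]])
        total = m.sum()
        frac = m / total if total > 0 else np.zeros(n)
        libsize = rng.uniform(*config.lib_size_range)
        mu = libsize * frac
        if phi <= 1e-12:
            draws = rng.poisson(mu)
        else:
            # NB with var = mu + phi*mu^2: shape r = 1/phi, p = r/(r+mu)
            r = 1.0 / phi
            p = r / (r + np.maximum(mu, 1e-300))
            draws = np.where(mu > 0, rng.negative_binomial(r, p), 0)
        cols[row["sample_id"]] = draws
    values = pd.DataFrame(cols, index=traj.gene_ids, dtype=float)
    return ExpressionMatrix(values, "raw_count")


def sample_intensities(
    traj: TrueTrajectories,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    samples: Optional[pd.DataFrame] = None,
    plate_effects: Optional[dict[str, np.ndarray]] = None,
) -> ExpressionMatrix:
    """Draw log2 intensities around log protein fractions.

    log-intensity = log2(P_g(t)/sum_g P_g(t) * intensity_scale)
                    + N(0, intensity_noise_sd^2) + plate effect.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if samples is None:
        samples = _protein_sample_table(config)
    n = len(traj.gene_ids)
    cols = {}
    for _, row in samples.iterrows():
        p = traj.protein_at(row["time_h"])[:, 0]
        total = p.sum()
        frac = p / total if total > 0 else np.zeros(n)
        with np.errstate(divide="ignore"):
            x = np.log2(frac * config.intensity_scale)
        noise_sd = config.intensity_noise_sd + config.intensity_noise_gradient * row["time_h"]
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=n)
        if plate_effects is not None and row["sample_id"] in plate_effects:
            x = x + plate_effects[row["sample_id"]]
        cols[row["sample_id"]] = x
    values = pd.DataFrame(cols, index=traj.gene_ids, dtype=float)
    return ExpressionMatrix(values, "log_intensity")


def apply_mnar_censoring(
    matrix: ExpressionMatrix,
    config: SimulationConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    samples: Optional[pd.DataFrame] = None,
) -> ExpressionMatrix:
    """Censor values missing-not-at-random with logistic intensity dependence.

    p_miss(x) = 1 / (1 + exp(slope * (x - midpoint))); low values are more
    likely to go missing when slope > 0. With a sample table and a nonzero
    ``mnar_midpoint_gradient`` the midpoint rises with the sample's time
    point (stronger censoring later in the course).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    x = matrix.values.to_numpy(dtype=float)
    if x.size == 0:
        return ExpressionMatrix(matrix.values.copy(), matrix.value_kind)
    midpoint = np.full(x.shape[1], config.mnar_midpoint)
    if samples is not None and config.mnar_midpoint_gradient != 0.0:
        times = samples.set_index("sample_id")["time_h"]
        for j, col in enumerate(matrix.values.columns):
            midpoint[j] += config.mnar_midpoint_gradient * float(times.get(col, 0.0))
    z = np.clip(config.mnar_slope * (x - midpoint[None, :]), -700, 700)
    p_miss = 1.0 / (1.0 + np.exp(z))
    p_miss[~np.isfinite(x)] = 1.0  # -inf log intensity (zero protein) always missing
    miss = rng.random(x.shape) < p_miss
    out = matrix.values.copy()
    out[miss] = np.nan
    return ExpressionMatrix(out, matrix.value_kind)


def generate_paired_dataset(config: SimulationConfig) -> PairedOmicsDataset:
    """Generate the full paired dataset: counts, censored intensities,
    sample table with plate pairing, 1:1 gene annotation, and truth table.

    Protein replicate r at time t shares a plate (and a per-gene log-scale
    perturbation of s.d. ``plate_effect_sd``) with RNA replicate r at t.
    Identical seeds yield bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    traj = simulate_mrna_profiles(config)
    alpha = rng.uniform(*config.alpha_range, size=config.n_genes)
    delta = rng.uniform(*config.delta_range, size=config.n_genes)
    traj = protein_from_mrna(traj, alpha, delta)

    rna_samples = _rna_sample_table(config)
    prot_samples = _protein_sample_table(config)

    # per-gene noise, shared within a plate, independent otherwise
    plate_effects: dict[str, np.ndarray] = {}
    if config.plate_effect_sd > 0:
        for _, row in rna_samples.iterrows():
            eff = rng.normal(0.0, config.plate_effect_sd, size=config.n_genes)
            plate_effects[row["sample_id"]] = eff
            if row["plate"]:
                partner = row["sample_id"].replace("rna_", "prot_")
                plate_effects[partner] = eff

    counts = sample_counts(traj, config, rng=rng, samples=rna_samples, plate_effects=plate_effects)
    intensities = sample_intensities(
        traj, config, rng=rng, samples=prot_samples, plate_effects=plate_effects
    )
    intensities = apply_mnar_censoring(intensities, config, rng=rng, samples=prot_samples)

    samples = pd.concat([rna_samples, prot_samples], ignore_index=True)
    annot = GeneAnnotation(
        pd.DataFrame(
            {
                "is_protein_coding": True,
                "protein_group": traj.gene_ids,
            },
            index=pd.Index(traj.gene_ids, name="gene_id"),
        )
    )
    truth = traj.params.copy()
    truth.index.name = "gene_id"
    return PairedOmicsDataset(counts, intensities, samples, annot, truth)
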