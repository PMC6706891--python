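"""Synthetic benchmark data: random stable gLV communities, post-perturbation
replicate trajectories, Poisson sequencing counts and log-normal biomass
measurement noise.

The generator reproduces the statistical structure of the standard synthetic
benchmark for biomass-aware gLV inference: sparse, self-limited, stable
communities; replicates started from random perturbations of the coexistence
equilibrium so that every replicate shows an informative transient toward the
same attractor; 16S-like counts drawn per sample from Poisson distributions
whose means are the densities rescaled to a fixed sequencing depth; and
optional qPCR/flow-cytometry-like biomass measurements with a specified
coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glv import GLVIntegrationError, GLVParameters, integrate_glv


@dataclass
class SimulationConfig:
    """Settings for one synthetic dataset.

    Defaults are the benchmark's standard condition: 10 species, 60
    replicates of 30 unit-spaced time points, expected sequencing depth
    5e4 reads per sample.
    """

    n_species: int = 10
    n_replicates: int = 60
    n_timepoints: int = 30
    time_span: float = 29.0
    read_depth: float = 5e4
    seed: int = 0
    # parameter prior (sparse, self-limited, stable regime)
    interaction_density: float = 0.2
    mu_range: tuple[float, float] = (0.1, 1.0)
    self_limitation_range: tuple[float, float] = (1.0, 5.0)
    interaction_sd_scale: float = 0.25
    # initial perturbation: equilibrium * Uniform(lo, hi) element-wise
    perturbation_range: tuple[float, float] = (0.1, 1.0)

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_replicates, self.n_timepoints) < 1:
            raise ValueError("counts must be >= 1")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")

    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.time_span, self.n_timepoints)


@dataclass
class SyntheticDataset:
    """One simulated benchmark dataset with ground truth attached."""

    params_true: GLVParameters
    trajectories: list[np.ndarray]  # per replicate, (p, T) densities
    counts: list[np.ndarray]  # per replicate, (p, T) integer counts
    biomass_true: list[np.ndarray]  # per replicate, (T,) column sums
    times: list[np.ndarray]  # per replicate time grids
    config: SimulationConfig | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.trajectories)

    def relative_abundances_true(self) -> list[np.ndarray]:
        """Noise-free composition: densities divided by their column sums."""
        return [traj / traj.sum(axis=0, keepdims=True) for traj in self.trajectories]

    def biomass_flat(self) -> np.ndarray:
        return np.concatenate(self.biomass_true)


def sample_glv_parameters(
    config: SimulationConfig,
    rng: np.random.Generator,
    max_rejections: int = 100,
) -> GLVParameters:
    """Draw a random sparse stable gLV parameter set by rejection sampling.

    Prior: ``mu_i ~ Uniform(0.1, 1)``; ``beta_ii ~ -Uniform(1, 5)``;
    off-diagonal ``beta_ij`` nonzero with probability
    ``interaction_density``, magnitudes ``Normal(0, 0.25 * |mean beta_ii|)``
    with both signs. A draw is accepted when the community has a feasible
    (all-positive), locally stable coexistence equilibrium and trajectories
    from random perturbed initial states stay bounded.
    """
    p = config.n_species
    for _ in range(max_rejections):
        mu = rng.uniform(*config.mu_range, size=p)
        diag = -rng.uniform(*config.self_limitation_range, size=p)
        beta = np.zeros((p, p))
        if p > 1 and config.interaction_density > 0:
            off = ~np.eye(p, dtype=bool)
            mask = rng.random((p, p)) < config.interaction_density
            sd = config.interaction_sd_scale * np.abs(diag.mean())
            vals = rng.normal(0.0, sd, size=(p, p))
            beta[off & mask] = vals[off & mask]
        np.fill_diagonal(beta, diag)
        params = GLVParameters(mu=mu, beta=beta)

        try:
            xeq = params.equilibrium()
        except np.linalg.LinAlgError:
            continue
        if np.any(xeq <= 0):
            continue
        # local stability of the interior fixed point
        jac = np.diag(xeq) @ beta
        if np.any(np.linalg.eigvals(jac).real >= -1e-12):
            continue
        # boundedness check from one random perturbed start
        x0 = xeq * rng.uniform(*config.perturbation_range, size=p)
        try:
            integrate_glv(params, x0, config.time_grid())
        except GLVIntegrationError:
            continue
        return params
    raise RuntimeError(
        f"failed to sample a stable parameter set after {max_rejections} rejections; "
        "consider reducing interaction_density or interaction_sd_scale"
    )


def simulate_replicates(
    params: GLVParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SyntheticDataset:
    """Integrate independent replicates from random perturbed initial states.

    Each replicate mimics recovery after a random perturbation: its initial
    state is the coexistence equilibrium multiplied element-wise by
    independent Uniform factors, then integrated on a uniform time grid.
    The noise-free layer only: counts are filled in by
    :func:`add_sequencing_noise`.
    """
    xeq = params.equilibrium()
    if np.any(xeq <= 0):
        raise ValueError("parameters have no feasible coexistence equilibrium")
    times = config.time_grid()
    trajectories, biomass, tgrids = [], [], []
    for _ in range(config.n_replicates):
        x0 = xeq * rng.uniform(*config.perturbation_range, size=params.n_species)
        traj = integrate_glv(params, x0, times)
        trajectories.append(traj)
        biomass.append(traj.sum(axis=0))
        tgrids.append(times.copy())
    return SyntheticDataset(
        params_true=params,
        trajectories=trajectories,
        counts=[],
        biomass_true=biomass,
        times=tgrids,
        config=config,
    )


def add_sequencing_noise(
    trajectories: list[np.ndarray],
    read_depth: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Poisson-sample counts at fixed expected depth.

    Per sample (column), densities are rescaled to sum to ``read_depth`` and
    each species' count is drawn Poisson with that mean, so column sums are
    themselves Poisson(read_depth).
    """
    counts = []
    for traj in trajectories:
        if np.any(traj < 0):
            raise ValueError("densities must be non-negative")
        colsum = traj.sum(axis=0)
        if np.any(colsum <= 0):
            raise ValueError("all-zero sample encountered; cannot scale to read depth")
        lam = traj / colsum * read_depth
        counts.append(rng.poisson(lam).astype(np.int64))
    return counts


def simulate_biomass_measurement(
    biomass_true: np.ndarray,
    cv: float,
    n_technical_reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-normal biomass measurements with a given coefficient of variation.

    Each technical replicate is an independent log-normal draw with mean
    equal to the true biomass and the requested CV, via the moment
    parameterization ``sigma_log = sqrt(ln(1 + cv^2))``,
    ``mu_log = ln(m) - sigma_log^2 / 2``. CV = 0.51 emulates 16S qPCR;
    CV = 0.05 emulates flow cytometry.

    Returns
    -------
    draws : (n_technical_reps, T) array
    mean : (T,) array, the technical-replicate mean (the measurement a
        study averaging ``n_technical_reps`` qPCR replicates would use).
    """
    m = np.asarray(biomass_true, dtype=float)
    if cv <= 0:
        raise ValueError("cv must be positive")
    if n_technical_reps < 1:
        raise ValueError("n_technical_reps must be >= 1")
    if np.any(m <= 0):
        raise ValueError("true biomass must be positive")
    sigma = np.sqrt(np.log1p(cv**2))
    mu_log = np.log(m) - sigma**2 / 2.0
    draws = rng.lognormal(mean=mu_log, sigma=sigma, size=(n_technical_reps, m.size))
    return draws, draws.mean(axis=0)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full pipeline: sample parameters, integrate replicates, add counts.

    Reproducible bit-for-bit from ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    params = sample_glv_parameters(config, rng)
    ds = simulate_replicates(params, config, rng)
    ds.counts = add_sequencing_noise(ds.trajectories, config.read_depth, rng)
    return ds


# ---------------------------------------------------------------------------
# TSV export (dialect shared with the CLI reader)


def sample_name(rep: int, t_index: int) -> str:
    return f"r{rep + 1}_t{t_index + 1}"


def dataset_to_frames(ds: SyntheticDataset) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts, metadata and truth tables for TSV export.

    Counts: rows = species, columns = sample IDs. Metadata: sample_id,
    replicate, time. Truth: per-sample true biomass plus flattened mu/beta.
    """
    species = ds.params_true.species_ids
    cols, count_cols, meta_rows, truth_rows = [], [], [], []
    for rep, (cts, times, m) in enumerate(zip(ds.counts, ds.times, ds.biomass_true)):
        for k in range(cts.shape[1]):
            sid = sample_name(rep, k)
            cols.append(sid)
            count_cols.append(cts[:, k])
            meta_rows.append({"sample_id": sid, "replicate": rep + 1, "time": times[k]})
            truth_rows.append({"sample_id": sid, "biomass": m[k]})
    counts = pd.DataFrame(np.column_stack(count_cols), index=species, columns=cols)
    counts.index.name = "species_id"
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    p = ds.params_true.n_species
    par = pd.DataFrame(
        {
            "parameter": [f"mu_{s}" for s in species]
            + [f"beta_{species[i]}_{species[j]}" for i in range(p) for j in range(p)],
            "value": np.concatenate([ds.params_true.mu, ds.params_true.beta.ravel()]),
        }
    )
    truth = pd.concat([truth, par], axis=0, ignore_index=True)
    return counts, meta, truth


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write counts.tsv, metadata.tsv and truth.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, meta, truth = dataset_to_frames(ds)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    counts.to_csv(paths["counts"], sep="\t")
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
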