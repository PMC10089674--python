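"""Synthetic count datasets: gene-wise negative binomial, optional low-rank
confounders acting multiplicatively on the mean, and per-sample depth.

Counts are drawn as k_ji ~ NB(mean = d_i * mu_j * 2**C_ji, size = r_j) with
variance mean + mean**2 / size.  The confounder matrix C = A @ B.T is exactly
low-rank in the log2 domain the detector operates in, which makes rank
recovery by the optimal hard threshold a sharp test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import CountMatrix, RealMatrix

__all__ = ["SimulationConfig", "simulate_counts", "null_zscore_matrix"]


@dataclass
class SimulationConfig:
    """Knobs for the negative-binomial generator.

    Gene base means mu_j and NB sizes r_j are log-normal across genes;
    ``n_confounders`` low-rank factors perturb log2-means with loadings of
    scale ``confounder_sd``; sample depths are log-normal with ``depth_sd``.
    """

    n_genes: int = 2000
    n_samples: int = 100
    mean_log_mu: float = 5.5
    sd_log_mu: float = 1.0
    dispersion_log_mean: float = 2.5
    dispersion_log_sd: float = 0.5
    n_confounders: int = 3
    confounder_sd: float = 0.7
    depth_sd: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        if not 0 <= self.n_confounders < min(self.n_genes, self.n_samples):
            raise ValueError("n_confounders must lie in [0, min(J, N))")
        for name in ("sd_log_mu", "dispersion_log_sd", "confounder_sd", "depth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, dict]:
    """Draw a count matrix from the generator; metadata records all latents."""
    rng = np.random.default_rng(config.seed)
    J, N, k = config.n_genes, config.n_samples, config.n_confounders
    mu = np.exp(rng.normal(config.mean_log_mu, config.sd_log_mu, size=J))
    size = np.exp(rng.normal(config.dispersion_log_mean, config.dispersion_log_sd, size=J))
    if k > 0:
        loadings = rng.normal(0.0, config.confounder_sd, size=(J, k))
        factors = rng.normal(0.0, config.confounder_sd, size=(N, k))
        confound = loadings @ factors.T
    else:
        loadings = np.zeros((J, 0))
        factors = np.zeros((N, 0))
        confound = np.zeros((J, N))
    depth = np.exp(rng.normal(0.0, config.depth_sd, size=N))
    mean = depth[np.newaxis, :] * mu[:, np.newaxis] * np.exp2(confound)
    # numpy parameterizes NB by (n, p); mean = n(1-p)/p  =>  p = n/(n+mean)
    p = size[:, np.newaxis] / (size[:, np.newaxis] + mean)
    counts = rng.negative_binomial(size[:, np.newaxis], p)
    genes = [f"G{j:05d}" for j in range(J)]
    samples = [f"S{i:03d}" for i in range(N)]
    matrix = CountMatrix(genes=genes, samples=samples, values=counts.astype(np.int64))
    metadata = {
        "config": config,
        "gene_mean": mu,
        "gene_size": size,
        "confounder_loadings": loadings,
        "confounder_factors": factors,
        "depth": depth,
    }
    return matrix, metadata


def null_zscore_matrix(J: int, N: int, seed: int = 1) -> RealMatrix:
    """J x N matrix of independent standard-normal draws (pure-noise fixture)."""
    if J < 2 or N < 2:
        raise ValueError("need J >= 2 and N >= 2")
    rng = np.random.default_rng(seed)
    genes = [f"G{j:05d}" for j in range(J)]
    samples = [f"S{i:03d}" for i in range(N)]
    return RealMatrix(genes=genes, samples=samples, values=rng.standard_normal((J, N)))
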