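"""Plant confounder-masked artificial outliers by inverting the detector.

The forward pipeline is run on a base dataset to recover its signal matrix Z,
noise matrix E and normalization statistics.  Chosen cells of E are replaced
with mean_j(E) + sign * magnitude * sd_j(E), Z + E' is re-assembled, and the
standardization is inverted back to integer counts.  The injected cells then
carry noise-domain z-scores of approximately +-magnitude while remaining
hidden behind the dataset's own confounder structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats as sps

from .matrix_io import CountMatrix, RealMatrix
from .oht import split_signal_noise
from .zscores import forward_pipeline, invert_standardization

__all__ = [
    "OutlierSpec",
    "TruthMask",
    "plan_outliers",
    "inject",
    "expected_extreme_z",
]

SCHEMES = ("overexpressed", "underexpressed", "both")
MODES = ("per_sample", "frequency")


@dataclass
class OutlierSpec:
    """Planned injections: (gene, sample, signed z-magnitude) triples."""

    entries: list[tuple[str, str, float]]
    scheme: str
    magnitude: float
    mode: str
    frequency: float | None
    seed: int

    def __post_init__(self) -> None:
        cells = [(g, s) for g, s, _ in self.entries]
        if len(set(cells)) != len(cells):
            raise ValueError("duplicate (gene, sample) cell in outlier spec")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        for g, s, m in self.entries:
            if self.scheme == "overexpressed" and m <= 0:
                raise ValueError(f"non-positive magnitude {m} under scheme 'overexpressed'")
            if self.scheme == "underexpressed" and m >= 0:
                raise ValueError(f"non-negative magnitude {m} under scheme 'underexpressed'")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class TruthMask:
    """Boolean ground-truth matrix aligned with a count matrix."""

    genes: list[str]
    samples: list[str]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.genes), len(self.samples)):
            raise ValueError("mask shape does not match identifier lists")

    @property
    def n_true(self) -> int:
        return int(self.mask.sum())

    def to_real_matrix(self) -> RealMatrix:
        return RealMatrix(
            genes=list(self.genes),
            samples=list(self.samples),
            values=self.mask.astype(np.float64),
        )


def _signs(rng: np.random.Generator, n: int, scheme: str) -> np.ndarray:
    if scheme == "overexpressed":
        return np.ones(n)
    if scheme == "underexpressed":
        return -np.ones(n)
    return rng.choice([-1.0, 1.0], size=n)


def plan_outliers(
    counts: CountMatrix,
    scheme: str = "both",
    magnitude: float = 6.0,
    mode: str = "per_sample",
    frequency: float = 1e-4,
    seed: int = 1,
) -> OutlierSpec:
    """Choose injection cells and signed magnitudes.

    ``per_sample`` places exactly one outlier in every sample, at a gene drawn
    uniformly from the eligible (non-degenerate) genes.  ``frequency`` draws
    each eligible cell independently with the given probability.  Signs follow
    the scheme: + for overexpressed, - for underexpressed, a fair coin for both.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    std = forward_pipeline(counts)
    eligible = np.flatnonzero(~std.stats.degenerate)
    if eligible.size == 0:
        raise ValueError("no eligible genes (all rows are degenerate)")
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, str, float]] = []
    if mode == "per_sample":
        gene_idx = rng.choice(eligible, size=len(counts.samples), replace=True)
        signs = _signs(rng, len(counts.samples), scheme)
        for i, sample in enumerate(counts.samples):
            entries.append((counts.genes[gene_idx[i]], sample, signs[i] * magnitude))
    else:
        if not 0.0 < frequency < 1.0:
            raise ValueError("frequency must lie in (0, 1)")
        hits = rng.random((eligible.size, len(counts.samples))) < frequency
        signs = _signs(rng, int(hits.sum()), scheme)
        for t, (ej, i) in enumerate(np.argwhere(hits)):
            entries.append(
                (counts.genes[eligible[ej]], counts.samples[i], signs[t] * magnitude)
            )
    return OutlierSpec(
        entries=entries,
        scheme=scheme,
        magnitude=magnitude,
        mode=mode,
        frequency=frequency if mode == "frequency" else None,
        seed=seed,
    )


def inject(
    counts: CountMatrix,
    spec: OutlierSpec,
    *,
    fresh_noise: bool = False,
    rank_override: int | None = None,
) -> tuple[CountMatrix, TruthMask]:
    """Inject the planned outliers and invert back to an integer count matrix.

    The baseline noise at non-injected cells is the dataset's own residual E
    (so an empty spec is the exact identity); ``fresh_noise=True`` replaces it
    with Gaussian noise simulated at each gene's residual scale instead.
    """
    std = forward_pipeline(counts)
    split = split_signal_noise(std.matrix, rank_override=rank_override)
    e = split.noise.values.copy()
    row_mean = e.mean(axis=1)
    row_sd = e.std(axis=1, ddof=0)
    if fresh_noise:
        rng = np.random.default_rng(spec.seed)
        e = row_mean[:, np.newaxis] + row_sd[:, np.newaxis] * rng.standard_normal(e.shape)
    gene_pos = {g: j for j, g in enumerate(counts.genes)}
    sample_pos = {s: i for i, s in enumerate(counts.samples)}
    mask = np.zeros(e.shape, dtype=bool)
    for gene, sample, signed_mag in spec.entries:
        j, i = gene_pos[gene], sample_pos[sample]
        if std.stats.degenerate[j]:
            raise ValueError(f"cannot inject into degenerate gene {gene!r}")
        e[j, i] = row_mean[j] + signed_mag * row_sd[j]
        mask[j, i] = True
    z_new = RealMatrix(
        genes=list(counts.genes),
        samples=list(counts.samples),
        values=split.signal.values + e,
    )
    new_counts = invert_standardization(z_new, std.stats, std.size_factors)
    return new_counts, TruthMask(
        genes=list(counts.genes), samples=list(counts.samples), mask=mask
    )


def expected_extreme_z(J: int, N: int) -> float:
    """Expected maximum of |z| over J*N independent standard-normal draws.

    Uses E[max] = integral_0^inf (1 - F(x)) dx with F(x) = (2*Phi(x) - 1)^n,
    the CDF of the maximum absolute value of n independent normals.
    """
    n = int(J) * int(N)
    if n < 2:
        raise ValueError("J*N must be at least 2")

    def tail(x: float) -> float:
        # 1 - (2*Phi(x)-1)^n, computed stably via log1p for large n
        core = 2.0 * sps.norm.cdf(x) - 1.0
        if core <= 0.0:
            return 1.0
        return -np.expm1(n * np.log(core))

    # the integrand transitions from 1 to 0 around sqrt(2 log n); split there
    pivot = np.sqrt(2.0 * np.log(n))
    a, _ = integrate.quad(tail, 0.0, pivot, epsabs=1e-8, limit=200)
    b, _ = integrate.quad(tail, pivot, np.inf, epsabs=1e-8, limit=200)
    return float(a + b)
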