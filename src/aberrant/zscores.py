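"""Depth normalization, log-fold transform and gene-wise standardization.

The forward chain maps a count matrix K to a standardized z-score matrix:

    s_i  = median over eligible genes of k_ji / geomean_j(k)       (size factors)
    c_ji = k_ji / s_i                                              (controlled counts)
    l_ji = log2((c_ji + 1) / (cbar_j + 1))                         (log fold)
    z_ji = (l_ji - mu_j) / tau_j                                   (row z-scores)

Every intermediate needed to run the chain backwards (size factors, row
baselines cbar_j, row moments mu_j/tau_j) is retained, so that
:func:`invert_standardization` maps a modified z-matrix back to integer
counts, reproducing the input exactly when z is unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import CountMatrix, RealMatrix

__all__ = [
    "SizeFactors",
    "RowStats",
    "StandardizedMatrix",
    "SizeFactorError",
    "InversionOverflowError",
    "size_factors",
    "log_fold_transform",
    "standardize_rows",
    "invert_standardization",
]


class SizeFactorError(ValueError):
    """No gene with strictly positive counts in every sample."""


class InversionOverflowError(FloatingPointError):
    """Count inversion produced a non-finite intermediate."""


@dataclass
class SizeFactors:
    """Per-sample sequencing-depth multipliers (median-of-ratios)."""

    samples: list[str]
    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64)
        if self.s.shape != (len(self.samples),):
            raise ValueError("size factor vector does not match sample list")
        if not (np.isfinite(self.s).all() and (self.s > 0).all()):
            raise ValueError("size factors must be positive and finite")


@dataclass
class RowStats:
    """Per-gene moments of the log-fold matrix plus controlled-count baselines.

    ``mean``/``sd`` are the row moments used for standardization (log2 units),
    ``baseline`` the row means of controlled counts (cbar_j), and ``degenerate``
    flags rows with zero standard deviation.
    """

    genes: list[str]
    baseline: np.ndarray
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    degenerate: np.ndarray | None = None


@dataclass
class StandardizedMatrix:
    """Row-standardized z-scores together with the statistics to invert them."""

    matrix: RealMatrix
    stats: RowStats
    size_factors: SizeFactors

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values


def size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Genes containing any zero count have geometric mean 0 and are excluded
    from the per-sample median; computation is done in log space to avoid
    overflow of the count product.
    """
    k = counts.values
    eligible = (k > 0).all(axis=1)
    if not eligible.any():
        raise SizeFactorError(
            "no gene has strictly positive counts in every sample"
        )
    logk = np.log(k[eligible].astype(np.float64))
    log_ratios = logk - logk.mean(axis=1, keepdims=True)
    # median taken on the ratio scale: for an even gene count the middle two
    # ratios are averaged arithmetically, per the formula as written
    s = np.median(np.exp(log_ratios), axis=0)
    return SizeFactors(samples=list(counts.samples), s=s)


def log_fold_transform(
    counts: CountMatrix, sf: SizeFactors
) -> tuple[RealMatrix, RowStats]:
    """Controlled counts and pseudocounted log2 fold change against row means.

    Returns the l-matrix and a :class:`RowStats` with ``baseline`` (cbar_j)
    filled in; row moments are attached later by :func:`standardize_rows`.
    """
    if sf.samples != counts.samples:
        raise ValueError("size factors were computed for different samples")
    c = counts.values / sf.s[np.newaxis, :]
    cbar = c.mean(axis=1)
    l = np.log2((c + 1.0) / (cbar[:, np.newaxis] + 1.0))
    lmat = RealMatrix(genes=list(counts.genes), samples=list(counts.samples), values=l)
    return lmat, RowStats(genes=list(counts.genes), baseline=cbar)


def standardize_rows(
    l: RealMatrix,
    stats: RowStats | None = None,
    sf: SizeFactors | None = None,
    sd_divisor: str = "population",
) -> StandardizedMatrix:
    """Standardize each row of ``l`` to mean 0 and unit standard deviation.

    Parameters
    ----------
    sd_divisor : {"population", "sample"}
        Divisor-N (default) or divisor-(N-1) standard deviation.

    Rows with zero standard deviation are flagged degenerate and set to
    all-zero z-scores rather than dropped, so matrix shape is stable.
    """
    if sd_divisor not in ("population", "sample"):
        raise ValueError("sd_divisor must be 'population' or 'sample'")
    ddof = 0 if sd_divisor == "population" else 1
    vals = l.values
    mu = vals.mean(axis=1)
    tau = vals.std(axis=1, ddof=ddof)
    degenerate = tau == 0.0
    safe_tau = np.where(degenerate, 1.0, tau)
    z = (vals - mu[:, np.newaxis]) / safe_tau[:, np.newaxis]
    z[degenerate] = 0.0
    if stats is None:
        stats = RowStats(genes=list(l.genes), baseline=np.zeros(len(l.genes)))
    stats.mean = mu
    stats.sd = tau
    stats.degenerate = degenerate
    if sf is None:
        sf = SizeFactors(samples=list(l.samples), s=np.ones(len(l.samples)))
    zmat = RealMatrix(genes=list(l.genes), samples=list(l.samples), values=z)
    return StandardizedMatrix(matrix=zmat, stats=stats, size_factors=sf)


def forward_pipeline(counts: CountMatrix, sd_divisor: str = "population") -> StandardizedMatrix:
    """Convenience composition: size factors -> log fold -> row z-scores."""
    sf = size_factors(counts)
    lmat, stats = log_fold_transform(counts, sf)
    return standardize_rows(lmat, stats=stats, sf=sf, sd_divisor=sd_divisor)


def invert_standardization(
    z: RealMatrix, stats: RowStats, sf: SizeFactors
) -> CountMatrix:
    """Map a z-score matrix back to integer counts.

    Applies l = mu + tau*z, c = (cbar + 1) * 2**l - 1, k = round(c * s)
    (half-to-even) clipped below at zero.  With the pipeline's own z-matrix
    this reproduces the original counts exactly.
    """
    if stats.mean is None or stats.sd is None:
        raise ValueError("RowStats is missing row moments; run standardize_rows first")
    zv = z.values
    l = stats.mean[:, np.newaxis] + stats.sd[:, np.newaxis] * zv
    with np.errstate(over="ignore"):
        c = (stats.baseline[:, np.newaxis] + 1.0) * np.exp2(l) - 1.0
        k = c * sf.s[np.newaxis, :]
    if not np.isfinite(k).all():
        jj, ii = np.argwhere(~np.isfinite(k))[0]
        raise InversionOverflowError(
            f"non-finite count at gene {z.genes[jj]!r}, sample {z.samples[ii]!r} "
            "(z-score too extreme)"
        )
    counts = np.maximum(np.rint(k), 0.0).astype(np.int64)
    return CountMatrix(genes=list(z.genes), samples=list(z.samples), values=counts)
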