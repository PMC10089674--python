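"""SVD signal/noise split with the optimal hard threshold for singular values.

A standardized matrix is decomposed as Z~ = Z + E, where Z is the low-rank
"signal" (coherent confounder structure) and E the residual noise carrying any
sparse outlier impulses.  The retained rank is chosen by hard-thresholding the
singular values at omega(beta) * sigma_median, where omega is calibrated
against the median of the Marcenko-Pastur distribution -- the noise-level-free
variant of the optimal hard threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize

from .matrix_io import RealMatrix

__all__ = [
    "SVDTriplet",
    "OHTResult",
    "SignalNoiseSplit",
    "mp_median",
    "lambda_coef",
    "omega_coef",
    "svd_decompose",
    "select_rank",
    "split_signal_noise",
]


@dataclass
class SVDTriplet:
    """Thin SVD factors: left/right orthonormal columns and singular values."""

    left_vectors: np.ndarray
    singular_values: np.ndarray
    right_vectors: np.ndarray
    transposed: bool = False  # True if the input was re-oriented so J >= N


@dataclass
class OHTResult:
    """Aspect ratio, threshold coefficients and the selected rank."""

    beta: float
    mp_med: float
    lambda_coef: float
    omega_coef: float
    median_sv: float
    threshold: float
    rank: int

    def as_dict(self) -> dict[str, float]:
        return {
            "beta": self.beta,
            "mp_median": self.mp_med,
            "lambda": self.lambda_coef,
            "omega": self.omega_coef,
            "median_singular_value": self.median_sv,
            "threshold": self.threshold,
            "rank": self.rank,
        }


@dataclass
class SignalNoiseSplit:
    """Additive split Z~ = signal + noise with the OHT diagnostics."""

    signal: RealMatrix
    noise: RealMatrix
    oht: OHTResult
    svd: SVDTriplet = field(repr=False, default=None)  # type: ignore[assignment]


def _mp_support(beta: float) -> tuple[float, float]:
    sqb = np.sqrt(beta)
    return (1.0 - sqb) ** 2, (1.0 + sqb) ** 2


def _mp_density(t: np.ndarray | float, beta: float) -> np.ndarray | float:
    lo, hi = _mp_support(beta)
    return np.sqrt(np.maximum((hi - t) * (t - lo), 0.0)) / (2.0 * np.pi * beta * t)


@lru_cache(maxsize=256)
def mp_median(beta: float) -> float:
    """Median of the Marcenko-Pastur distribution with aspect ratio ``beta``.

    Solves F(mu) = 1/2 where F is the MP cumulative distribution with density
    sqrt(((1+sqrt(beta))^2 - t)(t - (1-sqrt(beta))^2)) / (2 pi beta t) on its
    support, via adaptive quadrature and bracketed root finding.
    """
    beta = float(beta)
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    lo, hi = _mp_support(beta)

    def cdf_minus_half(x: float) -> float:
        val, _ = integrate.quad(_mp_density, lo, x, args=(beta,), epsabs=1e-9, limit=200)
        return val - 0.5

    return float(optimize.brentq(cdf_minus_half, lo + 1e-12, hi - 1e-12, xtol=1e-10))


def lambda_coef(beta: float) -> float:
    """Closed-form optimal hard threshold coefficient for known noise level."""
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    return float(
        np.sqrt(2.0 * (beta + 1.0) + 8.0 * beta / (beta + 1.0 + np.sqrt(beta**2 + 14.0 * beta + 1.0)))
    )


def omega_coef(beta: float) -> float:
    """Noise-level-free threshold coefficient omega(beta) = lambda(beta)/sqrt(mp_median(beta))."""
    return lambda_coef(beta) / np.sqrt(mp_median(beta))


def svd_decompose(z: RealMatrix) -> SVDTriplet:
    """Thin SVD of a z-score matrix, re-oriented internally so rows >= columns."""
    vals = z.values
    if not np.isfinite(vals).all():
        raise ValueError("input matrix contains non-finite values")
    transposed = vals.shape[0] < vals.shape[1]
    if transposed:
        vals = vals.T
    u, s, vt = np.linalg.svd(vals, full_matrices=False)
    return SVDTriplet(
        left_vectors=u, singular_values=s, right_vectors=vt.T, transposed=transposed
    )


def select_rank(
    svd: SVDTriplet, J: int, N: int, rank_override: int | None = None
) -> OHTResult:
    """Optimal-hard-threshold rank: count singular values above omega(beta) * median.

    ``rank_override`` bypasses the threshold rule (diagnostics / ablations)
    while still reporting the threshold quantities.
    """
    m = min(J, N)
    beta = m / max(J, N)
    sv = svd.singular_values
    if sv.shape[0] != m:
        raise ValueError(f"expected {m} singular values, got {sv.shape[0]}")
    med = float(np.median(sv))
    lam = lambda_coef(beta)
    mu = mp_median(beta)
    omega = lam / np.sqrt(mu)
    threshold = omega * med
    if rank_override is not None:
        if not 0 <= rank_override <= m:
            raise ValueError(f"rank override must lie in [0, {m}]")
        rank = int(rank_override)
    else:
        rank = int((sv > threshold).sum())
    return OHTResult(
        beta=beta,
        mp_med=mu,
        lambda_coef=lam,
        omega_coef=omega,
        median_sv=med,
        threshold=threshold,
        rank=rank,
    )


def split_signal_noise(
    z: RealMatrix, rank_override: int | None = None
) -> SignalNoiseSplit:
    """Split ``z`` into a rank-r signal reconstruction and the residual noise."""
    J, N = z.values.shape
    svd = svd_decompose(z)
    oht = select_rank(svd, J, N, rank_override=rank_override)
    r = oht.rank
    u, s, v = svd.left_vectors, svd.singular_values, svd.right_vectors
    sig = (u[:, :r] * s[:r]) @ v[:, :r].T
    noi = (u[:, r:] * s[r:]) @ v[:, r:].T
    if svd.transposed:
        sig, noi = sig.T, noi.T
    signal = RealMatrix(genes=list(z.genes), samples=list(z.samples), values=sig)
    noise = RealMatrix(genes=list(z.genes), samples=list(z.samples), values=noi)
    return SignalNoiseSplit(signal=signal, noise=noise, oht=oht, svd=svd)
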