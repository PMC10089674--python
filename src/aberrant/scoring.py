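"""Noise-domain z-scores, two-sided normal P-values, BY-FDR and the detector.

After the signal/noise split the residual matrix E is re-standardized per
gene; two-sided standard-normal P-values are attached to each cell and
corrected matrix-wide with the Benjamini-Yekutieli step-up (valid under
arbitrary dependence).  ``detect`` composes the full pipeline from raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .matrix_io import CountMatrix, RealMatrix
from .oht import OHTResult, split_signal_noise
from .zscores import (
    RowStats,
    StandardizedMatrix,
    forward_pipeline,
    standardize_rows,
)

__all__ = [
    "OutlierReport",
    "noise_zscores",
    "pvalues",
    "by_adjust",
    "detect",
]

# floor for P-values: smallest positive normal double, keeps -log10(p) finite
_P_FLOOR = np.finfo(np.float64).tiny


@dataclass
class OutlierReport:
    """Scores and provenance for one detection run."""

    zhat: RealMatrix
    pvalues: RealMatrix
    qvalues: RealMatrix
    oht: OHTResult
    noise_stats: RowStats
    calls: np.ndarray
    fdr_level: float
    standardized: StandardizedMatrix | None = None

    @property
    def n_calls(self) -> int:
        return int(self.calls.sum())


def noise_zscores(noise: RealMatrix, sd_divisor: str = "population") -> tuple[RealMatrix, RowStats]:
    """Gene-wise standardization of the noise matrix (same arithmetic as the
    forward z-score step); returns the z-hat matrix and the row stats of E."""
    std = standardize_rows(noise, sd_divisor=sd_divisor)
    return std.matrix, std.stats


def pvalues(zhat: RealMatrix) -> RealMatrix:
    """Two-sided standard-normal P-values, p = 2 * min(Phi(z), 1 - Phi(z)).

    Values are floored at the smallest positive normal double and capped at 1.
    """
    z = zhat.values
    if not np.isfinite(z).all():
        raise ValueError("z-score matrix contains non-finite values")
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.clip(p, _P_FLOOR, 1.0)
    return RealMatrix(genes=list(zhat.genes), samples=list(zhat.samples), values=p)


def _by_vector(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli step-up on a flat vector of P-values."""
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    # enforce monotone non-decreasing adjusted values from the smallest p up
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def by_adjust(p: RealMatrix, scope: str = "matrix") -> RealMatrix:
    """BY-adjusted q-values.

    scope="matrix" corrects all J*N tests jointly (default, conservative);
    scope="per_sample" corrects each sample column separately.
    """
    vals = p.values
    if (vals <= 0).any() or (vals > 1).any():
        raise ValueError("P-values must lie in (0, 1]")
    if scope == "matrix":
        q = _by_vector(vals.ravel()).reshape(vals.shape)
    elif scope == "per_sample":
        q = np.column_stack([_by_vector(vals[:, i]) for i in range(vals.shape[1])])
    else:
        raise ValueError("scope must be 'matrix' or 'per_sample'")
    return RealMatrix(genes=list(p.genes), samples=list(p.samples), values=q)


def detect(
    counts: CountMatrix,
    fdr_level: float = 0.05,
    *,
    sd_divisor: str = "population",
    by_scope: str = "matrix",
    rank_override: int | None = None,
) -> OutlierReport:
    """End-to-end detection: counts -> z-scores -> OHT split -> scored noise.

    Cells with BY q-value below ``fdr_level`` are flagged in ``calls``.
    Degenerate genes (zero variance anywhere along the chain) report z-hat 0,
    p = q = 1, and are never called.  ``rank_override=0`` disables the
    signal/noise split (scores the standardized matrix directly), which is
    useful as an ablation.
    """
    if not 0.0 < fdr_level < 1.0:
        raise ValueError("fdr_level must lie in (0, 1)")
    std = forward_pipeline(counts, sd_divisor=sd_divisor)
    split = split_signal_noise(std.matrix, rank_override=rank_override)
    zhat, noise_stats = noise_zscores(split.noise, sd_divisor=sd_divisor)
    degenerate = std.stats.degenerate | noise_stats.degenerate
    p = pvalues(zhat)
    p.values[degenerate] = 1.0
    q = by_adjust(p, scope=by_scope)
    calls = q.values < fdr_level
    calls[degenerate] = False
    return OutlierReport(
        zhat=zhat,
        pvalues=p,
        qvalues=q,
        oht=split.oht,
        noise_stats=noise_stats,
        calls=calls,
        fdr_level=fdr_level,
        standardized=std,
    )
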