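import numpy as np
import pytest

from aberrant import (
    CountMatrix,
    RealMatrix,
    forward_pipeline,
    invert_standardization,
    log_fold_transform,
    size_factors,
    standardize_rows,
)
from aberrant.zscores import SizeFactorError, SizeFactors

from conftest import real_from


def brute_force_size_factors(values: np.ndarray) -> np.ndarray:
    """Direct evaluation: per-gene ratio to geometric mean, per-sample median."""
    J, N = values.shape
    ratios = []
    for j in range(J):
        row = values[j].astype(float)
        if (row > 0).all():
            geo = np.prod(row) ** (1.0 / N)
            ratios.append(row / geo)
    return np.median(np.array(ratios), axis=0)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = CountMatrix(
            genes=["a", "b", "c"],
            samples=["x", "y", "z"],
            values=np.array([[5, 5, 5], [9, 9, 9], [2, 2, 2]]),
        )
        assert np.allclose(size_factors(cm).s, 1.0)

    def test_hand_worked_2x2(self, tiny_counts):
        # geomeans (2.828, 11.314); both ratio columns constant
        sf = size_factors(tiny_counts)
        assert np.allclose(sf.s, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        values = rng.integers(1, 500, size=(6, 3))
        cm = CountMatrix(
            genes=[f"g{j}" for j in range(6)],
            samples=["a", "b", "c"],
            values=values,
        )
        assert np.allclose(size_factors(cm).s, brute_force_size_factors(values))

    def test_zero_containing_genes_excluded(self):
        rng = np.random.default_rng(4)
        values = rng.integers(1, 100, size=(8, 4))
        values[3, 2] = 0  # gene 3 must not influence the medians
        cm = CountMatrix(
            genes=[f"g{j}" for j in range(8)],
            samples=list("wxyz"),
            values=values,
        )
        assert np.allclose(size_factors(cm).s, brute_force_size_factors(values))

    def test_no_eligible_genes(self):
        values = np.array([[0, 1], [1, 0], [0, 0]])
        cm = CountMatrix(genes=["a", "b", "c"], samples=["x", "y"], values=values)
        with pytest.raises(SizeFactorError):
            size_factors(cm)

    def test_scaling_covariance(self):
        """Scaling one sample by c scales its factor by c relative to others."""
        rng = np.random.default_rng(9)
        values = rng.integers(1, 300, size=(20, 5))
        cm = CountMatrix(
            genes=[f"g{j}" for j in range(20)],
            samples=[f"s{i}" for i in range(5)],
            values=values,
        )
        s0 = size_factors(cm).s
        scaled = values.copy()
        scaled[:, 0] *= 7
        cm2 = CountMatrix(genes=cm.genes, samples=cm.samples, values=scaled)
        s1 = size_factors(cm2).s
        assert np.allclose((s1[0] / s1[1:]), 7.0 * (s0[0] / s0[1:]))


class TestLogFoldTransform:
    def test_all_zero_gene_row(self):
        cm = CountMatrix(
            genes=["z", "g"],
            samples=["x", "y"],
            values=np.array([[0, 0], [3, 3]]),
        )
        sf = SizeFactors(samples=["x", "y"], s=np.ones(2))
        lmat, stats = log_fold_transform(cm, sf)
        assert np.allclose(lmat.values[0], 0.0)
        assert stats.baseline[0] == 0.0

    def test_constant_controlled_row_is_zero(self):
        cm = CountMatrix(
            genes=["g", "h"],
            samples=["x", "y", "z"],
            values=np.array([[4, 4, 4], [1, 2, 3]]),
        )
        sf = SizeFactors(samples=["x", "y", "z"], s=np.ones(3))
        lmat, _ = log_fold_transform(cm, sf)
        assert np.allclose(lmat.values[0], 0.0)

    def test_hand_worked_row(self):
        cm = CountMatrix(
            genes=["g", "h"],
            samples=["x", "y", "z"],
            values=np.array([[1, 3, 7], [2, 2, 2]]),
        )
        sf = SizeFactors(samples=["x", "y", "z"], s=np.ones(3))
        lmat, stats = log_fold_transform(cm, sf)
        expected = np.log2(np.array([2, 4, 8]) / (11 / 3 + 1))
        assert np.allclose(lmat.values[0], expected, atol=1e-12)
        assert np.allclose(expected, [-1.22239242, -0.22239242, 0.77760758], atol=1e-8)


class TestStandardizeRows:
    def test_hand_worked_row(self):
        std = standardize_rows(real_from([[1.0, 2.0, 3.0], [0.0, 0.0, 1.0]]))
        assert np.allclose(std.values[0], [-1.22474487, 0.0, 1.22474487])
        assert np.isclose(std.stats.mean[0], 2.0)
        assert np.isclose(std.stats.sd[0], np.sqrt(2.0 / 3.0))

    def test_constant_row_degenerate(self):
        std = standardize_rows(real_from([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert std.stats.degenerate[0]
        assert not std.stats.degenerate[1]
        assert np.allclose(std.values[0], 0.0)

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(5)
        std = standardize_rows(real_from(rng.standard_normal((40, 12))))
        assert np.allclose(std.values.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(std.values.std(axis=1), 1.0, atol=1e-9)

    def test_sample_divisor_option(self):
        std = standardize_rows(real_from([[1.0, 2.0, 3.0], [0.0, 4.0, 8.0]]),
                               sd_divisor="sample")
        assert np.isclose(std.stats.sd[0], 1.0)  # ddof=1 sd of (1,2,3)


class TestInvertStandardization:
    def test_exact_roundtrip_on_simulation(self, sim_confounded):
        counts, _ = sim_confounded
        std = forward_pipeline(counts)
        back = invert_standardization(std.matrix, std.stats, std.size_factors)
        assert np.array_equal(back.values, counts.values)

    def test_exact_roundtrip_tiny(self, tiny_counts):
        std = forward_pipeline(tiny_counts)
        back = invert_standardization(std.matrix, std.stats, std.size_factors)
        assert back == tiny_counts

    def test_degenerate_row_reproduced_regardless_of_z(self):
        # both rows constant so size factors are 1 and tau is exactly 0
        cm = CountMatrix(
            genes=["flat", "g"],
            samples=["x", "y", "z"],
            values=np.array([[7, 7, 7], [5, 5, 5]]),
        )
        std = forward_pipeline(cm)
        z = RealMatrix(genes=cm.genes, samples=cm.samples,
                       values=std.values.copy())
        z.values[0] = [3.0, -2.0, 10.0]  # ignored: tau=0
        back = invert_standardization(z, std.stats, std.size_factors)
        assert np.array_equal(back.values[0], [7, 7, 7])

    def test_positive_z_bump_increases_count(self, sim_confounded):
        counts, _ = sim_confounded
        std = forward_pipeline(counts)
        j = int(np.flatnonzero(~std.stats.degenerate)[0])
        z = RealMatrix(genes=counts.genes, samples=counts.samples,
                       values=std.values.copy())
        z.values[j, 0] += 6.0
        back = invert_standardization(z, std.stats, std.size_factors)
        assert back.values[j, 0] > counts.values[j, 0]

    def test_overflow_raises_named_cell(self, tiny_counts):
        std = forward_pipeline(tiny_counts)
        z = RealMatrix(genes=tiny_counts.genes, samples=tiny_counts.samples,
                       values=np.full((2, 2), 0.0))
        # force a huge l value through non-degenerate stats
        std.stats.sd = np.array([1.0, 1.0])
        std.stats.mean = np.array([0.0, 0.0])
        z.values[1, 1] = 5000.0
        from aberrant.zscores import InversionOverflowError
        with pytest.raises(InversionOverflowError, match="g2"):
            invert_standardization(z, std.stats, std.size_factors)


class TestPipelineInvariants:
    def test_depth_rescaling_leaves_z_stable(self):
        """z-scores are invariant to per-sample depth rescaling up to pseudocount."""
        rng = np.random.default_rng(21)
        values = rng.integers(500, 5000, size=(60, 10))
        cm = CountMatrix(
            genes=[f"g{j}" for j in range(60)],
            samples=[f"s{i}" for i in range(10)],
            values=values,
        )
        z0 = forward_pipeline(cm).values
        scale = rng.uniform(0.5, 2.0, size=10)
        cm2 = CountMatrix(
            genes=cm.genes,
            samples=cm.samples,
            values=np.rint(values * scale).astype(np.int64),
        )
        z1 = forward_pipeline(cm2).values
        assert np.abs(z0 - z1).max() < 0.05
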