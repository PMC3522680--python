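import numpy as np
import pytest

from mtglasso.simulate import SimulationDesign, simulate_dataset
from mtglasso.stacking import (
    MultiResponseData,
    WhiteningSpec,
    backtransform,
    estimate_sigma,
    orthonormalize,
    stack,
    to_orthonormal,
)


class TestMultiResponseData:
    def test_rejects_bad_genotype_codes(self, rng):
        G = rng.integers(0, 3, size=(10, 4))
        G[3, 2] = 5
        with pytest.raises(ValueError, match="not in {0,1,2}"):
            MultiResponseData(G, rng.normal(size=(10, 2)))

    def test_rejects_missing_genotypes(self, rng):
        G = rng.integers(0, 3, size=(10, 4)).astype(float)
        G[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            MultiResponseData(G, rng.normal(size=(10, 2)))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="subjects"):
            MultiResponseData(
                rng.integers(0, 3, size=(10, 4)), rng.normal(size=(9, 2))
            )

    def test_subset_and_trait_views(self, random_data):
        half = random_data.subset(np.arange(15))
        assert half.n == 15 and half.p == random_data.p
        t0 = random_data.trait(1)
        assert t0.q == 1
        np.testing.assert_array_equal(
            t0.phenotypes[:, 0], random_data.phenotypes[:, 1]
        )


class TestStack:
    def test_q1_reduces_to_single_trait_design(self, rng):
        """With one trait and identity whitening the stacked design is the
        ordinary standardized Lasso design: block j is column j."""
        G = rng.integers(0, 3, size=(25, 5))
        G[:3] = [[0, 1, 2, 0, 1], [1, 2, 0, 1, 2], [2, 0, 1, 2, 0]]
        y = rng.normal(size=(25, 1))
        stacked = stack(MultiResponseData(G, y), standardize_traits=False)
        assert stacked.N == 25
        yc = y[:, 0] - y.mean()
        np.testing.assert_allclose(stacked.y, yc, atol=1e-12)
        for j in range(5):
            np.testing.assert_allclose(
                stacked.block(j)[:, 0], stacked.Xs[:, j], atol=1e-14
            )

    def test_q2_grouping_layout(self):
        """Worked two-trait illustration: p=6 SNPs give 6 groups of size two,
        coefficient layout (b11, b12, b21, b22, ...) with stacked row order
        subject-major, trait-minor."""
        rng = np.random.default_rng(5)
        G = rng.integers(0, 3, size=(12, 6))
        G[:3] = rng.permuted([[0, 1, 2, 0, 1, 2]] * 3, axis=1)
        Y = rng.normal(size=(12, 2))
        data = MultiResponseData(G, Y)
        stacked = stack(data)
        assert stacked.N == 24
        assert list(stacked.group_sizes) == [2] * 6
        # grand mean of stacked response is zero
        assert abs(stacked.y.mean()) < 1e-12
        # row (i, k) of block j is nonzero only in column k where it equals x_ij
        B3 = stacked.block(3)
        for i in range(12):
            np.testing.assert_allclose(B3[2 * i, 0], stacked.Xs[i, 3])
            assert B3[2 * i, 1] == 0
            np.testing.assert_allclose(B3[2 * i + 1, 1], stacked.Xs[i, 3])
            assert B3[2 * i + 1, 0] == 0

    def test_all_zero_genotypes_give_zero_blocks(self):
        data = MultiResponseData(
            np.zeros((3, 4), dtype=int),
            np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 3.0]]),
        )
        stacked = stack(data, standardize_traits=False)
        for j in range(4):
            assert np.all(stacked.block(j) == 0)
        Yc = data.phenotypes - data.phenotypes.mean(axis=0)
        np.testing.assert_allclose(stacked.y, Yc.ravel(), atol=1e-14)

    def test_identity_whitening_is_noop(self, random_data):
        s1 = stack(random_data)
        s2 = stack(random_data, WhiteningSpec.identity(2))
        np.testing.assert_array_equal(s1.Yw, s2.Yw)

    def test_whitening_dimension_mismatch(self, random_data):
        with pytest.raises(ValueError, match="q ="):
            stack(random_data, WhiteningSpec.identity(3))


class TestEstimateSigma:
    def test_identity(self, random_data):
        spec = estimate_sigma(random_data, "identity")
        np.testing.assert_array_equal(spec.sigma, np.eye(2))
        np.testing.assert_array_equal(spec.whitener, np.eye(2))

    def test_plugin_recovers_generator_residual_correlation(self):
        """With zero preliminary fit and pure-noise traits generated at
        residual correlation 0.9, the plugin covariance's off-diagonal
        should average 0.9*sd1*sd2 over replicates."""
        ratios = []
        rng = np.random.default_rng(77)
        design = SimulationDesign(
            n=300, p=20, q=2, rho=0.9, effect_size=0.0, causal_clusters=(),
        )
        for _ in range(50):
            ds = simulate_dataset(design, rng)
            spec = estimate_sigma(ds.data, "plugin")
            s = spec.sigma
            ratios.append(s[0, 1] / np.sqrt(s[0, 0] * s[1, 1]))
        assert abs(np.mean(ratios) - 0.9) < 0.02

    def test_user_supplied_not_pd_rejected(self, random_data):
        with pytest.raises(ValueError, match="positive definite"):
            estimate_sigma(
                random_data, "user_supplied", sigma=[[1.0, 2.0], [2.0, 1.0]]
            )


class TestOrthonormalize:
    def test_block_gram_is_c_times_identity(self, stacked_basis):
        stacked, basis = stacked_basis
        c = stacked.c
        for j in range(stacked.p):
            Xt = stacked.block(j) @ basis.Rinv[j]
            np.testing.assert_allclose(
                Xt.T @ Xt, c * np.eye(stacked.q), atol=1e-10 * c
            )

    def test_identity_whitening_gives_scalar_R(self, stacked_basis):
        """Kronecker structure + identity whitening make each R_j a positive
        multiple of I_q (here exactly I since columns are standardized)."""
        stacked, basis = stacked_basis
        for j in range(stacked.p):
            np.testing.assert_allclose(basis.R[j], np.eye(stacked.q), atol=1e-10)

    def test_round_trip_reconstruction(self, stacked_basis):
        stacked, basis = stacked_basis
        for j in range(stacked.p):
            Xt = stacked.block(j) @ basis.Rinv[j]
            np.testing.assert_allclose(Xt @ basis.R[j], stacked.block(j), atol=1e-10)

    def test_nontrivial_whitener_still_orthonormalizes(self, random_data):
        spec = WhiteningSpec(np.array([[1.0, 0.6], [0.6, 1.5]]), method="user_supplied")
        stacked = stack(random_data, spec)
        basis = orthonormalize(stacked)
        for j in (0, 3):
            Xt = stacked.block(j) @ basis.Rinv[j]
            np.testing.assert_allclose(
                Xt.T @ Xt, stacked.c * np.eye(2), atol=1e-8 * stacked.c
            )

    def test_constant_snp_rejected(self, rng):
        G = rng.integers(0, 3, size=(20, 3))
        G[:, 1] = 1
        data = MultiResponseData(G, rng.normal(size=(20, 2)), snp_ids=["a", "b", "c"])
        with pytest.raises(ValueError, match="'b'"):
            orthonormalize(stack(data))


class TestBacktransform:
    def test_zero_stays_zero(self, stacked_basis):
        _, basis = stacked_basis
        b = np.zeros((6, 2))
        assert np.all(backtransform(b, basis) == 0)

    def test_scalar_inverse(self, stacked_basis):
        stacked, basis = stacked_basis
        # overwrite with R_j = 2I: beta = b / 2
        import dataclasses

        p, q = stacked.p, stacked.q
        R = np.tile(2.0 * np.eye(q), (p, 1, 1))
        basis2 = dataclasses.replace(
            basis, R=R, Rinv=np.tile(0.5 * np.eye(q), (p, 1, 1))
        )
        b = np.zeros((p, q))
        b[2] = [1.0, -1.0]
        beta = backtransform(b, basis2)
        np.testing.assert_allclose(beta[2], [0.5, -0.5])

    def test_fitted_values_invariant(self, stacked_basis, rng):
        """X beta equals X-tilde b: fitted values do not depend on whether
        coefficients are expressed on the orthonormalized scale."""
        stacked, basis = stacked_basis
        b = rng.normal(size=(stacked.p, stacked.q))
        beta = backtransform(b, basis)
        fit_orth = sum(
            stacked.block(j) @ basis.Rinv[j] @ b[j] for j in range(stacked.p)
        )
        fit_orig = sum(stacked.block(j) @ beta[j] for j in range(stacked.p))
        np.testing.assert_allclose(fit_orth, fit_orig, atol=1e-10)

    def test_round_trip_inverse(self, stacked_basis, rng):
        stacked, basis = stacked_basis
        beta = rng.normal(size=(stacked.p, stacked.q))
        np.testing.assert_allclose(
            backtransform(to_orthonormal(beta, basis), basis), beta, atol=1e-10
        )

    def test_dimension_mismatch(self, stacked_basis):
        _, basis = stacked_basis
        with pytest.raises(ValueError, match="shape"):
            backtransform(np.zeros((3, 2)), basis)
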