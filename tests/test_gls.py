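import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mixtrack as mt
from mixtrack.exceptions import (
    CollinearityError,
    DegenerateSampleError,
    EstimationError,
    SingularityError,
)
from mixtrack.gls import SigmaInverse, postprocess_raw_estimates


def identity_sigma_inverse(n):
    """An inverse operator equal to the identity (for OLS comparison)."""
    return SigmaInverse(mode="pinv", annihilates_ones=False,
                        _basis=np.eye(n), _eigenvalues=np.ones(n))


class TestDesignMatrix:
    def test_direct_construction(self):
        prof = mt.SourceProfiles(np.array([[0.5, 0.3, 0.2], [0.2, 0.2, 0.6]]))
        design = mt.build_design_matrix(prof)
        np.testing.assert_allclose(
            design.matrix,
            [[1, 0.5, 0.2], [1, 0.3, 0.2], [1, 0.2, 0.6]],
        )

    def test_single_source(self):
        design = mt.build_design_matrix(mt.SourceProfiles(np.array([[1.0, 0.0]])))
        np.testing.assert_allclose(design.matrix, [[1, 1], [1, 0]])

    def test_non_normalized_profile_rejected(self):
        with pytest.raises(ValueError):
            mt.SourceProfiles(np.array([[0.5, 0.4]]))


class TestMultinomialCovariance:
    def test_formula_on_small_vector(self):
        cov = mt.multinomial_covariance(np.array([2, 1, 1]))
        expected = np.array([
            [1.0, -0.5, -0.5],
            [-0.5, 0.75, -0.25],
            [-0.5, -0.25, 0.75],
        ])
        np.testing.assert_allclose(cov.sigma, expected)

    def test_degenerate_all_mass_on_one_taxon(self):
        cov = mt.multinomial_covariance(np.array([7, 0, 0]))
        np.testing.assert_allclose(cov.sigma, np.zeros((3, 3)))

    def test_always_singular_and_rows_sum_zero(self, rng):
        x = rng.integers(0, 100, size=12)
        x[0] += 1
        cov = mt.multinomial_covariance(x)
        np.testing.assert_allclose(cov.sigma, cov.sigma.T)
        np.testing.assert_allclose(cov.sigma.sum(axis=1), 0,
                                   atol=1e-8 * x.sum())
        assert np.linalg.matrix_rank(cov.sigma) <= x.size - 1

    def test_zero_depth_rejected(self):
        with pytest.raises(DegenerateSampleError):
            mt.multinomial_covariance(np.zeros(3))


class TestRegularizedInverse:
    def test_pinv_defining_property(self):
        cov = mt.multinomial_covariance(np.array([2, 1, 1]))
        inv = mt.regularized_inverse(cov, mode="pinv")
        pinv = inv.apply(np.eye(3))
        np.testing.assert_allclose(cov.sigma @ pinv @ cov.sigma, cov.sigma,
                                   atol=1e-8)

    def test_drop_mode_exact_2x2_inverse(self):
        cov = mt.multinomial_covariance(np.array([2, 1, 1]))
        inv = mt.regularized_inverse(cov, mode="drop", drop_index=0)
        expected = np.linalg.inv([[0.75, -0.25], [-0.25, 0.75]])
        np.testing.assert_allclose(inv._inverse, expected)

    def test_default_drop_is_largest_count(self):
        cov = mt.multinomial_covariance(np.array([1, 9, 2]))
        inv = mt.regularized_inverse(cov, mode="drop")
        assert inv.drop_index == 1

    def test_drop_mode_still_singular_advises_pinv(self):
        # a zero-count taxon leaves a zero row in the reduced matrix
        cov = mt.multinomial_covariance(np.array([5, 5, 0]))
        with pytest.raises(SingularityError, match="pinv"):
            mt.regularized_inverse(cov, mode="drop", drop_index=0)

    def test_pinv_and_drop_agree_on_noiseless_instance(self):
        """Both sanctioned singularity workarounds give the same estimate
        on a 3-taxa, single-source instance whose unknown remainder is
        uniform (so the intercept fits it exactly)."""
        g1 = np.array([0.6, 0.3, 0.1])
        beta = 0.8 * g1 + 0.2 * np.ones(3) / 3
        sink = (beta * 15_000).astype(int)
        assert sink.sum() == 15_000
        com = mt.CommunitySet(["a", "b", "c"], sink,
                              (g1 * 1000).astype(int)[None, :])
        e1 = mt.estimate_proportions(com, inverse_mode="pinv")
        e2 = mt.estimate_proportions(com, inverse_mode="drop")
        np.testing.assert_allclose(e1.proportions, e2.proportions, atol=1e-6)
        np.testing.assert_allclose(e1.alpha_observed, [0.8], atol=1e-9)
        assert e1.alpha_unknown == pytest.approx(0.2, abs=1e-9)


class TestGlsSolve:
    def test_noiseless_mixture_recovery(self, noiseless_community):
        community, alpha = noiseless_community
        est = mt.estimate_proportions(community)
        np.testing.assert_allclose(est.alpha_observed, alpha, atol=1e-6)
        assert est.alpha_unknown < 1e-6

    def test_identity_covariance_equals_ols(self, rng):
        """With Sigma = I the GLS estimate is ordinary least squares."""
        gamma = rng.dirichlet(np.full(30, 0.7), size=3)
        design = mt.build_design_matrix(mt.SourceProfiles(gamma))
        x = rng.integers(1, 200, size=30).astype(float)
        alpha_tilde, _ = mt.gls_solve(x, design, identity_sigma_inverse(30))
        ols, *_ = np.linalg.lstsq(design.matrix, x, rcond=None)
        np.testing.assert_allclose(alpha_tilde, ols, atol=1e-9)

    def test_self_mixture_identity(self):
        counts = np.array([40, 35, 15, 10])
        com = mt.CommunitySet(list("abcd"), counts, counts[None, :])
        est = mt.estimate_proportions(com)
        np.testing.assert_allclose(est.alpha_observed, [1.0], atol=1e-9)
        assert abs(est.alpha_tilde[0]) < 1e-9
        assert est.alpha_unknown < 1e-9

    def test_duplicate_sources_raise_collinearity(self):
        src = np.array([[10, 20, 30], [10, 20, 30]])
        com = mt.CommunitySet(list("abc"), np.array([5, 10, 15]), src)
        with pytest.raises(CollinearityError, match="0 and 1"):
            mt.estimate_proportions(com)

    def test_exact_recovery_property(self, rng):
        """Any simplex alpha with zero unknown mass is recovered exactly
        from the unrounded mixture."""
        for _ in range(5):
            k, n = 3, 40
            gamma = rng.dirichlet(np.full(n, 0.5), size=k)
            alpha = rng.dirichlet(np.ones(k))
            x = 1e6 * (alpha @ gamma)  # exact expected counts (non-integer)
            design = mt.build_design_matrix(mt.SourceProfiles(gamma))
            cov = mt.multinomial_covariance(np.round(x).astype(int))
            inv = mt.regularized_inverse(cov)
            alpha_tilde, _ = mt.gls_solve(x, design, inv)
            np.testing.assert_allclose(alpha_tilde[1:] / x.sum(), alpha,
                                       atol=1e-6)

    def test_scale_equivariance_on_exact_mixture(self):
        g1 = np.array([0.4, 0.3, 0.2, 0.1])
        g2 = np.array([0.05, 0.15, 0.3, 0.5])
        gamma = np.vstack([g1, g2])
        beta = np.array([0.3, 0.7]) @ gamma
        results = []
        for scale in (1, 5, 25):
            sink = np.round(beta * 20_000 * scale).astype(int)
            com = mt.CommunitySet(
                list("abcd"), sink,
                np.vstack([(g1 * 10_000).astype(int),
                           (g2 * 10_000).astype(int)]),
            )
            results.append(mt.estimate_proportions(com).proportions)
        np.testing.assert_allclose(results[0], results[1], atol=1e-9)
        np.testing.assert_allclose(results[0], results[2], atol=1e-9)


class TestPostprocess:
    def test_identity_case(self):
        observed, unknown, clipped = postprocess_raw_estimates(
            np.array([0.0, 30.0, 70.0]), depth=100, n_taxa=10
        )
        np.testing.assert_allclose(observed, [0.3, 0.7])
        assert unknown == 0.0 and not clipped

    def test_clip_then_renormalize(self):
        # raw proportions (-0.02, 0.52, 0.55), zero intercept
        observed, unknown, clipped = postprocess_raw_estimates(
            np.array([0.0, -2.0, 52.0, 55.0]), depth=100, n_taxa=10
        )
        np.testing.assert_allclose(observed, [0.0, 0.52 / 1.07, 0.55 / 1.07],
                                   atol=1e-12)
        assert clipped and unknown == 0.0

    def test_all_nonpositive_fails(self):
        with pytest.raises(EstimationError):
            postprocess_raw_estimates(np.array([-1.0, -5.0]), depth=10,
                                      n_taxa=4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-5, 50), min_size=2, max_size=8),
           st.integers(2, 1000))
    def test_simplex_output_property(self, raw, n_taxa):
        """Whenever post-processing succeeds, the result is a point on the
        probability simplex."""
        raw = np.asarray(raw)
        try:
            observed, unknown, _ = postprocess_raw_estimates(
                raw, depth=100.0, n_taxa=n_taxa
            )
        except EstimationError:
            return
        assert np.all(observed >= 0) and unknown >= 0
        assert abs(observed.sum() + unknown - 1.0) < 1e-9


class TestEstimateProportions:
    def test_simplex_invariant_on_simulated_data(self):
        for seed in range(5):
            truth = mt.simulate_scenario1(
                mt.SimulationConfig(K=4, n_major=2, N=120, sink_depth=20_000,
                                    source_depths=20_000, seed=seed)
            )
            est = mt.estimate_proportions(truth.community)
            assert np.all(est.alpha_observed >= 0)
            assert 0 <= est.alpha_unknown <= 1
            assert abs(est.alpha_observed.sum() + est.alpha_unknown - 1) < 1e-9
            assert abs(est.fitted_beta.sum() - 1) < 1e-9

    def test_mae_decreases_with_depth(self):
        """Deeper sequencing gives better proportion recovery on average."""
        maes = []
        for depth in (1_000, 10_000, 100_000):
            errs = []
            for seed in range(30):
                truth = mt.simulate_scenario1(
                    mt.SimulationConfig(K=3, n_major=2, N=150,
                                        sink_depth=depth, source_depths=depth,
                                        seed=100 + seed)
                )
                est = mt.estimate_proportions(truth.community)
                errs.append(np.mean(np.abs(
                    est.proportions[1:] - truth.alpha_true[1:])))
            maes.append(np.mean(errs))
        assert maes[0] > maes[1] > maes[2]
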