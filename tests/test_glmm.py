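"""Binary cophylogenetic GLMM: augmentation, diagnostics, and recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from coralsym import glmm as G
from coralsym.pg import sample_pg
from coralsym.simulate import (SimulationScenario, recovery_scenario,
                               simulate_cophylo_dataset)


class TestPolyaGamma:
    @pytest.mark.parametrize("z", [0.0, 0.8, 2.0, 6.0])
    def test_mean_matches_closed_form(self, z):
        rng = np.random.default_rng(7)
        draws = sample_pg(np.full(60_000, z), rng)
        mean_true = 0.25 if z == 0 else math.tanh(z / 2) / (2 * z)
        assert draws.mean() == pytest.approx(mean_true, rel=0.01)

    def test_variance_at_zero(self):
        rng = np.random.default_rng(8)
        draws = sample_pg(np.zeros(120_000), rng)
        assert draws.var() == pytest.approx(1 / 24, rel=0.05)

    def test_sign_invariance_and_shape(self):
        rng = np.random.default_rng(9)
        z = np.array([[-3.0, 3.0], [0.5, -0.5]])
        out = sample_pg(z, rng)
        assert out.shape == z.shape
        assert (out > 0).all()

    def test_numpy_fallback_agrees_on_moments(self):
        from coralsym.pg import _sample_pg_numpy

        rng = np.random.default_rng(10)
        draws = _sample_pg_numpy(np.full(40_000, 1.5), rng)
        assert draws.mean() == pytest.approx(math.tanh(0.75) / 3.0,
                                             rel=0.02)


class TestKernelSolves:
    def test_triangular_solves_invert_cholesky(self):
        from coralsym._glmm_kernels import _bwd, _fwd

        rng = np.random.default_rng(3)
        a = rng.standard_normal((9, 9))
        Q = a @ a.T + 9 * np.eye(9)
        L = np.linalg.cholesky(Q)
        b = rng.standard_normal(9)
        x = _bwd(L, _fwd(L, b))
        np.testing.assert_allclose(Q @ x, b, atol=1e-10)


class TestIcc:
    def make_post(self, var_rows):
        v = np.asarray(var_rows, dtype=float)
        return G.VarianceComponentPosterior(
            term_names=tuple(f"t{k}" for k in range(v.shape[1])),
            var_draws=v, beta_draws=np.zeros((v.shape[0], 2)))

    def test_single_term_reference_value(self):
        post = self.make_post([[1.0]] * 120)
        icc = G.icc(post)
        assert icc[0, 0] == pytest.approx(0.18905, abs=1e-5)

    def test_zero_variance_zero_icc(self):
        post = self.make_post([[0.0, 2.0]] * 120)
        assert (G.icc(post)[:, 0] == 0).all()

    def test_normalization_sum_below_one(self):
        rng = np.random.default_rng(0)
        post = self.make_post(rng.gamma(2.0, 1.0, size=(200, 5)))
        icc = G.icc(post)
        assert (icc.sum(axis=1) < 1).all()
        assert (icc >= 0).all()


class TestHpd:
    def test_constant_draws(self):
        lo, hi = G.hpd_interval(np.full(200, 3.2))
        assert (lo, hi) == (3.2, 3.2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        draws = rng.gamma(2.0, 1.0, 500)
        lo, hi = G.hpd_interval(draws, 0.9)
        x = np.sort(draws)
        m = math.ceil(0.9 * x.size)
        widths = [(x[i + m - 1] - x[i], x[i], x[i + m - 1])
                  for i in range(x.size - m + 1)]
        w, lo_o, hi_o = min(widths)
        assert (lo, hi) == (lo_o, hi_o)

    def test_uniform_width(self):
        rng = np.random.default_rng(3)
        lo, hi = G.hpd_interval(rng.random(10_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            G.hpd_interval(np.arange(50.0))


class TestEss:
    def test_iid_near_n(self):
        rng = np.random.default_rng(4)
        ess = G.effective_sample_size(rng.standard_normal(5000))
        assert 4000 <= ess <= 6000

    def test_ar1_matches_closed_form(self):
        rng = np.random.default_rng(5)
        phi, n = 0.9, 20_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * math.sqrt(1 - phi ** 2)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert G.effective_sample_size(x) == pytest.approx(expected,
                                                           rel=0.25)

    def test_constant_chain_zero(self):
        assert G.effective_sample_size(np.full(200, 1.0)) == 0.0


class TestCallSignificance:
    def make_post_from_icc(self, icc_value, n=200):
        # invert the ICC formula for a single term
        denom = G.RESIDUAL_VARIANCE + G.LINK_VARIANCE
        var = icc_value * denom / (1 - icc_value)
        return G.VarianceComponentPosterior(
            ("term",), np.full((n, 1), var), np.zeros((n, 1)))

    def test_large_icc_significant(self):
        calls = G.call_significance(self.make_post_from_icc(0.5))
        assert calls.significant.iloc[0]

    def test_zero_icc_not_significant(self):
        calls = G.call_significance(self.make_post_from_icc(0.0))
        assert not calls.significant.iloc[0]

    def test_boundary_exactly_threshold_not_significant(self):
        post = self.make_post_from_icc(0.01)
        calls = G.call_significance(post)
        assert calls.icc_lower.iloc[0] == pytest.approx(0.01)
        # strict ">": a lower bound exactly at the threshold does not fire
        at_bound = G.call_significance(post,
                                       threshold=calls.icc_lower.iloc[0])
        assert not at_bound.significant.iloc[0]

    def test_constant_chain_flags_not_converged(self):
        calls = G.call_significance(self.make_post_from_icc(0.5))
        assert not calls.converged.iloc[0]  # constant chain has ESS 0


class TestDesign:
    @pytest.fixture
    def small(self):
        sc = SimulationScenario(host_n_tips=2, microbe_n_tips=2,
                                samples_per_host=2, seed=1)
        return simulate_cophylo_dataset(sc)

    def test_kronecker_interaction_covariances(self, small):
        table, truth = small
        design = G.build_cophylo_design(table, truth.host_tree,
                                        truth.microbe_tree)
        terms = {t.name: t for t in design.terms}
        coph = terms["hostphylo_x_microbephylo"]
        A, B, _, _ = coph.kron
        np.testing.assert_allclose(coph.cov, np.kron(A, B))
        np.testing.assert_allclose(np.diag(coph.cov), 1.0)
        assert terms["hostid_x_microbeid"].cov is None
        assert terms["hostid_x_microbeid"].n_levels == 4

    def test_occurrence_coding_and_depth_covariate(self, small):
        table, truth = small
        design = G.build_cophylo_design(table, truth.host_tree,
                                        truth.microbe_tree)
        counts = table.counts.to_numpy().T.ravel()
        np.testing.assert_array_equal(design.y, (counts > 0).astype(float))
        totals = table.sample_totals().to_numpy(dtype=float)
        np.testing.assert_allclose(
            design.X[:, 1].reshape(len(table.sample_ids), -1)[:, 0],
            np.log(totals))

    def test_missing_host_or_feature_errors(self, small):
        table, truth = small
        md = table.metadata.copy()
        md.loc[md.index[0], "host"] = "nonexistent"
        from coralsym.tables import FeatureTable

        bad = FeatureTable(table.counts, metadata=md,
                           taxonomy=table.taxonomy)
        with pytest.raises(ValueError, match="nonexistent"):
            G.build_cophylo_design(bad, truth.host_tree,
                                   truth.microbe_tree)
        renamed = FeatureTable(
            table.counts.rename(index={table.feature_ids[0]: "ghost"}),
            metadata=table.metadata)
        with pytest.raises(ValueError, match="ghost"):
            G.build_cophylo_design(renamed, truth.host_tree,
                                   truth.microbe_tree)

    def test_zero_total_sample_rejected(self, small):
        """Empty samples have no depth covariate; they must be filtered
        out before the design is built."""
        table, truth = small
        from coralsym.tables import FeatureTable

        counts = table.counts.copy()
        counts.iloc[:, 0] = 0
        bad = FeatureTable(counts, metadata=table.metadata)
        with pytest.raises(ValueError, match="zero total"):
            G.build_cophylo_design(bad, truth.host_tree,
                                   truth.microbe_tree)


class TestFit:
    def test_bit_identical_given_seed(self):
        sc = SimulationScenario(host_n_tips=6, microbe_n_tips=8,
                                samples_per_host=2, seed=3)
        table, truth = simulate_cophylo_dataset(sc)
        design = G.build_cophylo_design(table, truth.host_tree,
                                        truth.microbe_tree)
        cfg = G.GlmmConfig(n_iter=600, burn_in=100, thin=2, seed=11)
        a = G.fit_binary_glmm(design, cfg)
        b = G.fit_binary_glmm(design, cfg)
        np.testing.assert_array_equal(a.var_draws, b.var_draws)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)

    def test_null_scenario_lower_bounds_stay_below_threshold(
            self, null_binary_fits):
        """All-null data: each term's ICC lower bound < 0.01 in >=90%
        of the replicate fits."""
        lowers = pd.concat([c.icc_lower for c in null_binary_fits], axis=1)
        frac_below = (lowers < 0.01).mean(axis=1)
        assert (frac_below >= 0.9).all(), frac_below

    def test_recovery_cophylogeny_dominates_interactions(
            self, recovery_binary_fits):
        """Dominant simulated cophylogeny variance: that term has the
        largest posterior-mean ICC among the four interactions in >=8/10
        fits."""
        wins = 0
        for calls in recovery_binary_fits:
            inter = calls.loc[list(G.INTERACTION_TERMS)]
            wins += inter.icc_mean.idxmax() == "hostphylo_x_microbephylo"
        assert wins >= 8, wins

    def test_prior_scale_insensitivity_of_calls(self):
        """Halving/doubling the prior scale leaves every significance
        call unchanged in the dominant-term scenario."""
        table, truth = simulate_cophylo_dataset(recovery_scenario())
        design = G.build_cophylo_design(table, truth.host_tree,
                                        truth.microbe_tree)
        calls = {}
        for scale in (0.5, 1.0, 2.0):
            # chains long enough that calls are posterior- rather than
            # Monte-Carlo-noise-driven
            cfg = G.GlmmConfig(n_iter=20_000, burn_in=5_000, thin=8,
                               prior_scale=scale, seed=5)
            calls[scale] = G.call_significance(
                G.fit_binary_glmm(design, cfg))["significant"]
        assert calls[0.5].equals(calls[1.0])
        assert calls[2.0].equals(calls[1.0])
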