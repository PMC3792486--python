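"""MCMC kernels: correctness against oracles, determinism, diagnostics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import neurofba as nf
from neurofba.catalog import ModelError
from neurofba.fixtures import ExplicitBoundary, _bare_system, _box_constraints
from neurofba.sampler import effective_sample_size


@pytest.fixture(scope="module")
def toy_2d():
    """Two fluxes with one soft balance f1 ~ f2 and a box: has both a stiff
    and a nearly flat direction, the structure of the full problem."""
    system = _bare_system(np.array([[1.0, -1.0]]), ["f1", "f2"])
    boundary = ExplicitBoundary(rhs=np.zeros(1), sigma=np.array([0.05]))
    cons = _box_constraints(["f1", "f2"], np.zeros(2), np.full(2, 1.0))
    return nf.build_density(system, boundary, cons)


class TestAgainstClosedForm:
    def test_gibbs_matches_truncated_normal_moments(self):
        # N(1, 0.5^2) truncated to [0, 10]
        toy = nf.toy_chain_system(length=1, influx=1.0, sigma=0.5)
        sample = nf.mcmc_sample(toy.density(), N=50_000, burn_in=500, seed=0)
        a, b = (0 - 1) / 0.5, (10 - 1) / 0.5
        exact_mean = stats.truncnorm.mean(a, b, loc=1.0, scale=0.5)
        exact_sd = stats.truncnorm.std(a, b, loc=1.0, scale=0.5)
        se = exact_sd / np.sqrt(effective_sample_size(sample.vectors[:, 0]))
        assert sample.vectors.mean() == pytest.approx(exact_mean, abs=3 * se)
        assert sample.vectors.std() == pytest.approx(exact_sd, rel=0.05)

    def test_chain_means_converge_to_influx(self):
        toy = nf.toy_chain_system(length=3, influx=0.3, sigma=0.01)
        sample = nf.mcmc_sample(toy.density(), N=20_000, burn_in=500, seed=1)
        for j in range(3):
            col = sample.vectors[:, j]
            se = col.std() / np.sqrt(effective_sample_size(col))
            assert col.mean() == pytest.approx(0.3, abs=max(3 * se, 1e-3))


class TestAgainstRejectionOracle:
    @pytest.mark.parametrize("method", ["gibbs", "gibbs-coordinate", "hit-and-run"])
    def test_marginals_match_oracle_on_toy_polytope(self, toy_2d, method):
        """1-D marginal KS distance < 0.02 against exact independent draws.

        The coordinate-sweep and hit-and-run kernels are exact but more
        autocorrelated than the eigenbasis Gibbs, so they are thinned to
        keep the comparison a test of distributional correctness rather
        than of mixing speed.
        """
        thin = 1 if method == "gibbs" else 20
        oracle = nf.rejection_oracle(toy_2d, N=50_000, seed=10)
        sample = nf.mcmc_sample(
            toy_2d, N=50_000, burn_in=1_000, thinning=thin, seed=11, method=method
        )
        for j in range(2):
            ks = stats.ks_2samp(oracle.vectors[:, j], sample.vectors[:, j])
            assert ks.statistic < 0.02, (method, j)

    def test_random_polytope_marginals_match_oracle(self):
        toy = nf.random_polytope_system(4, 2, seed=42)
        dens = toy.density()
        oracle = nf.rejection_oracle(dens, N=50_000, seed=12)
        sample = nf.mcmc_sample(dens, N=50_000, burn_in=1_000, seed=13)
        for j in range(4):
            ks = stats.ks_2samp(oracle.vectors[:, j], sample.vectors[:, j])
            assert ks.statistic < 0.02, j

    def test_gibbs_and_hit_and_run_agree(self, toy_2d):
        g = nf.mcmc_sample(toy_2d, N=50_000, burn_in=1_000, seed=14)
        hr = nf.mcmc_sample(toy_2d, N=50_000, burn_in=1_000, thinning=20,
                            seed=15, method="hit-and-run")
        for j in range(2):
            ks = stats.ks_2samp(g.vectors[:, j], hr.vectors[:, j])
            assert ks.statistic < 0.02


class TestFlatDirections:
    def test_flat_direction_explored_uniformly(self, toy_2d):
        """The f1+f2 direction is nearly flat; its marginal must cover the
        box instead of sticking near the start."""
        sample = nf.mcmc_sample(toy_2d, N=30_000, burn_in=1_000, seed=2)
        s = sample.vectors.sum(axis=1) / 2  # position along the flat diagonal
        assert s.min() < 0.1 and s.max() > 0.9
        se = s.std() / np.sqrt(effective_sample_size(s))
        assert s.mean() == pytest.approx(0.5, abs=4 * se)

    def test_target_control_realized_on_flat_coordinate(self):
        toy = nf.toy_chain_system(length=1, influx=0.0, sigma=1e6)
        dens = toy.density(targets=[nf.TargetControl("f1", 0.13, 0.005)])
        sample = nf.mcmc_sample(dens, N=20_000, burn_in=500, seed=3)
        assert sample.vectors.mean() == pytest.approx(0.13, abs=0.005)
        assert sample.vectors.std() == pytest.approx(0.005, rel=0.1)


class TestInvariants:
    def test_every_stored_vector_satisfies_hard_constraints(self, toy_2d):
        sample = nf.mcmc_sample(toy_2d, N=5_000, burn_in=100, seed=4)
        slack = sample.vectors @ toy_2d.constraints.C.T - toy_2d.constraints.c
        assert slack.min() >= -1e-9

    def test_seed_determinism_is_bit_exact(self, toy_2d):
        a = nf.mcmc_sample(toy_2d, N=2_000, burn_in=100, seed=5)
        b = nf.mcmc_sample(toy_2d, N=2_000, burn_in=100, seed=5)
        assert np.array_equal(a.vectors, b.vectors)
        c = nf.mcmc_sample(toy_2d, N=2_000, burn_in=100, seed=6)
        assert not np.array_equal(a.vectors, c.vectors)

    def test_infeasible_start_rejected(self, toy_2d):
        with pytest.raises(ModelError, match="start"):
            nf.mcmc_sample(toy_2d, start=np.array([-1.0, 0.5]), N=10, seed=0)

    def test_thinning_and_burn_in_validation(self, toy_2d):
        with pytest.raises(ModelError):
            nf.mcmc_sample(toy_2d, N=0, seed=0)
        with pytest.raises(ModelError):
            nf.mcmc_sample(toy_2d, N=10, thinning=0, seed=0)


class TestSummaries:
    def test_mean_of_single_vector_is_that_vector(self):
        s = nf.FluxSample(np.array([[1.0, 2.0]]), ["a", "b"])
        assert nf.sample_mean(s).tolist() == [1.0, 2.0]

    def test_mean_of_symmetric_pair_is_zero(self):
        u = np.array([0.3, -1.2])
        s = nf.FluxSample(np.vstack([u, -u]), ["a", "b"])
        assert nf.sample_mean(s) == pytest.approx([0.0, 0.0])

    def test_spread_of_constant_sample_is_zero(self):
        s = nf.FluxSample(np.ones((50, 2)), ["a", "b"])
        assert nf.sample_spread(s)["sd"] == pytest.approx([0.0, 0.0])

    def test_two_point_variance_formula(self):
        a, b = 0.2, 1.0
        s = nf.FluxSample(np.array([[a], [b]]), ["f"])
        assert nf.sample_spread(s)["sd"][0] ** 2 == pytest.approx((b - a) ** 2 / 2)

    def test_spread_requires_two_vectors(self):
        s = nf.FluxSample(np.ones((1, 1)), ["f"])
        with pytest.raises(ModelError):
            nf.sample_spread(s)


class TestDiagnostics:
    def test_independent_draws_have_full_ess(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        assert effective_sample_size(x) > 0.5 * x.size

    def test_constant_chain_is_flagged(self):
        vec = np.ones((500, 2))
        vec[:, 1] = np.random.default_rng(1).normal(size=500)
        s = nf.FluxSample(vec, ["const", "noise"])
        diag = nf.chain_diagnostics(s)
        assert "const" in diag["flagged"]
        assert "noise" not in diag["flagged"]

    def test_toy_chain_at_defaults_is_unflagged(self):
        toy = nf.toy_chain_system(length=2, influx=0.5, sigma=0.05)
        sample = nf.mcmc_sample(toy.density(), N=10_000, burn_in=500, seed=7)
        diag = nf.chain_diagnostics(sample)
        assert diag["flagged"] == []

    def test_diagnostics_require_minimum_size(self):
        s = nf.FluxSample(np.ones((10, 1)), ["f"])
        with pytest.raises(ModelError):
            nf.chain_diagnostics(s)
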