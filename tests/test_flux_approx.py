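"""EP moments against analytic values and the hit-and-run sampling oracle.

Analytic references: the chain polytope is a segment (uniform mean 1/2,
variance 1/12, perfect inter-reaction correlation); the triangle polytope
is the unit simplex in (v2, v3), where integration gives E[v2] = 1/3,
Var[v2] = 1/18, Cov(v2, v3) = -1/36 and E[v1] = 2/3.
"""

import numpy as np
import pytest

from commet.fixtures import (CHAIN_MEAN, CHAIN_VARIANCE, TRIANGLE_COV_BRANCHES,
                             TRIANGLE_MEAN_BRANCH, TRIANGLE_MEAN_INFLOW,
                             TRIANGLE_VAR_BRANCH, make_chain_model,
                             make_triangle_model)
from commet.flux_approx import EpConfig, ep_moments, sample_moments
from commet.model_core import FluxSpace, MetabolicModel, Metabolite, Reaction
from commet.preprocess import remove_blocked, run_fva


class TestEpChain:
    def test_means_by_symmetry(self, chain_reduced):
        fm = ep_moments(chain_reduced)
        np.testing.assert_allclose(fm.mean, CHAIN_MEAN, rtol=0.05)

    def test_variance_and_correlation(self, chain_reduced):
        fm = ep_moments(chain_reduced)
        np.testing.assert_allclose(fm.variance, CHAIN_VARIANCE, rtol=0.2)
        corr = fm.covariance[0, 1] / np.sqrt(
            fm.covariance[0, 0] * fm.covariance[1, 1])
        assert corr == pytest.approx(1.0, abs=1e-6)

    def test_convergence_recorded(self, chain_reduced):
        fm = ep_moments(chain_reduced)
        assert fm.convergence["converged"]
        assert fm.convergence["iterations"] >= 1


class TestEpTriangle:
    def test_branch_moments(self, triangle_reduced):
        fm = ep_moments(triangle_reduced)
        ids = fm.reaction_ids
        i1, i2, i3 = (ids.index(r) for r in ("v1", "v2", "v3"))
        assert fm.mean[i2] == pytest.approx(TRIANGLE_MEAN_BRANCH, rel=0.05)
        assert fm.mean[i1] == pytest.approx(TRIANGLE_MEAN_INFLOW, rel=0.05)
        assert fm.variance[i2] == pytest.approx(TRIANGLE_VAR_BRANCH, rel=0.2)
        assert fm.covariance[i2, i3] == pytest.approx(
            TRIANGLE_COV_BRANCHES, rel=0.2)
        assert fm.covariance[i2, i3] < 0


class TestEpContracts:
    def test_deterministic(self, triangle_reduced):
        a = ep_moments(triangle_reduced)
        b = ep_moments(triangle_reduced)
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)
        np.testing.assert_allclose(a.covariance, b.covariance, atol=1e-12)

    def test_covariance_symmetric_psd_diag(self, triangle_reduced):
        fm = ep_moments(triangle_reduced)
        C = fm.covariance
        assert np.max(np.abs(C - C.T)) <= 1e-8 * max(np.max(np.abs(C)), 1)
        np.testing.assert_allclose(np.diag(C), fm.variance, rtol=1e-8)
        assert np.linalg.eigvalsh(C).min() >= -1e-10

    def test_means_within_bounds(self, triangle_reduced):
        fm = ep_moments(triangle_reduced)
        assert (fm.mean >= triangle_reduced.lb - 1e-6).all()
        assert (fm.mean <= triangle_reduced.ub + 1e-6).all()

    def test_zero_width_reaction_gets_floor_variance(self, triangle_model):
        space = FluxSpace(triangle_model, "pinned", {"v2": (0.25, 0.25)})
        reduced = remove_blocked(space, run_fva(space))
        cfg = EpConfig()
        fm = ep_moments(reduced, cfg)
        i = fm.reaction_ids.index("v2")
        assert fm.variance[i] <= cfg.variance_floor
        assert fm.mean[i] == pytest.approx(0.25, abs=1e-6)

    def test_infeasible_space_errors(self, chain_model):
        # v1 pinned at 0.9, v2 at 0.1: S v = 0 cannot hold
        from commet.preprocess import ReducedFluxSpace
        bad = ReducedFluxSpace(
            MetabolicModel(chain_model.model_id,
                           list(chain_model.metabolites),
                           list(chain_model.reactions),
                           chain_model.S,
                           np.array([0.9, 0.1]), np.array([0.9, 0.1])),
            "bad", np.array([0.9, 0.1]), np.array([0.9, 0.1]))
        with pytest.raises(ValueError, match="infeasible"):
            ep_moments(bad)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EpConfig(max_iterations=0)
        with pytest.raises(ValueError):
            EpConfig(damping=1.0)


class TestSampler:
    def test_chain_moments(self, chain_reduced):
        fm = sample_moments(chain_reduced, n_samples=100_000, seed=11)
        np.testing.assert_allclose(fm.mean, CHAIN_MEAN, atol=0.01)
        np.testing.assert_allclose(fm.variance, CHAIN_VARIANCE, rtol=0.1)

    def test_triangle_moments(self, triangle_reduced):
        fm = sample_moments(triangle_reduced, n_samples=100_000, seed=11)
        ids = fm.reaction_ids
        i2, i3 = ids.index("v2"), ids.index("v3")
        assert fm.variance[i2] == pytest.approx(TRIANGLE_VAR_BRANCH, rel=0.1)
        assert fm.covariance[i2, i3] == pytest.approx(
            TRIANGLE_COV_BRANCHES, rel=0.15)

    def test_same_seed_identical(self, triangle_reduced):
        a = sample_moments(triangle_reduced, n_samples=2000, seed=5)
        b = sample_moments(triangle_reduced, n_samples=2000, seed=5)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.covariance, b.covariance)

    def test_samples_respect_mass_balance(self, triangle_reduced):
        fm = sample_moments(triangle_reduced, n_samples=5000, seed=3)
        # mean must satisfy S v = 0 like every sample
        assert np.abs(triangle_reduced.S @ fm.mean).max() < 1e-8

    def test_degenerate_space_point_mass(self, chain_model):
        from commet.preprocess import ReducedFluxSpace
        fixed = MetabolicModel(chain_model.model_id,
                               list(chain_model.metabolites),
                               list(chain_model.reactions),
                               chain_model.S,
                               np.array([0.3, 0.3]), np.array([0.3, 0.3]))
        space = ReducedFluxSpace(fixed, "point", fixed.lb, fixed.ub)
        fm = sample_moments(space, n_samples=100, seed=0)
        np.testing.assert_allclose(fm.mean, 0.3)
        np.testing.assert_allclose(fm.variance, 0.0)


class TestOracleEquivalence:
    """EP vs sampling on every small fixture polytope."""

    @pytest.mark.parametrize("maker", [
        lambda: make_chain_model(2),
        lambda: make_chain_model(4),
        make_triangle_model,
        "random7",
    ])
    def test_ep_matches_sampler(self, maker):
        if maker == "random7":
            S = np.array([
                [1, -1, 0, 0, 1, 0, -1],
                [0, 1, -1, 0, 0, -1, 0],
                [0, 0, 1, -1, 0, 1, 0],
            ], float)
            mets = [Metabolite(f"m{i}", f"m{i}", "c") for i in range(3)]
            rxns = [Reaction(f"r{j}", f"r{j}", "s", False, "", "")
                    for j in range(7)]
            model = MetabolicModel("rand", mets, rxns, S,
                                   np.zeros(7), np.ones(7))
        else:
            model = maker()
        space = FluxSpace(model, "base")
        reduced = remove_blocked(space, run_fva(space))
        ep = ep_moments(reduced)
        mc = sample_moments(reduced, n_samples=60_000, seed=21)
        ranges = reduced.ub - reduced.lb
        assert np.all(np.abs(ep.mean - mc.mean) <= 0.05 * np.maximum(ranges, 1e-9))
        v = mc.covariance.ravel()
        if v.std() <= 1e-3 * np.abs(v).max():
            # fully coupled polytope: covariance is constant and the
            # correlation undefined; require elementwise agreement instead
            np.testing.assert_allclose(ep.covariance, mc.covariance, rtol=0.2)
        else:
            corr = np.corrcoef(ep.covariance.ravel(), v)[0, 1]
            assert corr >= 0.9
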