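import math

import numpy as np
import pytest

from vgdate import ep_engine as ep
from vgdate.arg_tables import build_logical_edges
from vgdate.ep_engine import CavityParams, EPConfig
from vgdate.synthcoal import quadrature_posterior, rejection_posterior

from conftest import make_tables


def fixed_cfg(mu, eta, **kw):
    return EPConfig(mutation_rate=mu, root_prior="fixed", eta=eta, **kw)


class TestPoissonLoglik:
    def test_zero_count(self):
        assert ep.poisson_edge_loglik(0, 1.0, 1.0) == pytest.approx(-1.0)

    def test_two_counts(self):
        assert ep.poisson_edge_loglik(2, 1.0, 1.0) == pytest.approx(
            math.log(0.5) - 1.0)

    def test_ordering_violation_is_minus_inf(self):
        assert ep.poisson_edge_loglik(1, -0.5, 1.0) == -math.inf
        assert ep.poisson_edge_loglik(0, 0.0, 1.0) == -math.inf


class TestSurrogateMoments:
    def test_sample_child_substitution(self):
        """Direct substitution: shape 1, rate 0, y=2, mu_s=1 gives the
        Gamma(3, 1) moments (3, 12)."""
        assert ep.surrogate_moments_sample_child(1.0, 0.0, 2.0, 1.0) == \
            pytest.approx((3.0, 12.0))

    def test_sample_child_exponential(self):
        assert ep.surrogate_moments_sample_child(1.0, 0.0, 0.0, 1.0) == \
            pytest.approx((1.0, 2.0))

    def test_sample_child_conjugate_gamma(self):
        a, b, y, mus = 2.3, 0.4, 5.0, 1.7
        m1, m2 = ep.surrogate_moments_sample_child(a, b, y, mus)
        assert m1 == pytest.approx((a + y) / (mus + b))
        assert m2 == pytest.approx((a + y) * (a + y + 1) / (mus + b)**2)

    def test_internal_child_z_zero_closed_form(self):
        """At z=0 the closed forms reduce to elementary integrals:
        E[ti]=1.5, E[tj]=0.75."""
        cav = CavityParams(2.0, 1.0, 1.0, 1.0)
        Eti, Eti2, Etj, Etj2 = ep.surrogate_moments(cav, 0.0, 1.0)
        assert Eti == pytest.approx(1.5)
        assert Etj == pytest.approx(0.75)

    def test_internal_child_vs_quadrature(self):
        from test_hypergeom import quad_moments

        for (ai, bi, aj, bj, y, mus) in [(2, 1, 3, 2, 1, 0.5),
                                         (0.5, 0.3, 1.5, 2.0, 3, 0.8),
                                         (5, 2, 0.7, 0.1, 2, 1.3)]:
            ref = quad_moments(ai, bi, aj, bj, y, mus)
            got = ep.surrogate_moments(CavityParams(ai, bi, aj, bj), y, mus)
            assert got == pytest.approx(ref, rel=1e-6)

    def test_child_limit_to_sample_case(self):
        """As the child cavity shrinks to a point mass at 0, the parent
        moments approach the contemporary-sample closed form."""
        ai, bi, y, mus = 2.0, 1.0, 3.0, 0.7
        ref = ep.surrogate_moments_sample_child(ai, bi, y, mus)
        cav = CavityParams(ai, bi, 1e-4, 1e4)
        Eti, Eti2, Etj, _ = ep.surrogate_moments(cav, y, mus)
        assert Etj < 1e-6
        assert Eti == pytest.approx(ref[0], rel=1e-3)
        assert Eti2 == pytest.approx(ref[1], rel=1e-3)

    def test_infeasible_cavity_raises(self):
        with pytest.raises(FloatingPointError):
            ep.surrogate_moments(CavityParams(1.0, 0.0, -1.0, 0.0), 0.0, 1.0)


class TestProjection:
    def test_feasible_step_untouched(self):
        lam = ep.project_feasible(np.array([[1.0, 1.0]]),
                                  np.array([[0.0, 1.0]]))
        assert lam == 1.0

    def test_alpha_hits_bound_exactly(self):
        # posterior a = 0.5 - lam*1.0 must stay >= alpha_min - 1
        cur = np.array([[0.5, 1.0]])
        step = np.array([[-2.0, 0.0]])
        lam = ep.project_feasible(step, cur, alpha_min=1e-3)
        a_final = cur[0, 0] + lam * step[0, 0]
        assert a_final == pytest.approx(1e-3 - 1.0)

    def test_pathological_gives_zero(self):
        cur = np.array([[1e-3 - 1.0, 1.0]])
        step = np.array([[-1.0, 0.0]])
        assert ep.project_feasible(step, cur) == 0.0


class TestRootEM:
    def test_fixed_point_exponential(self, star5):
        """Roots distributed Exp(eta): the EM update returns eta."""
        cfg = fixed_cfg(0.01, 2.0)
        store = ep.init_store(star5, cfg)
        # posterior = prior only: alpha\0 = 1, beta\0 = 0 -> eta' = eta
        eta = ep.root_em_update(store)
        assert eta == pytest.approx(2.0)

    def test_printed_update_substitution(self, star5):
        """alpha\\0=4, beta\\0=1, eta=1 -> eta' = 1/2."""
        cfg = fixed_cfg(0.01, 1.0)
        store = ep.init_store(star5, cfg)
        root = store.root_nodes[0]
        store.post[root] = np.array([3.0, 2.0])  # shape 4, rate 1 + eta
        eta = ep.root_em_update(store)
        assert eta == pytest.approx(0.5)

    def test_identical_roots_ratio_invariance(self):
        """k identical roots give the same update as one root."""
        nodes = [(0, 0.0, 1, -1), (1, 0.0, 1, -1),
                 (2, np.nan, 0, -1), (3, np.nan, 0, -1)]
        edges = [(0.0, 50.0, 2, 0), (0.0, 50.0, 2, 1),
                 (50.0, 100.0, 3, 0), (50.0, 100.0, 3, 1)]
        t = make_tables(nodes, edges)
        cfg = fixed_cfg(0.01, 1.0)
        store = ep.init_store(t, cfg)
        for r in store.root_nodes:
            store.post[r] = np.array([3.0, 2.0])
        assert ep.root_em_update(store) == pytest.approx(0.5)


class TestEPOnFixtures:
    def test_star_conjugate_exact(self, star5):
        """A star ARG is conjugate: EP must recover
        Gamma(1 + sum y, eta + mu * sum s) to 1e-8 in <= 3 sweeps."""
        mu, eta = 0.02, 0.5
        res = ep.date(star5, fixed_cfg(mu, eta, max_iter=3))
        root = star5.roots()[0]
        assert res.node_shape[root] == pytest.approx(1.0 + 6.0, abs=1e-8)
        assert res.node_rate[root] == pytest.approx(eta + mu * 1000.0,
                                                    abs=1e-8)
        assert res.iterations <= 3

    def test_bookkeeping_identity_after_updates(self, chain):
        cfg = fixed_cfg(0.02, 0.3)
        store = ep.init_store(chain, cfg)
        for e in store.order:
            ep.update_edge(store, e, cfg)
            assert store.check_bookkeeping()

    def test_fixed_point_idempotence(self, chain):
        """Re-sweeping a converged store changes nothing."""
        cfg = fixed_cfg(0.02, 0.3, max_iter=50, tol=1e-12)
        res = ep.date(chain, cfg)
        post = res.store.post.copy()
        delta = ep.ep_sweep(res.store, cfg)
        assert delta < 1e-9
        assert np.allclose(res.store.post, post, atol=1e-9)

    def test_edge_order_invariance(self, small_sim):
        """Permuting edge-table rows leaves the result identical: the
        sweep order is fixed internally."""
        import pandas as pd

        sim, cfg_sim = small_sim
        tables = sim.tables
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(tables.edges))
        from vgdate.arg_tables import ArgTables

        shuffled = ArgTables.from_frames(
            tables.nodes, tables.edges.iloc[perm].reset_index(drop=True),
            tables.sites, tables.mutations,
            sequence_length=tables.sequence_length)
        cfg = fixed_cfg(cfg_sim.mutation_rate, 1e-4, max_iter=3)
        with pytest.warns(UserWarning):
            r1 = ep.date(tables, cfg)
        with pytest.warns(UserWarning):
            r2 = ep.date(shuffled, cfg)
        assert np.array_equal(r1.store.post, r2.store.post)

    def test_chain_matches_quadrature_oracle(self, chain):
        mu, eta = 0.02, 0.3
        res = ep.date(chain, fixed_cfg(mu, eta, max_iter=50, tol=1e-10))
        oracle = quadrature_posterior(chain, mu, eta)
        for v in (1, 2):
            m = oracle.loc[v, "mean"]
            sd = math.sqrt(oracle.loc[v, "m2"] - m * m)
            assert res.node_mean[v] == pytest.approx(m, rel=0.02)
            assert math.sqrt(res.node_variance[v]) == pytest.approx(sd,
                                                                    rel=0.10)

    def test_chain_matches_rejection_oracle(self, chain):
        mu, eta = 0.02, 0.3
        res = ep.date(chain, fixed_cfg(mu, eta, max_iter=50, tol=1e-10))
        oracle = rejection_posterior(chain, mu, eta, n_accept=150_000,
                                     seed=7)
        for v in (1, 2):
            m = oracle.loc[v, "mean"]
            tol = max(0.02 * m, 4 * oracle.loc[v, "se_mean"])
            assert abs(res.node_mean[v] - m) < tol


class TestConstrainTimes:
    def test_ordering_enforced(self, chain):
        means = np.array([0.0, 5.0, 2.0])  # parent younger than child
        ct = ep.constrain_times(chain, means)
        assert ct[2] > ct[1] > ct[0]

    def test_no_op_when_ordered(self, chain):
        means = np.array([0.0, 1.0, 2.0])
        ct = ep.constrain_times(chain, means)
        assert np.allclose(ct, means)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"mutation_rate": -1.0},
        {"mutation_rate": 1.0, "tol": 0.0},
        {"mutation_rate": 1.0, "damping": 1.5},
        {"mutation_rate": 1.0, "root_prior": "fixed"},
    ])
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValueError):
            EPConfig(**kw)
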