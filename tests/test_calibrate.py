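import numpy as np
import pytest
from scipy import stats

from vgdate.calibrate import (TimeTransform, apply_transform_to_posterior,
                              fit_area_rescaling, fit_path_rescaling,
                              transform_gamma_arrays)
from vgdate.gamma import GammaParams


class TestTimeTransform:
    def test_identity(self):
        g = TimeTransform.identity()
        x = np.array([0.0, 1.5, 100.0])
        assert np.allclose(g(x), x)

    def test_piecewise_values_and_inverse(self):
        g = TimeTransform(np.array([0.0, 10.0, 20.0]),
                          np.array([1.0, 2.0, 0.5]))
        assert g(5.0) == pytest.approx(5.0)
        assert g(15.0) == pytest.approx(10.0 + 2.0 * 5.0)
        assert g(30.0) == pytest.approx(30.0 + 0.5 * 10.0)
        x = np.linspace(0, 50, 101)
        assert np.allclose(g.inverse(g(x)), x)

    def test_monotone(self):
        g = TimeTransform(np.array([0.0, 1.0, 5.0]),
                          np.array([0.3, 4.0, 1.0]))
        x = np.linspace(0, 10, 200)
        assert (np.diff(g(x)) > 0).all()

    def test_invalid_slopes_rejected(self):
        with pytest.raises(ValueError):
            TimeTransform(np.array([0.0, 1.0]), np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            TimeTransform(np.array([1.0, 2.0]), np.array([1.0, 1.0]))


class TestQuantileMatching:
    def test_identity_preserves_posterior(self):
        post = GammaParams(3.0, 0.7)
        out = apply_transform_to_posterior(TimeTransform.identity(), post)
        assert out.shape == pytest.approx(post.shape, abs=1e-7)
        assert out.rate == pytest.approx(post.rate, abs=1e-7)

    def test_single_slope_is_scale_family(self):
        """g(t) = 2t maps Gamma(a, b) to Gamma(a, b/2) exactly."""
        post = GammaParams(2.5, 1.4)
        g = TimeTransform(np.array([0.0]), np.array([2.0]))
        out = apply_transform_to_posterior(g, post)
        assert out.shape == pytest.approx(2.5, rel=1e-9)
        assert out.rate == pytest.approx(0.7, rel=1e-9)

    def test_piecewise_reproduces_transformed_quantiles(self):
        post = GammaParams(4.0, 0.9)
        g = TimeTransform(np.array([0.0, 2.0, 6.0]),
                          np.array([1.0, 3.0, 0.8]))
        out = apply_transform_to_posterior(g, post, 0.025, 0.975)
        for q in (0.025, 0.975):
            target = g(post.quantile(q))
            assert out.quantile(q) == pytest.approx(target, rel=1e-9)

    def test_ordering_preserved(self):
        g = TimeTransform(np.array([0.0, 1.0]), np.array([0.5, 2.0]))
        a = GammaParams(2.0, 2.0)
        b = GammaParams(6.0, 1.0)
        ta = apply_transform_to_posterior(g, a)
        tb = apply_transform_to_posterior(g, b)
        assert ta.quantile(0.5) < tb.quantile(0.5)

    def test_vectorized_matches_scalar(self):
        g = TimeTransform(np.array([0.0, 3.0]), np.array([1.0, 1.7]))
        shapes = np.array([1.0, 5.0, 0.5])
        rates = np.array([0.2, 1.0, 3.0])
        s, r = transform_gamma_arrays(g, shapes, rates)
        for k in range(3):
            out = apply_transform_to_posterior(
                g, GammaParams(shapes[k], rates[k]))
            assert s[k] == pytest.approx(out.shape, rel=1e-6)
            assert r[k] == pytest.approx(out.rate, rel=1e-6)


class TestRescalingFits:
    def test_true_times_give_unit_slopes(self, small_sim):
        """Dating at the true rate with true node times is already on
        the molecular clock: slopes near 1 (Poisson noise only)."""
        sim, cfg = small_sim
        mut_ages = sim.true_mutation_ages
        g = fit_path_rescaling(sim.tables, sim.true_node_times, mut_ages,
                               cfg.mutation_rate, n_intervals=4)
        assert np.all(np.abs(g.slopes - 1.0) < 0.25)
        assert abs(np.mean(g.slopes) - 1.0) < 0.1

    def test_doubling_mu_halves_slopes(self, small_sim):
        sim, cfg = small_sim
        mut_ages = sim.true_mutation_ages
        g1 = fit_path_rescaling(sim.tables, sim.true_node_times, mut_ages,
                                cfg.mutation_rate, n_intervals=3)
        g2 = fit_path_rescaling(sim.tables, sim.true_node_times, mut_ages,
                                2 * cfg.mutation_rate, n_intervals=3)
        assert np.allclose(g2.slopes, g1.slopes / 2.0)

    def test_single_interval_collapse(self, small_sim):
        """n_intervals=1 gives one global factor: (mean mutations per
        sample) / (mu * mean per-sample opportunity)."""
        from vgdate.calibrate import edge_carrier_weights
        from vgdate.ep_engine import constrain_times

        sim, cfg = small_sim
        g = fit_path_rescaling(sim.tables, sim.true_node_times,
                               sim.true_mutation_ages, cfg.mutation_rate,
                               n_intervals=1)
        assert len(g.slopes) == 1
        ct = constrain_times(sim.tables, sim.true_node_times)
        weights, _, carriers = edge_carrier_weights(sim.tables, ct)
        n = sim.tables.num_samples
        obs = carriers.sum() / n
        t = sim.true_node_times
        exp = sum(w * (t[p] - t[c])
                  for (p, c), w in weights.items()) / n * cfg.mutation_rate
        assert g.slopes[0] == pytest.approx(obs / exp, rel=1e-9)

    def test_area_agrees_with_path_on_binary_arg(self, small_sim):
        """On a fully supported binary ARG both rescaling modes are
        similarly calibrated."""
        sim, cfg = small_sim
        gp = fit_path_rescaling(sim.tables, sim.true_node_times,
                                sim.true_mutation_ages, cfg.mutation_rate,
                                n_intervals=2)
        ga = fit_area_rescaling(sim.tables, sim.true_node_times,
                                sim.true_mutation_ages, cfg.mutation_rate,
                                n_intervals=2)
        assert np.allclose(gp.slopes, ga.slopes, rtol=0.35)

    def test_clock_property_after_path_rescaling(self, small_sim):
        """Per-sample mutation counts per interval match mu * interval
        length within 3 Poisson standard errors after rescaling."""
        from vgdate.calibrate import edge_carrier_weights
        from vgdate.ep_engine import constrain_times

        sim, cfg = small_sim
        mu = cfg.mutation_rate
        t = sim.true_node_times
        g = fit_path_rescaling(sim.tables, t, sim.true_mutation_ages, mu,
                               n_intervals=4)
        # recompute observed and expected per interval on rescaled times
        ct = constrain_times(sim.tables, t)
        weights, _, carriers = edge_carrier_weights(sim.tables, ct)
        n = sim.tables.num_samples
        grid = np.concatenate([g.breakpoints, [np.inf]])
        for k in range(len(g.slopes)):
            lo, hi = grid[k], grid[k + 1]
            sel = (sim.true_mutation_ages >= lo) & \
                (sim.true_mutation_ages < hi)
            obs = carriers[sel.to_numpy() if hasattr(sel, "to_numpy")
                           else sel].sum() / n
            exp = sum(w * max(0.0, min(t[p], hi) - max(t[c], lo))
                      for (p, c), w in weights.items()) / n * mu
            exp_scaled = exp * g.slopes[k]
            se = np.sqrt(max(obs, 1.0) / 1.0) / n
            # after rescaling: observed == expected * slope by construction
            # up to the uniform-in-age spreading approximation
            assert obs == pytest.approx(exp_scaled, rel=0.35)
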