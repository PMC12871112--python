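"""Model/Results interface tying the EP engine, calibration, singleton
handling and mutation dating together.

Typical use::

    from vgdate import ArgDatingModel, read_tables

    tables = read_tables("arg_dir/")
    model = ArgDatingModel(tables, mutation_rate=1e-8)
    res = model.fit()
    print(res.summary())
    res.node_posteriors      # DataFrame of per-node Gamma posteriors
    res.mutation_posteriors  # DataFrame of per-mutation posteriors
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .arg_tables import MISSING, ArgTables, read_tables
from .calibrate import (DEFAULT_Q_HI, DEFAULT_Q_LO, TimeTransform,
                        edge_carrier_weights, fit_area_rescaling,
                        fit_path_rescaling, transform_gamma_arrays)
from .ep_engine import EPConfig, EPResult, constrain_times, date
from .gamma import GammaParams, moments_to_canonical
from .mutation_dating import uniform_edge_moments
from .singletons import (PhaseState, date_phase_agnostic,
                         phase_all_random, phase_all_shortest_edge)

__all__ = ["ArgDatingModel", "ArgDatingResults"]


class ArgDatingModel:
    """Variational-Gamma dating of an ancestral recombination graph.

    Parameters
    ----------
    tables:
        Validated :class:`~vgdate.arg_tables.ArgTables` with
        contemporary (age-0) samples.
    mutation_rate:
        Per-base, per-generation mutation probability (the molecular
        clock rate).
    singletons:
        How to treat mutations flagged unphased: ``"agnostic"``
        (default; marginalize over phase inside EP), ``"shortest-edge"``
        (heuristic pre-phasing), ``"random"`` (worst-case baseline) or
        ``"drop"``.
    rescale:
        ``"path"`` (default; per-sample molecular-clock calibration),
        ``"area"`` (total-count calibration) or ``"none"``.
    root_prior / eta:
        ``"em"`` refits the exponential root-prior rate each sweep;
        ``"fixed"`` pins it at ``eta``.
    """

    def __init__(self, tables: ArgTables, mutation_rate: float, *,
                 singletons: str = "agnostic", rescale: str = "path",
                 rescale_intervals: int = 100, root_prior: str = "em",
                 eta: float | None = None, q_lo: float = DEFAULT_Q_LO,
                 q_hi: float = DEFAULT_Q_HI, seed: int | None = None):
        if singletons not in ("agnostic", "shortest-edge", "random", "drop"):
            raise ValueError(f"unknown singleton mode {singletons!r}")
        if rescale not in ("path", "area", "none"):
            raise ValueError(f"unknown rescale mode {rescale!r}")
        self.tables = tables
        self.mutation_rate = float(mutation_rate)
        self.singletons = singletons
        self.rescale = rescale
        self.rescale_intervals = int(rescale_intervals)
        self.root_prior = root_prior
        self.eta = eta
        self.q_lo = float(q_lo)
        self.q_hi = float(q_hi)
        self.seed = seed

    @classmethod
    def from_tsv(cls, path, mutation_rate: float, **kwargs
                 ) -> "ArgDatingModel":
        return cls(read_tables(path), mutation_rate, **kwargs)

    @classmethod
    def from_tree_sequence(cls, ts, mutation_rate: float, **kwargs
                           ) -> "ArgDatingModel":
        return cls(ArgTables.from_tree_sequence(ts), mutation_rate, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, max_iter: int = 25, tol: float = 1e-6,
            damping: float = 1.0) -> "ArgDatingResults":
        config = EPConfig(mutation_rate=self.mutation_rate,
                          max_iter=max_iter, tol=tol, damping=damping,
                          root_prior=self.root_prior, eta=self.eta,
                          seed=self.seed)
        tables = self.tables
        phase_state: PhaseState | None = None
        has_unphased = bool(
            len(tables.mutations)
            and (tables.mutations["unphased_individual"].to_numpy()
                 != MISSING).any())
        dropped = np.zeros(len(tables.mutations), dtype=bool)
        if has_unphased:
            if self.singletons == "shortest-edge":
                tables = phase_all_shortest_edge(tables)
            elif self.singletons == "random":
                tables = phase_all_random(tables, seed=self.seed or 0)
            elif self.singletons == "drop":
                unph = (tables.mutations["unphased_individual"].to_numpy()
                        != MISSING)
                dropped = unph
        if has_unphased and self.singletons == "agnostic":
            from .singletons import split_terminal_edges

            work_tables = split_terminal_edges(tables)
            ep_result, phase_state = date_phase_agnostic(
                work_tables, config, presplit=True)
        else:
            ep_result = date(tables, config)
            work_tables = tables
        return _assemble_results(self, work_tables, tables, config,
                                 ep_result, phase_state, dropped)


@dataclass
class ArgDatingResults:
    """Fitted node and mutation age posteriors.

    ``node_posteriors`` columns: id, post_shape, post_rate, mean,
    variance, constrained_time (calibrated generations; samples appear
    with zero constrained time and NaN posteriors).

    ``mutation_posteriors`` columns: id, site, mean, variance, lower,
    upper (central credible bounds), phase_prob (NaN unless an unphased
    singleton), dac, daf.
    """

    model: ArgDatingModel
    node_posteriors: pd.DataFrame
    mutation_posteriors: pd.DataFrame
    transform: TimeTransform
    eta: float
    iterations: int
    final_delta: float
    converged: bool
    n_projected: int
    n_skipped: int
    n_updates: int
    ep_result: EPResult = field(repr=False, default=None)
    phase_state: PhaseState | None = field(repr=False, default=None)
    ci_level: float = 0.95
    fit_options: dict = field(default_factory=dict)

    # -- convenience accessors -----------------------------------------
    def node_posterior(self, node: int) -> GammaParams:
        row = self.node_posteriors.loc[self.node_posteriors["id"] == node]
        return GammaParams(shape=float(row["post_shape"].iloc[0]),
                           rate=float(row["post_rate"].iloc[0]))

    @property
    def node_means(self) -> np.ndarray:
        return self.node_posteriors["mean"].to_numpy()

    @property
    def mutation_means(self) -> np.ndarray:
        return self.mutation_posteriors["mean"].to_numpy()

    def metadata(self) -> dict:
        return {
            "version": _version,
            "mutation_rate": self.model.mutation_rate,
            "singletons": self.model.singletons,
            "rescale": self.model.rescale,
            "rescale_intervals": self.model.rescale_intervals,
            "root_prior": self.model.root_prior,
            "eta": self.eta,
            "iterations": self.iterations,
            "final_delta": self.final_delta,
            "converged": self.converged,
            **self.fit_options,
            "transform_quantiles": [self.model.q_lo, self.model.q_hi],
            "n_projected": self.n_projected,
            "n_skipped": self.n_skipped,
            "n_updates": self.n_updates,
            "seed": self.model.seed,
            "transform_breakpoints": self.transform.breakpoints.tolist(),
            "transform_slopes": self.transform.slopes.tolist(),
        }

    def save(self, path) -> None:
        from .arg_tables import write_results

        write_results(self, path)

    def summary(self) -> str:
        np_ = self.node_posteriors
        internal = np_[np.isfinite(np_["post_shape"])]
        mp = self.mutation_posteriors
        ages = mp["mean"].dropna()
        lines = [
            "Variational-Gamma ARG dating results",
            "=" * 52,
            f"nodes: {len(np_)} ({len(internal)} dated internal)",
            f"mutations dated: {int(ages.notna().sum())} of {len(mp)}",
            f"mutation rate: {self.model.mutation_rate:.3e} /bp/gen",
            f"converged: {self.converged} "
            f"({self.iterations} sweeps, final delta {self.final_delta:.2e})",
            f"root prior rate eta: {self.eta:.6g} "
            f"({self.model.root_prior})",
            f"rescaling: {self.model.rescale} "
            f"({len(self.transform.slopes)} intervals)",
            f"projected/skipped updates: {self.n_projected}/{self.n_skipped} "
            f"of {self.n_updates}",
        ]
        if len(internal):
            q = internal["mean"].quantile([0.25, 0.5, 0.75])
            lines.append("node age quartiles (generations): "
                         f"{q.iloc[0]:.4g} / {q.iloc[1]:.4g} / "
                         f"{q.iloc[2]:.4g}")
        if len(ages):
            q = ages.quantile([0.25, 0.5, 0.75])
            lines.append("mutation age quartiles (generations): "
                         f"{q.iloc[0]:.4g} / {q.iloc[1]:.4g} / "
                         f"{q.iloc[2]:.4g}")
        return "\n".join(lines)

    def plot_posterior(self, node: int, ax=None):
        """Plot one node's age posterior density (requires matplotlib)."""
        import matplotlib.pyplot as plt
        from scipy import stats

        g = self.node_posterior(node)
        if ax is None:
            _, ax = plt.subplots()
        x = np.linspace(0, g.quantile(0.999), 400)
        ax.plot(x, stats.gamma.pdf(x, g.shape, scale=1 / g.rate))
        ax.set_xlabel("age (generations)")
        ax.set_ylabel("density")
        ax.set_title(f"node {node}")
        return ax


# ---------------------------------------------------------------------------

def _assemble_results(model: ArgDatingModel, work_tables: ArgTables,
                      orig_tables: ArgTables, config: EPConfig,
                      ep_result: EPResult, phase_state: PhaseState | None,
                      dropped: np.ndarray) -> ArgDatingResults:
    from scipy import stats

    n = work_tables.num_nodes
    internal = ep_result.internal
    shape = ep_result.node_shape.copy()
    rate = ep_result.node_rate.copy()
    # nodes outside the graph (possible after branch collapsing) are undated
    in_graph = np.zeros(n, dtype=bool)
    in_graph[work_tables.edges["parent"].to_numpy()] = True
    in_graph[work_tables.edges["child"].to_numpy()] = True
    undated = internal & ~in_graph
    shape[undated] = np.nan
    rate[undated] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ep = shape / rate
    mean_ep = np.where(internal & in_graph, mean_ep, 0.0)

    # mutation placement in the worked tables
    muts = work_tables.mutations
    edge_row = work_tables.assign_mutations_to_edges()
    unphased = muts["unphased_individual"].to_numpy() != MISSING \
        if len(muts) else np.empty(0, bool)
    parent_arr = work_tables.edges["parent"].to_numpy()
    child_arr = work_tables.edges["child"].to_numpy()
    is_sample = work_tables.is_sample()

    m1_mut = np.full(len(muts), np.nan)
    m2_mut = np.full(len(muts), np.nan)
    # phased mutations: uniform on their edge
    ok = (~unphased) & (edge_row >= 0) & ~dropped
    mp = parent_arr[edge_row[ok]]
    mc = child_arr[edge_row[ok]]
    with np.errstate(invalid="ignore", divide="ignore"):
        pm1 = shape[mp] / rate[mp]
        pm2 = shape[mp] * (shape[mp] + 1.0) / rate[mp] ** 2
        cm1 = np.where(is_sample[mc], 0.0, shape[mc] / rate[mc])
        cm2 = np.where(is_sample[mc], 0.0,
                       shape[mc] * (shape[mc] + 1.0) / rate[mc] ** 2)
    m1_mut[ok], m2_mut[ok] = uniform_edge_moments(pm1, pm2, cm1, cm2)
    # unphased singletons: responsibility-weighted mixture over the two
    # candidate edges (both with sample children)
    if phase_state is not None and len(phase_state.w):
        mid_lookup = {int(m): i for i, m in enumerate(muts["id"].to_numpy())}
        for s, w in zip(phase_state.singletons, phase_state.w):
            i = mid_lookup[s.mutation_id]
            parts = []
            for node_p, wt in ((s.parent_a, w), (s.parent_b, 1.0 - w)):
                pm1s = shape[node_p] / rate[node_p]
                pm2s = shape[node_p] * (shape[node_p] + 1.0) / rate[node_p]**2
                parts.append((wt, *uniform_edge_moments(pm1s, pm2s, 0.0, 0.0)))
            m1_mut[i] = sum(wt * a for wt, a, _ in parts)
            m2_mut[i] = sum(wt * b for wt, _, b in parts)

    # Gamma fits for mutations (EP time)
    mut_shape = np.full(len(muts), np.nan)
    mut_rate = np.full(len(muts), np.nan)
    for i in range(len(muts)):
        if not (np.isfinite(m1_mut[i]) and np.isfinite(m2_mut[i])):
            continue
        try:
            mut_shape[i], mut_rate[i] = moments_to_canonical(
                m1_mut[i], m2_mut[i])
        except ValueError:
            pass  # degenerate: left NaN, reported as point estimate

    # -- timescale calibration -----------------------------------------
    mut_mean_ep = m1_mut
    fit_fn = {"path": fit_path_rescaling, "area": fit_area_rescaling,
              "none": None}[model.rescale]
    finite_mut = mut_mean_ep[np.isfinite(mut_mean_ep)]
    if fit_fn is not None and len(finite_mut):
        transform = fit_fn(work_tables, mean_ep, finite_mut,
                           model.mutation_rate, model.rescale_intervals)
    else:
        transform = TimeTransform.identity()
    node_shape_t, node_rate_t = transform_gamma_arrays(
        transform, shape, rate, model.q_lo, model.q_hi)
    mut_shape_t, mut_rate_t = transform_gamma_arrays(
        transform, mut_shape, mut_rate, model.q_lo, model.q_hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        node_mean_t = node_shape_t / node_rate_t
        node_var_t = node_shape_t / node_rate_t**2
        mut_mean_t = mut_shape_t / mut_rate_t
        mut_var_t = mut_shape_t / mut_rate_t**2
    node_mean_t = np.where(internal & in_graph, node_mean_t, np.nan)

    ct = constrain_times(work_tables,
                         np.where(np.isfinite(node_mean_t), node_mean_t, 0.0))

    # -- carrier counts -------------------------------------------------
    dac = np.full(len(muts), -1, dtype=np.int64)
    daf = np.full(len(muts), np.nan)
    try:
        _, _, carriers = edge_carrier_weights(work_tables, ct)
        dac = carriers
        dac[unphased] = 1  # singletons by definition
        daf = dac / work_tables.num_samples
        daf[dac < 0] = np.nan
    except Exception:  # carrier counting must never sink a fit
        pass

    node_df = pd.DataFrame({
        "id": np.arange(n),
        "post_shape": node_shape_t,
        "post_rate": node_rate_t,
        "mean": node_mean_t,
        "variance": np.where(np.isfinite(node_mean_t), node_var_t, np.nan),
        "constrained_time": ct,
    })
    lo = np.full(len(muts), np.nan)
    hi = np.full(len(muts), np.nan)
    okq = np.isfinite(mut_shape_t) & np.isfinite(mut_rate_t)
    a_lo = (1.0 - 0.95) / 2.0
    if okq.any():
        lo[okq] = stats.gamma.ppf(a_lo, mut_shape_t[okq],
                                  scale=1.0 / mut_rate_t[okq])
        hi[okq] = stats.gamma.ppf(1.0 - a_lo, mut_shape_t[okq],
                                  scale=1.0 / mut_rate_t[okq])
    phase_prob = np.full(len(muts), np.nan)
    if phase_state is not None and len(phase_state.w):
        for s, w in zip(phase_state.singletons, phase_state.w):
            phase_prob[mid_lookup[s.mutation_id]] = w
    mut_df = pd.DataFrame({
        "id": muts["id"].to_numpy() if len(muts) else np.empty(0, np.int64),
        "site": muts["site"].to_numpy() if len(muts) else
        np.empty(0, np.int64),
        "post_shape": mut_shape_t,
        "post_rate": mut_rate_t,
        "mean": mut_mean_t,
        "variance": mut_var_t,
        "lower": lo,
        "upper": hi,
        "phase_prob": phase_prob,
        "dac": dac,
        "daf": daf,
    })
    store = ep_result.store
    return ArgDatingResults(
        model=model, node_posteriors=node_df, mutation_posteriors=mut_df,
        transform=transform, eta=ep_result.eta,
        iterations=ep_result.iterations, final_delta=ep_result.final_delta,
        converged=ep_result.converged, n_projected=store.n_projected,
        n_skipped=store.n_skipped, n_updates=store.n_updates,
        ep_result=ep_result, phase_state=phase_state,
        fit_options={"max_iter": config.max_iter, "tol": config.tol,
                     "damping": config.damping})
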