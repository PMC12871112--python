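"""Coalescent simulation fixtures and brute-force posterior oracles.

Ancestry is simulated with :mod:`msprime` (Kingman coalescent, with or
without recombination), so simulated ARGs carry exact true node times;
mutations are then dropped by hand as a Poisson process over edge areas
so that every mutation's true age is recorded.  Truth tables ride along
with the :class:`SimulatedArg` and are written as extra TSVs.

Two independent oracles compute exact posterior moments on small ARGs
(used to validate the EP engine): vectorized rejection sampling and
nested adaptive quadrature over the node-age ordering polytope.  Both
target the same posterior as the EP engine — Poisson edge likelihoods,
an exponential prior with rate ``eta`` on ultimate roots and a flat
prior on other internal nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arg_tables import ArgTables, build_logical_edges
from .ep_engine import poisson_edge_loglik

__all__ = [
    "SimConfig", "SimulatedArg", "simulate_arg", "drop_mutations",
    "collapse_unsupported_branches", "rejection_posterior",
    "quadrature_posterior", "random_small_arg",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the bundled simulator.

    Defaults emulate a neutral human-like setting: 200 sample genomes
    over 1 Mb with per-generation per-base mutation and recombination
    rates of 1e-8 and a diploid effective population size of 1e4.
    """

    n_samples: int = 200          # haploid genomes (individuals if diploid)
    ploidy: int = 1
    sequence_length: float = 1e6
    population_size: float = 1e4
    recombination_rate: float = 1e-8
    mutation_rate: float = 1e-8
    seed: int = 1

    def __post_init__(self):
        if min(self.n_samples, self.sequence_length, self.population_size,
               self.mutation_rate) <= 0 or self.recombination_rate < 0:
            raise ValueError("SimConfig fields must be positive")


@dataclass(frozen=True)
class SimulatedArg:
    """A simulated ARG with truth tables for benchmarking."""

    tables: ArgTables
    true_node_times: np.ndarray
    truth_mutations: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def true_mutation_ages(self) -> np.ndarray:
        return self.truth_mutations["age"].to_numpy()


def simulate_arg(config: SimConfig) -> SimulatedArg:
    """Simulate a coalescent ARG (no mutations yet) with true times."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=config.n_samples,
        ploidy=config.ploidy,
        sequence_length=config.sequence_length,
        population_size=config.population_size,
        recombination_rate=config.recombination_rate,
        random_seed=(config.seed % (2**31 - 1)) + 1,
    )
    tables = ArgTables.from_tree_sequence(ts)
    return SimulatedArg(tables=tables,
                        true_node_times=tables.nodes["time"].to_numpy().copy())


def drop_mutations(sim: SimulatedArg, mu: float, seed: int) -> SimulatedArg:
    """Drop Poisson mutations on every edge segment using true times.

    Per segment the count is Poisson(mu * span * dt); positions are
    uniform on the segment and true ages uniform on (t_child, t_parent).
    """
    tables = sim.tables
    t = sim.true_node_times
    rng = np.random.default_rng(seed)
    edges = tables.edges
    left = edges["left"].to_numpy()
    right = edges["right"].to_numpy()
    parent = edges["parent"].to_numpy()
    child = edges["child"].to_numpy()
    dt = t[parent] - t[child]
    lam = mu * (right - left) * dt
    counts = rng.poisson(lam)
    pos_list, age_list, node_list = [], [], []
    for e in np.flatnonzero(counts):
        k = counts[e]
        pos_list.append(rng.uniform(left[e], right[e], size=k))
        age_list.append(rng.uniform(t[child[e]], t[parent[e]], size=k))
        node_list.append(np.full(k, child[e]))
    if pos_list:
        pos = np.concatenate(pos_list)
        age = np.concatenate(age_list)
        node = np.concatenate(node_list)
    else:
        pos = np.empty(0)
        age = np.empty(0)
        node = np.empty(0, dtype=np.int64)
    # infinite-sites: nudge the (measure-zero) duplicate positions
    while len(pos) != len(np.unique(pos)):  # pragma: no cover
        _, idx, cnt = np.unique(pos, return_index=True, return_counts=True)
        dup = idx[cnt > 1]
        pos[dup] += rng.uniform(0, 1e-6, size=len(dup))
    order = np.argsort(pos, kind="stable")
    pos, age, node = pos[order], age[order], node[order].astype(np.int64)
    k = len(pos)
    sites = pd.DataFrame({"id": np.arange(k), "position": pos,
                          "ancestral_state": ["0"] * k})
    muts = pd.DataFrame({"id": np.arange(k), "site": np.arange(k),
                         "node": node, "derived_state": ["1"] * k,
                         "unphased_individual": np.full(k, -1)})
    new_tables = ArgTables.from_frames(
        tables.nodes, tables.edges, sites, muts,
        sequence_length=tables.sequence_length)
    truth = pd.DataFrame({"id": np.arange(k), "site": np.arange(k),
                          "position": pos, "node": node, "age": age})
    return SimulatedArg(tables=new_tables, true_node_times=sim.true_node_times,
                        truth_mutations=truth)


def collapse_unsupported_branches(sim: SimulatedArg) -> SimulatedArg:
    """Contract, within every marginal tree, each branch that carries no
    mutation over that tree's interval (children re-attach to the
    grandparent), producing polytomies that mimic topology uncertainty.

    Node ids are preserved; nodes left without any edge simply drop out
    of the graph.  The mutation count is conserved exactly.
    """
    tables = sim.tables
    edges = tables.edges
    left = edges["left"].to_numpy()
    right = edges["right"].to_numpy()
    parent = edges["parent"].to_numpy()
    child = edges["child"].to_numpy()
    is_sample = tables.is_sample()
    mut_pos = tables.sites["position"].to_numpy()[
        tables.mutations["site"].to_numpy()] if len(tables.mutations) else \
        np.empty(0)
    mut_node = tables.mutations["node"].to_numpy()
    breaks = np.unique(np.concatenate([left, right]))
    new_edges: dict[tuple[int, int], list[list[float]]] = {}
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        active = (left <= lo) & (right >= hi)
        par_of = {int(c): int(p) for p, c in zip(parent[active],
                                                 child[active])}
        in_int = (mut_pos >= lo) & (mut_pos < hi)
        supported = set(mut_node[in_int].tolist())
        def kept(c: int) -> bool:
            return bool(is_sample[c]) or c in supported
        for c, p in par_of.items():
            if not kept(c):
                continue
            q = p
            while q in par_of and not kept(q):
                q = par_of[q]
            ivs = new_edges.setdefault((q, c), [])
            if ivs and ivs[-1][1] == lo:
                ivs[-1][1] = hi
            else:
                ivs.append([lo, hi])
    rows = [(iv[0], iv[1], p, c)
            for (p, c), ivs in sorted(new_edges.items()) for iv in ivs]
    edf = pd.DataFrame(rows, columns=["left", "right", "parent", "child"])
    new_tables = ArgTables.from_frames(tables.nodes, edf, tables.sites,
                                       tables.mutations,
                                       sequence_length=tables.sequence_length)
    return SimulatedArg(tables=new_tables,
                        true_node_times=sim.true_node_times,
                        truth_mutations=sim.truth_mutations)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def _oracle_structure(tables: ArgTables):
    ledges = build_logical_edges(tables)
    is_sample = tables.is_sample()
    internal = np.flatnonzero(~is_sample)
    rank = tables.topological_ranks()
    roots = set(tables.roots().tolist())
    parents_of: dict[int, list[int]] = {int(v): [] for v in internal}
    for e in ledges:
        if not is_sample[e.child]:
            parents_of[e.child].append(e.parent)
    # oldest first for proposal / integration nesting
    order = sorted(internal.tolist(), key=lambda v: (-rank[v], v))
    return ledges, internal, roots, parents_of, order


class OracleError(RuntimeError):
    pass


def rejection_posterior(tables: ArgTables, mu: float, eta: float,
                        n_accept: int = 100_000, seed: int = 1,
                        batch: int = 200_000,
                        max_batches: int = 2000) -> pd.DataFrame:
    """Exact posterior moments of internal node ages by rejection
    sampling (vectorized).

    Proposal: root ages ~ Exp(eta); every other internal node, visited
    oldest-first, uniform on (0, youngest proposed parent).  The
    acceptance weight is the Poisson edge likelihood times the uniform
    interval lengths (the proposal-density correction for the flat
    prior), capped by a pilot-estimated maximum.

    Returns a frame indexed by node id with columns mean, m2, se_mean,
    n_accepted.
    """
    from scipy.special import gammaln

    if (~tables.is_sample()).sum() > 6:
        raise OracleError("rejection oracle limited to <= 6 internal nodes")
    ledges, internal, roots, parents_of, order = _oracle_structure(tables)
    rng = np.random.default_rng(seed)
    col = {v: k for k, v in enumerate(order)}

    def propose(m):
        t = np.zeros((m, len(order)))
        logq_corr = np.zeros(m)  # log(prior/proposal) for non-roots
        for v in order:
            k = col[v]
            if v in roots:
                t[:, k] = rng.exponential(1.0 / eta, size=m)
            else:
                ub = np.min(np.stack([t[:, col[p]] for p in parents_of[v]],
                                     axis=1), axis=1)
                t[:, k] = rng.uniform(0.0, ub)
                logq_corr += np.log(ub)
        return t, logq_corr

    def log_lik(t):
        out = np.zeros(len(t))
        for e in ledges:
            ti = t[:, col[e.parent]]
            tj = (t[:, col[e.child]] if e.child in col
                  else np.zeros(len(t)))
            dt = ti - tj
            ms = mu * e.span
            with np.errstate(divide="ignore", invalid="ignore"):
                lp = np.where(dt > 0,
                              e.y * np.log(ms * np.maximum(dt, 1e-300))
                              - ms * dt - gammaln(e.y + 1.0),
                              -np.inf)
            out += lp
        return out

    # pilot for the acceptance cap
    t, corr = propose(min(batch, 100_000))
    logw = log_lik(t) + corr
    finite = logw[np.isfinite(logw)]
    if len(finite) == 0:
        raise OracleError("no finite-weight proposals in pilot")
    cap = float(np.max(finite))
    acc_t = []
    n_acc = 0
    n_prop = 0
    for _ in range(max_batches):
        t, corr = propose(batch)
        logw = log_lik(t) + corr
        n_prop += batch
        u = rng.uniform(size=batch)
        keep = np.log(u) < logw - cap  # weights above cap always accepted
        if keep.any():
            acc_t.append(t[keep])
            n_acc += int(keep.sum())
        if n_acc >= n_accept:
            break
        if n_prop >= 20 * batch and n_acc / n_prop < 1e-6:
            raise OracleError(
                "acceptance rate < 1e-6; shrink the instance")
    ts = np.concatenate(acc_t, axis=0)
    out = {}
    for v in order:
        x = ts[:, col[v]]
        out[v] = (x.mean(), np.mean(x**2), x.std(ddof=1) / np.sqrt(len(x)),
                  len(x))
    df = pd.DataFrame.from_dict(
        out, orient="index", columns=["mean", "m2", "se_mean", "n_accepted"])
    df.index.name = "node"
    return df.sort_index()


def quadrature_posterior(tables: ArgTables, mu: float,
                         eta: float) -> pd.DataFrame:
    """Exact posterior moments by nested adaptive quadrature over the
    ordering polytope (tractable for <= 3 internal nodes).

    Internally times are nondimensionalized by the root-prior scale
    1/eta so the integrator works with O(1) variables; moments are
    scaled back on return.
    """
    from scipy import integrate

    if (~tables.is_sample()).sum() > 3:
        raise OracleError("quadrature oracle limited to <= 3 internal nodes")
    scale = 1.0 / eta
    mu = mu * scale   # expected mutations per *scaled* generation
    eta = 1.0
    ledges, internal, roots, parents_of, order = _oracle_structure(tables)
    # nquad integrates x0 innermost; make x0 the youngest node
    nq_order = order[::-1]
    col = {v: k for k, v in enumerate(nq_order)}

    def log_post(t):
        lp = 0.0
        for e in ledges:
            ti = t[col[e.parent]]
            tj = t[col[e.child]] if e.child in col else 0.0
            lp += poisson_edge_loglik(e.y, ti - tj, mu * e.span)
        for r in roots:
            lp += -eta * t[col[r]]
        return lp

    # stabilizing shift from a coarse probe of the posterior
    rng = np.random.default_rng(0)
    shift = -np.inf
    for _ in range(2000):
        t = {}
        for v in order:
            if v in roots:
                t[v] = rng.exponential(2.0 / eta)
            else:
                t[v] = rng.uniform(0.0, min(t[p] for p in parents_of[v]))
        shift = max(shift, log_post([t[v] for v in nq_order]))

    def ranges(k):
        v = nq_order[k]
        if v in roots:
            return lambda *outer: (0.0, np.inf)

        def rng_fn(*outer):
            # outer = (x_{k+1}, ..., x_{n-1}) per scipy convention
            full = {}
            for kk in range(k + 1, len(nq_order)):
                full[kk] = outer[kk - (k + 1)]
            ub = min(full[col[p]] for p in parents_of[v])
            return (0.0, ub)
        return rng_fn

    def integrand_factory(weight_node=None, power=0):
        def f(*args):
            lp = log_post(list(args)) - shift
            w = args[col[weight_node]]**power if weight_node is not None \
                else 1.0
            return np.exp(lp) * w
        return f

    opts = {"epsabs": 0.0, "epsrel": 1e-9, "limit": 100}
    rlist = [ranges(k) for k in range(len(nq_order))]
    Z, _ = integrate.nquad(integrand_factory(), rlist, opts=opts)
    out = {}
    for v in order:
        m1, _ = integrate.nquad(integrand_factory(v, 1), rlist, opts=opts)
        m2, _ = integrate.nquad(integrand_factory(v, 2), rlist, opts=opts)
        out[v] = (m1 / Z * scale, m2 / Z * scale**2)
    df = pd.DataFrame.from_dict(out, orient="index", columns=["mean", "m2"])
    df.index.name = "node"
    return df.sort_index()


def random_small_arg(seed: int, max_internal: int = 4,
                     mu_scaled: float = 1.0) -> SimulatedArg:
    """A small random mutated ARG with at most ``max_internal`` internal
    nodes, for oracle cross-validation; returns ``(sim, mu)``.

    ``mu_scaled`` rescales the mutation rate so that edges carry O(1)
    mutations regardless of the coalescent timescale.
    """
    rng = np.random.default_rng(seed)
    for attempt in range(100):
        n = int(rng.integers(3, max_internal + 2))
        use_rec = bool(rng.integers(0, 2)) and n <= max_internal
        cfg = SimConfig(
            n_samples=n, sequence_length=1e4, population_size=1e4,
            recombination_rate=2e-8 if use_rec else 0.0,
            mutation_rate=1e-8, seed=int(seed * 100 + attempt + 1))
        sim = simulate_arg(cfg)
        n_internal = int((~sim.tables.is_sample()).sum())
        if not 2 <= n_internal <= max_internal:
            continue
        # scale mu so expected counts are O(1) per edge
        height = sim.true_node_times.max()
        mu = mu_scaled / (height * cfg.sequence_length)
        return drop_mutations(sim, mu, seed=int(seed * 7 + 3)), mu
    raise OracleError("could not draw a small ARG")
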