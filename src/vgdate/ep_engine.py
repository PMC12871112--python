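"""Expectation-propagation core for ARG node-age inference.

The model: each logical edge (parent ``i``, child ``j``, genomic span
``s``, mutation count ``y``) contributes a Poisson likelihood for ``y``
given the edge duration ``t_i - t_j`` with rate ``mu * s`` per
generation; ultimate roots carry an exponential prior with rate ``eta``;
all other internal nodes have an improper flat prior.  The joint
posterior over internal node ages is approximated by a product of Gamma
marginals, refined by expectation propagation:

1. remove one edge's factors from its two node marginals (the cavity);
2. multiply the cavity by the exact Poisson edge factor (the surrogate);
3. compute the surrogate's first two moments for each node in closed
   form (Gauss-hypergeometric ratios, see :mod:`vgdate.hypergeom`);
4. moment-match new Gamma marginals and store the factor differences.

Messages are stored in natural coordinates: a factor ``(a, b)`` has
density ``t**a * exp(-b*t)``, so a node's marginal is the elementwise
sum of its prior factor and all incident edge factors (an exact
bookkeeping identity maintained by every update).

One sweep traverses all logical edges from leaves to roots and back,
then refits the root prior rate by an EM step.  Convergence is declared
when the largest absolute change in any node's natural parameters falls
below ``tol``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .arg_tables import ArgTables, build_logical_edges, warn_if_internal_times
from .gamma import GammaParams, moments_to_canonical, moments_to_natural
from .hypergeom import SeriesNotConverged, _log_f_de, hyp_f_ratios, log_hyp2f1_pos

__all__ = [
    "EPConfig", "CavityParams", "MessageStore", "EPResult",
    "poisson_edge_loglik", "hyp_ratio", "surrogate_moments",
    "surrogate_moments_sample_child", "moments_to_natural",
    "init_store", "update_edge", "project_feasible", "root_em_update",
    "ep_sweep", "date", "constrain_times",
]

# status codes returned by update_edge
OK, PROJECTED, SKIPPED = 0, 1, 2


@dataclass
class EPConfig:
    """Tuning knobs for the EP engine.

    ``mutation_rate`` is per base pair per generation.  ``root_prior``
    is ``"em"`` (exponential root prior with rate refit each sweep) or
    ``"fixed"`` (rate pinned at ``eta``).  ``damping`` in (0, 1] scales
    factor steps; 1 means undamped.
    """

    mutation_rate: float
    max_iter: int = 25
    tol: float = 1e-6
    damping: float = 1.0
    root_prior: str = "em"
    eta: float | None = None
    alpha_min: float = 1e-3
    beta_min: float = 1e-12
    seed: int | None = None

    def __post_init__(self):
        if not self.mutation_rate > 0:
            raise ValueError("mutation_rate must be positive")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")
        if self.root_prior not in ("em", "fixed"):
            raise ValueError("root_prior must be 'em' or 'fixed'")
        if self.root_prior == "fixed" and not (self.eta and self.eta > 0):
            raise ValueError("fixed root prior requires eta > 0")


@dataclass(frozen=True)
class CavityParams:
    """Cavity Gamma parameters for one edge (tilde-ed shapes/rates)."""

    shape_parent: float
    rate_parent: float
    shape_child: float
    rate_child: float


def poisson_edge_loglik(y: float, dt: float, mu_s: float) -> float:
    """Log Poisson probability of ``y`` mutations on an edge of duration
    ``dt`` generations with ``mu_s`` expected mutations per generation.

    Total on the reals: returns −inf when the ordering constraint
    ``dt > 0`` is violated.
    """
    if dt <= 0.0:
        return -math.inf
    return y * math.log(mu_s * dt) - mu_s * dt - float(gammaln(y + 1.0))


def _hyp_args(cavity: CavityParams, y: float, mu_s: float):
    ai, bi = cavity.shape_parent, cavity.rate_parent
    aj, bj = cavity.shape_child, cavity.rate_child
    T = ai + aj + y
    d = mu_s + bi
    z = (mu_s - bj) / d
    return aj, T, d, z


def hyp_ratio(n: int, cavity: CavityParams, y: float, mu_s: float) -> float:
    """The ratio ``F_n / F_0`` of Gauss hypergeometric values entering
    the surrogate moments; ``n`` is 1 or 2."""
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    aj, T, _, z = _hyp_args(cavity, y, mu_s)
    try:
        lf0 = log_hyp2f1_pos(aj, T, aj + y + 1.0, z)
        lfn = log_hyp2f1_pos(aj + n, T + n, aj + y + n + 1.0, z)
    except SeriesNotConverged:
        lf0 = _log_f_de(aj, y, T, z, 0)
        lfn = _log_f_de(aj, y, T, z, n)
    return float(np.exp(lfn - lf0))


def surrogate_moments(cavity: CavityParams, y: float, mu_s: float
                      ) -> tuple[float, float, float, float]:
    """First two moments ``(E[ti], E[ti^2], E[tj], E[tj^2])`` of the
    surrogate density for an edge with an internal (non-sample) child."""
    ai, bi = cavity.shape_parent, cavity.rate_parent
    aj, T, d, z = _hyp_args(cavity, y, mu_s)
    if not (aj > 0 and T > 0 and d > 0 and bi + cavity.rate_child > 0):
        raise FloatingPointError("infeasible cavity for surrogate moments")
    r1, r2 = hyp_f_ratios(aj, y, T, z)
    Etj = aj * T / (d * (aj + y + 1.0)) * r1
    Etj2 = (aj * (aj + 1.0) * T * (T + 1.0)
            / (d * d * (aj + y + 1.0) * (aj + y + 2.0)) * r2)
    Eti = Etj * z + T / d
    Eti2 = Etj2 * z * z + (T + 1.0) / d * (2.0 * Eti - T / d)
    return Eti, Eti2, Etj, Etj2


def surrogate_moments_sample_child(shape_parent: float, rate_parent: float,
                                   y: float, mu_s: float
                                   ) -> tuple[float, float]:
    """Moments of the parent age when the child is a contemporary sample
    (age zero): the surrogate is then Gamma(ai + y, mu_s + bi) exactly."""
    a = shape_parent + y
    b = mu_s + rate_parent
    if not (a > 0 and b > 0):
        raise FloatingPointError("infeasible cavity for sample-child moments")
    return a / b, a * (a + 1.0) / (b * b)


# ---------------------------------------------------------------------------
# message store
# ---------------------------------------------------------------------------

@dataclass
class MessageStore:
    """Per-node prior factors, per-edge factors and posterior
    accumulators, in natural ``(a, b)`` coordinates, plus the static
    logical-edge arrays the sweep iterates over.

    Invariant (asserted in tests): ``post[i] == prior[i] + sum of
    fac_parent over edges with parent i + sum of fac_child over edges
    with child i`` after every update.
    """

    # edges
    parent: np.ndarray
    child: np.ndarray
    span: np.ndarray
    y: np.ndarray
    mu_s: np.ndarray
    child_is_sample: np.ndarray
    order: np.ndarray          # sweep order, leaves-to-roots
    # factors
    prior: np.ndarray          # (n_nodes, 2)
    fac_parent: np.ndarray     # (n_edges, 2)
    fac_child: np.ndarray      # (n_edges, 2)
    post: np.ndarray           # (n_nodes, 2)
    # node classification
    internal: np.ndarray       # bool mask
    root_nodes: np.ndarray
    eta: float
    # adaptive damping state
    damp: np.ndarray = field(default=None)
    proj_streak: np.ndarray = field(default=None)
    n_projected: int = 0
    n_skipped: int = 0
    n_updates: int = 0

    def posterior(self, node: int) -> GammaParams:
        a, b = self.post[node]
        return GammaParams(shape=a + 1.0, rate=b)

    def check_bookkeeping(self, atol: float = 1e-8) -> bool:
        acc = self.prior.copy()
        np.add.at(acc, self.parent, self.fac_parent)
        np.add.at(acc, self.child, self.fac_child)
        return bool(np.allclose(acc[self.internal], self.post[self.internal],
                                atol=atol, rtol=1e-10))


def _default_eta(y_total: float, area_bp: float, mu: float) -> float:
    # 1 / T-hat with T-hat a crude tree-height scale from total mutational
    # density; falls back to the pure-span scale when there are no mutations
    if y_total > 0:
        return mu * area_bp / y_total
    return mu * max(area_bp, 1.0)


def init_store(tables: ArgTables, config: EPConfig,
               logical_edges=None) -> MessageStore:
    if logical_edges is None:
        logical_edges = build_logical_edges(tables)
    n = tables.num_nodes
    parent = np.array([e.parent for e in logical_edges], dtype=np.int64)
    child = np.array([e.child for e in logical_edges], dtype=np.int64)
    span = np.array([e.span for e in logical_edges], dtype=float)
    y = np.array([e.y for e in logical_edges], dtype=float)
    mu_s = config.mutation_rate * span
    is_sample = tables.is_sample()
    rank = tables.topological_ranks()
    order = np.lexsort((parent, child, rank[parent], rank[child]))
    roots = tables.roots()
    if config.eta is not None:
        eta = float(config.eta)
    else:
        eta = _default_eta(float(y.sum()), float(span.sum()),
                           config.mutation_rate)
    prior = np.zeros((n, 2))
    prior[roots, 1] = eta
    ne = len(logical_edges)
    store = MessageStore(
        parent=parent, child=child, span=span, y=y, mu_s=mu_s,
        child_is_sample=is_sample[child], order=order,
        prior=prior, fac_parent=np.zeros((ne, 2)),
        fac_child=np.zeros((ne, 2)), post=prior.copy(),
        internal=~is_sample, root_nodes=roots, eta=eta,
        damp=np.full(ne, config.damping), proj_streak=np.zeros(ne, np.int64))
    return store


def project_feasible(step: np.ndarray, current_post: np.ndarray,
                     alpha_min: float = 1e-3, beta_min: float = 1e-12
                     ) -> float:
    """Largest step fraction lambda in [0, 1] such that
    ``current_post + lambda * step`` keeps the posterior normalizable
    with shape >= alpha_min and rate >= beta_min.

    ``current_post`` and ``step`` are ``(a, b)`` natural pairs (or
    stacks of them for a multi-node update).
    """
    cur = np.atleast_2d(current_post)
    stp = np.atleast_2d(step)
    bounds = np.array([alpha_min - 1.0, beta_min])  # on (a, b)
    lam = 1.0
    for k in (0, 1):
        for c, s in zip(cur[:, k], stp[:, k]):
            if s < 0.0:
                limit = (bounds[k] - c) / s
                if limit < lam:
                    lam = max(limit, 0.0)
    return lam


def _match_and_propose(m1: float, m2: float, cavity_nat: np.ndarray,
                       old_fac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    shape, rate = moments_to_canonical(m1, m2)
    target = np.array([shape - 1.0, rate])
    proposed = target - cavity_nat
    return proposed, proposed - old_fac


def update_edge(store: MessageStore, e: int, config: EPConfig) -> int:
    """One EP refinement of logical edge ``e`` (in place).

    Returns OK, PROJECTED (step shortened to stay feasible) or SKIPPED
    (infeasible cavity or degenerate moments; factors untouched).
    """
    i = store.parent[e]
    j = store.child[e]
    y = store.y[e]
    mu_s = store.mu_s[e]
    store.n_updates += 1
    cav_i = store.post[i] - store.fac_parent[e]
    d = store.damp[e]
    try:
        if store.child_is_sample[e]:
            m1, m2 = surrogate_moments_sample_child(cav_i[0] + 1.0, cav_i[1],
                                                    y, mu_s)
            _, step_i = _match_and_propose(m1, m2, cav_i, store.fac_parent[e])
            step = d * step_i[None, :]
            lam = project_feasible(step, store.post[i][None, :],
                                   config.alpha_min, config.beta_min)
            if lam <= 0.0:
                return _mark(store, e, SKIPPED)
            store.fac_parent[e] += lam * step[0]
            store.post[i] = cav_i + store.fac_parent[e]
            return _mark(store, e, OK if lam == 1.0 else PROJECTED)
        cav_j = store.post[j] - store.fac_child[e]
        cavity = CavityParams(cav_i[0] + 1.0, cav_i[1],
                              cav_j[0] + 1.0, cav_j[1])
        Eti, Eti2, Etj, Etj2 = surrogate_moments(cavity, y, mu_s)
        if not (Eti > Etj > 0.0 and np.isfinite(Eti2) and np.isfinite(Etj2)):
            return _mark(store, e, SKIPPED)
        _, step_i = _match_and_propose(Eti, Eti2, cav_i, store.fac_parent[e])
        _, step_j = _match_and_propose(Etj, Etj2, cav_j, store.fac_child[e])
        step = d * np.vstack([step_i, step_j])
        lam = project_feasible(step, np.vstack([store.post[i], store.post[j]]),
                               config.alpha_min, config.beta_min)
        if lam <= 0.0:
            return _mark(store, e, SKIPPED)
        store.fac_parent[e] += lam * step[0]
        store.fac_child[e] += lam * step[1]
        store.post[i] = cav_i + store.fac_parent[e]
        store.post[j] = cav_j + store.fac_child[e]
        return _mark(store, e, OK if lam == 1.0 else PROJECTED)
    except (FloatingPointError, ValueError, ZeroDivisionError,
            OverflowError):
        return _mark(store, e, SKIPPED)


def _mark(store: MessageStore, e: int, status: int) -> int:
    if status == OK:
        store.proj_streak[e] = 0
    else:
        if status == PROJECTED:
            store.n_projected += 1
        else:
            store.n_skipped += 1
        store.proj_streak[e] += 1
        # safety valve: halve per-edge damping after two consecutive
        # projected/skipped updates
        if store.proj_streak[e] >= 2:
            store.damp[e] = max(store.damp[e] * 0.5, 1.0 / 64.0)
            store.proj_streak[e] = 0
    return status


def root_em_update(store: MessageStore, eta: float | None = None) -> float:
    """EM refit of the exponential root-prior rate.

    The update is ``eta' = (sum_r 1) / (sum_r alpha_r / beta_r)`` over
    ultimate roots ``r`` — the reciprocal mean of the current root-age
    posterior means — after which the root prior factors and posteriors
    are shifted to the new rate.  If any root posterior is degenerate
    the current rate is kept.
    """
    if eta is None:
        eta = store.eta
    roots = store.root_nodes
    if len(roots) == 0:
        return eta
    a = store.post[roots, 0] + 1.0
    b = store.post[roots, 1]
    if not ((a > 0).all() and (b > 0).all()):
        return eta
    denom = float(np.sum(a / b))
    if not denom > 0:
        return eta
    eta_new = len(roots) / denom
    store.prior[roots, 1] = eta_new
    store.post[roots, 1] += eta_new - eta
    store.eta = eta_new
    return eta_new


def ep_sweep(store: MessageStore, config: EPConfig) -> float:
    """One leaves-to-roots then roots-to-leaves pass over all logical
    edges, followed by the root-prior EM step (if enabled).  Returns the
    maximum absolute change in any node's natural parameters."""
    before = store.post.copy()
    for e in store.order:
        update_edge(store, e, config)
    for e in store.order[::-1]:
        update_edge(store, e, config)
    if config.root_prior == "em":
        root_em_update(store)
    delta = np.abs(store.post - before)[store.internal]
    return float(delta.max()) if delta.size else 0.0


@dataclass
class EPResult:
    """Raw EP output: per-node Gamma posteriors in EP time."""

    store: MessageStore
    iterations: int
    final_delta: float
    converged: bool
    eta: float
    node_shape: np.ndarray
    node_rate: np.ndarray
    internal: np.ndarray

    @property
    def node_mean(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            m = self.node_shape / self.node_rate
        m[~self.internal] = 0.0
        return m

    @property
    def node_variance(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            v = self.node_shape / self.node_rate**2
        v[~self.internal] = 0.0
        return v


def date(tables: ArgTables, config: EPConfig,
         store: MessageStore | None = None,
         phase_state=None) -> EPResult:
    """Run EP to convergence on the given ARG tables.

    ``phase_state`` (from :mod:`vgdate.singletons`) carries fractional
    singleton placements; its responsibilities are refreshed after every
    sweep so phase uncertainty propagates into the posteriors.
    """
    warn_if_internal_times(tables)
    if store is None:
        store = init_store(tables, config)
    delta = math.inf
    it = 0
    for it in range(1, config.max_iter + 1):
        delta = ep_sweep(store, config)
        if phase_state is not None:
            phase_state.update_responsibilities(store)
        if delta < config.tol:
            break
    n = tables.num_nodes
    shape = store.post[:, 0] + 1.0
    rate = store.post[:, 1].copy()
    internal = store.internal
    return EPResult(store=store, iterations=it, final_delta=delta,
                    converged=bool(delta < config.tol), eta=store.eta,
                    node_shape=np.where(internal, shape, np.nan),
                    node_rate=np.where(internal, rate, np.nan),
                    internal=internal)


def constrain_times(tables: ArgTables, node_mean: np.ndarray,
                    eps: float = 1e-9) -> np.ndarray:
    """Point times satisfying child < parent everywhere.

    Posterior means are topologically unconstrained; for output tables
    (and tskit round-trips) each node is lifted, leaves-to-roots, to at
    least ``eps`` above its oldest child.
    """
    rank = tables.topological_ranks()
    ct = np.array(node_mean, dtype=float)
    ct[tables.is_sample()] = 0.0
    parent = tables.edges["parent"].to_numpy()
    child = tables.edges["child"].to_numpy()
    pairs = sorted({(int(p), int(c)) for p, c in zip(parent, child)},
                   key=lambda pc: (rank[pc[0]], pc[0]))
    for p, c in pairs:
        if ct[p] < ct[c] + eps:
            ct[p] = ct[c] + eps
    return ct
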