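"""Molecular-clock timescale calibration.

EP node-age posteriors are internally consistent but their overall
timescale can drift, and topology uncertainty encoded as polytomies
biases total edge area relative to mutational density.  Calibration
finds a piecewise-linear, strictly monotone map ``g`` from EP time to
generations such that, within each of a set of time intervals, mutation
counts match the molecular-clock expectation ``mu * interval length``.

Two matching modes are provided:

* **path rescaling** (default) matches the *average mutation count per
  sample* against the per-sample root-to-leaf opportunity — every
  mutation and every unit of edge area is weighted by the fraction of
  samples that inherit it.  This quantity is insensitive to spurious
  polytomies.
* **area rescaling** matches *total* mutation counts against total edge
  area, the convention used by MCMC-based ARG daters; it is biased when
  unsupported branches have been collapsed into polytomies.

Posteriors are moved through ``g`` by transforming a lower and an upper
quantile and refitting the Gamma that matches the transformed pair
(a vectorized bisection on the shape, then one rate solve).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .arg_tables import ArgTables
from .ep_engine import constrain_times
from .gamma import GammaParams

__all__ = ["TimeTransform", "fit_path_rescaling", "fit_area_rescaling",
           "apply_transform_to_posterior", "transform_gamma_arrays",
           "edge_carrier_weights"]

DEFAULT_Q_LO = 0.025
DEFAULT_Q_HI = 0.975


@dataclass(frozen=True)
class TimeTransform:
    """Continuous piecewise-linear monotone map with ``g(0) = 0``.

    ``breakpoints[0] == 0``; ``slopes[k]`` applies on
    ``[breakpoints[k], breakpoints[k+1])`` and the last slope extends to
    infinity.
    """

    breakpoints: np.ndarray
    slopes: np.ndarray

    def __post_init__(self):
        bk = np.asarray(self.breakpoints, dtype=float)
        sl = np.asarray(self.slopes, dtype=float)
        if bk[0] != 0.0 or (np.diff(bk) <= 0).any():
            raise ValueError("breakpoints must start at 0 and increase")
        if len(sl) != len(bk) or not (np.isfinite(sl) & (sl > 0)).all():
            raise ValueError("need one positive finite slope per interval")
        object.__setattr__(self, "breakpoints", bk)
        object.__setattr__(self, "slopes", sl)

    @classmethod
    def identity(cls) -> "TimeTransform":
        return cls(np.array([0.0]), np.array([1.0]))

    @cached_property
    def _values(self) -> np.ndarray:
        widths = np.diff(self.breakpoints)
        return np.concatenate([[0.0],
                               np.cumsum(self.slopes[:-1] * widths)])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.breakpoints, t, side="right") - 1,
                      0, len(self.slopes) - 1)
        out = self._values[idx] + self.slopes[idx] * (t - self.breakpoints[idx])
        return out if out.ndim else float(out)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        idx = np.clip(np.searchsorted(self._values, y, side="right") - 1,
                      0, len(self.slopes) - 1)
        out = self.breakpoints[idx] + (y - self._values[idx]) / self.slopes[idx]
        return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# carrier counts from marginal trees
# ---------------------------------------------------------------------------

def edge_carrier_weights(tables: ArgTables, node_times: np.ndarray):
    """Span-and-carrier totals per logical edge and carrier counts per
    mutation, from a single pass over marginal trees.

    Returns ``(weights, spans, mut_carriers)`` where ``weights`` maps
    (parent, child) to ``sum over segments of span * samples below`` and
    ``spans`` to plain span totals.  ``node_times`` must already satisfy
    the ordering constraint (see ``constrain_times``).
    """
    ts = tables.to_tree_sequence(node_times)
    weights: dict[tuple[int, int], float] = {}
    spans: dict[tuple[int, int], float] = {}
    mut_carriers = np.zeros(len(tables.mutations), dtype=np.int64)
    # map back from tskit's (sorted) site order to input mutation ids
    for tree in ts.trees():
        span = tree.span
        for u in tree.postorder():
            p = tree.parent(u)
            if p == -1:
                continue
            key = (int(p), int(u))
            ns = tree.num_samples(u)
            weights[key] = weights.get(key, 0.0) + span * ns
            spans[key] = spans.get(key, 0.0) + span
        for site in tree.sites():
            for mut in site.mutations:
                mut_carriers[mut.id] = tree.num_samples(mut.node)
    # tskit preserved our mutation order (tables were pre-sorted by site)
    return weights, spans, mut_carriers


# ---------------------------------------------------------------------------
# rescaling fits
# ---------------------------------------------------------------------------

def _interval_overlap(lo, hi, grid):
    """Overlap lengths of [lo, hi] with each cell of ``grid`` (the last
    cell extends to infinity); vectorized over (lo, hi) pairs."""
    lo = np.asarray(lo)[:, None]
    hi = np.asarray(hi)[:, None]
    starts = grid[None, :]
    ends = np.concatenate([grid[1:], [np.inf]])[None, :]
    return np.clip(np.minimum(hi, ends) - np.maximum(lo, starts), 0.0, None)


def _fit_rescaling(tables: ArgTables, node_means, mutation_means, mu,
                   n_intervals, weight_by_carriers: bool) -> TimeTransform:
    node_means = np.asarray(node_means, dtype=float)
    mutation_means = np.asarray(mutation_means, dtype=float)
    if len(mutation_means) == 0:
        return TimeTransform.identity()
    ct = constrain_times(tables, node_means)
    weights, spans, mut_carriers = edge_carrier_weights(tables, ct)
    n = tables.num_samples

    # time grid from equally spaced quantiles of mutation ages
    qs = np.quantile(mutation_means, np.linspace(0, 1, n_intervals + 1))
    grid = np.unique(np.concatenate([[0.0], qs[1:-1]]))
    k = len(grid)

    # expected mutational opportunity per interval (edge areas)
    pairs = sorted(spans)
    p_mean = node_means[[p for p, _ in pairs]]
    c_mean = np.array([0.0 if tables.is_sample()[c] else node_means[c]
                       for _, c in pairs])
    ok = p_mean > c_mean
    if weight_by_carriers:
        w = np.array([weights[k_] for k_ in pairs]) / n
    else:
        w = np.array([spans[k_] for k_ in pairs])
    per_unit_time = np.where(ok, w, 0.0)[:, None]
    expected = (per_unit_time
                * _interval_overlap(np.where(ok, c_mean, 0.0),
                                    np.where(ok, p_mean, 0.0), grid)
                ).sum(axis=0) * mu

    # observed mutation mass per interval, uniform over each edge extent
    edge_row = tables.assign_mutations_to_edges()
    mc = tables.mutations
    phased = mc["unphased_individual"].to_numpy() == -1 if len(mc) else \
        np.empty(0, bool)
    use = phased & (edge_row >= 0)
    mp = tables.edges["parent"].to_numpy()[edge_row[use]]
    mchild = tables.edges["child"].to_numpy()[edge_row[use]]
    lo = np.where(tables.is_sample()[mchild], 0.0, node_means[mchild])
    hi = node_means[mp]
    width = np.maximum(hi - lo, 1e-300)
    frac = _interval_overlap(np.minimum(lo, hi), np.maximum(lo, hi), grid) \
        / width[:, None]
    mw = (mut_carriers[use] / n) if weight_by_carriers \
        else np.ones(int(use.sum()))
    observed = (mw[:, None] * frac).sum(axis=0)

    # slopes, merging intervals without signal into their successor
    bks, sls = [0.0], []
    acc_obs = acc_exp = 0.0
    for kk in range(k):
        acc_obs += observed[kk]
        acc_exp += expected[kk]
        is_last = kk == k - 1
        if acc_obs > 0 and acc_exp > 0 and not is_last:
            sls.append(acc_obs / acc_exp)
            bks.append(grid[kk + 1])
            acc_obs = acc_exp = 0.0
        elif is_last:
            if acc_obs > 0 and acc_exp > 0:
                sls.append(acc_obs / acc_exp)
            elif sls:
                bks.pop()  # fold the empty tail into the previous slope
            else:
                sls.append(1.0)
    return TimeTransform(np.array(bks), np.array(sls))


def fit_path_rescaling(tables: ArgTables, node_means, mutation_means,
                       mu: float, n_intervals: int = 100) -> TimeTransform:
    """Clock calibration matching the average per-sample mutation count
    (mutations and edge areas weighted by carrier fraction)."""
    return _fit_rescaling(tables, node_means, mutation_means, mu,
                          n_intervals, weight_by_carriers=True)


def fit_area_rescaling(tables: ArgTables, node_means, mutation_means,
                       mu: float, n_intervals: int = 100) -> TimeTransform:
    """Clock calibration matching total mutation counts to total edge
    area (biased in the presence of spurious polytomies)."""
    return _fit_rescaling(tables, node_means, mutation_means, mu,
                          n_intervals, weight_by_carriers=False)


# ---------------------------------------------------------------------------
# posterior transformation by quantile matching
# ---------------------------------------------------------------------------

def transform_gamma_arrays(g: TimeTransform, shapes, rates,
                           q_lo: float = DEFAULT_Q_LO,
                           q_hi: float = DEFAULT_Q_HI):
    """Vectorized quantile-matching transform of Gamma posteriors.

    Maps the ``q_lo`` and ``q_hi`` quantiles through ``g`` and returns
    the (shape, rate) arrays of the Gammas reproducing the transformed
    pair.  Entries with non-finite parameters pass through unchanged.
    """
    from scipy.special import gammaincinv

    shapes = np.atleast_1d(np.asarray(shapes, dtype=float))
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    out_shape = shapes.copy()
    out_rate = rates.copy()
    ok = np.isfinite(shapes) & np.isfinite(rates) & (shapes > 0) & (rates > 0)
    if not ok.any():
        return out_shape, out_rate
    a = shapes[ok]
    x_lo = gammaincinv(a, q_lo) / rates[ok]
    x_hi = gammaincinv(a, q_hi) / rates[ok]
    y_lo = np.asarray(g(x_lo))
    y_hi = np.asarray(g(x_hi))
    target = y_hi / y_lo
    # R(shape) = Q(q_hi; shape) / Q(q_lo; shape) is strictly decreasing;
    # bisection on log-shape, then the rate follows from the upper quantile
    lo = np.full(a.shape, -30.0)
    hi = np.full(a.shape, 30.0)
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        am = np.exp(mid)
        q_lo_v = gammaincinv(am, q_lo)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = gammaincinv(am, q_hi) / q_lo_v
        # tiny trial shapes underflow the lower quantile to 0: the true
        # ratio there is huge, so steer towards larger shapes
        r = np.where(q_lo_v > 0, r, np.inf)
        bigger = r > target  # ratio too large -> need larger shape
        lo = np.where(bigger, mid, lo)
        hi = np.where(bigger, hi, mid)
    new_shape = np.exp(0.5 * (lo + hi))
    new_rate = gammaincinv(new_shape, q_hi) / y_hi
    out_shape[ok] = new_shape
    out_rate[ok] = new_rate
    return out_shape, out_rate


def apply_transform_to_posterior(g: TimeTransform, post: GammaParams,
                                 q_lo: float = DEFAULT_Q_LO,
                                 q_hi: float = DEFAULT_Q_HI) -> GammaParams:
    """Transform one Gamma posterior through ``g`` by quantile matching.

    Falls back to a moment transform through the local slope if the
    quantile solve fails to reproduce the transformed pair.
    """
    s, r = transform_gamma_arrays(g, [post.shape], [post.rate], q_lo, q_hi)
    cand = GammaParams(shape=float(s[0]), rate=float(r[0]))
    if cand.is_proper:
        lo_t, hi_t = g(post.quantile(q_lo)), g(post.quantile(q_hi))
        if (abs(cand.quantile(q_lo) - lo_t) <= 1e-9 * max(1.0, lo_t)
                and abs(cand.quantile(q_hi) - hi_t) <= 1e-9 * max(1.0, hi_t)):
            return cand
    # moment fallback: scale by the local slope at the mean
    import warnings

    warnings.warn("quantile matching failed; falling back to moment "
                  "transform")
    m = post.mean
    slope = (g(m * 1.001) - g(m * 0.999)) / (0.002 * m) if m > 0 else 1.0
    return GammaParams(shape=post.shape, rate=post.rate / slope)
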