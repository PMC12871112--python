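"""Dating singleton mutations whose phase within a diploid is unknown.

A singleton (derived allele count 1) observed in a diploid individual
could sit on either of the individual's two haplotypes, i.e. on either
of the two terminal edges above its two sample nodes at that position.
Three strategies are provided:

* ``phase_shortest_edge`` — deterministic heuristic: put the mutation
  on the candidate edge with the smaller genomic span (the longer-lived
  parent haplotype is the likelier carrier of a mutation at any base);
* phase-agnostic EP (``date_phase_agnostic``) — each unphased singleton
  contributes fractional mutation counts ``(w, 1-w)`` to its two
  candidate edges, and after every EP sweep ``w`` is refreshed to the
  posterior probability of the first phase given the current parent-age
  cavities (a ratio of marginal Poisson evidences); phase uncertainty
  thus propagates into all posteriors;
* random assignment (a worst-case baseline for benchmarking).

``split_terminal_edges`` pre-processes the edge table so that each
individual has at most two immediate ancestors over the span of every
attached edge, making the two candidate edges well defined everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arg_tables import MISSING, ArgTables
from .ep_engine import EPConfig, EPResult, date, init_store

__all__ = ["UnphasedSingleton", "split_terminal_edges", "phase_shortest_edge",
           "find_unphased_singletons", "PhaseState", "date_phase_agnostic"]


@dataclass
class UnphasedSingleton:
    """One unphased singleton and its two candidate terminal edges."""

    mutation_id: int
    position: float
    individual: int
    node_a: int          # sample node of candidate edge a
    node_b: int
    parent_a: int
    parent_b: int
    span_a: float        # logical-edge spans
    span_b: float
    phase_prob: float = 0.5   # probability the mutation lies on edge a


def split_terminal_edges(tables: ArgTables) -> ArgTables:
    """Subdivide terminal edges at every position where either haplotype
    of the owning individual changes parent.

    Spans and mutation placements are conserved exactly; logical edges
    are unchanged (the split only refines the segment structure).
    """
    edges = tables.edges
    is_sample = tables.is_sample()
    individual = tables.nodes["individual"].to_numpy()
    child = edges["child"].to_numpy()
    terminal = is_sample[child]
    rows = []
    # collect split points per individual from all of its terminal edges
    cuts: dict[int, np.ndarray] = {}
    for ind in np.unique(individual[individual >= 0]):
        own = terminal & (individual[child] == ind)
        pts = np.unique(np.concatenate([
            edges["left"].to_numpy()[own], edges["right"].to_numpy()[own]]))
        cuts[int(ind)] = pts
    for _, e in edges.iterrows():
        c = int(e["child"])
        ind = int(individual[c]) if is_sample[c] else MISSING
        if ind < 0 or ind not in cuts:
            rows.append((e["left"], e["right"], int(e["parent"]), c))
            continue
        pts = cuts[ind]
        inner = pts[(pts > e["left"]) & (pts < e["right"])]
        bounds = np.concatenate([[e["left"]], inner, [e["right"]]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            rows.append((lo, hi, int(e["parent"]), c))
    edf = pd.DataFrame(rows, columns=["left", "right", "parent", "child"])
    return ArgTables.from_frames(tables.nodes, edf, tables.sites,
                                 tables.mutations,
                                 sequence_length=tables.sequence_length)


def find_unphased_singletons(tables: ArgTables) -> list[UnphasedSingleton]:
    """Locate candidate edges for every mutation flagged unphased."""
    muts = tables.mutations
    unph = muts["unphased_individual"].to_numpy() != MISSING
    out = []
    if not unph.any():
        return out
    individual = tables.nodes["individual"].to_numpy()
    is_sample = tables.is_sample()
    edges = tables.edges
    left = edges["left"].to_numpy()
    right = edges["right"].to_numpy()
    parent = edges["parent"].to_numpy()
    child = edges["child"].to_numpy()
    # logical spans per (parent, child)
    span_of: dict[tuple[int, int], float] = {}
    for p, c, lo, hi in zip(parent, child, left, right):
        span_of[(int(p), int(c))] = span_of.get((int(p), int(c)), 0.0) \
            + float(hi - lo)
    positions = tables.sites["position"].to_numpy()
    for m in np.flatnonzero(unph):
        ind = int(muts["unphased_individual"].iat[m])
        samples = np.flatnonzero((individual == ind) & is_sample)
        if len(samples) != 2:
            raise ValueError(
                f"unphased singleton {int(muts['id'].iat[m])}: individual "
                f"{ind} must have exactly two sample nodes, found "
                f"{len(samples)}")
        pos = float(positions[int(muts["site"].iat[m])])
        pars = []
        for u in samples:
            cover = (child == u) & (left <= pos) & (pos < right)
            if not cover.any():
                raise ValueError(
                    f"sample {u} not covered at position {pos}")
            pars.append(int(parent[np.flatnonzero(cover)[0]]))
        a, b = int(samples[0]), int(samples[1])
        sl = UnphasedSingleton(
            mutation_id=int(muts["id"].iat[m]), position=pos, individual=ind,
            node_a=a, node_b=b, parent_a=pars[0], parent_b=pars[1],
            span_a=span_of[(pars[0], a)], span_b=span_of[(pars[1], b)])
        # shortest-edge-favoring initial responsibility
        sl.phase_prob = sl.span_b / (sl.span_a + sl.span_b) \
            if sl.span_a + sl.span_b > 0 else 0.5
        out.append(sl)
    return out


def phase_shortest_edge(tables: ArgTables,
                        singleton: UnphasedSingleton) -> pd.Series:
    """Phase one singleton onto the candidate edge with smaller span
    (ties broken towards the lower sample node id); returns the phased
    mutation row."""
    if (singleton.span_a < singleton.span_b
            or (singleton.span_a == singleton.span_b
                and singleton.node_a <= singleton.node_b)):
        node = singleton.node_a
    else:
        node = singleton.node_b
    row = tables.mutations.loc[
        tables.mutations["id"] == singleton.mutation_id].iloc[0].copy()
    row["node"] = node
    row["unphased_individual"] = MISSING
    return row


def _phase_all(tables: ArgTables, chooser) -> ArgTables:
    """Rewrite all unphased rows with a per-singleton node chooser."""
    singles = find_unphased_singletons(tables)
    muts = tables.mutations.copy()
    for s in singles:
        node = chooser(s)
        muts.loc[muts["id"] == s.mutation_id, "node"] = node
        muts.loc[muts["id"] == s.mutation_id, "unphased_individual"] = MISSING
    return ArgTables.from_frames(tables.nodes, tables.edges, tables.sites,
                                 muts, sequence_length=tables.sequence_length)


def phase_all_shortest_edge(tables: ArgTables) -> ArgTables:
    def choose(s: UnphasedSingleton) -> int:
        if (s.span_a < s.span_b
                or (s.span_a == s.span_b and s.node_a <= s.node_b)):
            return s.node_a
        return s.node_b
    return _phase_all(tables, choose)


def phase_all_random(tables: ArgTables, seed: int) -> ArgTables:
    rng = np.random.default_rng(seed)
    return _phase_all(
        tables, lambda s: s.node_a if rng.uniform() < 0.5 else s.node_b)


class PhaseState:
    """Fractional singleton placements threaded through the EP sweeps.

    Each singleton adds responsibility ``w`` to candidate edge a and
    ``1-w`` to edge b (so counts are conserved exactly).  After each
    sweep ``w`` is set to the posterior probability of phase a: the
    ratio of marginal Poisson evidences with the singleton moved to a
    vs b, all other counts held fixed, computed under the parents'
    current cavity Gammas.
    """

    def __init__(self, singletons: list[UnphasedSingleton],
                 edge_index: dict[tuple[int, int], int]):
        self.singletons = singletons
        self.idx_a = np.array([edge_index[(s.parent_a, s.node_a)]
                               for s in singletons], dtype=np.int64)
        self.idx_b = np.array([edge_index[(s.parent_b, s.node_b)]
                               for s in singletons], dtype=np.int64)
        self.w = np.array([s.phase_prob for s in singletons])

    def attach(self, store) -> None:
        np.add.at(store.y, self.idx_a, self.w)
        np.add.at(store.y, self.idx_b, 1.0 - self.w)

    @staticmethod
    def _log_evidence_gain(store, e: int, y_base: float) -> float:
        """log Z(y_base + 1) - log Z(y_base) for a sample-child edge
        under the parent's cavity Gamma."""
        cav = store.post[store.parent[e]] - store.fac_parent[e]
        at, bt = cav[0] + 1.0, cav[1]
        mus = store.mu_s[e]
        if not (at + y_base > 0 and mus + bt > 0):
            return 0.0
        return (np.log(mus) - np.log1p(y_base) + np.log(at + y_base)
                - np.log(mus + bt))

    def update_responsibilities(self, store) -> None:
        for k in range(len(self.w)):
            ia, ib = self.idx_a[k], self.idx_b[k]
            w = self.w[k]
            ya = store.y[ia] - w
            yb = store.y[ib] - (1.0 - w)
            r = (self._log_evidence_gain(store, ia, ya)
                 - self._log_evidence_gain(store, ib, yb))
            w_new = 1.0 / (1.0 + np.exp(-r))
            store.y[ia] += w_new - w
            store.y[ib] += w - w_new
            self.w[k] = w_new
        for s, w in zip(self.singletons, self.w):
            s.phase_prob = float(w)


def date_phase_agnostic(tables: ArgTables, config: EPConfig, *,
                        presplit: bool = False
                        ) -> tuple[EPResult, PhaseState]:
    """EP dating marginalizing over singleton phase.

    With no unphased singletons this is identical to
    :func:`vgdate.ep_engine.date` (same engine, empty phase state).
    Set ``presplit=True`` when ``split_terminal_edges`` has already been
    applied.
    """
    if not presplit:
        tables = split_terminal_edges(tables)
    singles = find_unphased_singletons(tables)
    store = init_store(tables, config)
    edge_index = {(int(p), int(c)): e
                  for e, (p, c) in enumerate(zip(store.parent, store.child))}
    state = PhaseState(singles, edge_index)
    state.attach(store)
    result = date(tables, config, store=store, phase_state=state)
    return result, state
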