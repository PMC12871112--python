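"""ARG topology tables: data model, validation, text I/O and adapters.

An ancestral recombination graph (ARG) is held as four tables mirroring
the succinct-tree-sequence layout:

* ``nodes(id, time, is_sample, individual)`` — one row per haplotype;
  contemporary samples have time 0 and internal node times are unknown
  on input (if present they are ignored by the dating engine).
* ``edges(left, right, parent, child)`` — inheritance of the half-open
  genomic interval ``[left, right)`` by ``child`` from the older
  ``parent``.
* ``sites(id, position, ancestral_state)`` and
  ``mutations(id, site, node, derived_state, unphased_individual)`` —
  mutations sit above ``node`` on the edge towards its parent at the
  site position; singletons whose carrier haplotype within a diploid
  individual is unknown carry the individual id in
  ``unphased_individual`` (−1 means phased).

The canonical on-disk form is four TSV files with these headers.  An
adapter to/from ``tskit.TreeSequence`` is provided for interoperability
with the surrounding ecosystem.

Missing values are encoded as −1 for integer columns (individual,
unphased_individual) and NaN for internal node times.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArgTables",
    "LogicalEdge",
    "ArgValidationError",
    "read_tables",
    "write_tables",
    "build_logical_edges",
    "write_results",
]

NODE_COLUMNS = ["id", "time", "is_sample", "individual"]
EDGE_COLUMNS = ["left", "right", "parent", "child"]
SITE_COLUMNS = ["id", "position", "ancestral_state"]
MUTATION_COLUMNS = ["id", "site", "node", "derived_state", "unphased_individual"]

MISSING = -1


class ArgValidationError(ValueError):
    """A structural invariant of the ARG tables is violated."""


@dataclass(frozen=True)
class LogicalEdge:
    """All genomic segments shared by one (parent, child) pair.

    ``span`` is the total base pairs transmitted and ``y`` the number of
    (phased) mutations on those segments; ``y`` may become fractional
    when unphased singletons are spread across candidate edges.
    """

    parent: int
    child: int
    span: float
    y: float


@dataclass(frozen=True)
class ArgTables:
    """Validated, immutable ARG tables.

    Construct through :func:`ArgTables.from_frames`, :func:`read_tables`
    or :func:`ArgTables.from_tree_sequence`; the plain constructor does
    not validate.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    sites: pd.DataFrame
    mutations: pd.DataFrame
    sequence_length: float = field(default=0.0)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_frames(cls, nodes, edges, sites=None, mutations=None,
                    sequence_length=None) -> "ArgTables":
        nodes = _coerce(nodes, NODE_COLUMNS,
                        {"id": np.int64, "time": float, "is_sample": np.int64,
                         "individual": np.int64})
        edges = _coerce(edges, EDGE_COLUMNS,
                        {"left": float, "right": float, "parent": np.int64,
                         "child": np.int64})
        if sites is None:
            sites = pd.DataFrame(columns=SITE_COLUMNS)
        if mutations is None:
            mutations = pd.DataFrame(columns=MUTATION_COLUMNS)
        sites = _coerce(sites, SITE_COLUMNS,
                        {"id": np.int64, "position": float,
                         "ancestral_state": str})
        mutations = _coerce(mutations, MUTATION_COLUMNS,
                            {"id": np.int64, "site": np.int64, "node": np.int64,
                             "derived_state": str,
                             "unphased_individual": np.int64})
        if sequence_length is None:
            sequence_length = float(edges["right"].max()) if len(edges) else 0.0
        out = cls(nodes=nodes, edges=edges, sites=sites, mutations=mutations,
                  sequence_length=float(sequence_length))
        out.validate()
        return out

    @classmethod
    def from_tree_sequence(cls, ts) -> "ArgTables":
        """Adapter from a ``tskit.TreeSequence`` (native binary format)."""
        t = ts.tables
        nodes = pd.DataFrame({
            "id": np.arange(ts.num_nodes, dtype=np.int64),
            "time": t.nodes.time,
            "is_sample": (t.nodes.flags & 1).astype(np.int64),
            "individual": t.nodes.individual.astype(np.int64),
        })
        # internal times from a simulator are "truth": keep them in the
        # table (the dating engine ignores them with a warning)
        edges = pd.DataFrame({
            "left": t.edges.left, "right": t.edges.right,
            "parent": t.edges.parent.astype(np.int64),
            "child": t.edges.child.astype(np.int64),
        })
        sites = pd.DataFrame({
            "id": np.arange(ts.num_sites, dtype=np.int64),
            "position": t.sites.position,
            "ancestral_state": [s.ancestral_state for s in ts.sites()],
        })
        mutations = pd.DataFrame({
            "id": np.arange(ts.num_mutations, dtype=np.int64),
            "site": t.mutations.site.astype(np.int64),
            "node": t.mutations.node.astype(np.int64),
            "derived_state": [m.derived_state for m in ts.mutations()],
            "unphased_individual": np.full(ts.num_mutations, MISSING,
                                           dtype=np.int64),
        })
        return cls.from_frames(nodes, edges, sites, mutations,
                               sequence_length=ts.sequence_length)

    # -- basic properties -------------------------------------------------
    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.nodes.loc[self.nodes["is_sample"] == 1, "id"].to_numpy()

    @property
    def num_samples(self) -> int:
        return int((self.nodes["is_sample"] == 1).sum())

    def is_sample(self) -> np.ndarray:
        return self.nodes["is_sample"].to_numpy() == 1

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        nodes, edges = self.nodes, self.edges
        n = len(nodes)
        if not np.array_equal(nodes["id"].to_numpy(), np.arange(n)):
            raise ArgValidationError("node ids must be dense 0..N-1 in order")
        is_sample = nodes["is_sample"].to_numpy() == 1
        t = nodes["time"].to_numpy()
        if np.isnan(t[is_sample]).any():
            raise ArgValidationError("sample with missing time")
        if (t[is_sample] != 0).any():
            bad = nodes["id"].to_numpy()[is_sample & (t != 0)][0]
            raise ArgValidationError(
                f"unsupported: noncontemporary samples (sample node {bad} "
                "has nonzero time)")
        if len(edges):
            left = edges["left"].to_numpy()
            right = edges["right"].to_numpy()
            parent = edges["parent"].to_numpy()
            child = edges["child"].to_numpy()
            if (left >= right).any():
                i = int(np.argmax(left >= right))
                raise ArgValidationError(f"edge {i}: left >= right")
            if (parent == child).any():
                raise ArgValidationError("self edge (parent == child)")
            for col, arr in (("parent", parent), ("child", child)):
                if arr.min() < 0 or arr.max() >= n:
                    raise ArgValidationError(f"edge {col} out of range")
            if is_sample[parent].any():
                bad = parent[is_sample[parent]][0]
                raise ArgValidationError(
                    f"sample node {bad} appears as a parent")
            _check_parent_overlap(edges)
            _check_acyclic(n, parent, child)
        if len(self.sites):
            pos = self.sites["position"].to_numpy()
            if not np.array_equal(self.sites["id"].to_numpy(),
                                  np.arange(len(pos))):
                raise ArgValidationError("site ids must be dense 0..k-1")
            if (np.diff(pos) <= 0).any():
                raise ArgValidationError(
                    "site positions must be strictly increasing")
            if pos.min() < 0 or pos.max() > self.sequence_length:
                raise ArgValidationError("site position outside sequence")
        if len(self.mutations):
            site = self.mutations["site"].to_numpy()
            node = self.mutations["node"].to_numpy()
            if site.min() < 0 or site.max() >= len(self.sites):
                raise ArgValidationError("mutation site out of range")
            if node.min() < 0 or node.max() >= n:
                raise ArgValidationError("mutation node out of range")
            # each phased mutation must sit on an edge whose child is `node`
            edge_idx = self.assign_mutations_to_edges()
            phased = self.mutations["unphased_individual"].to_numpy() == MISSING
            if (edge_idx[phased] < 0).any():
                mid = self.mutations["id"].to_numpy()[phased][
                    edge_idx[phased] < 0][0]
                raise ArgValidationError(
                    f"mutation {mid}: no edge with child == node covers its "
                    "site position")

    # -- derived structure ------------------------------------------------
    def assign_mutations_to_edges(self) -> np.ndarray:
        """For each mutation, the index of the edge row carrying it.

        Returns −1 where no edge with ``child == node`` covers the site
        position (e.g. mutations flagged unphased, or above a local
        root).
        """
        out = np.full(len(self.mutations), -1, dtype=np.int64)
        if not len(self.mutations) or not len(self.edges):
            return out
        pos = self.sites["position"].to_numpy()[
            self.mutations["site"].to_numpy()]
        node = self.mutations["node"].to_numpy()
        edges = self.edges
        by_child: dict[int, np.ndarray] = {}
        for m, (p, c) in enumerate(zip(pos, node)):
            idx = by_child.get(c)
            if idx is None:
                idx = np.flatnonzero(edges["child"].to_numpy() == c)
                by_child[c] = idx
            for e in idx:
                if edges["left"].iat[e] <= p < edges["right"].iat[e]:
                    out[m] = e
                    break
        return out

    def topological_ranks(self) -> np.ndarray:
        """Longest-path rank from the leaves (samples have rank 0).

        Computed by Kahn's algorithm with a smallest-id-first queue so
        the resulting order (and hence the EP sweep order) is a pure
        function of the graph, not of edge-table row order.
        """
        import heapq

        n = self.num_nodes
        parent = self.edges["parent"].to_numpy()
        child = self.edges["child"].to_numpy()
        pairs = {(int(p), int(c)) for p, c in zip(parent, child)}
        children: dict[int, list[int]] = {i: [] for i in range(n)}
        out_deg = np.zeros(n, dtype=np.int64)
        for p, c in pairs:
            children[p].append(c)
            out_deg[p] += 1  # number of distinct children below p
        rank = np.zeros(n, dtype=np.int64)
        remaining = out_deg.copy()
        heap = [i for i in range(n) if remaining[i] == 0]
        heapq.heapify(heap)
        parents_of: dict[int, list[int]] = {i: [] for i in range(n)}
        for p, c in pairs:
            parents_of[c].append(p)
        seen = 0
        while heap:
            u = heapq.heappop(heap)
            seen += 1
            for p in parents_of[u]:
                rank[p] = max(rank[p], rank[u] + 1)
                remaining[p] -= 1
                if remaining[p] == 0:
                    heapq.heappush(heap, p)
        if seen != n:
            raise ArgValidationError("cycle detected in edge table")
        return rank

    def roots(self) -> np.ndarray:
        """Ultimate roots: internal nodes with children but no parents.

        Nodes attached to no edge at all (possible after branch
        collapsing) are not roots — they are simply outside the graph.
        """
        has_parent = np.zeros(self.num_nodes, dtype=bool)
        has_parent[self.edges["child"].to_numpy()] = True
        has_child = np.zeros(self.num_nodes, dtype=bool)
        has_child[self.edges["parent"].to_numpy()] = True
        is_internal = ~self.is_sample()
        return np.flatnonzero(is_internal & ~has_parent & has_child)

    def to_tree_sequence(self, node_times: np.ndarray):
        """Build a ``tskit.TreeSequence`` using the given node times.

        Times must satisfy the parent-older-than-child constraint (use
        the constrained point times from a dating result).
        """
        import tskit

        tables = tskit.TableCollection(sequence_length=self.sequence_length)
        individuals = self.nodes["individual"].to_numpy()
        n_ind = individuals.max() + 1 if (individuals >= 0).any() else 0
        for _ in range(int(n_ind)):
            tables.individuals.add_row()
        for i in range(self.num_nodes):
            tables.nodes.add_row(
                flags=(tskit.NODE_IS_SAMPLE
                       if self.nodes["is_sample"].iat[i] else 0),
                time=float(node_times[i]),
                individual=int(individuals[i]) if individuals[i] >= 0 else -1)
        for _, e in self.edges.iterrows():
            tables.edges.add_row(left=e["left"], right=e["right"],
                                 parent=int(e["parent"]), child=int(e["child"]))
        for _, s in self.sites.iterrows():
            tables.sites.add_row(position=s["position"],
                                 ancestral_state=s["ancestral_state"])
        for _, m in self.mutations.iterrows():
            tables.mutations.add_row(site=int(m["site"]), node=int(m["node"]),
                                     derived_state=m["derived_state"])
        tables.sort()
        tables.build_index()
        tables.compute_mutation_parents()
        return tables.tree_sequence()


def _coerce(df, columns, dtypes) -> pd.DataFrame:
    df = pd.DataFrame(df).copy()
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ArgValidationError(f"missing columns: {missing}")
    df = df[columns].reset_index(drop=True)
    for c, dt in dtypes.items():
        try:
            df[c] = df[c].astype(dt)
        except (TypeError, ValueError) as err:
            raise ArgValidationError(f"malformed column {c!r}: {err}") from err
    return df


def _check_parent_overlap(edges: pd.DataFrame) -> None:
    df = edges.sort_values(["child", "left"], kind="stable")
    child = df["child"].to_numpy()
    left = df["left"].to_numpy()
    right = df["right"].to_numpy()
    same = child[1:] == child[:-1]
    overlap = same & (left[1:] < right[:-1])
    if overlap.any():
        i = int(np.argmax(overlap))
        raise ArgValidationError(
            f"child {child[i]} has two parents over overlapping span "
            f"[{left[i + 1]}, {right[i]})")


def _check_acyclic(n, parent, child) -> None:
    # cycle check piggybacks on topological ranking; duplicated cheaply
    # here so invalid inputs fail at read time with a clear message
    import heapq

    pairs = {(int(p), int(c)) for p, c in zip(parent, child)}
    out_deg = np.zeros(n, dtype=np.int64)
    parents_of: dict[int, list[int]] = {i: [] for i in range(n)}
    for p, c in pairs:
        out_deg[p] += 1
        parents_of[c].append(p)
    heap = [i for i in range(n) if out_deg[i] == 0]
    heapq.heapify(heap)
    seen = 0
    while heap:
        u = heapq.heappop(heap)
        seen += 1
        for p in parents_of[u]:
            out_deg[p] -= 1
            if out_deg[p] == 0:
                heapq.heappush(heap, p)
    if seen != n:
        raise ArgValidationError("cycle detected in edge table")


# ---------------------------------------------------------------------------
# logical edges
# ---------------------------------------------------------------------------

def build_logical_edges(tables: ArgTables) -> list[LogicalEdge]:
    """Merge per-segment edge rows into one logical edge per
    (parent, child) pair, accumulating genomic span and phased mutation
    counts.

    The dating model is a function of per-pair totals only, so this
    aggregation is lossless for inference; the per-segment rows are kept
    in the tables for mutation placement and output.
    """
    edges = tables.edges
    key = list(zip(edges["parent"].to_numpy(), edges["child"].to_numpy()))
    span = (edges["right"] - edges["left"]).to_numpy()
    totals: dict[tuple[int, int], float] = {}
    for k, s in zip(key, span):
        totals[k] = totals.get(k, 0.0) + float(s)
    counts: dict[tuple[int, int], float] = {k: 0.0 for k in totals}
    edge_idx = tables.assign_mutations_to_edges()
    if len(tables.mutations):
        phased = tables.mutations["unphased_individual"].to_numpy() == MISSING
        for m in np.flatnonzero(phased):
            e = edge_idx[m]
            k = (int(edges["parent"].iat[e]), int(edges["child"].iat[e]))
            counts[k] += 1.0
    return [LogicalEdge(parent=p, child=c, span=totals[(p, c)],
                        y=counts[(p, c)])
            for (p, c) in sorted(totals)]


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

_TABLE_FILES = {"nodes": NODE_COLUMNS, "edges": EDGE_COLUMNS,
                "sites": SITE_COLUMNS, "mutations": MUTATION_COLUMNS}


def read_tables(path: str | os.PathLike) -> ArgTables:
    """Read ARG tables from a directory of nodes/edges/sites/mutations TSVs."""
    frames = {}
    for name in _TABLE_FILES:
        fn = os.path.join(path, f"{name}.tsv")
        if not os.path.exists(fn):
            if name in ("sites", "mutations"):
                frames[name] = None
                continue
            raise FileNotFoundError(fn)
        frames[name] = pd.read_csv(fn, sep="\t", float_precision="round_trip")
    return ArgTables.from_frames(frames["nodes"], frames["edges"],
                                 frames["sites"], frames["mutations"])


def write_tables(tables: ArgTables, path: str | os.PathLike) -> None:
    os.makedirs(path, exist_ok=True)
    for name in _TABLE_FILES:
        getattr(tables, name).to_csv(os.path.join(path, f"{name}.tsv"),
                                     sep="\t", index=False,
                                     float_format="%.17g")


def write_results(result, path: str | os.PathLike) -> None:
    """Write a dating result as node/mutation TSVs plus JSON metadata.

    ``result`` is a :class:`vgdate.model.ArgDatingResults`.
    """
    os.makedirs(path, exist_ok=True)
    result.node_posteriors.to_csv(os.path.join(path, "dated_nodes.tsv"),
                                  sep="\t", index=False, float_format="%.17g")
    result.mutation_posteriors.to_csv(
        os.path.join(path, "dated_mutations.tsv"), sep="\t", index=False,
        float_format="%.17g")
    with open(os.path.join(path, "metadata.json"), "w") as fh:
        json.dump(result.metadata(), fh, indent=2)


def warn_if_internal_times(tables: ArgTables) -> None:
    internal = ~tables.is_sample()
    t = tables.nodes["time"].to_numpy()
    if np.isfinite(t[internal]).any() and (t[internal] != 0).any():
        warnings.warn(
            "input tables carry times for internal nodes; these are ignored "
            "and re-estimated", stacklevel=3)
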