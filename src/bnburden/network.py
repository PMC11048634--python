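"""Discrete Bayesian networks with clinical role annotations.

A :class:`Network` is a DAG of categorical nodes, each carrying a conditional
probability table (CPT) and a *role* tag describing its place in the clinical
model: ``pretreatment`` (patient/tumour factors), ``intervention`` (treatment
choices such as the RT field), ``outcome`` (benefit endpoints such as 7-year
DFS), ``toxicity`` (harms such as clinical lymphedema) or ``derived``.

CPT layout
----------
A node with parents ``(P1, ..., Pm)`` stores its CPT as an array of shape
``(prod_i |Pi|, |node|)``.  Row ``r`` corresponds to the parent-state
combination obtained by enumerating the declared parent order with the LAST
parent varying fastest — i.e. C-order (row-major) enumeration of
``(|P1|, ..., |Pm|)``.  This convention is fixed and documented because table
layout is otherwise a classic source of silent transposition bugs.

Construction is permissive (only shapes/types are enforced) so that broken
networks can be *loaded and reported on*; :func:`validate_network` lists every
violation, and inference refuses networks whose report is non-empty.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import InputError

ROLES = ("pretreatment", "intervention", "outcome", "toxicity", "derived")

#: Tolerance for CPT row normalisation.  Rows failing it are *rejected*, never
#: silently renormalised: a non-normalised row usually means an elicitation or
#: transcription error upstream and repairing it would mask that.
ROW_TOLERANCE = 1e-9


@dataclass(frozen=True)
class NodeSpec:
    """Declaration of one categorical node.

    Parameters
    ----------
    name : str
        Unique node identifier.
    states : tuple of str
        Ordered state labels (at least two, unique).
    role : str
        One of :data:`ROLES`.
    parents : tuple of str
        Ordered parent names; the order is the CPT's conditioning order.
    """

    name: str
    states: tuple[str, ...]
    role: str = "derived"
    parents: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parents", tuple(self.parents))
        if not self.name:
            raise InputError("node name must be non-empty")
        if len(self.states) < 2:
            raise InputError(f"node {self.name!r} needs >= 2 states")
        if self.role not in ROLES:
            raise InputError(
                f"node {self.name!r}: unknown role {self.role!r}; expected one of {ROLES}"
            )

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise InputError(
                f"node {self.name!r} has no state {state!r}; states are {list(self.states)}"
            ) from None


@dataclass
class CPT:
    """Conditional probability table for one node.

    ``table[r, k]`` is P(node = state_k | parent combination r), rows ordered
    with the last declared parent varying fastest.
    """

    node: str
    table: np.ndarray

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim == 1:
            self.table = self.table.reshape(1, -1)
        if self.table.ndim != 2:
            raise InputError(f"CPT for {self.node!r} must be 2-D, got {self.table.ndim}-D")


class Network:
    """A discrete Bayesian network: nodes + one CPT per node + metadata."""

    def __init__(
        self,
        nodes: Sequence[NodeSpec],
        cpts: Sequence[CPT] | Mapping[str, np.ndarray],
        metadata: Mapping[str, object] | None = None,
    ):
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        if isinstance(cpts, Mapping):
            cpts = [CPT(name, np.asarray(tab)) for name, tab in cpts.items()]
        self.cpts: dict[str, CPT] = {c.node: c for c in cpts}
        self.metadata: dict[str, object] = dict(metadata or {})
        self._by_name: dict[str, NodeSpec] = {}
        for spec in self.nodes:
            # duplicates are recorded by keeping the first; validate_network reports them
            self._by_name.setdefault(spec.name, spec)

    # -- lookups ---------------------------------------------------------

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(spec.name for spec in self.nodes)

    def node(self, name: str) -> NodeSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise InputError(f"unknown node {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def cpt(self, name: str) -> np.ndarray:
        return self.cpts[name].table

    def cardinality(self, name: str) -> int:
        return self.node(name).cardinality

    # -- structure -------------------------------------------------------

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for spec in self.nodes:
            for p in spec.parents:
                g.add_edge(p, spec.name)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph()))

    def row_index(self, node: str, parent_states: Mapping[str, str]) -> int:
        """Row index in ``node``'s CPT for a full parent-state assignment."""
        spec = self.node(node)
        missing = [p for p in spec.parents if p not in parent_states]
        if missing:
            raise InputError(f"row lookup for {node!r} missing parents {missing}")
        idx = 0
        for p in spec.parents:  # last parent varies fastest
            pspec = self.node(p)
            idx = idx * pspec.cardinality + pspec.state_index(parent_states[p])
        return idx

    def parent_combinations(self, node: str) -> Iterator[tuple[str, ...]]:
        """Parent-state tuples in row order (last parent fastest)."""
        spec = self.node(node)
        yield from itertools.product(*(self.node(p).states for p in spec.parents))

    def expected_rows(self, node: str) -> int:
        spec = self.node(node)
        n = 1
        for p in spec.parents:
            if p in self._by_name:
                n *= self.node(p).cardinality
        return n

    # -- convenience -----------------------------------------------------

    def copy(self) -> "Network":
        return Network(
            self.nodes,
            [CPT(c.node, c.table.copy()) for c in self.cpts.values()],
            dict(self.metadata),
        )

    def replace_cpt(self, node: str, table: np.ndarray) -> None:
        self.cpts[node] = CPT(node, np.asarray(table, dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        if set(self.cpts) != set(other.cpts):
            return False
        return all(
            np.array_equal(self.cpts[n].table, other.cpts[n].table) for n in self.cpts
        )

    def __repr__(self) -> str:
        return f"<Network {len(self.nodes)} nodes: {', '.join(self.node_names[:6])}{'...' if len(self.nodes) > 6 else ''}>"


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    kind: str
    node: str | None
    detail: str

    def __str__(self) -> str:
        where = f" [{self.node}]" if self.node else ""
        return f"{self.kind}{where}: {self.detail}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind: str, node: str | None, detail: str) -> None:
        self.violations.append(Violation(kind, node, detail))

    def __bool__(self) -> bool:  # truthy iff *valid*, matching "if report:" reading
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "network is valid"
        return "\n".join(str(v) for v in self.violations)


def validate_network(net: Network) -> ValidationReport:
    """Check every structural and numerical invariant; report all violations.

    Checks: unique node/state names, parents exist, acyclicity, exactly one
    CPT per node, CPT shape (rows = product of parent cardinalities, columns =
    node cardinality), entries in [0, 1], and each row summing to 1 within
    :data:`ROW_TOLERANCE`.
    """
    report = ValidationReport()

    seen: set[str] = set()
    for spec in net.nodes:
        if spec.name in seen:
            report.add("duplicate_node", spec.name, "node name declared twice")
        seen.add(spec.name)
        if len(set(spec.states)) != len(spec.states):
            report.add("duplicate_state", spec.name, f"states {list(spec.states)} not unique")
        for p in spec.parents:
            if p not in net:
                report.add("dangling_parent", spec.name, f"parent {p!r} is not a node")

    g = net.graph()
    # only consider edges among declared nodes (dangling parents reported above)
    try:
        cycle = nx.find_cycle(g.subgraph([s.name for s in net.nodes]))
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(u for u, _ in cycle) + " -> " + cycle[0][0]
        report.add("cycle", None, f"parent graph contains a cycle: {path}")

    for spec in net.nodes:
        if spec.name not in net.cpts:
            report.add("missing_cpt", spec.name, "no CPT supplied")
    for name in net.cpts:
        if name not in net:
            report.add("extra_cpt", name, "CPT for undeclared node")

    for spec in net.nodes:
        if spec.name not in net.cpts:
            continue
        tab = net.cpt(spec.name)
        n_rows = net.expected_rows(spec.name)
        if tab.shape != (n_rows, spec.cardinality):
            report.add(
                "bad_shape",
                spec.name,
                f"CPT shape {tab.shape} != expected ({n_rows}, {spec.cardinality})",
            )
            continue
        if np.any(tab < 0) or np.any(tab > 1):
            report.add("entry_out_of_range", spec.name, "CPT entries outside [0, 1]")
        bad = np.where(np.abs(tab.sum(axis=1) - 1.0) > ROW_TOLERANCE)[0]
        for r in bad:
            report.add(
                "row_not_normalized",
                spec.name,
                f"row {int(r)} sums to {tab[r].sum():.12g}",
            )

    return report


def require_valid(net: Network) -> None:
    """Raise :class:`NetworkInvalidError` unless ``net`` passes validation."""
    from .errors import NetworkInvalidError

    report = validate_network(net)
    if not report.ok:
        raise NetworkInvalidError(report)
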