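"""Exact inference under hard, virtual, interventional and mixture evidence.

Two engines share one contract:

``posterior_enumeration``
    Brute force: materialise the full joint as a dense array and marginalise.
    Guarded to small networks; exists as the independent oracle against which
    the scalable engine is verified.

``posterior_ve``
    Variable elimination with a greedy min-fill ordering (lexicographic
    tie-break, so runs are fully deterministic).

Evidence semantics
------------------
*Hard* evidence fixes a node to a state.  *Virtual* (soft) evidence attaches a
non-negative likelihood vector over a node's states, multiplied into the joint
(Pearl's virtual-evidence construction); the all-ones vector is uninformative.
*Do* assignments model randomised interventions: the node's incoming arcs are
severed and its CPT replaced by the given distribution, so conditioning on the
arm cannot flow back into pretreatment factors — this is what preserves the
randomisation effect between trial arms.  *Mixtures* express arms defined as
blends of treatment states (e.g. a 50/50 blend of two RT fields): the posterior
is the weight-convex combination of the component posteriors.  Mixtures nest
one level only; that covers every trial scenario the package targets and keeps
the semantics auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InconsistentEvidenceError, InputError
from .network import CPT, Network, require_valid

#: Enumeration guard: refuse joints larger than this many cells (~2^22, i.e.
#: about 22 binary-equivalent nodes / 32 MiB of float64).
ENUMERATION_LIMIT = 4_194_304

MIXTURE_WEIGHT_TOL = 1e-12


# ---------------------------------------------------------------------------
# evidence programs


@dataclass(frozen=True)
class EvidenceProgram:
    """A trial arm's evidence: hard states, virtual likelihoods, do's, mixture.

    ``do`` values may be either a state label (point intervention) or a
    distribution over the node's states.  Node/state names are resolved
    against a concrete network only when the program is applied, so programs
    are cheap, hashable descriptions that can live in config files.
    """

    hard: Mapping[str, str] = field(default_factory=dict)
    virtual: Mapping[str, Sequence[float]] = field(default_factory=dict)
    do: Mapping[str, str | Sequence[float]] = field(default_factory=dict)
    mixture: Sequence[tuple[float, "EvidenceProgram"]] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "hard", dict(self.hard))
        object.__setattr__(self, "virtual", {k: tuple(float(x) for x in v) for k, v in dict(self.virtual).items()})
        object.__setattr__(self, "do", {
            k: (v if isinstance(v, str) else tuple(float(x) for x in v))
            for k, v in dict(self.do).items()
        })
        object.__setattr__(self, "mixture", tuple((float(w), p) for w, p in self.mixture))

        groups = [set(self.hard), set(self.virtual), set(self.do)]
        for i in range(3):
            for j in range(i + 1, 3):
                clash = groups[i] & groups[j]
                if clash:
                    raise InputError(
                        f"node(s) {sorted(clash)} appear in more than one of hard/virtual/do"
                    )
        for node, vec in self.virtual.items():
            if any(x < 0 for x in vec):
                raise InputError(f"virtual likelihood for {node!r} has negative entries")
            if not any(x > 0 for x in vec):
                raise InputError(f"virtual likelihood for {node!r} is all zero")
        if self.mixture:
            weights = [w for w, _ in self.mixture]
            if any(w < 0 for w in weights):
                raise InputError("mixture weights must be >= 0")
            if abs(sum(weights) - 1.0) > MIXTURE_WEIGHT_TOL:
                raise InputError(f"mixture weights sum to {sum(weights)!r}, not 1")
            for _, comp in self.mixture:
                if comp.mixture:
                    raise InputError("mixtures may not nest beyond one level")

    @property
    def is_mixture(self) -> bool:
        return bool(self.mixture)

    def evidence_nodes(self) -> set[str]:
        nodes = set(self.hard) | set(self.virtual) | set(self.do)
        for _, comp in self.mixture:
            nodes |= comp.evidence_nodes()
        return nodes

    def merged_with(self, other: "EvidenceProgram") -> "EvidenceProgram":
        """Combine two programs; any node set by both is a conflict.

        Used both to push a mixture's top-level evidence into its components
        and to combine a trial's shared evidence with an arm's own program.
        At most one side may carry a mixture.
        """
        clash = sorted(
            (set(self.hard) | set(self.virtual) | set(self.do))
            & (set(other.hard) | set(other.virtual) | set(other.do))
        )
        if clash:
            raise InputError(f"conflicting evidence on node(s) {clash}")
        if self.mixture and other.mixture:
            raise InputError("cannot merge two mixture programs")
        return EvidenceProgram(
            hard={**self.hard, **other.hard},
            virtual={**self.virtual, **other.virtual},
            do={**self.do, **other.do},
            mixture=self.mixture or other.mixture,
        )

    def components(self) -> list[tuple[float, "EvidenceProgram"]]:
        """Flatten to weighted mixture-free components (weight 1 if no mixture)."""
        if not self.mixture:
            return [(1.0, self)]
        base = EvidenceProgram(hard=self.hard, virtual=self.virtual, do=self.do)
        return [(w, base.merged_with(comp)) for w, comp in self.mixture]

    # -- provenance ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "hard": dict(sorted(self.hard.items())),
            "virtual": {k: list(v) for k, v in sorted(self.virtual.items())},
            "do": {
                k: (v if isinstance(v, str) else list(v))
                for k, v in sorted(self.do.items())
            },
            "mixture": [[w, p.to_dict()] for w, p in self.mixture],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EvidenceProgram":
        return cls(
            hard=d.get("hard", {}),
            virtual=d.get("virtual", {}),
            do=d.get("do", {}),
            mixture=[(w, cls.from_dict(p)) for w, p in d.get("mixture", [])],
        )

    def digest(self) -> str:
        """Stable short hash of the program, recorded in result provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class Posterior:
    """Posterior distribution of one node given an evidence program."""

    node: str
    states: tuple[str, ...]
    probs: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise InconsistentEvidenceError(
                f"posterior for {self.node!r} not normalised (sum {self.probs.sum()!r})"
            )

    def prob(self, state: str) -> float:
        try:
            return float(self.probs[self.states.index(state)])
        except ValueError:
            raise InputError(f"{self.node!r} has no state {state!r}") from None

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.probs)}


# ---------------------------------------------------------------------------
# resolution helpers


def _as_distribution(net: Network, node: str, value: str | Sequence[float]) -> np.ndarray:
    spec = net.node(node)
    if isinstance(value, str):
        dist = np.zeros(spec.cardinality)
        dist[spec.state_index(value)] = 1.0
        return dist
    dist = np.asarray(value, dtype=float)
    if dist.shape != (spec.cardinality,):
        raise InputError(
            f"distribution for {node!r} has length {dist.size}, node has "
            f"{spec.cardinality} states"
        )
    if np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-9:
        raise InputError(f"distribution for {node!r} is not a probability vector")
    return dist


def _check_program(net: Network, ev: EvidenceProgram) -> None:
    for node, state in ev.hard.items():
        net.node(node).state_index(state)
    for node, vec in ev.virtual.items():
        if len(vec) != net.cardinality(node):
            raise InputError(
                f"virtual likelihood for {node!r} has length {len(vec)}, "
                f"node has {net.cardinality(node)} states"
            )
    for node, value in ev.do.items():
        _as_distribution(net, node, value)
    for _, comp in ev.mixture:
        _check_program(net, comp)


def apply_do(net: Network, node: str, distribution: str | Sequence[float]) -> Network:
    """Graph surgery: sever ``node``'s incoming arcs, clamp its distribution.

    Returns a new network; all other CPTs are untouched.  With the arcs gone,
    observing (or setting) the intervened node can no longer change the
    marginals of its former ancestors — the randomisation property trial-arm
    assignment relies on.
    """
    dist = _as_distribution(net, node, distribution)
    new_nodes = []
    for spec in net.nodes:
        if spec.name == node:
            new_nodes.append(
                type(spec)(name=spec.name, states=spec.states, role=spec.role, parents=())
            )
        else:
            new_nodes.append(spec)
    new_cpts = [CPT(c.node, c.table.copy()) for c in net.cpts.values() if c.node != node]
    new_cpts.append(CPT(node, dist.reshape(1, -1)))
    return Network(new_nodes, new_cpts, dict(net.metadata))


def _mutilate(net: Network, ev: EvidenceProgram) -> Network:
    out = net
    for node, value in ev.do.items():
        out = apply_do(out, node, value)
    return out


# ---------------------------------------------------------------------------
# enumeration engine (oracle)


def _joint_array(net: Network) -> tuple[list[str], np.ndarray]:
    """Dense joint over all nodes, axes in ``net.nodes`` declaration order."""
    names = list(net.node_names)
    axis = {n: i for i, n in enumerate(names)}
    cards = [net.cardinality(n) for n in names]
    size = int(np.prod(cards, dtype=np.int64))
    if size > ENUMERATION_LIMIT:
        raise InputError(
            f"joint of size {size} exceeds the enumeration guard "
            f"({ENUMERATION_LIMIT}); use posterior_ve"
        )
    joint = np.ones(cards)
    n = len(names)
    for spec in net.nodes:
        fam = list(spec.parents) + [spec.name]
        arr = net.cpt(spec.name).reshape([net.cardinality(p) for p in fam])
        axes = [axis[v] for v in fam]
        perm = np.argsort(axes)
        arr = arr.transpose(perm)
        shape = [1] * n
        for a in axes:
            shape[a] = cards[a]
        joint = joint * arr.reshape(shape)
    return names, joint


def posterior_enumeration(net: Network, ev: EvidenceProgram, query: str) -> Posterior:
    """Exact posterior by summing the full joint (test oracle, small nets only)."""
    require_valid(net)
    _check_program(net, ev)
    spec = net.node(query)

    if ev.is_mixture:
        return _mixture_posterior(net, ev, query, posterior_enumeration, "enumeration")
    if query in ev.hard:
        raise InputError(f"query node {query!r} carries hard evidence")

    mutilated = _mutilate(net, ev)
    names, joint = _joint_array(mutilated)
    axis = {n: i for i, n in enumerate(names)}
    n = len(names)

    for node, vec in ev.virtual.items():
        shape = [1] * n
        shape[axis[node]] = len(vec)
        joint = joint * np.asarray(vec, dtype=float).reshape(shape)
    for node, state in ev.hard.items():
        k = net.node(node).state_index(state)
        joint = np.take(joint, [k], axis=axis[node])

    qaxis = axis[query]
    marg = joint.sum(axis=tuple(i for i in range(n) if i != qaxis)).ravel()
    total = marg.sum()
    if total <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence has probability zero (query {query!r})"
        )
    return Posterior(
        node=query,
        states=spec.states,
        probs=marg / total,
        provenance={"method": "enumeration", "evidence": ev.digest()},
    )


def _mixture_posterior(net, ev, query, engine, method_name) -> Posterior:
    spec = net.node(query)
    probs = np.zeros(spec.cardinality)
    for w, comp in ev.components():
        if w == 0.0:
            continue
        if query in comp.hard:
            # conditioning a component on the query state makes that
            # component's posterior the point mass at the observed state
            point = np.zeros(spec.cardinality)
            point[spec.state_index(comp.hard[query])] = 1.0
            probs += w * point
        else:
            probs += w * engine(net, comp, query).probs
    return Posterior(
        node=query,
        states=spec.states,
        probs=probs,
        provenance={"method": f"{method_name}+mixture", "evidence": ev.digest()},
    )


# ---------------------------------------------------------------------------
# variable elimination engine


class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray):
        self.vars = vars
        self.values = np.asarray(values, dtype=float)

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = list(self.vars) + [v for v in other.vars if v not in self.vars]
        a = self._broadcast(out_vars)
        b = other._broadcast(out_vars)
        return _Factor(tuple(out_vars), a * b)

    def _broadcast(self, out_vars: list[str]) -> np.ndarray:
        # permute own axes into out_vars order, inserting singleton axes
        src = {v: i for i, v in enumerate(self.vars)}
        arr = self.values
        perm = [src[v] for v in out_vars if v in src]
        arr = arr.transpose(perm)
        shape, k = [], 0
        for v in out_vars:
            if v in src:
                shape.append(arr.shape[k])
                k += 1
            else:
                shape.append(1)
        return arr.reshape(shape)

    def sum_out(self, var: str) -> "_Factor":
        i = self.vars.index(var)
        return _Factor(
            self.vars[:i] + self.vars[i + 1 :], self.values.sum(axis=i)
        )

    def reduce(self, var: str, index: int) -> "_Factor":
        i = self.vars.index(var)
        return _Factor(
            self.vars[:i] + self.vars[i + 1 :], np.take(self.values, index, axis=i)
        )


def _min_fill_order(scopes: list[set[str]], to_eliminate: set[str]) -> list[str]:
    """Greedy min-fill elimination order; ties broken lexicographically."""
    adj: dict[str, set[str]] = {}
    for scope in scopes:
        for v in scope:
            adj.setdefault(v, set()).update(scope - {v})
    for v in to_eliminate:
        adj.setdefault(v, set())
    order = []
    remaining = set(to_eliminate)
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nbrs = [u for u in adj.get(v, ()) if u in adj]
            fill = sum(
                1
                for i, a in enumerate(nbrs)
                for b in nbrs[i + 1 :]
                if b not in adj[a]
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        nbrs = [u for u in adj[best] if u in adj]
        for i, a in enumerate(nbrs):
            for b in nbrs[i + 1 :]:
                adj[a].add(b)
                adj[b].add(a)
        for u in nbrs:
            adj[u].discard(best)
        del adj[best]
        remaining.discard(best)
        order.append(best)
    return order


def posterior_ve(net: Network, ev: EvidenceProgram, query: str) -> Posterior:
    """Exact posterior by variable elimination; same contract as enumeration."""
    require_valid(net)
    _check_program(net, ev)
    spec = net.node(query)

    if ev.is_mixture:
        return _mixture_posterior(net, ev, query, posterior_ve, "variable_elimination")
    if query in ev.hard:
        raise InputError(f"query node {query!r} carries hard evidence")

    mutilated = _mutilate(net, ev)
    factors: list[_Factor] = []
    for nspec in mutilated.nodes:
        fam = tuple(nspec.parents) + (nspec.name,)
        values = mutilated.cpt(nspec.name).reshape(
            [mutilated.cardinality(v) for v in fam]
        )
        factors.append(_Factor(fam, values))
    for node, vec in ev.virtual.items():
        factors.append(_Factor((node,), np.asarray(vec, dtype=float)))

    # hard evidence: slice every factor mentioning the node
    for node, state in ev.hard.items():
        k = net.node(node).state_index(state)
        factors = [f.reduce(node, k) if node in f.vars else f for f in factors]

    all_vars = set().union(*(set(f.vars) for f in factors)) if factors else set()
    order = _min_fill_order([set(f.vars) for f in factors], all_vars - {query})

    for var in order:
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.sum_out(var)]

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    if result.vars == ():
        # query never appeared in any factor scope — cannot happen for a valid
        # network (its own CPT mentions it), kept as a guard
        raise InputError(f"query {query!r} eliminated unexpectedly")
    probs = result._broadcast([query]).ravel()
    total = probs.sum()
    if total <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence has probability zero (query {query!r})"
        )
    return Posterior(
        node=query,
        states=spec.states,
        probs=probs / total,
        provenance={"method": "variable_elimination", "evidence": ev.digest()},
    )
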