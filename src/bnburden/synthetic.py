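"""Synthetic networks, expert panels and hand-checkable fixtures.

The package models a clinical decision problem — radiotherapy (RT) field
choice for (y)pN1 breast cancer — whose published conditional probabilities
and disability weights live in an external repository and are not shipped.
This module generates everything needed to exercise and test the pipeline:

* ``make_ypn1_network``: a network with the published *structure class* —
  pretreatment clinical factors, a 3-state RT-field intervention node
  (CW/breast alone, + high-tangent, + IMN/SCL), reconstruction factors, and
  outcome/toxicity nodes (7-year DFS, clinical lymphedema, reconstruction
  failure, RT pneumonitis, major cardiac event) — with seeded Dirichlet CPTs.
  The full published arc set is not printed anywhere, so this topology is a
  faithful-but-configurable reconstruction, not a claimed exact copy.
* ``make_random_network``: random DAGs for oracle-equivalence sweeps.
* ``make_expert_panel``: simulated multi-expert surveys around known truths.
* ``make_fixture_suite``: tiny networks whose posteriors are known exactly
  by hand computation, used as golden tests.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .burden import BurdenItem, BurdenRegistry
from .elicitation import ExpertResponse, ExpertSurvey
from .errors import InputError
from .inference import EvidenceProgram
from .network import CPT, Network, NodeSpec

# RT-field intervention states, as named in the clinical model
RT_FIELD_STATES = (
    "CW/breast alone",
    "CW/breast + high-tangent",
    "CW/breast + IMN/SCL",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generators; the seed fixes every output.

    Expert-panel calibration: each simulated expert reports
    ``estimate = truth + N(0, noise_sd)`` (truncated to [0, 1]) and an interval
    ``estimate +/- ci_half_width``.  The default half-width is
    ``z_{0.975} * noise_sd / sqrt(n_experts)`` so that the *mean-pooled* panel
    interval is an honestly calibrated 95% interval for the panel's pooled
    estimate — the regime the elicitation pipeline is designed to recover.
    """

    seed: int = 0
    topology: str = "ypn1_default"
    n_nodes: int = 8
    state_range: tuple[int, int] = (2, 4)
    dirichlet_concentration: float = 2.0
    edge_prob: float = 0.4
    n_experts: int = 30
    noise_sd: float = 0.05
    ci_half_width: float | None = None
    ci_level: float = 0.95
    extra_arcs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.dirichlet_concentration <= 0:
            raise InputError("dirichlet_concentration must be > 0")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")

    def resolved_half_width(self) -> float:
        if self.ci_half_width is not None:
            return self.ci_half_width
        from scipy.stats import norm

        z = norm.ppf(0.5 + self.ci_level / 2.0)
        return float(z * self.noise_sd / np.sqrt(self.n_experts))


# ---------------------------------------------------------------------------
# default (y)pN1 clinical network

# (name, states, role, parents)
_YPN1_SCHEMA: tuple[tuple[str, tuple[str, ...], str, tuple[str, ...]], ...] = (
    ("chemo_timing", ("adjuvant", "neoadjuvant"), "pretreatment", ()),
    ("mid_nac_progression", ("no", "yes"), "pretreatment", ("chemo_timing",)),
    ("surgery_type", ("BCS", "mastectomy"), "pretreatment", ()),
    ("axillary_surgery", ("SLNBx", "ALND"), "pretreatment", ()),
    ("ln_burden", ("1", "2-3"), "pretreatment", ()),
    ("ece", ("absent", "present"), "pretreatment", ()),
    ("resection_margin", ("negative", "close/positive"), "pretreatment", ()),
    ("lvi", ("absent", "present"), "pretreatment", ()),
    ("ecog", ("0", "1+"), "pretreatment", ()),
    ("subtype", ("non-TNBC", "TNBC"), "pretreatment", ()),
    ("rt_field", RT_FIELD_STATES, "intervention",
     ("surgery_type", "subtype", "axillary_surgery")),
    ("boost", ("no boost", "boost"), "intervention", ()),
    ("fractionation", ("conventional", "hypofractionated"), "intervention", ()),
    ("implant_preservation", ("no implant preservation", "implant-preserving RT"),
     "intervention", ()),
    ("recon_timing", ("immediate", "delayed"), "intervention", ()),
    ("recon_type", ("implant-based", "autologous"), "intervention", ()),
    ("rt_technique", ("3D-CRT/field-in-field", "IMRT/VMAT/Tomo"), "intervention", ()),
    ("dfs_7yr", ("disease-free", "failure"), "outcome",
     ("rt_field", "ln_burden", "ece", "lvi", "mid_nac_progression")),
    ("clinical_lymphedema", ("absent", "present"), "toxicity",
     ("axillary_surgery", "rt_field")),
    ("reconstruction_failure", ("no major failure", "major failure"), "toxicity",
     ("rt_field", "boost", "fractionation", "implant_preservation",
      "recon_timing", "recon_type", "rt_technique")),
    ("rt_pneumonitis", ("absent", "present"), "toxicity", ("rt_field", "fractionation")),
    ("major_cardiac_event", ("absent", "present"), "toxicity", ("rt_field",)),
)


def _dirichlet_cpt(rng: np.random.Generator, n_rows: int, card: int, conc: float) -> np.ndarray:
    return rng.dirichlet(np.full(card, conc), size=n_rows)


def make_ypn1_network(
    cfg: GeneratorConfig | None = None,
    cpt_overrides: Mapping[str, np.ndarray] | None = None,
) -> Network:
    """Generate the default clinical network with seeded Dirichlet CPTs.

    ``extra_arcs`` in the config adds parent->child arcs on top of the default
    schema (CPTs are re-dimensioned accordingly); ``cpt_overrides`` replaces
    whole tables by node name.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    schema = {name: [states, role, list(parents)] for name, states, role, parents in _YPN1_SCHEMA}
    for parent, child in cfg.extra_arcs:
        if parent not in schema or child not in schema:
            raise InputError(f"extra arc ({parent!r}, {child!r}) names unknown nodes")
        if parent not in schema[child][2]:
            schema[child][2].append(parent)

    nodes = [
        NodeSpec(name=name, states=tuple(states), role=role, parents=tuple(parents))
        for name, (states, role, parents) in schema.items()
    ]
    net = Network(nodes, [CPT(n.name, np.zeros((1, n.cardinality))) for n in nodes],
                  metadata={"generator": "ypn1_default", "seed": cfg.seed})
    overrides = dict(cpt_overrides or {})
    for spec in nodes:
        if spec.name in overrides:
            net.replace_cpt(spec.name, overrides[spec.name])
            continue
        n_rows = int(np.prod([len(schema[p][0]) for p in spec.parents])) if spec.parents else 1
        net.replace_cpt(
            spec.name,
            _dirichlet_cpt(rng, n_rows, spec.cardinality, cfg.dirichlet_concentration),
        )
    return net


def default_registry() -> BurdenRegistry:
    """Disability-weight registry for the ypn1 network.

    Weights are plausible defaults on the 0-1 scale (1 = worst possible
    state): disease recurrence dominates, and clinical lymphedema carries a
    higher weight than major cardiac events or reconstruction failure,
    matching its outsized impact on quality of life in expert surveys.
    The DFS benefit enters through its failure state.
    """
    return BurdenRegistry(
        [
            BurdenItem("disease_recurrence", "dfs_7yr", "failure", 0.45),
            BurdenItem("clinical_lymphedema", "clinical_lymphedema", "present", 0.20),
            BurdenItem("major_cardiac_event", "major_cardiac_event", "present", 0.15),
            BurdenItem("reconstruction_failure", "reconstruction_failure",
                       "major failure", 0.12),
            BurdenItem("rt_pneumonitis", "rt_pneumonitis", "present", 0.10),
        ]
    )


# ---------------------------------------------------------------------------
# random networks for oracle sweeps


def make_random_network(
    cfg: GeneratorConfig,
    max_parents: int = 3,
    max_joint_size: int | None = None,
) -> Network:
    """Random DAG (edges only forward in a shuffled order) with Dirichlet CPTs.

    ``max_parents`` bounds CPT width; ``max_joint_size`` (if given) trims state
    counts deterministically until the full joint fits, so the result stays
    within the enumeration oracle's guard during equivalence sweeps.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    names = [f"N{i}" for i in range(n)]
    order = list(rng.permutation(n))
    lo, hi = cfg.state_range
    cards = [int(c) for c in rng.integers(lo, hi + 1, size=n)]
    if max_joint_size is not None:
        while int(np.prod(cards, dtype=np.int64)) > max_joint_size:
            cards[int(np.argmax(cards))] = max(2, max(cards) - 1)
    parents: dict[str, list[str]] = {name: [] for name in names}
    for j_pos in range(1, len(order)):
        child = names[order[j_pos]]
        candidates = [names[order[i_pos]] for i_pos in range(j_pos)]
        chosen = [p for p in candidates if rng.random() < cfg.edge_prob]
        if len(chosen) > max_parents:
            keep = rng.choice(len(chosen), size=max_parents, replace=False)
            chosen = [chosen[k] for k in sorted(keep)]
        parents[child] = chosen
    nodes = []
    cpts = []
    for i, name in enumerate(names):
        card = cards[i]
        states = tuple(f"s{k}" for k in range(card))
        ps = tuple(parents[name])
        nodes.append(NodeSpec(name=name, states=states, role="derived", parents=ps))
        n_rows = int(np.prod([cards[names.index(p)] for p in ps])) if ps else 1
        cpts.append(CPT(name, _dirichlet_cpt(rng, n_rows, card, cfg.dirichlet_concentration)))
    return Network(nodes, cpts, metadata={"generator": "random_dag", "seed": cfg.seed})


def random_evidence_program(
    net: Network, rng: np.random.Generator, allow_mixture: bool = True
) -> EvidenceProgram:
    """Random hard/virtual/do/mixture program over a network (for sweeps)."""
    names = list(net.node_names)
    rng.shuffle(names)
    hard, virtual, do = {}, {}, {}
    for name in names[: max(1, len(names) // 3)]:
        kind = rng.choice(["hard", "virtual", "do", "none"])
        spec = net.node(name)
        if kind == "hard":
            hard[name] = spec.states[rng.integers(spec.cardinality)]
        elif kind == "virtual":
            vec = rng.uniform(0.1, 1.0, size=spec.cardinality)
            virtual[name] = tuple(vec)
        elif kind == "do":
            dist = rng.dirichlet(np.ones(spec.cardinality))
            do[name] = tuple(dist)
    base = EvidenceProgram(hard=hard, virtual=virtual, do=do)
    if allow_mixture and rng.random() < 0.3:
        free = [n for n in net.node_names if n not in base.evidence_nodes()]
        if free:
            node = free[int(rng.integers(len(free)))]
            spec = net.node(node)
            w = float(rng.uniform(0.2, 0.8))
            comp_a = EvidenceProgram(hard={node: spec.states[0]})
            comp_b = EvidenceProgram(do={node: spec.states[-1]})
            return EvidenceProgram(
                hard=hard, virtual=virtual, do=do,
                mixture=[(w, comp_a), (1.0 - w, comp_b)],
            )
    return base


# ---------------------------------------------------------------------------
# simulated expert panels


def make_expert_panel(cfg: GeneratorConfig, truths: Mapping[str, float]) -> ExpertSurvey:
    """Simulate a panel: estimate = truth + truncated Gaussian noise, CI = +/- hw."""
    for qid, t in truths.items():
        if not 0.0 <= t <= 1.0:
            raise InputError(f"truth for {qid!r} is {t!r}, outside [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    hw = cfg.resolved_half_width()
    responses = []
    for e in range(cfg.n_experts):
        for qid, truth in truths.items():
            est = float(np.clip(truth + rng.normal(0.0, cfg.noise_sd), 0.0, 1.0))
            responses.append(
                ExpertResponse(
                    expert_id=f"expert_{e:03d}",
                    quantity_id=qid,
                    estimate=est,
                    ci_low=float(np.clip(est - hw, 0.0, 1.0)),
                    ci_high=float(np.clip(est + hw, 0.0, 1.0)),
                    ci_level=cfg.ci_level,
                )
            )
    return ExpertSurvey.from_responses(responses)


# ---------------------------------------------------------------------------
# golden fixtures


@dataclass(frozen=True)
class Fixture:
    """A tiny network with an evidence program and its exact posterior."""

    name: str
    network: Network
    evidence: EvidenceProgram
    query: str
    expected: Mapping[str, float]
    notes: str = ""


def _net(specs, cpts) -> Network:
    return Network([NodeSpec(*s) for s in specs], cpts)


def make_fixture_suite() -> dict[str, Fixture]:
    """Hand-computed golden fixtures (2-4 nodes) for inference and burden tests."""
    fixtures: dict[str, Fixture] = {}

    # 1. a fair coin, no evidence
    coin = _net(
        [("A", ("0", "1"), "derived", ())],
        {"A": np.array([[0.5, 0.5]])},
    )
    fixtures["coin"] = Fixture(
        "coin", coin, EvidenceProgram(), "A", {"0": 0.5, "1": 0.5},
        notes="prior marginal of an independent fair coin",
    )

    # 2. two-node Bayes flip: P(A=1|B=1) = 0.5*0.9 / (0.5*0.9 + 0.5*0.2) = 9/11
    bayes2 = _net(
        [("A", ("0", "1"), "derived", ()), ("B", ("0", "1"), "derived", ("A",))],
        {"A": np.array([[0.5, 0.5]]), "B": np.array([[0.8, 0.2], [0.1, 0.9]])},
    )
    fixtures["bayes-2node"] = Fixture(
        "bayes-2node", bayes2, EvidenceProgram(hard={"B": "1"}), "A",
        {"0": float(Fraction(2, 11)), "1": float(Fraction(9, 11))},
        notes="hand Bayes: P(A=1|B=1) = .45/.55 = 9/11",
    )

    # 3. three-node chain, evidence on the far end:
    #    P(A=1, C=1) = .3(.8*.7 + .2*.2) = .18 ; P(A=0, C=1) = .7(.1*.7 + .9*.2) = .175
    #    P(A=1 | C=1) = 36/71
    chain = _net(
        [
            ("A", ("0", "1"), "derived", ()),
            ("B", ("0", "1"), "derived", ("A",)),
            ("C", ("0", "1"), "derived", ("B",)),
        ],
        {
            "A": np.array([[0.7, 0.3]]),
            "B": np.array([[0.9, 0.1], [0.2, 0.8]]),
            "C": np.array([[0.8, 0.2], [0.3, 0.7]]),
        },
    )
    fixtures["chain-3node"] = Fixture(
        "chain-3node", chain, EvidenceProgram(hard={"C": "1"}), "A",
        {"0": float(Fraction(35, 71)), "1": float(Fraction(36, 71))},
        notes="hand sum over B: P(A=1|C=1) = .18/.355 = 36/71",
    )

    # 4. collider / explaining away: A,B ~ Bern(.5) independent;
    #    P(C=1|A,B) = .9 unless both 0, else .1.
    #    P(A=1|C=1) = .45/.7 = 9/14 ; P(A=1|C=1,B=1) = 1/2 ; P(A=1|C=1,B=0) = 9/10
    collider = _net(
        [
            ("A", ("0", "1"), "derived", ()),
            ("B", ("0", "1"), "derived", ()),
            ("C", ("0", "1"), "derived", ("A", "B")),
        ],
        {
            "A": np.array([[0.5, 0.5]]),
            "B": np.array([[0.5, 0.5]]),
            # rows: (A=0,B=0), (A=0,B=1), (A=1,B=0), (A=1,B=1)
            "C": np.array([[0.9, 0.1], [0.1, 0.9], [0.1, 0.9], [0.1, 0.9]]),
        },
    )
    fixtures["collider"] = Fixture(
        "collider", collider, EvidenceProgram(hard={"C": "1"}), "A",
        {"0": float(Fraction(5, 14)), "1": float(Fraction(9, 14))},
        notes="explaining away: also P(A=1|C=1,B=1)=1/2, P(A=1|C=1,B=0)=9/10",
    )

    # 5. virtual evidence on a coin: likelihood (1, 2) -> posterior (1/3, 2/3)
    fixtures["virtual-coin"] = Fixture(
        "virtual-coin", coin, EvidenceProgram(virtual={"A": (1.0, 2.0)}), "A",
        {"0": float(Fraction(1, 3)), "1": float(Fraction(2, 3))},
        notes="Pearl virtual evidence: posterior ∝ prior x likelihood",
    )

    # 6. burden fixture: X ~ (.5,.5) -> Y; P(harm|X) = .2/.4 so P(harm) = .3;
    #    with dw = .5 the ODB is .15 (used by the burden tests)
    odbnet = _net(
        [
            ("X", ("0", "1"), "pretreatment", ()),
            ("Y", ("ok", "harm"), "toxicity", ("X",)),
        ],
        {"X": np.array([[0.5, 0.5]]), "Y": np.array([[0.8, 0.2], [0.6, 0.4]])},
    )
    fixtures["odb-2node"] = Fixture(
        "odb-2node", odbnet, EvidenceProgram(), "Y", {"ok": 0.7, "harm": 0.3},
        notes="P(harm) = .5*.2 + .5*.4 = .3; dw .5 gives ODB .15",
    )

    return fixtures
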