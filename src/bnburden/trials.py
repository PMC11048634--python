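"""In-silico trial arms, arm comparisons, and one-way sensitivity tables.

A trial arm is an :class:`~bnburden.inference.EvidenceProgram`; randomised
interventions use do-assignments so that arm assignment cannot alter
pretreatment marginals, observed population constraints use hard evidence,
and arms defined as blends of treatment states use mixtures.  Four built-in
templates express the ongoing (y)pN1 breast-cancer RT trials the model was
designed around — Alliance A011202, PORT-N1, RAPCHEM, RT-CHARM — as *data*
over the default clinical network schema, so new trials are config, not code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import BurdenRegistry, ODBResult, compute_odb
from .errors import InputError, SchemaMismatchError
from .inference import EvidenceProgram, posterior_enumeration, posterior_ve
from .network import Network

_ENGINES = {"ve": posterior_ve, "enumeration": posterior_enumeration}


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ArmSpec:
    """One trial arm: a name, its evidence program, endpoints to report."""

    name: str
    evidence: EvidenceProgram
    endpoints: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "endpoints", tuple((n, s) for n, s in self.endpoints))


@dataclass(frozen=True)
class TrialSpec:
    """A named set of >= 2 arms over one network, plus shared evidence."""

    name: str
    arms: tuple[ArmSpec, ...]
    shared_evidence: EvidenceProgram = field(default_factory=EvidenceProgram)

    def __post_init__(self):
        object.__setattr__(self, "arms", tuple(self.arms))
        if len(self.arms) < 2:
            raise InputError(f"trial {self.name!r} needs at least 2 arms")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise InputError(f"trial {self.name!r} has duplicate arm names")


@dataclass(frozen=True)
class SensitivitySpec:
    """A one-way sensitivity study: base evidence, scenarios, a target state."""

    name: str
    base: EvidenceProgram
    scenarios: tuple[tuple[str, tuple[tuple[str, str], ...]], ...]  # (label, ((node, state), ...))
    target: tuple[str, str]


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class ArmReport:
    name: str
    endpoints: Mapping[tuple[str, str], float]
    odb: ODBResult


class TrialResult:
    """Per-arm endpoint posteriors and ODB, with pairwise comparisons.

    ``summary()`` renders the arm table; ``comparisons()`` reports, for every
    ordered arm pair and endpoint, the absolute difference and the ratio
    (fold change) of the posteriors.
    """

    def __init__(self, trial: TrialSpec, arms: Sequence[ArmReport]):
        self.trial = trial
        self.arms: dict[str, ArmReport] = {a.name: a for a in arms}

    def summary(self) -> pd.DataFrame:
        rows = []
        for arm in self.arms.values():
            row: dict[str, object] = {
                "arm": arm.name,
                "odb": arm.odb.odb,
                "healthy_pct": arm.odb.healthy_pct,
            }
            for (node, state), p in arm.endpoints.items():
                row[f"P({node}={state})"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def comparisons(self) -> pd.DataFrame:
        names = list(self.arms)
        rows = []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                ra, rb = self.arms[a], self.arms[b]
                for key in ra.endpoints:
                    pa, pb = ra.endpoints[key], rb.endpoints[key]
                    rows.append(
                        {
                            "arm_a": a,
                            "arm_b": b,
                            "endpoint": f"{key[0]}={key[1]}",
                            "p_a": pa,
                            "p_b": pb,
                            "difference": pa - pb,
                            "ratio": pa / pb if pb > 0 else np.inf,
                        }
                    )
                rows.append(
                    {
                        "arm_a": a,
                        "arm_b": b,
                        "endpoint": "ODB",
                        "p_a": ra.odb.odb,
                        "p_b": rb.odb.odb,
                        "difference": ra.odb.odb - rb.odb.odb,
                        "ratio": ra.odb.odb / rb.odb.odb if rb.odb.odb > 0 else np.inf,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "trial": self.trial.name,
            "arms": {
                name: {
                    "odb": rep.odb.odb,
                    "healthy_pct": rep.odb.healthy_pct,
                    "endpoints": {
                        f"{n}={s}": p for (n, s), p in rep.endpoints.items()
                    },
                    "per_item": {
                        oid: {"posterior": p, "contribution": c}
                        for oid, (p, c) in rep.odb.per_item.items()
                    },
                }
                for name, rep in self.arms.items()
            },
        }


class PosteriorTable:
    """Scenario-by-scenario posterior of one target state, sorted descending."""

    def __init__(self, target: tuple[str, str], rows: Sequence[tuple[str, float]]):
        self.target = target
        frame = pd.DataFrame(rows, columns=["scenario", "posterior"])
        self.frame = frame.sort_values(
            "posterior", ascending=False, kind="stable"
        ).reset_index(drop=True)

    def formatted(self) -> pd.DataFrame:
        """Posterior rendered as a percentage at two decimals."""
        out = self.frame.copy()
        out["posterior"] = out["posterior"].map(lambda p: f"{100 * p:.2f}%")
        return out

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# engine


def _arm_program(trial: TrialSpec, arm: ArmSpec) -> EvidenceProgram:
    try:
        return trial.shared_evidence.merged_with(arm.evidence)
    except InputError as exc:
        raise InputError(f"arm {arm.name!r}: {exc}") from exc


def run_trial(
    net: Network,
    trial: TrialSpec,
    registry: BurdenRegistry,
    engine: str = "ve",
) -> TrialResult:
    """Evaluate every arm under shared + arm evidence; report endpoints and ODB."""
    post = _ENGINES[engine]
    reports = []
    for arm in trial.arms:
        ev = _arm_program(trial, arm)
        endpoints = {
            (node, state): post(net, ev, node).prob(state)
            for node, state in arm.endpoints
        }
        odb = compute_odb(net, ev, registry, engine=engine)
        reports.append(ArmReport(name=arm.name, endpoints=endpoints, odb=odb))
    return TrialResult(trial, reports)


def one_way_sensitivity(
    net: Network,
    base_ev: EvidenceProgram,
    scenarios: Sequence[tuple[str, Sequence[tuple[str, str]]]],
    target: tuple[str, str],
    engine: str = "ve",
    include_base: bool = True,
) -> PosteriorTable:
    """P(target | base + scenario) for each scenario; table sorted descending.

    Each scenario is ``(label, [(node, state), ...])`` — one or several
    single-node hard-evidence deltas applied on top of the base program.
    A scenario touching a node already hard-evidenced in the base is an error.
    """
    post = _ENGINES[engine]
    tnode, tstate = target
    rows: list[tuple[str, float]] = []
    if include_base:
        rows.append(("base", post(net, base_ev, tnode).prob(tstate)))
    for label, settings in scenarios:
        overlay = EvidenceProgram(hard=dict(settings))
        try:
            ev = base_ev.merged_with(overlay)
        except InputError as exc:
            raise InputError(f"scenario {label!r}: {exc}") from exc
        rows.append((label, post(net, ev, tnode).prob(tstate)))
    return PosteriorTable(target, rows)


# ---------------------------------------------------------------------------
# built-in templates for the four (y)pN1 trials

#: node -> states the templates rely on (the ypn1_default schema)
TEMPLATE_SCHEMA: dict[str, tuple[str, ...]] = {
    "chemo_timing": ("adjuvant", "neoadjuvant"),
    "mid_nac_progression": ("no", "yes"),
    "surgery_type": ("BCS", "mastectomy"),
    "axillary_surgery": ("SLNBx", "ALND"),
    "rt_field": (
        "CW/breast alone",
        "CW/breast + high-tangent",
        "CW/breast + IMN/SCL",
    ),
    "boost": ("no boost", "boost"),
    "fractionation": ("conventional", "hypofractionated"),
    "implant_preservation": ("no implant preservation", "implant-preserving RT"),
    "recon_timing": ("immediate", "delayed"),
    "recon_type": ("implant-based", "autologous"),
    "rt_technique": ("3D-CRT/field-in-field", "IMRT/VMAT/Tomo"),
    "dfs_7yr": ("disease-free", "failure"),
    "clinical_lymphedema": ("absent", "present"),
    "reconstruction_failure": ("no major failure", "major failure"),
}

_ENDPOINTS = (
    ("dfs_7yr", "disease-free"),
    ("clinical_lymphedema", "present"),
)


def check_template_schema(net: Network, nodes: Sequence[str]) -> None:
    missing = []
    for name in nodes:
        if name not in net:
            missing.append(name)
            continue
        spec = net.node(name)
        for state in TEMPLATE_SCHEMA[name]:
            if state not in spec.states:
                missing.append(f"{name}:{state}")
    if missing:
        raise SchemaMismatchError(missing)


def builtin_trial_templates() -> dict[str, TrialSpec | SensitivitySpec]:
    """The four built-in trial templates, keyed by short name.

    * ``alliance_a011202`` — SLNBx + full RNI vs ALND + a 50/50 mixture of
      high-tangent and IMN/SCL fields (the blended comparator arm).
    * ``port_n1`` — RT de-escalation: full field vs breast/CW alone, with the
      shared protocol constraint that mid-NAC outcomes are "no".
    * ``rapchem`` — the 2 axillary-surgery strata x 3 RT-field grid (six
      rows, as in the published risk-group comparison).
    * ``rt_charm`` — one-way sensitivity of major reconstruction failure to
      boost, fractionation, implant preservation, reconstruction timing,
      reconstruction type and RT technique.
    """
    f_alone, f_tangent, f_full = TEMPLATE_SCHEMA["rt_field"]

    alliance = TrialSpec(
        name="alliance_a011202",
        shared_evidence=EvidenceProgram(hard={"chemo_timing": "neoadjuvant"}),
        arms=(
            ArmSpec(
                name="SLNBx + IMN/SCL",
                evidence=EvidenceProgram(
                    do={"axillary_surgery": "SLNBx", "rt_field": f_full}
                ),
                endpoints=_ENDPOINTS,
            ),
            ArmSpec(
                name="ALND + mixed field",
                evidence=EvidenceProgram(
                    do={"axillary_surgery": "ALND"},
                    mixture=[
                        (0.5, EvidenceProgram(do={"rt_field": f_tangent})),
                        (0.5, EvidenceProgram(do={"rt_field": f_full})),
                    ],
                ),
                endpoints=_ENDPOINTS,
            ),
        ),
    )

    port_n1 = TrialSpec(
        name="port_n1",
        shared_evidence=EvidenceProgram(hard={"mid_nac_progression": "no"}),
        arms=(
            ArmSpec(
                name="control (PMRT or WBI+RNI)",
                evidence=EvidenceProgram(do={"rt_field": f_full}),
                endpoints=_ENDPOINTS,
            ),
            ArmSpec(
                name="experimental (no PMRT or WBI alone)",
                evidence=EvidenceProgram(do={"rt_field": f_alone}),
                endpoints=_ENDPOINTS,
            ),
        ),
    )

    rapchem_arms = []
    for stratum, axilla in (("intermediate", "ALND"), ("intermediate-or-high", "SLNBx")):
        for label, fld in (
            ("whole breast/CW", f_alone),
            ("whole breast/CW + level I/II", f_tangent),
            ("whole breast/CW + full regional", f_full),
        ):
            rapchem_arms.append(
                ArmSpec(
                    name=f"{stratum} | {label}",
                    evidence=EvidenceProgram(
                        hard={"axillary_surgery": axilla}, do={"rt_field": fld}
                    ),
                    endpoints=(("dfs_7yr", "disease-free"),),
                )
            )
    rapchem = TrialSpec(name="rapchem", arms=tuple(rapchem_arms))

    recon_factors = (
        "boost",
        "fractionation",
        "implant_preservation",
        "recon_timing",
        "recon_type",
        "rt_technique",
    )
    scenarios = tuple(
        (f"{node}={state}", ((node, state),))
        for node in recon_factors
        for state in TEMPLATE_SCHEMA[node]
    )
    rt_charm = SensitivitySpec(
        name="rt_charm",
        base=EvidenceProgram(
            hard={"surgery_type": "mastectomy"}, do={"rt_field": f_full}
        ),
        scenarios=scenarios,
        target=("reconstruction_failure", "major failure"),
    )

    return {
        "alliance_a011202": alliance,
        "port_n1": port_n1,
        "rapchem": rapchem,
        "rt_charm": rt_charm,
    }


def run_template(
    net: Network,
    name: str,
    registry: BurdenRegistry,
    engine: str = "ve",
) -> TrialResult | PosteriorTable:
    """Run a built-in template against a schema-compatible network."""
    templates = builtin_trial_templates()
    if name not in templates:
        raise InputError(f"unknown template {name!r}; have {sorted(templates)}")
    spec = templates[name]
    if isinstance(spec, SensitivitySpec):
        needed = {spec.target[0]} | {n for _, s in spec.scenarios for n, _ in s}
        needed |= spec.base.evidence_nodes()
        check_template_schema(net, sorted(needed & set(TEMPLATE_SCHEMA)))
        return one_way_sensitivity(net, spec.base, spec.scenarios, spec.target, engine=engine)
    needed = set()
    for arm in spec.arms:
        needed |= arm.evidence.evidence_nodes()
        needed |= {n for n, _ in arm.endpoints}
    needed |= spec.shared_evidence.evidence_nodes()
    check_template_schema(net, sorted(needed & set(TEMPLATE_SCHEMA)))
    return run_trial(net, spec, registry, engine=engine)


# ---------------------------------------------------------------------------
# declarative config


def trial_from_dict(doc: Mapping) -> TrialSpec:
    return TrialSpec(
        name=doc["name"],
        shared_evidence=EvidenceProgram.from_dict(doc.get("shared_evidence", {})),
        arms=tuple(
            ArmSpec(
                name=a["name"],
                evidence=EvidenceProgram.from_dict(a.get("evidence", {})),
                endpoints=tuple((e[0], e[1]) for e in a.get("endpoints", [])),
            )
            for a in doc["arms"]
        ),
    )


def load_trial(path: str | Path) -> TrialSpec:
    """Load a trial spec from a JSON config (schema in docs/schemas)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return trial_from_dict(doc)
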