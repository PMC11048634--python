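"""Overall disease burden (ODB) and the likelihood of being healthy.

ODB is the sum, over a registry of RT-related risks and benefits, of
``disability_weight x P(harm_state | evidence)``.  Disability weights are
expert-elicited severities on [0, 1] (1 = worst possible state, Global Burden
of Disease style).  A pure-benefit endpoint such as 7-year disease-free
survival enters through its *failure* state — the registry names the harm
state explicitly rather than hard-coding that convention.

The likelihood of being healthy is the linear transform ``100 x (1 - ODB)``,
reported as a percentage at one decimal.  An ODB above 1 is theoretically
possible with many registry items; the stored value is never clamped, only
the displayed percentage is floored at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .elicitation import apply_cpt_values
from .errors import InputError
from .inference import EvidenceProgram, posterior_enumeration, posterior_ve
from .network import Network

_ENGINES = {"ve": posterior_ve, "enumeration": posterior_enumeration}


@dataclass(frozen=True)
class BurdenItem:
    """One registered risk/benefit: an outcome node, its harm state, a weight."""

    outcome_id: str
    node: str
    harm_state: str
    dw: float
    dw_beta: tuple[float, float] | None = None

    def __post_init__(self):
        if not 0.0 <= self.dw <= 1.0:
            raise InputError(f"disability weight {self.dw!r} outside [0, 1]")


@dataclass(frozen=True)
class BurdenRegistry:
    items: tuple[BurdenItem, ...]

    def __init__(self, items: Sequence[BurdenItem]):
        object.__setattr__(self, "items", tuple(items))
        ids = [i.outcome_id for i in self.items]
        if len(set(ids)) != len(ids):
            raise InputError("outcome_ids must be unique")
        nodes = [i.node for i in self.items]
        if len(set(nodes)) != len(nodes):
            raise InputError("registry nodes must be distinct")

    def check_against(self, net: Network) -> None:
        for item in self.items:
            spec = net.node(item.node)  # raises InputError if missing
            spec.state_index(item.harm_state)
            if spec.role not in ("outcome", "toxicity"):
                raise InputError(
                    f"registry node {item.node!r} has role {spec.role!r}; "
                    "must be outcome or toxicity"
                )

    def with_weights(self, weights: Mapping[str, float]) -> "BurdenRegistry":
        """Copy with disability weights replaced by ``outcome_id -> dw``."""
        return BurdenRegistry(
            [
                BurdenItem(
                    outcome_id=i.outcome_id,
                    node=i.node,
                    harm_state=i.harm_state,
                    dw=float(weights.get(i.outcome_id, i.dw)),
                    dw_beta=i.dw_beta,
                )
                for i in self.items
            ]
        )

    def to_list(self) -> list[dict]:
        return [
            {
                "outcome_id": i.outcome_id,
                "node": i.node,
                "harm_state": i.harm_state,
                "dw": i.dw,
                **({"dw_beta": list(i.dw_beta)} if i.dw_beta else {}),
            }
            for i in self.items
        ]

    @classmethod
    def from_list(cls, data: Sequence[Mapping]) -> "BurdenRegistry":
        return cls(
            [
                BurdenItem(
                    outcome_id=d["outcome_id"],
                    node=d["node"],
                    harm_state=d["harm_state"],
                    dw=float(d["dw"]),
                    dw_beta=tuple(d["dw_beta"]) if d.get("dw_beta") else None,
                )
                for d in data
            ]
        )


@dataclass(frozen=True)
class ODBResult:
    """ODB with per-item decomposition and the healthy-likelihood transform."""

    odb: float
    healthy_pct: float
    per_item: Mapping[str, tuple[float, float]]  # outcome_id -> (posterior, contribution)
    uncertainty: tuple[float, float, float] | None = None  # (mean, 2.5%, 97.5%)

    def summary_rows(self) -> list[dict]:
        rows = [
            {
                "outcome_id": oid,
                "posterior": p,
                "contribution": c,
            }
            for oid, (p, c) in self.per_item.items()
        ]
        return rows

    def display_healthy(self) -> str:
        return f"{max(self.healthy_pct, 0.0):.1f}%"


def healthy_likelihood(odb: float) -> float:
    """``100 x (1 - ODB)`` — the likelihood of being healthy, in percent.

    Negative ODB is an input error; ODB above 1 warns (the linear transform
    then goes negative, floored only at display time).
    """
    if odb < 0.0:
        raise InputError(f"ODB must be non-negative, got {odb!r}")
    if odb > 1.0:
        warnings.warn(
            f"ODB {odb} exceeds 1; likelihood of being healthy is negative "
            "and will display as 0%",
            stacklevel=2,
        )
    return 100.0 * (1.0 - odb)


def compute_odb(
    net: Network,
    ev: EvidenceProgram,
    registry: BurdenRegistry,
    engine: str = "ve",
) -> ODBResult:
    """ODB = sum of dw x P(harm_state | evidence) over the registry."""
    registry.check_against(net)
    post = _ENGINES[engine]
    per_item: dict[str, tuple[float, float]] = {}
    odb = 0.0
    for item in registry.items:
        p = post(net, ev, item.node).prob(item.harm_state)
        contribution = item.dw * p
        per_item[item.outcome_id] = (p, contribution)
        odb += contribution
    return ODBResult(odb=odb, healthy_pct=healthy_likelihood(odb), per_item=per_item)


def odb_uncertainty(
    net: Network,
    ev: EvidenceProgram,
    registry: BurdenRegistry,
    samples: pd.DataFrame,
    engine: str = "ve",
) -> tuple[float, float, float]:
    """Monte-Carlo propagation of elicited uncertainty into ODB.

    ``samples`` is a parameter-draw table from
    :func:`bnburden.elicitation.draw_parameters`: one row per draw, columns
    named by quantity id (``cpt:...`` cells substituted into the network,
    ``dw:<outcome_id>`` into the registry).  Returns ``(mean, 2.5%, 97.5%)``
    of the per-draw ODB.  Reproducibility comes from the seed used to draw
    ``samples``; this function is deterministic given the table.
    """
    registry.check_against(net)
    dw_cols = {c for c in samples.columns if c.startswith("dw:")}
    cpt_cols = [c for c in samples.columns if c.startswith("cpt:")]
    registry_betas = {f"dw:{i.outcome_id}" for i in registry.items if i.dw_beta}
    missing = registry_betas - dw_cols
    if missing:
        raise InputError(f"sample table missing disability-weight draws {sorted(missing)}")

    draws = np.empty(len(samples))
    for k, (_, row) in enumerate(samples.iterrows()):
        net_k = apply_cpt_values(net, {c: row[c] for c in cpt_cols}) if cpt_cols else net
        weights = {c[3:]: float(row[c]) for c in dw_cols}
        reg_k = registry.with_weights(weights) if weights else registry
        draws[k] = compute_odb(net_k, ev, reg_k, engine=engine).odb
    return (
        float(draws.mean()),
        float(np.quantile(draws, 0.025)),
        float(np.quantile(draws, 0.975)),
    )
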