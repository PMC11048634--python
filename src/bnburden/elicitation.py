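"""Turn multi-expert survey responses into model parameters with uncertainty.

Each expert reports, per quantity (a CPT cell or a disability weight), a point
estimate in [0, 1] and a confidence interval.  Quantities are named with a
small grammar::

    cpt:<node>|<parent=state,...>|<state>    a CPT cell (no parents: cpt:<node>||<state>)
    dw:<outcome_id>                          a disability weight

Aggregation is a linear opinion pool: the pooled point is the arithmetic mean
(default; median available) of the expert estimates, and the pooled CI bounds
are the same statistic applied to the expert bounds.  The pooled interval is
then converted to a Beta distribution by equal-tailed quantile matching — the
(alpha, beta) whose ci_level quantiles reproduce the pooled bounds — because
every elicited quantity lives on [0, 1].  Intervals a Beta cannot match (e.g.
degenerate or spanning the whole unit interval) fall back to a PERT-style fit
from (point, low, high) with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ElicitationWarning, InputError

QUANTILE_MATCH_TOL = 1e-6

SURVEY_COLUMNS = ["expert_id", "quantity_id", "estimate", "ci_low", "ci_high", "ci_level"]


@dataclass(frozen=True)
class ExpertResponse:
    """One expert's answer for one quantity."""

    expert_id: str
    quantity_id: str
    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95

    def __post_init__(self):
        for name in ("estimate", "ci_low", "ci_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v!r} outside [0, 1] (expert {self.expert_id})")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise InputError(
                f"interval ordering violated for expert {self.expert_id}: "
                f"{self.ci_low} <= {self.estimate} <= {self.ci_high} fails"
            )
        if not 0.0 < self.ci_level < 1.0:
            raise InputError(f"ci_level={self.ci_level!r} must be in (0, 1)")


@dataclass(frozen=True)
class PooledEstimate:
    quantity_id: str
    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_experts: int


@dataclass(frozen=True)
class ElicitedQuantity:
    """A pooled quantity with a fitted Beta uncertainty distribution."""

    quantity_id: str
    pooled_estimate: float
    alpha: float
    beta: float
    n_experts: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    ci_level: float = 0.95

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise InputError("Beta parameters must be finite")
        if self.alpha <= 0 or self.beta <= 0:
            raise InputError("Beta parameters must be positive")
        if not 0.0 <= self.pooled_estimate <= 1.0:
            raise InputError("pooled estimate outside [0, 1]")

    def interval(self, level: float | None = None) -> tuple[float, float]:
        level = self.ci_level if level is None else level
        tail = (1.0 - level) / 2.0
        d = stats.beta(self.alpha, self.beta)
        return float(d.ppf(tail)), float(d.ppf(1.0 - tail))


class ExpertSurvey:
    """Container for a multi-expert survey table (one row per response)."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in SURVEY_COLUMNS if c not in frame.columns]
        if missing:
            raise InputError(f"survey table missing columns {missing}")
        self.frame = frame[SURVEY_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_responses(cls, responses: Iterable[ExpertResponse]) -> "ExpertSurvey":
        rows = [
            (r.expert_id, r.quantity_id, r.estimate, r.ci_low, r.ci_high, r.ci_level)
            for r in responses
        ]
        return cls(pd.DataFrame(rows, columns=SURVEY_COLUMNS))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpertSurvey":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def quantity_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["quantity_id"]))

    def responses_for(self, quantity_id: str) -> list[ExpertResponse]:
        sub = self.frame[self.frame["quantity_id"] == quantity_id]
        return [
            ExpertResponse(
                expert_id=str(r.expert_id),
                quantity_id=str(r.quantity_id),
                estimate=float(r.estimate),
                ci_low=float(r.ci_low),
                ci_high=float(r.ci_high),
                ci_level=float(r.ci_level),
            )
            for r in sub.itertuples()
        ]


# ---------------------------------------------------------------------------
# pooling


def pool_experts(
    responses: Sequence[ExpertResponse], method: str = "mean"
) -> PooledEstimate:
    """Linear opinion pool of one quantity's responses.

    The pooled point and the pooled CI bounds are the mean (or median) of the
    corresponding expert values, clamped to [0, 1].  Pooling is permutation
    invariant in expert order.
    """
    if not responses:
        raise InputError("pool_experts needs at least one response")
    qids = {r.quantity_id for r in responses}
    if len(qids) != 1:
        raise InputError(f"responses mix quantity_ids {sorted(qids)}")
    levels = {r.ci_level for r in responses}
    if len(levels) != 1:
        raise InputError(f"responses mix ci_levels {sorted(levels)}")
    if method == "mean":
        stat = np.mean
    elif method == "median":
        stat = np.median
    else:
        raise InputError(f"unknown pooling method {method!r}; use 'mean' or 'median'")

    clip = lambda x: float(np.clip(x, 0.0, 1.0))
    return PooledEstimate(
        quantity_id=responses[0].quantity_id,
        estimate=clip(stat([r.estimate for r in responses])),
        ci_low=clip(stat([r.ci_low for r in responses])),
        ci_high=clip(stat([r.ci_high for r in responses])),
        ci_level=responses[0].ci_level,
        n_experts=len(responses),
    )


# ---------------------------------------------------------------------------
# CI -> Beta


def _pert_fallback(point: float) -> tuple[float, float]:
    # PERT on [0,1] with mode at the point estimate and concentration 4
    return 1.0 + 4.0 * point, 1.0 + 4.0 * (1.0 - point)


def ci_to_beta(
    point: float, ci_low: float, ci_high: float, ci_level: float = 0.95
) -> tuple[float, float]:
    """Fit Beta(alpha, beta) whose equal-tailed ``ci_level`` quantiles match the CI.

    Deterministic two-parameter root finding in (log alpha, log beta); the
    fitted quantiles reproduce (ci_low, ci_high) within ``1e-6``.  Infeasible
    intervals — degenerate width, bounds pinned to 0/1, or no Beta achieving
    the match — fall back to a PERT-style fit from the point estimate and emit
    an :class:`ElicitationWarning`.
    """
    if not (0.0 <= ci_low <= 1.0 and 0.0 <= ci_high <= 1.0):
        raise InputError("CI bounds must lie in [0, 1]")
    if ci_low >= ci_high:
        raise InputError(f"ci_low ({ci_low}) must be < ci_high ({ci_high})")
    if not 0.0 < ci_level < 1.0:
        raise InputError("ci_level must be in (0, 1)")

    tail = (1.0 - ci_level) / 2.0

    if ci_low <= 0.0 or ci_high >= 1.0:
        warnings.warn(
            f"interval ({ci_low}, {ci_high}) cannot be matched exactly by Beta "
            "quantiles; using PERT-style fallback",
            ElicitationWarning,
            stacklevel=2,
        )
        return _pert_fallback(point)

    # moment-matched starting values from a normal approximation of the CI
    z = stats.norm.ppf(1.0 - tail)
    mu = 0.5 * (ci_low + ci_high)
    sigma = max((ci_high - ci_low) / (2.0 * z), 1e-6)
    nu = max(mu * (1.0 - mu) / sigma**2 - 1.0, 1e-2)
    x0 = np.log([max(mu * nu, 1e-3), max((1.0 - mu) * nu, 1e-3)])

    def residual(x: np.ndarray) -> np.ndarray:
        a, b = np.exp(x)
        return np.array(
            [
                stats.beta.ppf(tail, a, b) - ci_low,
                stats.beta.ppf(1.0 - tail, a, b) - ci_high,
            ]
        )

    sol = optimize.root(residual, x0, method="hybr", tol=1e-14)
    res = residual(sol.x)
    if np.max(np.abs(res)) <= QUANTILE_MATCH_TOL:
        a, b = np.exp(sol.x)
        return float(a), float(b)

    warnings.warn(
        f"quantile matching failed for interval ({ci_low}, {ci_high}) at level "
        f"{ci_level} (residual {np.max(np.abs(res)):.3g}); using PERT-style fallback",
        ElicitationWarning,
        stacklevel=2,
    )
    return _pert_fallback(point)


def elicit(survey: ExpertSurvey, method: str = "mean") -> list[ElicitedQuantity]:
    """Pool every quantity in a survey and fit its Beta uncertainty."""
    out = []
    for qid in survey.quantity_ids:
        pooled = pool_experts(survey.responses_for(qid), method=method)
        if pooled.ci_low >= pooled.ci_high:
            # degenerate pooled interval (e.g. zero half-width surveys):
            # no Beta can match it, take the PERT fallback directly
            warnings.warn(
                f"degenerate pooled interval for {qid!r} "
                f"({pooled.ci_low}, {pooled.ci_high}); using PERT-style fallback",
                ElicitationWarning,
                stacklevel=2,
            )
            a, b = _pert_fallback(pooled.estimate)
        else:
            a, b = ci_to_beta(
                pooled.estimate, pooled.ci_low, pooled.ci_high, pooled.ci_level
            )
        out.append(
            ElicitedQuantity(
                quantity_id=qid,
                pooled_estimate=pooled.estimate,
                alpha=a,
                beta=b,
                n_experts=pooled.n_experts,
                ci_low=pooled.ci_low,
                ci_high=pooled.ci_high,
                ci_level=pooled.ci_level,
            )
        )
    return out


# ---------------------------------------------------------------------------
# parameter draws


def draw_parameters(
    quantities: Sequence[ElicitedQuantity], n_draws: int, seed: int
) -> pd.DataFrame:
    """Seeded independent Beta draws, one column per quantity, one row per draw."""
    if n_draws < 1:
        raise InputError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    data = {
        q.quantity_id: rng.beta(q.alpha, q.beta, size=n_draws) for q in quantities
    }
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# quantity-id grammar


def parse_quantity_id(qid: str):
    """Parse ``cpt:<node>|<parent=state,...>|<state>`` or ``dw:<outcome_id>``.

    Returns ``("dw", outcome_id)`` or ``("cpt", node, {parent: state}, state)``.
    """
    if qid.startswith("dw:"):
        outcome = qid[3:]
        if not outcome:
            raise InputError(f"empty outcome id in {qid!r}")
        return ("dw", outcome)
    if qid.startswith("cpt:"):
        body = qid[4:]
        parts = body.split("|")
        if len(parts) != 3:
            raise InputError(
                f"bad cpt quantity {qid!r}; expected cpt:<node>|<parent=state,...>|<state>"
            )
        node, cond, state = parts
        if not node or not state:
            raise InputError(f"bad cpt quantity {qid!r}: empty node or state")
        assignment: dict[str, str] = {}
        if cond:
            for item in cond.split(","):
                if "=" not in item:
                    raise InputError(f"bad parent assignment {item!r} in {qid!r}")
                p, s = item.split("=", 1)
                assignment[p] = s
        return ("cpt", node, assignment, state)
    raise InputError(f"quantity id {qid!r} must start with 'cpt:' or 'dw:'")


def apply_cpt_values(net, values: Mapping[str, float]):
    """Return a copy of ``net`` with elicited CPT cells substituted.

    ``values`` maps ``cpt:...`` quantity ids to probabilities (``dw:`` entries
    are ignored here; the burden registry consumes them).  For a binary node
    with a single elicited cell in a row, the complement state is derived;
    rows with several independently drawn cells are renormalised — declared,
    testable behaviour for multi-state rows.
    """
    out = net.copy()
    touched: dict[tuple[str, int], dict[int, float]] = {}
    for qid, value in values.items():
        parsed = parse_quantity_id(qid)
        if parsed[0] != "cpt":
            continue
        _, node, assignment, state = parsed
        spec = out.node(node)
        extra = set(assignment) - set(spec.parents)
        if extra:
            raise InputError(f"{qid!r} conditions on non-parents {sorted(extra)}")
        row = out.row_index(node, assignment)
        col = spec.state_index(state)
        touched.setdefault((node, row), {})[col] = float(value)

    for (node, row), cells in touched.items():
        spec = out.node(node)
        tab = out.cpt(node).copy()
        if spec.cardinality == 2 and len(cells) == 1:
            ((col, v),) = cells.items()
            tab[row, col] = v
            tab[row, 1 - col] = 1.0 - v
        else:
            for col, v in cells.items():
                tab[row, col] = v
            total = tab[row].sum()
            if total <= 0:
                raise InputError(f"row {row} of {node!r} sums to zero after substitution")
            tab[row] = tab[row] / total
        out.replace_cpt(node, tab)
    return out
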