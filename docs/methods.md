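# Methods

## Model

The package operates on discrete Bayesian networks with clinical role tags
(`pretreatment`, `intervention`, `outcome`, `toxicity`, `derived`).  The
joint distribution is the product of per-node conditional probability tables
(CPTs).  CPT rows enumerate parent-state combinations in the declared parent
order with the **last parent varying fastest** (C-order); this layout is
fixed by convention because no table layout is canonical across tools, and it
coincides with the XMLBIF table ordering, so serialization is a flat reshape.

Rows must sum to 1 within 1e-9.  Rows failing the tolerance are rejected
rather than renormalized: a non-normalized row almost always indicates an
elicitation or transcription error, and silent repair would mask it.
Probabilities are stored at full float64 precision; rounding (one decimal for
burden-derived percentages, two decimals for posterior tables) happens only
in report rendering.

## Inference

Two exact engines share a single contract.

* **Enumeration** materialises the full joint as a dense array (a sequence
  of broadcast multiplications of the CPTs) and marginalises.  It is guarded
  to joints of at most 2^22 cells (~22 binary-equivalent nodes, 32 MiB) and
  exists primarily as the independent oracle for the second engine.
* **Variable elimination** multiplies and sums out factors along a greedy
  min-fill elimination order with lexicographic tie-breaking, making runs
  fully deterministic.

Evidence semantics:

* *Hard* evidence reduces every factor mentioning the node.
* *Virtual* evidence multiplies in a single-node likelihood factor (Pearl's
  construction); the all-ones vector is uninformative, and a one-hot vector
  reproduces hard evidence exactly.
* *Do* assignments perform graph surgery: incoming arcs severed, CPT
  replaced by the assigned distribution.  This is how randomized arm
  assignment is modelled — observing or setting the intervened node then
  carries no information about its former ancestors, so pretreatment
  marginals are provably identical across arms.  Plain conditioning on the
  intervention node does change ancestor marginals, which is why arm
  assignment must not be encoded as observation.
* *Mixtures* — arms defined as weighted blends of treatment states — are the
  weight-convex combination of component posteriors.  Top-level evidence is
  pushed into each component; a component that hard-fixes the query state
  contributes the corresponding point mass.  Mixtures nest one level only:
  that expresses every blended arm the package targets while keeping the
  semantics auditable.

The proprietary "likelihood matching" arm-evaluation mechanism of the
commercial tool the original model was built in is undocumented; this
package declares its emulation openly as hard evidence + do-assignment +
mixtures, and verifies the two behaviours that characterise it (fixed
pretreatment marginals across arms; blended arms as convex combinations).

Evidence with probability zero raises an explicit inconsistent-evidence
error instead of returning NaN distributions.

## Elicitation

Each expert reports, per quantity (CPT cell `cpt:<node>|<parents>|<state>` or
disability weight `dw:<id>`), a point estimate and a confidence interval on
[0, 1].  Aggregation is a linear opinion pool: pooled point and pooled CI
bounds are the arithmetic mean (default; median available) of the expert
values, clamped to [0, 1].  The published work does not state its pooling
rule, so the choice is exposed as an option rather than hard-coded.

The pooled interval is converted to a Beta distribution by equal-tailed
quantile matching: deterministic root finding in (log α, log β) from a
normal-approximation start, accepted when both quantiles match within 1e-6.
Beta is the natural family because every elicited quantity is a probability
or a probability-like weight on [0, 1].  Infeasible intervals (degenerate
width, bounds pinned to 0 or 1, or no achievable match) fall back to a
PERT-style fit `α = 1 + 4·point, β = 1 + 4·(1 − point)` with a warning.

For binary nodes only the "present" cell is elicited and the complement is
derived; multi-state rows assembled from independently drawn cells are
renormalized per row — declared, testable behaviour.

Parameter uncertainty is propagated by seeded independent Beta draws per
quantity; the burden module recomputes ODB per draw and summarises
(mean, 2.5%, 97.5%).

### Simulated panels

The panel generator emulates the elicitation setting with known ground
truth: `estimate = truth + N(0, sd)` truncated to [0, 1] (sd 0.05, 30 experts
by default) and interval `estimate ± half-width`.  The default half-width is
`z_0.975 · sd / √n_experts`, i.e. experts report *panel-calibrated*
intervals: the mean-pooled interval is then an honest 95% interval for the
pooled estimate, which is the regime in which interval pooling followed by
quantile-matched Beta fitting can be validated for coverage (the recovery
test observes ~95% coverage over 1,000 panels).  Real experts are typically
over- or under-confident individually and their errors are correlated;
neither feature is simulated, so passing recovery tests validate the
*pipeline arithmetic*, not the behavioural quality of any real survey.

## Burden

`ODB = Σ dw_k · P(harm_k | evidence)`; `healthy = 100 × (1 − ODB)`.
The registry names each outcome node's harm state explicitly, so whether the
disease-free-survival benefit contributes through its failure-state
probability is a modelling choice recorded in data, not code.  ODB above 1 is
possible in principle with many items; the stored value is never clamped and
only the displayed percentage is floored at 0.  The transform is exactly the
×100 complement; published burden/healthy pairs confirm it at one-decimal
rounding (one published row carries a half-ulp rounding artifact, consistent
with round-half-up of an unrounded burden of 0.2525).

## Synthetic clinical network

The `ypn1_default` topology contains every node and arc the published model
description names: pretreatment factors (chemo timing, mid-NAC progression,
surgery type, axillary surgery, nodal burden, extracapsular extension,
resection margin, LVI, ECOG, subtype), the 3-state RT-field intervention with
surgery type / subtype / axillary surgery as parents, six reconstruction
factors, and five outcome/toxicity nodes each fed by the RT field.  The full
published arc set is not printed anywhere, so the remaining structure is a
reconstruction: binary states wherever the source names none, extra arcs
addable through `GeneratorConfig.extra_arcs`, CPTs drawn from a seeded
Dirichlet (concentration 2.0 — diffuse but not extreme rows) unless
overridden.  No claim of parameter realism is made; the published parameter
values live in an external repository and are deliberately not shipped.
Default disability weights follow the published qualitative ordering
(recurrence > lymphedema > cardiac > reconstruction failure > pneumonitis).

Consequently the built-in trial templates reproduce the published *report
structures* (the 2-strata × 3-field cohort grid; the six-factor sensitivity
families for reconstruction failure) and the structural guarantees
(randomization property, mixture semantics), but not the published endpoint
numbers, which require the external CPTs.

## Numerical choices

* Engine agreement asserted at 1e-10 max-norm; observed agreement is at
  machine precision (~1e-16) on the sweep sizes used (200 networks, 3–12
  nodes, 2–4 states — kept small because enumeration is exponential).
* Mixture weights must sum to 1 within 1e-12; posteriors within 1e-12.
* Elimination-order ties and all report orderings are lexicographic/stable,
  so identical inputs give byte-identical reports.
* Monte-Carlo burden summaries use 10,000 draws by default in tests — enough
  for the 3-standard-error closed-form check on the 2-node fixture in a few
  seconds.
* Degenerate inputs: empty registries give ODB 0 / healthy 100%; zero-width
  pooled intervals take the PERT fallback; all-zero likelihood vectors are
  rejected at construction.

## Known limitations

* Exact inference only; no sampling or MAP queries, no structure learning.
* Mixtures nest one level; deeper hierarchies must be flattened by the user.
* XMLBIF interchange drops role tags (format limitation; warned).
* The expert-noise model is truncated-Gaussian with shared calibrated
  half-width; alternative behavioural models are pluggable but not built in.
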