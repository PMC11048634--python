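# bnburden

Expert-knowledge Bayesian networks for weighing the benefits and harms of
radiotherapy (RT) in (y)pN1 breast cancer — patients with 1–3 involved
axillary nodes, with or without neoadjuvant chemotherapy (NAC).

The open clinical question is de-escalation: does shrinking the RT field
(chest wall/breast alone, vs adding high tangents, vs full internal-mammary +
supraclavicular nodal irradiation) or omitting axillary dissection cost
oncologic outcome, and what does it buy in avoided toxicity?  Because the
randomized trials addressing this (Alliance A011202, PORT-N1, RAPCHEM,
RT-CHARM) will not read out for years, the question can be studied *in
silico*: a discrete Bayesian network over pretreatment factors, the RT-field
intervention, and outcome/toxicity nodes, parameterised from expert surveys,
on which trial arms are evaluated as evidence programs.

## The model

A network is a DAG of categorical nodes, each with a conditional probability
table (CPT); the joint is `P(x) = Π P(x_i | pa(x_i))`.  On top of exact
inference the package computes the **overall disease burden**

```
ODB = Σ_k  dw_k · P(harm state of outcome k | evidence)
```

where `dw_k ∈ [0,1]` is an expert-elicited disability weight (1 = worst
possible state) and the sum runs over a registry of RT-related risks and
benefits (a pure-benefit endpoint like 7-year disease-free survival enters
through its failure state).  The **likelihood of being healthy** is the
linear transform `100 × (1 − ODB)`, a percentage.

Trial arms are *evidence programs*:

* **hard evidence** for observed population facts (e.g. "no progression
  mid-NAC"),
* **do-interventions** for randomized assignments — the node's incoming arcs
  are severed and its distribution clamped, so arm assignment cannot flow
  back into pretreatment marginals (the randomization effect),
* **virtual evidence** (likelihood vectors) for soft findings,
* **weighted mixtures** for arms defined as blends of treatment states
  (e.g. a 50/50 blend of high-tangent and full-RNI fields).

Two exact engines share one contract — brute-force joint enumeration (the
test oracle) and variable elimination with deterministic min-fill ordering —
and agree to 1e-10 on hundreds of randomized networks.

Expert surveys (point estimate + confidence interval per CPT cell or
disability weight) are pooled with a linear opinion pool and converted to
Beta distributions by equal-tailed quantile matching, which feeds seeded
Monte-Carlo propagation of parameter uncertainty into ODB.

## Worked example

The published CPTs live in an external repository, so the package ships a
seeded generator for a structurally faithful synthetic network (the
`ypn1_default` topology: pretreatment factors → 3-state RT-field intervention
→ outcome/toxicity nodes, Dirichlet CPTs).  Running the built-in PORT-N1
template (RT de-escalation, both arms do-assigned, shared constraint
mid-NAC = "no") on the seed-0 network:

```python
import bnburden as bb

net = bb.make_ypn1_network(bb.GeneratorConfig(seed=0))
reg = bb.default_registry()
res = bb.run_template(net, "port_n1", reg)
print(res.summary().round(4).to_string(index=False))
```

```
                                arm    odb  healthy_pct  P(dfs_7yr=disease-free)  P(clinical_lymphedema=present)
          control (PMRT or WBI+RNI) 0.4385      56.1516                   0.5267                          0.2409
experimental (no PMRT or WBI alone) 0.5153      48.4669                   0.4839                          0.6192
```

Each row is one arm: its overall disease burden, the likelihood of being
healthy (`100 × (1 − ODB)`), and the requested endpoint posteriors.  With
seed-0 Dirichlet CPTs the numbers are arbitrary — what is meaningful is the
machinery: both arms share identical pretreatment marginals (do-semantics),
and `res.comparisons()` reports per-endpoint differences and fold changes.
A one-way sensitivity template produces a ranked posterior table
(two-decimal percent, descending — the presentation used for reconstruction
failure):

```
                                  scenario posterior
implant_preservation=implant-preserving RT    53.07%
               rt_technique=IMRT/VMAT/Tomo    52.38%
                    recon_timing=immediate    52.07%
```

The same operations are available from the shell: `bnburden simulate`,
`validate`, `infer`, `odb`, `trial run`, `trial sensitivity`, `elicit`.

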