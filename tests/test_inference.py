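"""Exact inference: golden fixtures, evidence semantics, engine equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bnburden as bb
from bnburden.network import CPT, Network, NodeSpec
from bnburden.synthetic import random_evidence_program

ENGINES = [bb.posterior_enumeration, bb.posterior_ve]


@pytest.mark.parametrize("engine", ENGINES, ids=["enumeration", "ve"])
@pytest.mark.parametrize(
    "name", ["coin", "bayes-2node", "chain-3node", "collider", "virtual-coin"]
)
def test_golden_fixture_posteriors(fixture_suite, engine, name):
    """Hand-computed posteriors (e.g. P(A=1|B=1) = 9/11) are reproduced exactly."""
    fx = fixture_suite[name]
    post = engine(fx.network, fx.evidence, fx.query)
    for state, expected in fx.expected.items():
        assert post.prob(state) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("engine", ENGINES, ids=["enumeration", "ve"])
def test_uninformative_virtual_evidence_is_prior(engine):
    net = bb.make_random_network(bb.GeneratorConfig(seed=3, n_nodes=6))
    prior = engine(net, bb.EvidenceProgram(), "N0")
    card = net.cardinality("N2")
    flat = engine(net, bb.EvidenceProgram(virtual={"N2": (1.0,) * card}), "N0")
    assert np.allclose(prior.probs, flat.probs, atol=1e-12)


@pytest.mark.parametrize("engine", ENGINES, ids=["enumeration", "ve"])
def test_onehot_virtual_equals_hard_evidence(fixture_suite, engine):
    """A (1,0,...) likelihood is hard evidence in the limit — exactly, here."""
    fx = fixture_suite["bayes-2node"]
    hard = engine(fx.network, bb.EvidenceProgram(hard={"B": "1"}), "A")
    virt = engine(fx.network, bb.EvidenceProgram(virtual={"B": (0.0, 1.0)}), "A")
    assert np.allclose(hard.probs, virt.probs, atol=1e-12)


def test_fully_observed_query_is_row_lookup(fixture_suite):
    fx = fixture_suite["bayes-2node"]
    post = bb.posterior_ve(fx.network, bb.EvidenceProgram(hard={"A": "1"}), "B")
    assert np.allclose(post.probs, [0.1, 0.9], atol=1e-12)


def test_long_chain_beyond_enumeration_guard():
    """25 binary nodes: enumeration refuses, VE finishes and matches closed form."""
    n = 25
    nodes = [NodeSpec("X0", ("0", "1"))]
    cpts = [CPT("X0", np.array([[0.7, 0.3]]))]
    rng = np.random.default_rng(11)
    T = []
    for i in range(1, n):
        nodes.append(NodeSpec(f"X{i}", ("0", "1"), parents=(f"X{i-1}",)))
        rows = rng.dirichlet((2.0, 2.0), size=2)
        T.append(rows)
        cpts.append(CPT(f"X{i}", rows))
    net = Network(nodes, cpts)
    with pytest.raises(bb.InputError, match="enumeration"):
        bb.posterior_enumeration(net, bb.EvidenceProgram(), f"X{n-1}")
    post = bb.posterior_ve(net, bb.EvidenceProgram(), f"X{n-1}")
    assert post.probs.sum() == pytest.approx(1.0, abs=1e-12)
    marg = np.array([0.7, 0.3])
    for rows in T:  # forward pass oracle
        marg = marg @ rows
    assert np.allclose(post.probs, marg, atol=1e-10)


@pytest.mark.parametrize("engine", ENGINES, ids=["enumeration", "ve"])
def test_zero_probability_evidence_raises(engine):
    net = Network(
        [NodeSpec("A", ("0", "1")), NodeSpec("B", ("0", "1"), parents=("A",))],
        {"A": np.array([[1.0, 0.0]]), "B": np.array([[1.0, 0.0], [0.0, 1.0]])},
    )
    with pytest.raises(bb.InconsistentEvidenceError):
        engine(net, bb.EvidenceProgram(hard={"B": "1"}), "A")


def test_evidence_validation_errors(fixture_suite):
    fx = fixture_suite["bayes-2node"]
    with pytest.raises(bb.InputError):
        bb.posterior_ve(fx.network, bb.EvidenceProgram(hard={"Z": "1"}), "A")
    with pytest.raises(bb.InputError):
        bb.posterior_ve(fx.network, bb.EvidenceProgram(hard={"B": "nope"}), "A")
    with pytest.raises(bb.InputError, match="length"):
        bb.posterior_ve(fx.network, bb.EvidenceProgram(virtual={"B": (1, 1, 1)}), "A")
    with pytest.raises(bb.InputError, match="hard evidence"):
        bb.posterior_ve(fx.network, bb.EvidenceProgram(hard={"A": "1"}), "A")


class TestEvidenceProgramInvariants:
    def test_node_in_two_groups_rejected(self):
        with pytest.raises(bb.InputError, match="more than one"):
            bb.EvidenceProgram(hard={"A": "1"}, do={"A": "0"})

    def test_all_zero_virtual_rejected(self):
        with pytest.raises(bb.InputError, match="all zero"):
            bb.EvidenceProgram(virtual={"A": (0.0, 0.0)})

    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(bb.InputError, match="sum"):
            bb.EvidenceProgram(
                mixture=[(0.6, bb.EvidenceProgram()), (0.6, bb.EvidenceProgram())]
            )

    def test_mixture_single_nesting_level(self):
        inner = bb.EvidenceProgram(
            mixture=[(1.0, bb.EvidenceProgram(hard={"A": "1"}))]
        )
        with pytest.raises(bb.InputError, match="nest"):
            bb.EvidenceProgram(mixture=[(1.0, inner)])

    def test_digest_is_stable(self):
        p1 = bb.EvidenceProgram(hard={"A": "1", "B": "0"})
        p2 = bb.EvidenceProgram(hard={"B": "0", "A": "1"})
        assert p1.digest() == p2.digest()


class TestDoSemantics:
    def test_do_on_root_with_own_prior_is_noop(self, fixture_suite):
        fx = fixture_suite["bayes-2node"]
        done = bb.apply_do(fx.network, "A", (0.5, 0.5))
        for q in ("A", "B"):
            a = bb.posterior_enumeration(fx.network, bb.EvidenceProgram(), q)
            b = bb.posterior_enumeration(done, bb.EvidenceProgram(), q)
            assert np.allclose(a.probs, b.probs, atol=1e-12)

    def test_do_clamps_marginal_exactly(self, ypn1):
        ev = bb.EvidenceProgram(do={"rt_field": (0.5, 0.3, 0.2)})
        post = bb.posterior_ve(ypn1, ev, "rt_field")
        assert np.allclose(post.probs, [0.5, 0.3, 0.2], atol=1e-15)

    def test_do_preserves_ancestor_marginals_but_conditioning_does_not(self):
        """The randomisation property: intervening on a child cannot inform its
        causes, while observing it does."""
        net = bb.make_random_network(bb.GeneratorConfig(seed=5, n_nodes=6))
        g = net.graph()
        # pick a node with at least one ancestor
        target = next(
            n for n in reversed(net.topological_order()) if net.node(n).parents
        )
        anc = next(iter(net.node(target).parents))
        state = net.node(target).states[0]
        prior = bb.posterior_enumeration(net, bb.EvidenceProgram(), anc)
        do = bb.posterior_enumeration(
            net, bb.EvidenceProgram(do={target: state}), anc
        )
        assert np.allclose(prior.probs, do.probs, atol=1e-12)
        cond = bb.posterior_enumeration(
            net, bb.EvidenceProgram(hard={target: state}), anc
        )
        assert np.max(np.abs(cond.probs - prior.probs)) > 1e-6

    def test_do_distribution_validation(self, ypn1):
        with pytest.raises(bb.InputError):
            bb.apply_do(ypn1, "rt_field", (0.5, 0.5))  # wrong length
        with pytest.raises(bb.InputError):
            bb.apply_do(ypn1, "rt_field", "not-a-state")


class TestMixtures:
    @pytest.mark.parametrize("engine", ENGINES, ids=["enumeration", "ve"])
    def test_mixture_is_convex_combination_for_every_query(self, engine):
        net = bb.make_random_network(bb.GeneratorConfig(seed=9, n_nodes=6))
        s0 = net.node("N1").states[0]
        s1 = net.node("N1").states[-1]
        comp_a = bb.EvidenceProgram(do={"N1": s0})
        comp_b = bb.EvidenceProgram(do={"N1": s1})
        mix = bb.EvidenceProgram(mixture=[(0.3, comp_a), (0.7, comp_b)])
        for q in net.node_names:
            pa = engine(net, comp_a, q).probs
            pb = engine(net, comp_b, q).probs
            pm = engine(net, mix, q).probs
            assert np.allclose(pm, 0.3 * pa + 0.7 * pb, atol=1e-12)

    def test_toplevel_evidence_pushed_into_components(self, fixture_suite):
        fx = fixture_suite["chain-3node"]
        mix = bb.EvidenceProgram(
            hard={"C": "1"},
            mixture=[
                (0.5, bb.EvidenceProgram(do={"B": "0"})),
                (0.5, bb.EvidenceProgram(do={"B": "1"})),
            ],
        )
        direct = [
            bb.posterior_enumeration(
                fx.network,
                bb.EvidenceProgram(hard={"C": "1"}, do={"B": s}),
                "A",
            ).probs
            for s in ("0", "1")
        ]
        got = bb.posterior_enumeration(fx.network, mix, "A").probs
        assert np.allclose(got, 0.5 * direct[0] + 0.5 * direct[1], atol=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), evseed=st.integers(0, 10_000))
def test_ve_matches_enumeration_on_random_networks(seed, evseed):
    """Property: the two engines agree to 1e-10 on arbitrary small networks
    under arbitrary hard/virtual/do/mixture evidence."""
    cfg = bb.GeneratorConfig(seed=seed, n_nodes=3 + seed % 8, state_range=(2, 4))
    net = bb.make_random_network(cfg, max_joint_size=2**18)
    rng = np.random.default_rng(evseed)
    ev = random_evidence_program(net, rng)
    queries = [q for q in net.node_names if q not in ev.hard][:3]
    for q in queries:
        try:
            a = bb.posterior_enumeration(net, ev, q)
        except bb.InconsistentEvidenceError:
            with pytest.raises(bb.InconsistentEvidenceError):
                bb.posterior_ve(net, ev, q)
            continue
        b = bb.posterior_ve(net, ev, q)
        assert np.max(np.abs(a.probs - b.probs)) < 1e-10
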