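"""Trial-arm engine, sensitivity tables, built-in templates."""

import numpy as np
import pytest

import bnburden as bb
from bnburden.trials import (
    ArmSpec,
    SensitivitySpec,
    TrialSpec,
    check_template_schema,
    trial_from_dict,
)

F_ALONE, F_TANGENT, F_FULL = (
    "CW/breast alone",
    "CW/breast + high-tangent",
    "CW/breast + IMN/SCL",
)
ENDPOINTS = (("dfs_7yr", "disease-free"), ("clinical_lymphedema", "present"))


def two_arm_trial(ev_a, ev_b, shared=None):
    return TrialSpec(
        name="t",
        shared_evidence=shared or bb.EvidenceProgram(),
        arms=(
            ArmSpec("A", ev_a, ENDPOINTS),
            ArmSpec("B", ev_b, ENDPOINTS),
        ),
    )


class TestRunTrial:
    def test_identical_arms_identical_reports(self, ypn1, registry):
        ev = bb.EvidenceProgram(do={"rt_field": F_FULL})
        res = bb.run_trial(ypn1, two_arm_trial(ev, ev), registry)
        a, b = res.arms["A"], res.arms["B"]
        assert a.endpoints == b.endpoints
        assert a.odb.odb == b.odb.odb
        comp = res.comparisons()
        assert np.allclose(comp["difference"], 0.0)
        assert np.allclose(comp["ratio"], 1.0)

    def test_mixture_arm_equals_average_of_hard_runs(self, ypn1, registry):
        """A 50/50 blended-field arm reproduces the mean of its two pure arms
        exactly, endpoint by endpoint."""
        mix = bb.EvidenceProgram(
            mixture=[
                (0.5, bb.EvidenceProgram(do={"rt_field": F_TANGENT})),
                (0.5, bb.EvidenceProgram(do={"rt_field": F_FULL})),
            ]
        )
        res = bb.run_trial(
            ypn1,
            TrialSpec(
                name="blend",
                arms=(
                    ArmSpec("tangent", bb.EvidenceProgram(do={"rt_field": F_TANGENT}), ENDPOINTS),
                    ArmSpec("full", bb.EvidenceProgram(do={"rt_field": F_FULL}), ENDPOINTS),
                    ArmSpec("mixed", mix, ENDPOINTS),
                ),
            ),
            registry,
        )
        for key in ENDPOINTS:
            avg = 0.5 * (res.arms["tangent"].endpoints[key] + res.arms["full"].endpoints[key])
            assert res.arms["mixed"].endpoints[key] == pytest.approx(avg, abs=1e-12)

    def test_do_arms_share_pretreatment_marginals(self, ypn1, registry):
        trial = two_arm_trial(
            bb.EvidenceProgram(do={"rt_field": F_ALONE}),
            bb.EvidenceProgram(do={"rt_field": F_FULL}),
        )
        pretreat = [s.name for s in ypn1.nodes if s.role == "pretreatment"]
        for node in pretreat:
            pa = bb.posterior_ve(ypn1, trial.arms[0].evidence, node).probs
            pb = bb.posterior_ve(ypn1, trial.arms[1].evidence, node).probs
            assert np.max(np.abs(pa - pb)) < 1e-10

    def test_arm_order_does_not_change_reports(self, ypn1, registry):
        ev_a = bb.EvidenceProgram(do={"rt_field": F_ALONE})
        ev_b = bb.EvidenceProgram(do={"rt_field": F_FULL})
        fwd = bb.run_trial(ypn1, two_arm_trial(ev_a, ev_b), registry)
        rev = bb.run_trial(
            ypn1,
            TrialSpec(name="t", arms=(ArmSpec("B", ev_b, ENDPOINTS), ArmSpec("A", ev_a, ENDPOINTS))),
            registry,
        )
        assert fwd.arms["A"].endpoints == rev.arms["A"].endpoints
        assert fwd.arms["B"].odb.odb == rev.arms["B"].odb.odb

    def test_fold_change_consistent_with_posteriors(self, ypn1, registry):
        res = bb.run_trial(
            ypn1,
            two_arm_trial(
                bb.EvidenceProgram(do={"rt_field": F_ALONE, "axillary_surgery": "SLNBx"}),
                bb.EvidenceProgram(do={"rt_field": F_FULL, "axillary_surgery": "ALND"}),
            ),
            registry,
        )
        comp = res.comparisons()
        for _, row in comp.iterrows():
            if row["p_b"] > 0:
                assert row["ratio"] == pytest.approx(row["p_a"] / row["p_b"], rel=1e-12)
            assert row["difference"] == pytest.approx(row["p_a"] - row["p_b"], abs=1e-15)

    def test_conflicting_shared_and_arm_evidence_names_node(self, ypn1, registry):
        shared = bb.EvidenceProgram(hard={"axillary_surgery": "SLNBx"})
        trial = two_arm_trial(
            bb.EvidenceProgram(do={"axillary_surgery": "ALND"}),
            bb.EvidenceProgram(do={"rt_field": F_FULL}),
            shared=shared,
        )
        with pytest.raises(bb.InputError, match="axillary_surgery"):
            bb.run_trial(ypn1, trial, registry)

    def test_trial_spec_invariants(self):
        with pytest.raises(bb.InputError, match="2 arms"):
            TrialSpec(name="x", arms=(ArmSpec("A", bb.EvidenceProgram()),))
        with pytest.raises(bb.InputError, match="duplicate"):
            TrialSpec(
                name="x",
                arms=(ArmSpec("A", bb.EvidenceProgram()), ArmSpec("A", bb.EvidenceProgram())),
            )


class TestOneWaySensitivity:
    def test_rows_match_enumeration_oracle(self, fixture_suite):
        fx = fixture_suite["chain-3node"]
        base = bb.EvidenceProgram()
        table = bb.one_way_sensitivity(
            fx.network,
            base,
            [("B=0", (("B", "0"),)), ("B=1", (("B", "1"),))],
            target=("A", "1"),
        )
        assert len(table) == 3  # base + 2 scenarios
        for _, row in table.frame.iterrows():
            if row["scenario"] == "base":
                ev = base
            else:
                ev = bb.EvidenceProgram(hard={"B": row["scenario"].split("=")[1]})
            want = bb.posterior_enumeration(fx.network, ev, "A").prob("1")
            assert row["posterior"] == pytest.approx(want, abs=1e-12)

    def test_sorted_descending(self, ypn1):
        table = bb.one_way_sensitivity(
            ypn1,
            bb.EvidenceProgram(),
            [(f"{n}={s}", ((n, s),)) for n in ("boost", "recon_timing")
             for s in ypn1.node(n).states],
            target=("reconstruction_failure", "major failure"),
        )
        post = table.frame["posterior"].to_numpy()
        assert np.all(np.diff(post) <= 1e-15)

    def test_factor_identical_to_base_reproduces_base_row(self, fixture_suite):
        fx = fixture_suite["chain-3node"]
        base = bb.EvidenceProgram()
        table = bb.one_way_sensitivity(
            fx.network, base, [("noop", ())], target=("A", "1")
        )
        vals = table.frame.set_index("scenario")["posterior"]
        assert vals["noop"] == pytest.approx(vals["base"], abs=1e-15)

    def test_factor_on_hard_evidenced_node_rejected(self, fixture_suite):
        fx = fixture_suite["chain-3node"]
        with pytest.raises(bb.InputError, match="C"):
            bb.one_way_sensitivity(
                fx.network,
                bb.EvidenceProgram(hard={"C": "1"}),
                [("clash", (("C", "0"),))],
                target=("A", "1"),
            )

    def test_formatted_percent_two_decimals(self, fixture_suite):
        fx = fixture_suite["coin"]
        table = bb.one_way_sensitivity(fx.network, bb.EvidenceProgram(), [], ("A", "1"))
        assert table.formatted()["posterior"].iloc[0] == "50.00%"


class TestTemplates:
    def test_all_templates_run_on_default_network(self, ypn1, registry):
        for name in ("alliance_a011202", "port_n1", "rapchem"):
            res = bb.run_template(ypn1, name, registry)
            summary = res.summary()
            assert {"arm", "odb", "healthy_pct"} <= set(summary.columns)
            assert summary["odb"].notna().all()
        table = bb.run_template(ypn1, "rt_charm", registry)
        assert isinstance(table, bb.PosteriorTable)

    def test_rapchem_grid_is_two_strata_by_three_fields(self, ypn1, registry):
        res = bb.run_template(ypn1, "rapchem", registry)
        summary = res.summary()
        assert len(summary) == 6
        strata = {arm.split(" | ")[0] for arm in summary["arm"]}
        fields = {arm.split(" | ")[1] for arm in summary["arm"]}
        assert len(strata) == 2 and len(fields) == 3

    def test_rt_charm_scenarios_cover_six_factor_families(self, ypn1, registry):
        table = bb.run_template(ypn1, "rt_charm", registry)
        factors = {
            row.split("=")[0]
            for row in table.frame["scenario"]
            if row != "base"
        }
        assert factors == {
            "boost", "fractionation", "implant_preservation",
            "recon_timing", "recon_type", "rt_technique",
        }
        assert table.target == ("reconstruction_failure", "major failure")

    def test_alliance_arm_b_is_5050_blend(self, ypn1, registry):
        res = bb.run_template(ypn1, "alliance_a011202", registry)
        tangent = bb.posterior_ve(
            ypn1,
            bb.EvidenceProgram(
                hard={"chemo_timing": "neoadjuvant"},
                do={"axillary_surgery": "ALND", "rt_field": F_TANGENT},
            ),
            "clinical_lymphedema",
        ).prob("present")
        full = bb.posterior_ve(
            ypn1,
            bb.EvidenceProgram(
                hard={"chemo_timing": "neoadjuvant"},
                do={"axillary_surgery": "ALND", "rt_field": F_FULL},
            ),
            "clinical_lymphedema",
        ).prob("present")
        got = res.arms["ALND + mixed field"].endpoints[("clinical_lymphedema", "present")]
        assert got == pytest.approx(0.5 * (tangent + full), abs=1e-12)

    def test_schema_mismatch_lists_missing_names(self, fixture_suite, registry):
        net = fixture_suite["odb-2node"].network
        with pytest.raises(bb.SchemaMismatchError) as err:
            bb.run_template(net, "port_n1", registry)
        assert "rt_field" in err.value.missing

    def test_unknown_template_rejected(self, ypn1, registry):
        with pytest.raises(bb.InputError, match="unknown template"):
            bb.run_template(ypn1, "nope", registry)


class TestConfig:
    def test_trial_roundtrip_through_dict(self):
        spec = two_arm_trial(
            bb.EvidenceProgram(do={"rt_field": F_ALONE}),
            bb.EvidenceProgram(
                do={"axillary_surgery": "ALND"},
                mixture=[
                    (0.5, bb.EvidenceProgram(do={"rt_field": F_TANGENT})),
                    (0.5, bb.EvidenceProgram(do={"rt_field": F_FULL})),
                ],
            ),
            shared=bb.EvidenceProgram(hard={"chemo_timing": "neoadjuvant"}),
        )
        doc = {
            "name": spec.name,
            "shared_evidence": spec.shared_evidence.to_dict(),
            "arms": [
                {
                    "name": a.name,
                    "evidence": a.evidence.to_dict(),
                    "endpoints": [list(e) for e in a.endpoints],
                }
                for a in spec.arms
            ],
        }
        back = trial_from_dict(doc)
        assert back.arms[1].evidence.digest() == spec.arms[1].evidence.digest()
        assert back.shared_evidence.digest() == spec.shared_evidence.digest()
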