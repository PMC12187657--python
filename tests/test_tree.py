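"""Strategy trees: arms, risk adjustment, outcome splits, evaluation."""

import pytest
from hypothesis import given, settings, strategies as st

from brcascreen import (adjusted_risks, build_strategy, cancer_outcome_split,
                        carrier_arms, enumerate_paths, evaluate,
                        evaluate_strategy, leaf_qaly)
from brcascreen.tree import (LEAF_STATES, STRATEGIES, InvalidParametersError,
                             TreeStructureError, Branch, ChanceNode,
                             DecisionTree, Leaf, _expect)


class TestCarrierArms:
    def test_surveillance_takes_residual_weight(self, defaults):
        arms = {a.label: a for a in carrier_arms(defaults)}
        assert arms["surveillance_only"].weight == pytest.approx(0.0755)
        assert sum(a.weight for a in arms.values()) == pytest.approx(1.0)

    def test_rrso_arms_include_hormone_replacement(self, defaults):
        arms = {a.label: a for a in carrier_arms(defaults)}
        assert arms["RRSO_only"].arm_cost == 26881 + 4200
        assert arms["RRM_and_RRSO"].arm_cost == 5414 + 26881 + 4200
        assert arms["surveillance_only"].arm_cost == 1500

    def test_first_year_surgical_disutilities(self, defaults):
        arms = {a.label: a for a in carrier_arms(defaults)}
        assert arms["RRM_and_RRSO"].arm_disutility_qaly == pytest.approx(0.17)
        assert arms["RRA"].arm_disutility_qaly == 0.0

    def test_uptake_sum_above_one_raises(self, defaults):
        bad = defaults.replace(p20=0.9)
        with pytest.raises(InvalidParametersError):
            carrier_arms(bad)


class TestAdjustedRisks:
    @pytest.mark.parametrize("arm_label, expected", [
        ("RRA", (0.130385 * 0.53, 0.374 * 0.64)),
        ("surveillance_only", (0.130385, 0.374)),
        ("RRM_and_RRSO", (0.130385 * 0.21, 0.374 * 0.05)),
    ])
    def test_penetrance_times_risk_ratio(self, defaults, arm_label, expected):
        arm = {a.label: a for a in carrier_arms(defaults)}[arm_label]
        assert adjusted_risks(arm, defaults) == pytest.approx(expected)


class TestLeafQaly:
    @pytest.mark.parametrize("leaf, expected", [
        ("no_cancer", 10 * 0.977658738 * 1.0),
        ("early_BC", 10 * 0.739 * 0.71),
        ("late_OC", 10 * 0.176 * 0.55),
    ])
    def test_horizon_times_survival_times_utility(self, defaults, leaf, expected):
        assert leaf_qaly(leaf, defaults) == pytest.approx(expected)


class TestOutcomeSplit:
    def test_zero_risks_give_certain_no_cancer(self, defaults):
        split = cancer_outcome_split(0.0, 0.0, defaults)
        assert split["no_cancer"] == 1.0

    def test_certain_ovarian_cancer_crowds_out_breast(self, defaults):
        split = cancer_outcome_split(1.0, 0.5, defaults)
        assert split["early_OC"] == pytest.approx(0.3)
        assert split["late_OC"] == pytest.approx(0.7)
        assert split["early_BC"] == split["late_BC"] == 0.0

    def test_cancers_are_mutually_exclusive_additive(self, defaults):
        # breast-cancer mass is the full risk (not conditioned on no-OC)
        # as long as the risks fit in the unit interval together
        split = cancer_outcome_split(0.004, 0.034654, defaults)
        assert split["early_BC"] == pytest.approx(0.034654 * 0.621)
        assert split["early_OC"] + split["late_OC"] == pytest.approx(0.004)

    def test_detected_carriers_are_staged_early(self, defaults):
        split = cancer_outcome_split(0.2, 0.3, defaults, detected=True)
        assert split["late_OC"] == split["late_BC"] == 0.0
        assert split["early_OC"] == pytest.approx(0.2)
        assert split["early_BC"] == pytest.approx(0.3)

    @settings(derandomize=True, max_examples=200)
    @given(risk_oc=st.floats(0, 1), risk_bc=st.floats(0, 1),
           detected=st.booleans())
    def test_split_is_a_probability_distribution(self, risk_oc, risk_bc, detected):
        split = cancer_outcome_split(risk_oc, risk_bc, default_params(),
                                     detected=detected)
        assert all(v >= -1e-15 for v in split.values())
        assert sum(split.values()) == pytest.approx(1.0, abs=1e-12)


def default_params():
    from brcascreen import default_parameters
    return default_parameters()


class TestBuildAndEvaluate:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_path_probabilities_sum_to_one(self, defaults, strategy):
        tree = build_strategy(strategy, defaults)
        paths = enumerate_paths(tree)
        assert sum(p.probability for p in paths) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_recursion_agrees_with_flat_enumeration(self, defaults, strategy):
        tree = build_strategy(strategy, defaults)
        res = evaluate(tree)
        paths = enumerate_paths(tree)
        assert res.expected_cost == pytest.approx(
            sum(p.probability * p.cost for p in paths), abs=1e-10)
        assert sum(res.leaf_probabilities.values()) == pytest.approx(1.0, abs=1e-12)

    def test_symptom_tree_carrier_branch_mass(self, defaults):
        tree = build_strategy("symptom_only", defaults)
        carrier_mass = sum(p.probability for p in enumerate_paths(tree)
                           if p.labels[0] == "BRCA_pos_undetected")
        assert carrier_mass == pytest.approx(0.003965)

    def test_fh_joint_detected_mass(self, defaults):
        tree = build_strategy("fh_based", defaults)
        detected = sum(p.probability for p in enumerate_paths(tree)
                       if p.labels[:2] == ("FH_pos", "BRCA_pos"))
        assert detected == pytest.approx(0.0098 * 0.10)

    def test_compat_qaly_wiring_uses_p1_p51_detected_mass(self, compat):
        tree = build_strategy("fh_based", compat)
        detected = sum(p.probability for p in enumerate_paths(tree, which="qaly")
                       if p.labels[:2] == ("FH_pos", "BRCA_pos"))
        assert detected == pytest.approx(0.003965 * 0.10)
        # while the cost wiring keeps the epidemiological p50*p51 mass
        cost_mass = sum(p.probability for p in enumerate_paths(tree, which="cost")
                        if p.labels[:2] == ("FH_pos", "BRCA_pos"))
        assert cost_mass == pytest.approx(0.0098 * 0.10)

    def test_zero_uptake_costs_testing_plus_surveillance(self, defaults):
        quiet = defaults.replace(p20=0.0, p26=0.0, p32=0.0, p38=0.0)
        sym = evaluate_strategy("symptom_only", quiet)
        pop = evaluate_strategy("population_based", quiet)
        expected_extra = (quiet.cost_brca_test
                          + quiet.p1 * quiet.cost_periodical_examination)
        assert pop.expected_cost - sym.expected_cost == pytest.approx(
            expected_extra, abs=1e-9)

    def test_null_interventions_and_null_staging_equalise_qalys(self, defaults):
        # with no risk reduction, no uptake, and a degenerate all-early stage
        # mix, detection confers nothing: all three strategies tie on QALYs
        null = defaults.replace(
            p20=0.0, p26=0.0, p32=0.0, p38=0.0,
            rr_OC_RRA=1.0, rr_BC_RRA=1.0, rr_OC_RRM=1.0, rr_BC_RRM=1.0,
            rr_OC_RRSO=1.0, rr_BC_RRSO=1.0, rr_BC_RRM_RRSO=1.0,
            ratio_early_OC=1.0, ratio_early_BC=1.0,
        )
        qalys = [evaluate_strategy(s, null).expected_qaly for s in STRATEGIES]
        assert qalys[0] == pytest.approx(qalys[1], abs=1e-10)
        assert qalys[0] == pytest.approx(qalys[2], abs=1e-10)

    def test_strategy_nesting_universal_family_history(self, defaults):
        # if everyone is FH+ and the FH+ carrier rate is the population
        # prevalence, FH-based testing is population testing plus counselling
        nested = defaults.replace(p50=1.0, p51=defaults.p1)
        pop = evaluate_strategy("population_based", nested)
        fh = evaluate_strategy("fh_based", nested)
        assert fh.expected_qaly == pytest.approx(pop.expected_qaly, abs=1e-12)
        assert fh.expected_cost - pop.expected_cost == pytest.approx(
            nested.cost_FH_consel, abs=1e-9)

    @pytest.mark.parametrize("cost_field", [
        "cost_brca_test", "cost_diagnosis_cancer", "cost_rrso",
        "cost_general_examination"])
    def test_raising_a_unit_cost_never_lowers_expected_cost(self, defaults,
                                                            cost_field):
        bumped = defaults.replace(**{cost_field:
                                     getattr(defaults, cost_field) + 500.0})
        for s in STRATEGIES:
            assert (evaluate_strategy(s, bumped).expected_cost
                    >= evaluate_strategy(s, defaults).expected_cost - 1e-12)

    def test_weaker_intervention_never_raises_carrier_qaly(self, defaults):
        weaker = defaults.replace(rr_BC_RRM=0.6, rr_OC_RRSO=0.8)
        assert (evaluate_strategy("population_based", weaker).expected_qaly
                <= evaluate_strategy("population_based", defaults).expected_qaly)

    def test_coherent_mode_rejects_excess_fh_carriers(self, defaults):
        bad = defaults.replace(p50=0.05, p51=0.5)
        with pytest.raises(InvalidParametersError):
            build_strategy("fh_based", bad)

    def test_structural_error_names_offending_node(self):
        broken = DecisionTree("synthetic", ChanceNode("lopsided", (
            Branch("a", 0.5, Leaf("no_cancer", 0.0, 1.0)),
            Branch("b", 0.3, Leaf("no_cancer", 0.0, 1.0)),
        )))
        with pytest.raises(TreeStructureError, match="lopsided"):
            evaluate(broken)

    def test_leaf_states_partition_every_path(self, defaults):
        for s in STRATEGIES:
            for p in enumerate_paths(build_strategy(s, defaults)):
                assert p.leaf in LEAF_STATES
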