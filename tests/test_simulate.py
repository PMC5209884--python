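"""Synthetic populations: exact proportions, dispositions, sampling, convergence."""

from fractions import Fraction

import numpy as np
import pytest

from bdxo.fixtures import (
    convergence_demo_spec,
    dipstick_study_spec,
    randomization_illustration_spec,
    rf_population_spec,
)
from bdxo.model import IdFactory, InputShapeError, InstanceGraph, ModelError, TestClass
from bdxo.simulate import (
    PopulationSpec,
    SubgroupSpec,
    build_population,
    execute_tests,
    make_disposition,
    run_convergence_experiment,
    sample_population,
    true_npv,
    true_ppv,
    true_prevalence,
    true_rt_linked_proportion,
    true_sensitivity,
    true_specificity,
)

IT = TestClass("IT1", role="index")
RT = TestClass("RT1", role="reference")


def two_subgroup_spec(w1, w2, p1, p2, *, p_ref_fp=0.0, healthy_per_group=0):
    """Diseased subgroups of sizes w1/w2 with index response p1/p2."""
    def subgroup(name, size, p_index):
        return SubgroupSpec(
            name=name,
            size=size + healthy_per_group,
            diseased_fraction=size / (size + healthy_per_group) if size + healthy_per_group else 0.0,
            p_index_pos_given_diseased=p_index,
            p_index_pos_given_healthy=0.0,
            p_ref_pos_given_diseased=1.0,
            p_ref_pos_given_healthy=p_ref_fp,
        )

    return PopulationSpec(subgroups=[subgroup("sg1", w1, p1), subgroup("sg2", w2, p2)])


class TestBuildPopulation:
    def test_rf_example_two_deterministic_subgroups(self):
        pop = build_population(rf_population_spec())
        assert len(pop.members) == 1000
        assert all(m.diseased for m in pop.members)
        by_subgroup = {}
        for m in pop.members:
            by_subgroup.setdefault(m.subgroup, set()).add(m.response_prob["IT_RF"])
        assert by_subgroup == {"factor_present": {1.0}, "factor_absent": {0.0}}

    def test_deterministic_diseased_counts(self):
        spec = PopulationSpec(
            subgroups=[
                SubgroupSpec(
                    name="g", size=1000, diseased_fraction=0.10,
                    p_index_pos_given_diseased=0.5, p_index_pos_given_healthy=0.1,
                    p_ref_pos_given_diseased=1.0, p_ref_pos_given_healthy=0.0,
                )
            ]
        )
        pop = build_population(spec)
        assert sum(m.diseased for m in pop.members) == 100

    def test_empty_spec_rejected(self):
        with pytest.raises(Exception):
            PopulationSpec(subgroups=[])
        with pytest.raises(Exception):
            PopulationSpec(
                subgroups=[
                    SubgroupSpec(
                        name="g", size=0, diseased_fraction=0.5,
                        p_index_pos_given_diseased=1.0, p_index_pos_given_healthy=0.0,
                        p_ref_pos_given_diseased=1.0, p_ref_pos_given_healthy=0.0,
                    )
                ]
            )


class TestTrueProportions:
    def test_rf_sensitivity_is_subgroup_weight(self):
        pop = build_population(rf_population_spec())
        assert true_sensitivity(pop, "IT_RF", disease="M_RA").value == 0.8

    def test_homogeneous_response_is_its_own_mean(self):
        pop = build_population(randomization_illustration_spec())
        assert true_sensitivity(pop, "IT1").value == pytest.approx(0.15, abs=0)
        assert true_prevalence(pop).value == pytest.approx(0.10, abs=0)
        assert true_specificity(pop, "IT1").value == pytest.approx(0.95, abs=1e-12)

    def test_spectrum_effect_closed_form(self):
        # weighted mean w*p1 + (1-w)*p2, and a different mix shifts the value
        pop_a = build_population(two_subgroup_spec(600, 400, 0.9, 0.5))
        pop_b = build_population(two_subgroup_spec(200, 800, 0.9, 0.5))
        se_a = true_sensitivity(pop_a, "IT1").value
        se_b = true_sensitivity(pop_b, "IT1").value
        assert se_a == pytest.approx(0.6 * 0.9 + 0.4 * 0.5, abs=1e-12)
        assert se_b == pytest.approx(0.2 * 0.9 + 0.8 * 0.5, abs=1e-12)
        assert se_a != se_b

    def test_no_diseased_members_is_an_error(self):
        spec = PopulationSpec(
            subgroups=[
                SubgroupSpec(
                    name="g", size=10, diseased_fraction=0.0,
                    p_index_pos_given_diseased=0.5, p_index_pos_given_healthy=0.1,
                    p_ref_pos_given_diseased=1.0, p_ref_pos_given_healthy=0.0,
                )
            ]
        )
        pop = build_population(spec)
        with pytest.raises(ModelError):
            true_sensitivity(pop, "IT1")

    def test_true_ppv_npv_match_bayes_composition(self):
        from bdxo.bayes import BayesInputs, npv_from_bayes, ppv_from_bayes

        pop = build_population(convergence_demo_spec())
        inputs = BayesInputs(
            prev=true_prevalence(pop).value,
            se=true_sensitivity(pop, "IT1").value,
            sp=true_specificity(pop, "IT1").value,
        )
        assert true_ppv(pop, "IT1").value == pytest.approx(ppv_from_bayes(inputs), abs=1e-12)
        assert true_npv(pop, "IT1").value == pytest.approx(npv_from_bayes(inputs), abs=1e-12)


class TestReferenceLinkedProportions:
    def test_perfect_reference_makes_f3_equal_f2(self):
        for spec in (rf_population_spec(), randomization_illustration_spec()):
            pop = build_population(spec)
            f2 = true_sensitivity(pop, spec.index_class).value
            f3 = true_rt_linked_proportion(pop, spec.index_class, spec.reference_class, "se").value
            assert abs(f3 - f2) < 1e-12
            if any(not m.diseased for m in pop.members):  # rf fixture is all-diseased
                f2_sp = true_specificity(pop, spec.index_class).value
                f3_sp = true_rt_linked_proportion(
                    pop, spec.index_class, spec.reference_class, "sp"
                ).value
                assert abs(f3_sp - f2_sp) < 1e-12

    def test_reference_false_positives_drag_f3_below_f2(self):
        # 10-person population; healthy members sometimes trip the reference
        # test but never the index test, diluting the reference-positive pool.
        spec = two_subgroup_spec(3, 2, 1.0, 0.5, p_ref_fp=0.4, healthy_per_group=3)
        pop = build_population(spec)
        assert len(pop.members) == 11  # 3+3 and 2+3
        # Fraction-arithmetic oracle over the member list
        num = den = Fraction(0)
        for m in pop.members:
            p_ref = Fraction(m.response_prob["RT1"]).limit_denominator(10)
            p_index = Fraction(m.response_prob["IT1"]).limit_denominator(10)
            num += p_ref * p_index
            den += p_ref
        oracle = num / den
        f3 = true_rt_linked_proportion(pop, "IT1", "RT1", "se").value
        f2 = true_sensitivity(pop, "IT1").value
        assert f3 == pytest.approx(float(oracle), abs=1e-12)
        assert f3 < f2

    def test_zero_reference_mass_is_an_error(self):
        spec = PopulationSpec(
            subgroups=[
                SubgroupSpec(
                    name="g", size=5, diseased_fraction=1.0,
                    p_index_pos_given_diseased=0.5, p_index_pos_given_healthy=0.0,
                    p_ref_pos_given_diseased=0.0, p_ref_pos_given_healthy=0.0,
                )
            ]
        )
        pop = build_population(spec)
        with pytest.raises(ModelError):
            true_rt_linked_proportion(pop, "IT1", "RT1", "se")


class TestDispositions:
    def test_probability_equals_exact_proportion_for_all_kinds(self):
        pop = build_population(convergence_demo_spec())
        expectations = {
            "prevalence": true_prevalence(pop).value,
            "sensitivity": true_sensitivity(pop, "IT1").value,
            "specificity": true_specificity(pop, "IT1").value,
            "ppv": true_ppv(pop, "IT1").value,
            "npv": true_npv(pop, "IT1").value,
        }
        for kind, expected in expectations.items():
            index = None if kind == "prevalence" else "IT1"
            disposition = make_disposition(pop, kind, index)
            assert disposition.probability == expected
            assert disposition.bearer_id == pop.id
            assert disposition.trigger_descriptor
            assert disposition.realization_descriptor

    def test_illustration_probabilities(self):
        pop = build_population(randomization_illustration_spec())
        assert make_disposition(pop, "prevalence").probability == pytest.approx(0.10, abs=0)
        assert make_disposition(pop, "sensitivity", "IT1").probability == pytest.approx(0.15, abs=0)

    def test_all_diseased_population_has_prevalence_one(self):
        pop = build_population(rf_population_spec())
        assert make_disposition(pop, "prevalence", disease="M_RA").probability == 1.0


class TestSampling:
    def test_full_sample_is_whole_population(self):
        pop = build_population(randomization_illustration_spec())
        sample = sample_population(pop, len(pop.members), seed=7)
        assert sample.member_ids == [m.id for m in pop.members]

    def test_same_seed_same_sample(self):
        pop = build_population(randomization_illustration_spec())
        s1 = sample_population(pop, 50, seed=3)
        s2 = sample_population(pop, 50, seed=3)
        s3 = sample_population(pop, 50, seed=4)
        assert s1.member_ids == s2.member_ids
        assert s1.member_ids != s3.member_ids

    def test_out_of_range_sizes_rejected(self):
        pop = build_population(randomization_illustration_spec())
        with pytest.raises(InputShapeError):
            sample_population(pop, 0, seed=1)
        with pytest.raises(InputShapeError):
            sample_population(pop, len(pop.members) + 1, seed=1)


class TestExecuteTests:
    def test_deterministic_responses_give_closed_form_counts(self):
        pop = build_population(rf_population_spec())
        sample = sample_population(pop, len(pop.members), seed=0)
        it = TestClass("IT_RF", role="index")
        rt = TestClass("RT_RF", role="reference")
        _, table = execute_tests(pop, sample, it, rt, seed=5)
        assert (table.tp, table.fp, table.fn, table.tn) == (800, 0, 200, 0)

    def test_fixed_seed_reproduces_table(self):
        pop = build_population(dipstick_study_spec())
        sample = sample_population(pop, 204, seed=11)
        _, t1 = execute_tests(pop, sample, IT, RT, seed=12)
        _, t2 = execute_tests(pop, sample, IT, RT, seed=12)
        _, t3 = execute_tests(pop, sample, IT, RT, seed=13)
        assert (t1.tp, t1.fp, t1.fn, t1.tn) == (t2.tp, t2.fp, t2.fn, t2.tn)
        assert (t1.tp, t1.fp, t1.fn, t1.tn) != (t3.tp, t3.fp, t3.fn, t3.tn)

    def test_missing_response_probability_is_integrity_error(self):
        from bdxo.model import IntegrityError

        pop = build_population(dipstick_study_spec())
        sample = sample_population(pop, 10, seed=1)
        with pytest.raises(IntegrityError):
            execute_tests(pop, sample, TestClass("IT_OTHER", role="index"), RT, seed=2)

    def test_execution_graph_validates(self, graph, ids):
        pop = build_population(dipstick_study_spec(), ids=ids, graph=graph)
        graph.add_node(IT)
        graph.add_node(RT)
        sample = sample_population(pop, 204, seed=1, ids=ids, graph=graph)
        execution, _ = execute_tests(pop, sample, IT, RT, seed=2, ids=ids, graph=graph)
        from bdxo.model import validate_instance_graph

        assert len(execution.processes) == 408
        assert validate_instance_graph(graph).ok


class TestConvergence:
    def test_mean_sample_deviation_shrinks_with_n(self):
        pop = build_population(convergence_demo_spec())
        frame = run_convergence_experiment(pop, IT, RT, [40, 400], replicates=60, seed=9)
        assert list(frame["n"]) == [40, 400]
        assert frame["mean_abs_dev"].iloc[1] < frame["mean_abs_dev"].iloc[0]
        assert (frame["mean_abs_dev"] <= frame["binomial_se"]).all()
        assert frame.attrs["monotone_decreasing"]

    def test_sample_mean_close_to_population_value(self):
        # mean f4 over replicates sits within 4 standard errors of f3
        pop = build_population(convergence_demo_spec())
        f3 = true_rt_linked_proportion(pop, "IT1", "RT1", "se").value
        rng_seeds = range(40)
        values = []
        for s in rng_seeds:
            sample = sample_population(pop, 400, seed=1000 + s)
            _, table = execute_tests(pop, sample, IT, RT, seed=2000 + s)
            values.append(table.tp / (table.tp + table.fn))
        mean_p_ref = np.mean([m.response_prob["RT1"] for m in pop.members])
        se = np.sqrt(f3 * (1 - f3) / (400 * mean_p_ref)) / np.sqrt(len(values))
        assert abs(np.mean(values) - f3) < 4 * se

    def test_whole_population_deterministic_responses_deviate_zero(self):
        pop = build_population(rf_population_spec())
        it = TestClass("IT_RF", role="index")
        rt = TestClass("RT_RF", role="reference")
        frame = run_convergence_experiment(pop, it, rt, [len(pop.members)], replicates=3, seed=0)
        assert frame["mean_abs_dev"].iloc[0] == 0.0

    def test_empty_grid_rejected(self):
        pop = build_population(convergence_demo_spec())
        with pytest.raises(InputShapeError):
            run_convergence_experiment(pop, IT, RT, [], replicates=5, seed=0)
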