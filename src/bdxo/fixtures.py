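"""Ready-made synthetic study configurations.

All populations here are synthetic: they are built to exhibit particular
structural features (a deterministic two-subgroup spectrum, a small
fixed-prevalence group, a 204-patient accuracy study) rather than to
reproduce any real cohort.
"""

from __future__ import annotations

from .model import DiseaseClass, TestClass, TestClassRegistry
from .simulate import PopulationSpec, SubgroupSpec

__all__ = [
    "rf_population_spec",
    "randomization_illustration_spec",
    "dipstick_study_spec",
    "convergence_demo_spec",
    "default_registry",
    "FIXTURE_SPECS",
]


def rf_population_spec(seed: int = 0) -> PopulationSpec:
    """Two-subgroup diseased population with deterministic responses.

    All members have the disease.  80 % of them carry the factor the index
    test detects and would test positive with certainty; the other 20 %
    lack it and would test negative with certainty.  The exact sensitivity
    is therefore 0.8 — and would shift if the subgroup mix shifted, which
    is the spectrum effect in its purest form.  The reference test is
    perfect.
    """
    return PopulationSpec(
        seed=seed,
        index_class="IT_RF",
        reference_class="RT_RF",
        disease="M_RA",
        subgroups=[
            SubgroupSpec(
                name="factor_present",
                size=800,
                diseased_fraction=1.0,
                p_index_pos_given_diseased=1.0,
                p_index_pos_given_healthy=0.0,
                p_ref_pos_given_diseased=1.0,
                p_ref_pos_given_healthy=0.0,
            ),
            SubgroupSpec(
                name="factor_absent",
                size=200,
                diseased_fraction=1.0,
                p_index_pos_given_diseased=0.0,
                p_index_pos_given_healthy=0.0,
                p_ref_pos_given_diseased=1.0,
                p_ref_pos_given_healthy=0.0,
            ),
        ],
    )


def randomization_illustration_spec(seed: int = 0) -> PopulationSpec:
    """One subgroup of 1000 with 10 % diseased and Se-response 0.15.

    Exactly 100 members are diseased, so the prevalence disposition gets
    probability 0.10; every diseased member's index-positive probability is
    0.15, so the sensitivity disposition gets probability 0.15.  The
    reference test is perfect.
    """
    return PopulationSpec(
        seed=seed,
        index_class="IT1",
        reference_class="RT1",
        disease="M",
        subgroups=[
            SubgroupSpec(
                name="g",
                size=1000,
                diseased_fraction=0.10,
                p_index_pos_given_diseased=0.15,
                p_index_pos_given_healthy=0.05,
                p_ref_pos_given_diseased=1.0,
                p_ref_pos_given_healthy=0.0,
            )
        ],
    )


def dipstick_study_spec(seed: int = 0) -> PopulationSpec:
    """A 2040-person two-stratum population for a 204-patient accuracy study.

    Mimics the shape of a point-of-care dipstick study on diabetic
    patients: a sample of 204 drawn from this population and tested with
    index + reference tests yields 408 test processes.  Strata differ in
    disease frequency and index response (a mild spectrum), and the
    laboratory reference test is near-perfect but not perfect.
    """
    return PopulationSpec(
        seed=seed,
        index_class="IT1",
        reference_class="RT1",
        disease="M_ALB",
        subgroups=[
            SubgroupSpec(
                name="early_disease",
                size=1428,
                diseased_fraction=0.15,
                p_index_pos_given_diseased=0.75,
                p_index_pos_given_healthy=0.05,
                p_ref_pos_given_diseased=0.99,
                p_ref_pos_given_healthy=0.01,
            ),
            SubgroupSpec(
                name="advanced_disease",
                size=612,
                diseased_fraction=0.40,
                p_index_pos_given_diseased=0.92,
                p_index_pos_given_healthy=0.08,
                p_ref_pos_given_diseased=0.99,
                p_ref_pos_given_healthy=0.01,
            ),
        ],
    )


def convergence_demo_spec(seed: int = 0) -> PopulationSpec:
    """A 4000-person heterogeneous population for sample-size experiments.

    Prevalence ~0.3 keeps the reference-positive stratum large enough that
    small samples rarely miss it entirely, while the two strata give the
    index test genuinely different sensitivities (0.7 vs 0.9).
    """
    return PopulationSpec(
        seed=seed,
        index_class="IT1",
        reference_class="RT1",
        disease="M",
        subgroups=[
            SubgroupSpec(
                name="mild",
                size=2400,
                diseased_fraction=0.25,
                p_index_pos_given_diseased=0.70,
                p_index_pos_given_healthy=0.08,
                p_ref_pos_given_diseased=0.95,
                p_ref_pos_given_healthy=0.05,
            ),
            SubgroupSpec(
                name="severe",
                size=1600,
                diseased_fraction=0.375,
                p_index_pos_given_diseased=0.90,
                p_index_pos_given_healthy=0.12,
                p_ref_pos_given_diseased=0.95,
                p_ref_pos_given_healthy=0.05,
            ),
        ],
    )


FIXTURE_SPECS = {
    "rf": rf_population_spec,
    "randomization": randomization_illustration_spec,
    "dipstick": dipstick_study_spec,
    "convergence": convergence_demo_spec,
}


def default_registry() -> TestClassRegistry:
    """A registry with one two-level index/reference hierarchy per fixture."""
    registry = TestClassRegistry()
    for disease_id, label in [
        ("M", "target condition"),
        ("M_RA", "rheumatoid arthritis"),
        ("M_ALB", "albuminuria"),
    ]:
        registry.add_disease(DiseaseClass(id=disease_id, label=label))
    registry.add_test(TestClass("IT0", "point-of-care index tests", "index", None, "M_ALB"))
    registry.add_test(TestClass("RT0", "laboratory reference tests", "reference", None, "M_ALB"))
    registry.add_test(TestClass("IT1", "dipstick, cutoff 3.4", "index", "IT0", "M_ALB"))
    registry.add_test(TestClass("RT1", "laboratory ACR, cutoff 3.4", "reference", "RT0", "M_ALB"))
    registry.add_test(TestClass("IT2", "dipstick, cutoff 2.65", "index", "IT0", "M_ALB"))
    registry.add_test(TestClass("RT2", "laboratory ACR, cutoff 2.65", "reference", "RT0", "M_ALB"))
    registry.add_test(TestClass("IT_RF", "rheumatoid factor assay", "index", None, "M_RA"))
    registry.add_test(TestClass("RT_RF", "clinical reference exam", "reference", None, "M_RA"))
    return registry
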