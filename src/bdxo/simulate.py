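"""Synthetic populations with subgroup-structured test responses.

The simulator realizes the *spectrum effect*: a population is a mixture of
subgroups, and each subgroup carries its own latent probabilities of
responding positive to the index and reference tests, separately for
diseased and healthy members.  Because an indicator such as sensitivity is
the average of those latent response probabilities over the diseased
members, changing the subgroup mix changes the indicator — with no change
to the tests themselves.

Three tiers of quantity are kept apart and computable:

* ``true_*`` functions evaluate population proportions *exactly*, by
  arithmetic over the latent probabilities (the disease-linked f2-style
  values, and their reference-test-linked f3-style counterparts);
* :func:`execute_tests` draws actual binary results for a sample, giving a
  2x2 table whose proportions are the f4-style sample measurements;
* :func:`make_disposition` attaches an exact proportion, as a probability,
  to a population-borne disposition with explicit trigger/realization
  descriptors (the randomization reading of a "real" indicator value).

:func:`run_convergence_experiment` measures how the sample value f4
approaches the population value f3 as the sample grows.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .model import (
    ContingencyTable,
    Disposition,
    IdFactory,
    InputShapeError,
    InstanceGraph,
    IntegrityError,
    ModelError,
    PersonRecord,
    Population,
    Sample,
    TestClass,
    TestsExecution,
    build_tests_execution,
    record_tests_results,
)

__all__ = [
    "SubgroupSpec",
    "PopulationSpec",
    "TrueProportion",
    "build_population",
    "true_prevalence",
    "true_sensitivity",
    "true_specificity",
    "true_ppv",
    "true_npv",
    "true_rt_linked_proportion",
    "make_disposition",
    "sample_population",
    "execute_tests",
    "run_convergence_experiment",
]


class SubgroupSpec(BaseModel):
    """One homogeneous stratum of the synthetic population."""

    name: str
    size: int = Field(ge=0)
    diseased_fraction: float = Field(ge=0.0, le=1.0)
    p_index_pos_given_diseased: float = Field(ge=0.0, le=1.0)
    p_index_pos_given_healthy: float = Field(ge=0.0, le=1.0)
    p_ref_pos_given_diseased: float = Field(ge=0.0, le=1.0)
    p_ref_pos_given_healthy: float = Field(ge=0.0, le=1.0)


class PopulationSpec(BaseModel):
    """Full simulator configuration (JSON-loadable)."""

    subgroups: list[SubgroupSpec]
    seed: int = 0
    index_class: str = "IT1"
    reference_class: str = "RT1"
    disease: str = "M"

    @field_validator("subgroups")
    @classmethod
    def _non_empty(cls, v: list[SubgroupSpec]) -> list[SubgroupSpec]:
        if sum(sg.size for sg in v) < 1:
            raise ValueError("population spec must describe at least one person")
        return v


class TrueProportion(BaseModel):
    """An exactly evaluated population proportion (no sampling noise)."""

    kind: str  # prev | f2_se | f2_sp | f2_ppv | f2_npv | f3_se | f3_sp
    value: float = Field(ge=0.0, le=1.0)
    population_id: str
    index_class: Optional[str] = None
    reference_class: Optional[str] = None
    disease: Optional[str] = None


def build_population(
    spec: PopulationSpec,
    *,
    ids: Optional[IdFactory] = None,
    graph: Optional[InstanceGraph] = None,
) -> Population:
    """Materialize a population from its spec, deterministically.

    Diseased counts per subgroup are deterministic (``round(size *
    diseased_fraction)``, the first members of the subgroup), not binomial
    draws, so every ``true_*`` value is an exact arithmetic consequence of
    the spec.  Each member's ``response_prob`` holds its positive-response
    probability for the index and reference test classes.
    """
    ids = ids or IdFactory()
    members: list[PersonRecord] = []
    for sg in spec.subgroups:
        n_diseased = int(math.floor(sg.size * sg.diseased_fraction + 0.5))
        for i in range(sg.size):
            diseased = i < n_diseased
            members.append(
                PersonRecord(
                    id=ids.mint("p"),
                    subgroup=sg.name,
                    diseased=diseased,
                    response_prob={
                        spec.index_class: (
                            sg.p_index_pos_given_diseased if diseased else sg.p_index_pos_given_healthy
                        ),
                        spec.reference_class: (
                            sg.p_ref_pos_given_diseased if diseased else sg.p_ref_pos_given_healthy
                        ),
                    },
                )
            )
    population = Population(id=ids.mint("g"), members=members)
    if graph is not None:
        graph.add_node(population)
        for m in members:
            graph.add_node(m)
            graph.add_edge(m.id, "part_of", population.id)
    return population


def true_prevalence(pop: Population, *, disease: str = "M") -> TrueProportion:
    """Exact proportion of diseased members."""
    if not pop.members:
        raise ModelError(f"population {pop.id!r} is empty")
    value = sum(1 for m in pop.members if m.diseased) / len(pop.members)
    return TrueProportion(kind="prev", value=value, population_id=pop.id, disease=disease)


def _mean_response(pop: Population, index_class: str, *, diseased: bool, positive: bool) -> float:
    group = [m for m in pop.members if m.diseased is diseased]
    if not group:
        status = "diseased" if diseased else "healthy"
        raise ModelError(f"population {pop.id!r} has no {status} members")
    probs = []
    for m in group:
        try:
            p = m.response_prob[index_class]
        except KeyError:
            raise IntegrityError(f"person {m.id!r} has no response probability for {index_class!r}")
        probs.append(p if positive else 1.0 - p)
    return float(np.mean(probs))


def true_sensitivity(pop: Population, index_class: str, *, disease: str = "M") -> TrueProportion:
    """Exact f2-style sensitivity: mean positive-response probability over the diseased."""
    value = _mean_response(pop, index_class, diseased=True, positive=True)
    return TrueProportion(
        kind="f2_se", value=value, population_id=pop.id, index_class=index_class, disease=disease
    )


def true_specificity(pop: Population, index_class: str, *, disease: str = "M") -> TrueProportion:
    """Exact f2-style specificity: mean negative-response probability over the healthy."""
    value = _mean_response(pop, index_class, diseased=False, positive=False)
    return TrueProportion(
        kind="f2_sp", value=value, population_id=pop.id, index_class=index_class, disease=disease
    )


def true_ppv(pop: Population, index_class: str, *, disease: str = "M") -> TrueProportion:
    """Exact PPV: expected diseased mass among expected index-positives."""
    num = sum(m.response_prob[index_class] for m in pop.members if m.diseased)
    den = sum(m.response_prob[index_class] for m in pop.members)
    if den == 0.0:
        raise ModelError("PPV undefined: nobody would ever test positive")
    return TrueProportion(
        kind="f2_ppv", value=num / den, population_id=pop.id, index_class=index_class, disease=disease
    )


def true_npv(pop: Population, index_class: str, *, disease: str = "M") -> TrueProportion:
    """Exact NPV: expected healthy mass among expected index-negatives."""
    num = sum(1.0 - m.response_prob[index_class] for m in pop.members if not m.diseased)
    den = sum(1.0 - m.response_prob[index_class] for m in pop.members)
    if den == 0.0:
        raise ModelError("NPV undefined: nobody would ever test negative")
    return TrueProportion(
        kind="f2_npv", value=num / den, population_id=pop.id, index_class=index_class, disease=disease
    )


def true_rt_linked_proportion(
    pop: Population, index_class: str, reference_class: str, kind: str = "se"
) -> TrueProportion:
    """Exact f3-style proportion, conditioning on the reference test.

    For ``kind="se"``: among the expected reference-test positives, the
    expected fraction who would also test index-positive — the population
    quantity a sample sensitivity measurement actually estimates.  Computed
    as a ratio of expectations over all members, with a person's two test
    responses independent given their latent probabilities:

        sum_i p_ref_i * p_index_i  /  sum_i p_ref_i

    ``kind="sp"`` uses the complementary (negative/negative) masses.  With a
    perfect reference test the conditioning event coincides with disease
    status and the value equals the f2-style one exactly.
    """
    if kind not in ("se", "sp"):
        raise ModelError(f"kind must be 'se' or 'sp', got {kind!r}")
    num = den = 0.0
    for m in pop.members:
        try:
            p_index = m.response_prob[index_class]
            p_ref = m.response_prob[reference_class]
        except KeyError as exc:
            raise IntegrityError(f"person {m.id!r} lacks a response probability: {exc}")
        if kind == "se":
            den += p_ref
            num += p_ref * p_index
        else:
            den += 1.0 - p_ref
            num += (1.0 - p_ref) * (1.0 - p_index)
    if den == 0.0:
        side = "positive" if kind == "se" else "negative"
        raise ModelError(f"no expected reference-test {side} mass in population {pop.id!r}")
    return TrueProportion(
        kind=f"f3_{kind}",
        value=num / den,
        population_id=pop.id,
        index_class=index_class,
        reference_class=reference_class,
    )


_TRIGGER_TEMPLATES = {
    "prevalence": (
        "random draw of one individual from group {g}",
        "the draw returns someone who has the disease {m}",
    ),
    "sensitivity": (
        "performance of test {it} on the individuals in {g}, and random draw of an "
        "individual among those who have the disease {m}",
        "the draw returns someone who got a positive result to {it}",
    ),
    "specificity": (
        "performance of test {it} on the individuals in {g}, and random draw of an "
        "individual among those who do not have the disease {m}",
        "the draw returns someone who got a negative result to {it}",
    ),
    "ppv": (
        "performance of test {it} on the individuals in {g}, and random draw of an "
        "individual among those who got a positive result to {it}",
        "the draw returns someone who has the disease {m}",
    ),
    "npv": (
        "performance of test {it} on the individuals in {g}, and random draw of an "
        "individual among those who got a negative result to {it}",
        "the draw returns someone who does not have the disease {m}",
    ),
}


def make_disposition(
    pop: Population,
    kind: str,
    index_class: Optional[str] = None,
    disease: str = "M",
    *,
    ids: Optional[IdFactory] = None,
    graph: Optional[InstanceGraph] = None,
) -> Disposition:
    """Attach the exact population proportion, as a probability, to a disposition.

    This is the randomization reading: the "real" indicator value is the
    objective probability that a suitably triggered random draw realizes —
    e.g. for prevalence, drawing a diseased member; for sensitivity,
    drawing an index-test positive among the diseased, had the test been
    performed on everyone.  The probability equals the exact proportion.
    """
    if kind == "prevalence":
        value = true_prevalence(pop, disease=disease).value
        index_for_node = None
    else:
        if index_class is None:
            raise ModelError(f"a {kind} disposition requires an index test class")
        fn = {
            "sensitivity": true_sensitivity,
            "specificity": true_specificity,
            "ppv": true_ppv,
            "npv": true_npv,
        }.get(kind)
        if fn is None:
            raise ModelError(f"unknown indicator kind {kind!r}")
        value = fn(pop, index_class, disease=disease).value
        index_for_node = index_class
    trigger, realization = _TRIGGER_TEMPLATES[kind]
    fmt = {"g": pop.id, "it": index_class or "", "m": disease}
    ids = ids or IdFactory()
    disposition = Disposition(
        id=ids.mint(f"d_{kind}"),
        bearer_id=pop.id,
        kind=kind,
        disease=disease,
        index_class=index_for_node,
        trigger_descriptor=trigger.format(**fmt),
        realization_descriptor=realization.format(**fmt),
        probability=value,
    )
    if graph is not None:
        graph.add_node(disposition)
        graph.add_edge(disposition.id, "has_probability_value", disposition.probability)
    return disposition


def sample_population(
    pop: Population,
    n: int,
    seed: int,
    *,
    ids: Optional[IdFactory] = None,
    graph: Optional[InstanceGraph] = None,
) -> Sample:
    """Simple random sample without replacement; deterministic given the seed."""
    if not 1 <= n <= len(pop.members):
        raise InputShapeError(
            f"sample size {n} out of range [1, {len(pop.members)}] for population {pop.id!r}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pop.members), size=n, replace=False))
    ids = ids or IdFactory()
    sample = Sample(
        id=ids.mint("s"),
        population_id=pop.id,
        member_ids=[pop.members[i].id for i in idx],
    )
    if graph is not None:
        graph.add_node(sample)
        graph.add_edge(sample.id, "part_of", pop.id)
    return sample


def execute_tests(
    pop: Population,
    sample: Sample,
    index_class: TestClass,
    reference_class: TestClass,
    seed: int,
    *,
    ids: Optional[IdFactory] = None,
    graph: Optional[InstanceGraph] = None,
) -> tuple[TestsExecution, ContingencyTable]:
    """Perform both tests on every sample member and record the 2x2 table.

    Each result is an independent Bernoulli draw with the member's latent
    probability for that test class; results are deterministic given the
    seed.  Members whose latent probability is 0 or 1 respond with
    certainty, so fully degenerate populations yield closed-form counts.
    """
    index = pop.member_index
    p_index = np.empty(len(sample.member_ids))
    p_ref = np.empty(len(sample.member_ids))
    for j, person_id in enumerate(sample.member_ids):
        person = index.get(person_id)
        if person is None:
            raise IntegrityError(f"sample member {person_id!r} not in population {pop.id!r}")
        try:
            p_index[j] = person.response_prob[index_class.id]
            p_ref[j] = person.response_prob[reference_class.id]
        except KeyError as exc:
            raise IntegrityError(f"person {person_id!r} lacks a response probability: {exc}")
    rng = np.random.default_rng(seed)
    index_pos = rng.random(len(sample.member_ids)) < p_index
    ref_pos = rng.random(len(sample.member_ids)) < p_ref
    results = {
        person_id: (
            "positive" if index_pos[j] else "negative",
            "positive" if ref_pos[j] else "negative",
        )
        for j, person_id in enumerate(sample.member_ids)
    }
    execution = build_tests_execution(
        sample, index_class, reference_class, results, graph=graph, ids=ids
    )
    table = record_tests_results(execution, graph=graph, ids=ids)
    return execution, table


def run_convergence_experiment(
    pop: Population,
    index_class: TestClass,
    reference_class: TestClass,
    n_grid: list[int],
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Measure |f4 - f3| as a function of sample size.

    For each sample size ``n`` in the grid, draw ``replicates`` independent
    samples, execute both tests, compute the sample sensitivity f4 =
    tp/(tp+fn), and average its absolute deviation from the exact
    population value f3.  Replicates with no reference-test positives (an
    empty f4 denominator) are excluded and counted.

    Returns a DataFrame with columns ``n``, ``mean_abs_dev``,
    ``binomial_se`` (the sqrt(f3(1-f3)/E[#RT+]) envelope), ``n_excluded``
    and ``replicates_used``; ``df.attrs["monotone_decreasing"]`` reports
    whether ``mean_abs_dev`` decreases along the sorted grid.
    """
    if not n_grid:
        raise InputShapeError("the sample-size grid must be non-empty")
    if replicates < 1:
        raise InputShapeError("need at least one replicate")
    f3 = true_rt_linked_proportion(pop, index_class.id, reference_class.id, "se").value
    mean_p_ref = float(
        np.mean([m.response_prob[reference_class.id] for m in pop.members])
    )
    seeds = np.random.SeedSequence(seed).spawn(len(n_grid))
    rows = []
    for n, seq in zip(sorted(n_grid), seeds):
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(2 * replicates)]
        deviations = []
        excluded = 0
        for r in range(replicates):
            sample = sample_population(pop, n, child_seeds[2 * r])
            _, table = execute_tests(
                pop, sample, index_class, reference_class, child_seeds[2 * r + 1]
            )
            if table.tp + table.fn == 0:
                excluded += 1
                continue
            f4 = table.tp / (table.tp + table.fn)
            deviations.append(abs(f4 - f3))
        rows.append(
            {
                "n": n,
                "mean_abs_dev": float(np.mean(deviations)) if deviations else float("nan"),
                "binomial_se": math.sqrt(f3 * (1.0 - f3) / (n * mean_p_ref)) if mean_p_ref else float("nan"),
                "n_excluded": excluded,
                "replicates_used": len(deviations),
            }
        )
    frame = pd.DataFrame(rows)
    devs = frame["mean_abs_dev"].to_numpy()
    frame.attrs["monotone_decreasing"] = bool(np.all(np.diff(devs) < 0))
    return frame
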