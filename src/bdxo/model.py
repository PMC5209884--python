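"""Typed instance graph for diagnostic-accuracy bookkeeping.

The central idea is a strict separation of three kinds of entity that
everyday usage of the word "sensitivity" conflates:

* a *tests execution* — the concrete processes of performing an index test
  and a reference test on every member of a sample, yielding a 2x2 table of
  true/false positives/negatives;
* an *indicator-of-performance estimate* — a data item whose value is a
  proportion measured in the sample (true positives among reference-test
  positives, for sensitivity);
* the *real* indicator value — the probability attached to a disposition
  borne by a whole population (the proportion of diseased members who
  *would* test positive, were the test performed on all of them).

Entities are plain dataclasses; :class:`InstanceGraph` links them through a
closed vocabulary of relations (``instance_of``, ``part_of``, ``is_about``,
``has_probability_value`` ...) so that the whole analysis — who was tested,
what was computed from what, and what each number is a claim about — is an
auditable, serializable graph.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "RELATIONS",
    "LITERAL_RELATIONS",
    "ModelError",
    "InputShapeError",
    "IntegrityError",
    "VocabularyError",
    "IdFactory",
    "DiseaseClass",
    "TestClass",
    "TestClassRegistry",
    "PersonRecord",
    "Population",
    "Sample",
    "TestProcess",
    "TestsExecution",
    "ContingencyTable",
    "Disposition",
    "DispositionClass",
    "IPEstimate",
    "Computation",
    "Violation",
    "ValidationReport",
    "InstanceGraph",
    "build_tests_execution",
    "record_tests_results",
    "validate_instance_graph",
]

#: Closed relation vocabulary of the instance graph.
RELATIONS = frozenset(
    {
        "instance_of",
        "is_a",
        "part_of",
        "participates_in",
        "has_specified_input",
        "has_specified_output",
        "has_specified_value",
        "has_probability_value",
        "is_about",
        "se_of_test",
        "se_for_disease",
        "sp_of_test",
        "sp_for_disease",
        "ppv_of_test",
        "ppv_for_disease",
        "npv_of_test",
        "npv_for_disease",
    }
)

#: Relations whose object is a numeric literal, not a node identifier.
LITERAL_RELATIONS = frozenset({"has_specified_value", "has_probability_value"})

IP_KINDS = ("prevalence", "sensitivity", "specificity", "ppv", "npv")
RESULTS = ("positive", "negative")


class ModelError(ValueError):
    """Base class for instance-graph modelling errors."""


class InputShapeError(ModelError):
    """Inputs do not have the required shape (missing/extra records)."""


class IntegrityError(ModelError):
    """Referential integrity of the graph is broken."""


class VocabularyError(ModelError):
    """A relation or type outside the closed vocabulary was used."""


class IdFactory:
    """Mints opaque, stable identifiers ``<prefix><n>``.

    Counters are per-prefix so that serialized graphs are reproducible.
    """

    def __init__(self, prefix: str = "") -> None:
        self.prefix = prefix
        self._counters: dict[str, itertools.count] = {}

    def mint(self, stem: str) -> str:
        counter = self._counters.setdefault(stem, itertools.count(1))
        return f"{self.prefix}{stem}_{next(counter)}"


def _check_probability(value: float, what: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ModelError(f"{what} must lie in [0, 1], got {value!r}")


@dataclass
class DiseaseClass:
    """A target condition M."""

    id: str
    label: str = ""


@dataclass
class TestClass:
    """A class of medical tests (index or reference) for a target disease."""

    __test__ = False  # domain class, not a pytest suite

    id: str
    label: str = ""
    role: str = "index"
    parent_id: Optional[str] = None
    target_disease: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ("index", "reference"):
            raise ModelError(f"test role must be 'index' or 'reference', got {self.role!r}")


class TestClassRegistry:
    """Declared hierarchy of test classes and diseases.

    Subsumption is limited to the explicitly declared parent chain: two test
    classes can be pooled only if the registry names a common ancestor for
    them; nothing is inferred.
    """

    __test__ = False  # domain class, not a pytest suite

    def __init__(self) -> None:
        self.tests: dict[str, TestClass] = {}
        self.diseases: dict[str, DiseaseClass] = {}

    def add_disease(self, disease: DiseaseClass) -> DiseaseClass:
        if disease.id in self.diseases:
            raise ModelError(f"duplicate disease id {disease.id!r}")
        self.diseases[disease.id] = disease
        return disease

    def add_test(self, test: TestClass) -> TestClass:
        if test.id in self.tests:
            raise ModelError(f"duplicate test class id {test.id!r}")
        if test.parent_id is not None:
            parent = self.tests.get(test.parent_id)
            if parent is None:
                raise IntegrityError(f"parent test class {test.parent_id!r} not declared")
            if parent.role != test.role:
                raise ModelError(
                    f"test {test.id!r} has role {test.role!r} but parent "
                    f"{parent.id!r} has role {parent.role!r}"
                )
        self.tests[test.id] = test
        # acyclicity: the parent must already exist, so chains cannot loop,
        # but guard against later mutation all the same.
        self.ancestors(test.id)
        return test

    def ancestors(self, test_id: str) -> list[str]:
        """Ancestor chain of ``test_id``, starting with itself."""
        chain: list[str] = []
        seen: set[str] = set()
        current: Optional[str] = test_id
        while current is not None:
            if current in seen:
                raise IntegrityError(f"cycle in test-class parents at {current!r}")
            if current not in self.tests:
                raise IntegrityError(f"unknown test class {current!r}")
            seen.add(current)
            chain.append(current)
            current = self.tests[current].parent_id
        return chain

    def lowest_common_ancestor(self, test_ids: Sequence[str]) -> Optional[str]:
        """Deepest declared class subsuming all of ``test_ids`` (or None)."""
        if not test_ids:
            return None
        chains = [self.ancestors(t) for t in test_ids]
        common = set(chains[0]).intersection(*map(set, chains[1:]))
        for candidate in chains[0]:  # chains run child -> root, so first hit is deepest
            if candidate in common:
                return candidate
        return None

    @classmethod
    def from_json(cls, text: str) -> "TestClassRegistry":
        """Parse ``{"tests": [...], "diseases": [...]}`` declarations."""
        payload = json.loads(text)
        registry = cls()
        for entry in payload.get("diseases", []):
            registry.add_disease(DiseaseClass(id=entry["id"], label=entry.get("label", "")))
        pending = list(payload.get("tests", []))
        # insert parents before children regardless of declaration order
        while pending:
            progressed = False
            remaining = []
            for entry in pending:
                parent = entry.get("parent")
                if parent is None or parent in registry.tests:
                    registry.add_test(
                        TestClass(
                            id=entry["id"],
                            label=entry.get("label", ""),
                            role=entry["role"],
                            parent_id=parent,
                            target_disease=entry.get("target_disease"),
                        )
                    )
                    progressed = True
                else:
                    remaining.append(entry)
            if not progressed:
                missing = sorted(e.get("parent") for e in remaining)
                raise IntegrityError(f"unresolvable test-class parents: {missing}")
            pending = remaining
        return registry

    def to_json(self) -> str:
        return json.dumps(
            {
                "diseases": [
                    {"id": d.id, "label": d.label} for d in sorted(self.diseases.values(), key=lambda d: d.id)
                ],
                "tests": [
                    {
                        "id": t.id,
                        "label": t.label,
                        "role": t.role,
                        "parent": t.parent_id,
                        "target_disease": t.target_disease,
                    }
                    for t in sorted(self.tests.values(), key=lambda t: t.id)
                ],
            },
            indent=2,
        )


@dataclass
class PersonRecord:
    """An individual with latent disease status and test-response propensities.

    ``response_prob`` maps a test-class id to the probability that this
    person would test positive *were that test performed* — the latent,
    possibly-unmanifested quantity that the disposition semantics rest on.
    """

    id: str
    subgroup: str = ""
    diseased: bool = False
    response_prob: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for test_id, p in self.response_prob.items():
            _check_probability(p, f"response probability for {test_id!r}")


@dataclass
class Population:
    """An ordered collection of persons; may be part of a larger one."""

    id: str
    members: list[PersonRecord] = field(default_factory=list)
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ModelError(f"population {self.id!r} has duplicate member ids")

    def member(self, person_id: str) -> PersonRecord:
        for m in self.members:
            if m.id == person_id:
                return m
        raise IntegrityError(f"person {person_id!r} not in population {self.id!r}")

    @property
    def member_index(self) -> dict[str, PersonRecord]:
        return {m.id: m for m in self.members}


@dataclass
class Sample:
    """An ordered subset of a population's members."""

    id: str
    population_id: str
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.member_ids) != len(set(self.member_ids)):
            raise ModelError(f"sample {self.id!r} has duplicate member ids")


@dataclass
class TestProcess:
    """One performance of one test on one person, with its binary result."""

    __test__ = False  # domain class, not a pytest suite

    id: str
    test_class: str
    person_id: str
    result: str

    def __post_init__(self) -> None:
        if self.result not in RESULTS:
            raise ModelError(
                f"test result must be 'positive' or 'negative', got {self.result!r} "
                "(indeterminate results are not modelled)"
            )


@dataclass
class TestsExecution:
    """The paired performance of index and reference tests on a sample."""

    __test__ = False  # domain class, not a pytest suite

    id: str
    sample_id: str
    index_class: str
    reference_class: str
    processes: list[TestProcess] = field(default_factory=list)


@dataclass
class ContingencyTable:
    """Recorded 2x2 counts from a tests execution.

    A *false positive* is a person positive on the index test but negative
    on the reference test; the other three cells follow the same pattern.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    id: str = "table"
    source_execution: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            count = getattr(self, name)
            if not isinstance(count, (int,)) or isinstance(count, bool) or count < 0:
                raise ModelError(f"{name} must be a non-negative integer, got {count!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Disposition:
    """A population-borne disposition whose probability is a real IP value.

    The trigger/realization descriptors spell out the randomization reading:
    e.g. for sensitivity, the trigger is performing the index test on the
    whole group and drawing one diseased member at random; the realization
    is that draw returning someone who tested positive.
    """

    id: str
    bearer_id: str
    kind: str
    disease: str
    index_class: Optional[str] = None
    trigger_descriptor: str = ""
    realization_descriptor: str = ""
    probability: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in IP_KINDS:
            raise ModelError(f"unknown indicator kind {self.kind!r}")
        _check_probability(self.probability, "disposition probability")
        if self.kind == "prevalence":
            if self.index_class is not None:
                raise ModelError("a prevalence disposition has no index test class")
        elif self.index_class is None:
            raise ModelError(f"a {self.kind} disposition requires an index test class")


@dataclass
class DispositionClass:
    """The class of dispositions for one (kind, index test, disease) triple."""

    id: str
    kind: str
    index_class: str
    disease: str

    def __post_init__(self) -> None:
        if self.kind not in IP_KINDS:
            raise ModelError(f"unknown indicator kind {self.kind!r}")


@dataclass
class IPEstimate:
    """A data item: a measured or pooled indicator value, about a disposition."""

    id: str
    kind: str
    value: float
    n_denominator: int
    about: Optional[str] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    inputs: list[str] = field(default_factory=list)
    method: str = ""

    def __post_init__(self) -> None:
        if self.kind not in IP_KINDS:
            raise ModelError(f"unknown indicator kind {self.kind!r}")
        _check_probability(self.value, "estimate value")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ModelError("confidence interval needs both bounds")
        if self.ci_low is not None and self.ci_high is not None:
            if not 0.0 <= self.ci_low <= self.value <= self.ci_high <= 1.0:
                raise ModelError(
                    f"confidence interval [{self.ci_low}, {self.ci_high}] must "
                    f"bracket the estimate {self.value} within [0, 1]"
                )


@dataclass
class Computation:
    """A planned process turning inputs (tables, estimates) into an estimate."""

    id: str
    method: str = ""


NodeType = Union[
    DiseaseClass,
    TestClass,
    PersonRecord,
    Population,
    Sample,
    TestProcess,
    TestsExecution,
    ContingencyTable,
    Disposition,
    DispositionClass,
    IPEstimate,
    Computation,
]

Edge = tuple[str, str, Union[str, float]]


@dataclass
class Violation:
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self):
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)


class InstanceGraph:
    """Typed nodes plus edges drawn from the closed relation vocabulary."""

    def __init__(self) -> None:
        self.nodes: dict[str, NodeType] = {}
        self.edges: list[Edge] = []

    def add_node(self, node: NodeType) -> NodeType:
        existing = self.nodes.get(node.id)
        if existing is not None and existing is not node:
            raise ModelError(f"node id {node.id!r} already present")
        self.nodes[node.id] = node
        return node

    def add_edge(self, subject: str, relation: str, obj: Union[str, float]) -> Edge:
        if relation not in RELATIONS:
            raise VocabularyError(f"relation {relation!r} is outside the closed vocabulary")
        edge = (subject, relation, obj)
        self.edges.append(edge)
        return edge

    def has_edge(self, subject: str, relation: str, obj: Union[str, float]) -> bool:
        return (subject, relation, obj) in self.edges

    def objects(self, subject: str, relation: str) -> list[Union[str, float]]:
        return [o for s, r, o in self.edges if s == subject and r == relation]

    def subjects(self, relation: str, obj: Union[str, float]) -> list[str]:
        return [s for s, r, o in self.edges if r == relation and o == obj]


def build_tests_execution(
    sample: Sample,
    index_class: TestClass,
    reference_class: TestClass,
    results: Mapping[str, tuple[str, str]],
    *,
    graph: Optional[InstanceGraph] = None,
    ids: Optional[IdFactory] = None,
) -> TestsExecution:
    """Assemble the paired test processes for every member of a sample.

    ``results`` maps each sample member id to its ``(index_result,
    reference_result)`` pair.  Two process nodes are created per member, so
    an execution over ``n`` members always holds ``2n`` processes.  When a
    graph is supplied, ``participates_in`` and ``part_of`` edges are added.
    """
    if not sample.member_ids:
        raise InputShapeError("cannot execute tests on an empty sample")
    missing = [m for m in sample.member_ids if m not in results]
    extra = [m for m in results if m not in sample.member_ids]
    if missing or extra:
        raise InputShapeError(
            f"result pairs must cover the sample exactly; missing={missing!r}, extra={extra!r}"
        )
    ids = ids or IdFactory()
    execution = TestsExecution(
        id=ids.mint("tests_execution"),
        sample_id=sample.id,
        index_class=index_class.id,
        reference_class=reference_class.id,
    )
    for person_id in sample.member_ids:
        index_result, reference_result = results[person_id]
        it = TestProcess(ids.mint("it"), index_class.id, person_id, index_result)
        rt = TestProcess(ids.mint("rt"), reference_class.id, person_id, reference_result)
        execution.processes.extend((rt, it))
        if graph is not None:
            for proc in (rt, it):
                graph.add_node(proc)
                graph.add_edge(person_id, "participates_in", proc.id)
                graph.add_edge(proc.id, "part_of", execution.id)
    if graph is not None:
        graph.add_node(execution)
    return execution


def record_tests_results(
    execution: TestsExecution,
    *,
    graph: Optional[InstanceGraph] = None,
    ids: Optional[IdFactory] = None,
) -> ContingencyTable:
    """Classify each tested person as TP/FP/FN/TN and count.

    TP: index positive, reference positive.  FP: index positive, reference
    negative.  FN: index negative, reference positive.  TN: both negative.
    The four counts partition the sample, so they sum to its size.
    """
    by_person: dict[str, dict[str, str]] = {}
    for proc in execution.processes:
        slot = by_person.setdefault(proc.person_id, {})
        if proc.test_class == execution.index_class:
            key = "index"
        elif proc.test_class == execution.reference_class:
            key = "reference"
        else:
            raise IntegrityError(
                f"process {proc.id!r} uses test class {proc.test_class!r} foreign to the execution"
            )
        if key in slot:
            raise IntegrityError(f"person {proc.person_id!r} has duplicate {key} processes")
        slot[key] = proc.result
    counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for person_id, slot in by_person.items():
        if set(slot) != {"index", "reference"}:
            raise IntegrityError(f"person {person_id!r} is missing a test process")
        index_pos = slot["index"] == "positive"
        ref_pos = slot["reference"] == "positive"
        if index_pos and ref_pos:
            counts["tp"] += 1
        elif index_pos:
            counts["fp"] += 1
        elif ref_pos:
            counts["fn"] += 1
        else:
            counts["tn"] += 1
    ids = ids or IdFactory()
    table = ContingencyTable(
        id=ids.mint("tests_results"), source_execution=execution.id, **counts
    )
    if graph is not None:
        graph.add_node(table)
        graph.add_edge(execution.id, "has_specified_output", table.id)
    return table


def _part_of_cycles(graph: InstanceGraph) -> list[list[str]]:
    """Cycles in the union of part_of edges and population parent links."""
    succ: dict[str, set[str]] = {}
    for s, r, o in graph.edges:
        if r == "part_of" and isinstance(o, str):
            succ.setdefault(s, set()).add(o)
    for node in graph.nodes.values():
        if isinstance(node, Population) and node.parent_id:
            succ.setdefault(node.id, set()).add(node.parent_id)
    cycles: list[list[str]] = []
    color: dict[str, int] = {}

    def visit(n: str, stack: list[str]) -> None:
        color[n] = 1
        stack.append(n)
        for m in succ.get(n, ()):
            if color.get(m, 0) == 1:
                cycles.append(stack[stack.index(m) :] + [m])
            elif color.get(m, 0) == 0:
                visit(m, stack)
        stack.pop()
        color[n] = 2

    for n in list(succ):
        if color.get(n, 0) == 0:
            visit(n, [])
    return cycles


def validate_instance_graph(graph: InstanceGraph) -> ValidationReport:
    """Collect structural violations; an empty report means the graph is valid."""
    report = ValidationReport()

    for s, r, o in graph.edges:
        if r not in RELATIONS:
            report.violations.append(Violation("vocabulary", f"relation {r!r} unknown"))
            continue
        if s not in graph.nodes:
            report.violations.append(Violation("dangling", f"edge subject {s!r} has no node"))
        if r in LITERAL_RELATIONS:
            if not isinstance(o, (int, float)) or isinstance(o, bool):
                report.violations.append(
                    Violation("literal", f"{r} edge from {s!r} must carry a numeric literal")
                )
        elif isinstance(o, str):
            if o not in graph.nodes:
                report.violations.append(Violation("dangling", f"edge object {o!r} has no node"))
        else:
            report.violations.append(
                Violation("literal", f"{r} edge from {s!r} cannot carry a literal object")
            )

    for cycle in _part_of_cycles(graph):
        report.violations.append(
            Violation("part_of_cycle", "part_of cycle: " + " -> ".join(cycle))
        )

    for node in graph.nodes.values():
        if isinstance(node, Sample):
            pop = graph.nodes.get(node.population_id)
            if isinstance(pop, Population):
                known = set(pop.member_index)
                stray = [m for m in node.member_ids if m not in known]
                if stray:
                    report.violations.append(
                        Violation(
                            "sample_membership",
                            f"sample {node.id!r} members {stray!r} are not in population {pop.id!r}",
                        )
                    )
        elif isinstance(node, TestsExecution):
            sample = graph.nodes.get(node.sample_id)
            if isinstance(sample, Sample) and len(node.processes) != 2 * len(sample.member_ids):
                report.violations.append(
                    Violation(
                        "process_count",
                        f"execution {node.id!r} has {len(node.processes)} processes for "
                        f"{len(sample.member_ids)} members (expected 2 per member)",
                    )
                )
        elif isinstance(node, IPEstimate):
            about_edges = [o for o in graph.objects(node.id, "is_about") if isinstance(o, str)]
            if not about_edges and node.about is None:
                report.violations.append(
                    Violation("aboutness", f"estimate {node.id!r} lacks an is_about edge")
                )
            targets = set(about_edges)
            if node.about is not None:
                targets.add(node.about)
            for target in targets:
                disp = graph.nodes.get(target)
                if disp is None:
                    if target not in about_edges:  # edge-based danglers already reported
                        report.violations.append(
                            Violation("dangling", f"estimate {node.id!r} is about missing {target!r}")
                        )
                elif not isinstance(disp, Disposition):
                    report.violations.append(
                        Violation("aboutness", f"estimate {node.id!r} is about a non-disposition")
                    )
                elif disp.kind != node.kind:
                    report.violations.append(
                        Violation(
                            "kind_mismatch",
                            f"{node.kind} estimate {node.id!r} is about a {disp.kind} disposition",
                        )
                    )
    return report
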