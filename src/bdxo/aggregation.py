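"""Compatibility-checked pooling of indicator estimates.

Two estimates of the same indicator may be combined into a finer one only
when the studies behind them are commensurable: their index tests subsume
under a common declared index-test class, their reference tests under a
common reference-test class, and their samples' populations under a common
encompassing population.  :func:`check_compatibility` verifies exactly
that, by lowest-common-ancestor search over the declared hierarchies —
nothing is guessed when no hierarchy is declared.

Pooling itself is deliberately modest: exact pooled counts (concatenate
the underlying 2x2 tables and re-measure), or a fixed-effect
inverse-variance average on the logit scale.  The pooled estimate is a new
data item whose provenance records the input estimates, and which is
*about* the disposition of the encompassing population and test classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from scipy.stats import norm

from .model import (
    Computation,
    ContingencyTable,
    Disposition,
    IdFactory,
    InstanceGraph,
    IntegrityError,
    IPEstimate,
    ModelError,
    Population,
    Sample,
    TestClassRegistry,
    TestsExecution,
)

__all__ = [
    "CompatibilityReport",
    "AggregationMethod",
    "IncompatibleEstimatesError",
    "check_compatibility",
    "aggregate_estimates",
]

_NUMERATOR = {
    "sensitivity": lambda t: (t.tp, t.tp + t.fn),
    "specificity": lambda t: (t.tn, t.tn + t.fp),
    "ppv": lambda t: (t.tp, t.tp + t.fp),
    "npv": lambda t: (t.tn, t.tn + t.fn),
    "prevalence": lambda t: (t.tp + t.fn, t.total),
}


class IncompatibleEstimatesError(ModelError):
    """The estimates fail the subsumption conditions for pooling."""


@dataclass
class CompatibilityReport:
    compatible: bool
    common_index_class: Optional[str] = None
    common_reference_class: Optional[str] = None
    common_population: Optional[str] = None
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.compatible and None in (
            self.common_index_class,
            self.common_reference_class,
            self.common_population,
        ):
            raise ModelError("a compatible report must name all three common classes")


@dataclass
class AggregationMethod:
    name: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ("pooled_counts", "inverse_variance_logit"):
            raise ModelError(f"unknown aggregation method {self.name!r}")


def _leaf_tables(estimate: IPEstimate, graph: InstanceGraph) -> list[ContingencyTable]:
    """Resolve an estimate's provenance down to its contingency tables."""
    tables: list[ContingencyTable] = []
    for input_id in estimate.inputs:
        node = graph.nodes.get(input_id)
        if isinstance(node, ContingencyTable):
            tables.append(node)
        elif isinstance(node, IPEstimate):
            tables.extend(_leaf_tables(node, graph))
        else:
            raise IntegrityError(
                f"estimate {estimate.id!r} input {input_id!r} is not a table or estimate in the graph"
            )
    return tables


def _study_context(estimate: IPEstimate, graph: InstanceGraph) -> tuple[set[str], set[str], set[str]]:
    """(index classes, reference classes, population ids) behind an estimate."""
    index_classes: set[str] = set()
    reference_classes: set[str] = set()
    populations: set[str] = set()
    for table in _leaf_tables(estimate, graph):
        if table.source_execution is None:
            raise IntegrityError(f"table {table.id!r} has no source execution")
        execution = graph.nodes.get(table.source_execution)
        if not isinstance(execution, TestsExecution):
            raise IntegrityError(f"table {table.id!r} source {table.source_execution!r} missing")
        index_classes.add(execution.index_class)
        reference_classes.add(execution.reference_class)
        sample = graph.nodes.get(execution.sample_id)
        if not isinstance(sample, Sample):
            raise IntegrityError(f"execution {execution.id!r} sample {execution.sample_id!r} missing")
        populations.add(sample.population_id)
    return index_classes, reference_classes, populations


def _population_ancestors(pop_id: str, graph: InstanceGraph) -> list[str]:
    chain: list[str] = []
    seen: set[str] = set()
    current: Optional[str] = pop_id
    while current is not None:
        if current in seen:
            raise IntegrityError(f"cycle in population parents at {current!r}")
        node = graph.nodes.get(current)
        if not isinstance(node, Population):
            raise IntegrityError(f"population {current!r} missing from graph")
        seen.add(current)
        chain.append(current)
        current = node.parent_id
    return chain


def check_compatibility(
    estimates: list[IPEstimate], registry: TestClassRegistry, graph: InstanceGraph
) -> CompatibilityReport:
    """Decide whether estimates may be pooled, and under which common classes.

    The common index/reference class is the lowest common ancestor in the
    declared test hierarchy; the common population is the lowest common
    ancestor of the samples' populations along their declared parent
    links.  Estimates are compatible iff all three exist.
    """
    if not estimates:
        raise ModelError("need at least one estimate")
    kinds = {e.kind for e in estimates}
    if len(kinds) > 1:
        raise ModelError(f"cannot mix estimate kinds {sorted(kinds)}")
    index_classes: set[str] = set()
    reference_classes: set[str] = set()
    populations: set[str] = set()
    for estimate in estimates:
        its, rts, pops = _study_context(estimate, graph)
        index_classes |= its
        reference_classes |= rts
        populations |= pops
    reasons: list[str] = []

    def lca_or_reason(class_ids: set[str], what: str) -> Optional[str]:
        try:
            found = registry.lowest_common_ancestor(sorted(class_ids))
        except IntegrityError as exc:
            reasons.append(str(exc))
            return None
        if found is None:
            reasons.append(f"{what} classes {sorted(class_ids)} share no declared ancestor")
        return found

    common_index = lca_or_reason(index_classes, "index test")
    common_reference = lca_or_reason(reference_classes, "reference test")
    chains = [_population_ancestors(p, graph) for p in sorted(populations)]
    common_pop: Optional[str] = None
    if chains:
        shared = set(chains[0]).intersection(*map(set, chains[1:]))
        for candidate in chains[0]:
            if candidate in shared:
                common_pop = candidate
                break
    if common_pop is None:
        reasons.append(f"populations {sorted(populations)} share no encompassing population")
    compatible = None not in (common_index, common_reference, common_pop)
    return CompatibilityReport(
        compatible=compatible,
        common_index_class=common_index,
        common_reference_class=common_reference,
        common_population=common_pop,
        reasons=reasons,
    )


def _pooled_counts(estimates: list[IPEstimate], graph: InstanceGraph) -> tuple[float, int, int]:
    kind = estimates[0].kind
    take = _NUMERATOR[kind]
    num = den = 0
    for estimate in estimates:
        for table in _leaf_tables(estimate, graph):
            x, n = take(table)
            num += x
            den += n
    if den == 0:
        raise ModelError("pooled denominator is empty")
    return num / den, num, den


def _inverse_variance_logit(estimates: list[IPEstimate]) -> tuple[float, float, float, int]:
    """Fixed-effect logit pooling; returns (value, lo, hi, total n)."""
    xs, ns = [], []
    for estimate in estimates:
        n = estimate.n_denominator
        x = estimate.value * n
        xs.append(x)
        ns.append(n)
    corrected = any(x <= 0.0 or x >= n for x, n in zip(xs, ns))
    if corrected:
        # standard continuity correction at the boundaries
        xs = [x + 0.5 for x in xs]
        ns = [n + 1.0 for n in ns]
    weights, logits = [], []
    for x, n in zip(xs, ns):
        var = 1.0 / x + 1.0 / (n - x)
        weights.append(1.0 / var)
        logits.append(math.log(x / (n - x)))
    total_weight = sum(weights)
    pooled_logit = sum(w * l for w, l in zip(weights, logits)) / total_weight
    se = 1.0 / math.sqrt(total_weight)
    z = float(norm.ppf(0.975))
    inv = lambda t: 1.0 / (1.0 + math.exp(-t))
    return (
        inv(pooled_logit),
        inv(pooled_logit - z * se),
        inv(pooled_logit + z * se),
        int(sum(e.n_denominator for e in estimates)),
    )


def aggregate_estimates(
    estimates: list[IPEstimate],
    method: AggregationMethod,
    about: Disposition,
    *,
    registry: TestClassRegistry,
    graph: InstanceGraph,
    ids: Optional[IdFactory] = None,
) -> IPEstimate:
    """Pool compatible estimates into one finer estimate with provenance.

    Refuses outright if :func:`check_compatibility` fails.  The graph gains
    one computation node with a ``has_specified_input`` edge per input
    estimate and a single ``has_specified_output`` edge to the pooled
    estimate, which is ``is_about`` the encompassing disposition.
    """
    report = check_compatibility(estimates, registry, graph)
    if not report.compatible:
        raise IncompatibleEstimatesError("; ".join(report.reasons) or "estimates are incompatible")
    kind = estimates[0].kind
    if about.kind != kind:
        raise ModelError(f"cannot attach a {kind} pooled estimate to a {about.kind} disposition")
    ids = ids or IdFactory()
    if method.name == "pooled_counts":
        value, num, den = _pooled_counts(estimates, graph)
        from .estimation import wilson_interval

        ci = wilson_interval(num, den)
        ci_low, ci_high, n_total = ci.low, ci.high, den
        method_label = "pooled_counts"
    else:
        value, ci_low, ci_high, n_total = _inverse_variance_logit(estimates)
        method_label = "inverse_variance_logit (fixed effect)"
        if any(e.value in (0.0, 1.0) for e in estimates):
            method_label += ", continuity correction 0.5"
    pooled = IPEstimate(
        id=ids.mint(f"estimate_{kind}_pooled"),
        kind=kind,
        value=value,
        n_denominator=n_total,
        about=about.id,
        ci_low=min(ci_low, value),
        ci_high=max(ci_high, value),
        inputs=[e.id for e in estimates],
        method=method_label,
    )
    computation = Computation(id=ids.mint(f"computation_{kind}_pooled"), method=method_label)
    graph.add_node(pooled)
    graph.add_node(computation)
    for estimate in estimates:
        graph.add_edge(computation.id, "has_specified_input", estimate.id)
    graph.add_edge(computation.id, "has_specified_output", pooled.id)
    graph.add_edge(pooled.id, "has_specified_value", pooled.value)
    graph.add_edge(pooled.id, "is_about", about.id)
    return pooled
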