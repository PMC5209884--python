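"""Indicator-of-performance estimates from 2x2 contingency tables.

Each estimator turns a contingency table into an :class:`~bdxo.model.IPEstimate`
data item carrying the measured sample proportion, a binomial confidence
interval, the identifier of its source table (provenance) and, optionally,
the disposition the estimate is *about*.

The point values are the sample proportions:

* sensitivity  tp / (tp + fn)   — positives on the index test among
  reference-test positives;
* specificity  tn / (tn + fp);
* PPV          tp / (tp + fp);
* NPV          tn / (tn + fn);
* prevalence   (tp + fn) / n    — reference-test positives among all tested.

The confidence interval quantifies sampling uncertainty only: it speaks to
how well the sample proportion pins down the corresponding population
proportion under the chosen reference test, not to how far that proportion
sits from the disease-defined quantity an imperfect reference introduces.
Wilson score intervals are the default (good small-n coverage, never leave
[0, 1]); exact Clopper-Pearson intervals are available via ``method``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Optional

from statsmodels.stats.proportion import proportion_confint

from .model import (
    ContingencyTable,
    Disposition,
    IdFactory,
    InstanceGraph,
    IPEstimate,
    ModelError,
)

__all__ = [
    "ConfidenceInterval",
    "UndefinedProportionError",
    "wilson_interval",
    "clopper_pearson_interval",
    "estimate_sensitivity",
    "estimate_specificity",
    "estimate_ppv",
    "estimate_npv",
    "estimate_prevalence",
    "read_counts_csv",
    "estimate_to_json",
]


class UndefinedProportionError(ModelError):
    """The requested proportion has an empty denominator."""


@dataclass
class ConfidenceInterval:
    low: float
    high: float
    level: float

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ModelError(f"confidence level must lie in (0, 1), got {self.level!r}")
        if not 0.0 <= self.low <= self.high <= 1.0:
            raise ModelError(f"interval [{self.low}, {self.high}] is not ordered within [0, 1]")

    def __contains__(self, value: float) -> bool:
        return self.low <= value <= self.high


def _interval(successes: int, trials: int, level: float, method: str) -> ConfidenceInterval:
    if trials <= 0:
        raise UndefinedProportionError("confidence interval needs at least one trial")
    if not 0 <= successes <= trials:
        raise ModelError(f"successes {successes} must lie in [0, {trials}]")
    low, high = proportion_confint(successes, trials, alpha=1.0 - level, method=method)
    # at p-hat = 0 (resp. 1) both intervals have an exactly-0 (resp. 1) bound;
    # snap away float round-off so the bound is attained, then clip to [0, 1]
    if successes == 0:
        low = 0.0
    if successes == trials:
        high = 1.0
    return ConfidenceInterval(low=max(0.0, float(low)), high=min(1.0, float(high)), level=level)


def wilson_interval(successes: int, trials: int, level: float = 0.95) -> ConfidenceInterval:
    """Wilson score interval for a binomial proportion."""
    return _interval(successes, trials, level, "wilson")


def clopper_pearson_interval(successes: int, trials: int, level: float = 0.95) -> ConfidenceInterval:
    """Exact (Clopper-Pearson) interval for a binomial proportion."""
    return _interval(successes, trials, level, "beta")


_CI_METHODS = {"wilson": wilson_interval, "clopper-pearson": clopper_pearson_interval}


def _estimate(
    kind: str,
    successes: int,
    trials: int,
    table: ContingencyTable,
    about: Optional[Disposition],
    level: float,
    method: str,
    graph: Optional[InstanceGraph],
    ids: Optional[IdFactory],
) -> IPEstimate:
    if trials == 0:
        raise UndefinedProportionError(
            f"{kind} is undefined for this table: its denominator is empty"
        )
    if about is not None and about.kind != kind:
        raise ModelError(
            f"cannot attach a {kind} estimate to a {about.kind} disposition"
        )
    try:
        make_ci = _CI_METHODS[method]
    except KeyError:
        raise ModelError(f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}")
    ci = make_ci(successes, trials, level)
    ids = ids or IdFactory()
    estimate = IPEstimate(
        id=ids.mint(f"estimate_{kind}"),
        kind=kind,
        value=successes / trials,
        n_denominator=trials,
        about=None if about is None else about.id,
        ci_low=ci.low,
        ci_high=ci.high,
        inputs=[table.id],
        method=f"sample proportion; {method} {level:g} CI",
    )
    if graph is not None:
        from .model import Computation  # local to avoid import noise at module top

        graph.add_node(estimate)
        computation = Computation(id=ids.mint(f"computation_{kind}"), method=estimate.method)
        graph.add_node(computation)
        graph.add_edge(computation.id, "has_specified_input", table.id)
        graph.add_edge(computation.id, "has_specified_output", estimate.id)
        graph.add_edge(estimate.id, "has_specified_value", estimate.value)
        if about is not None:
            graph.add_edge(estimate.id, "is_about", about.id)
    return estimate


def estimate_sensitivity(
    table: ContingencyTable,
    about: Optional[Disposition] = None,
    level: float = 0.95,
    *,
    method: str = "wilson",
    graph: Optional[InstanceGraph] = None,
    ids: Optional[IdFactory] = None,
) -> IPEstimate:
    """Sensitivity estimate tp/(tp+fn): index positives among reference positives."""
    return _estimate("sensitivity", table.tp, table.tp + table.fn, table, about, level, method, graph, ids)


def estimate_specificity(
    table: ContingencyTable,
    about: Optional[Disposition] = None,
    level: float = 0.95,
    *,
    method: str = "wilson",
    graph: Optional[InstanceGraph] = None,
    ids: Optional[IdFactory] = None,
) -> IPEstimate:
    """Specificity estimate tn/(tn+fp): index negatives among reference negatives."""
    return _estimate("specificity", table.tn, table.tn + table.fp, table, about, level, method, graph, ids)


def estimate_ppv(
    table: ContingencyTable,
    about: Optional[Disposition] = None,
    level: float = 0.95,
    *,
    method: str = "wilson",
    graph: Optional[InstanceGraph] = None,
    ids: Optional[IdFactory] = None,
) -> IPEstimate:
    """Positive predictive value estimate tp/(tp+fp)."""
    return _estimate("ppv", table.tp, table.tp + table.fp, table, about, level, method, graph, ids)


def estimate_npv(
    table: ContingencyTable,
    about: Optional[Disposition] = None,
    level: float = 0.95,
    *,
    method: str = "wilson",
    graph: Optional[InstanceGraph] = None,
    ids: Optional[IdFactory] = None,
) -> IPEstimate:
    """Negative predictive value estimate tn/(tn+fn)."""
    return _estimate("npv", table.tn, table.tn + table.fn, table, about, level, method, graph, ids)


def estimate_prevalence(
    table: ContingencyTable,
    about: Optional[Disposition] = None,
    level: float = 0.95,
    *,
    method: str = "wilson",
    graph: Optional[InstanceGraph] = None,
    ids: Optional[IdFactory] = None,
) -> IPEstimate:
    """Prevalence estimate (tp+fn)/n, as operationalized by the reference test."""
    return _estimate("prevalence", table.tp + table.fn, table.total, table, about, level, method, graph, ids)


def read_counts_csv(text: str, *, table_id: str = "table") -> ContingencyTable:
    """Parse a one-row ``tp,fp,fn,tn`` CSV into a contingency table."""
    import pandas as pd

    frame = pd.read_csv(io.StringIO(text))
    expected = ["tp", "fp", "fn", "tn"]
    if list(frame.columns) != expected:
        raise ModelError(f"counts CSV must have header {','.join(expected)!r}, got {list(frame.columns)!r}")
    if len(frame) != 1:
        raise ModelError(f"counts CSV must have exactly one data row, got {len(frame)}")
    row = frame.iloc[0]
    return ContingencyTable(
        tp=int(row.tp), fp=int(row.fp), fn=int(row.fn), tn=int(row.tn), id=table_id
    )


def estimate_to_json(estimate: IPEstimate, level: float = 0.95) -> str:
    """Serialize an estimate to the interchange JSON shape."""
    return json.dumps(
        {
            "kind": estimate.kind,
            "value": estimate.value,
            "ci": [estimate.ci_low, estimate.ci_high],
            "level": level,
            "n": estimate.n_denominator,
            "about": estimate.about,
            "inputs": estimate.inputs,
            "method": estimate.method,
        }
    )
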