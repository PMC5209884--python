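"""Bayes equations linking predictive values to prevalence, Se and Sp.

With Prev the prevalence, Se the sensitivity and Sp the specificity,

    PPV = Prev*Se / (Prev*Se + (1 - Prev)*(1 - Sp))
    NPV = (1 - Prev)*Sp / (Prev*(1 - Se) + (1 - Prev)*Sp)

These hold exactly when the three inputs are the proportions of one group,
and the same identity holds for the sample proportions of any single 2x2
table — which :func:`bayes_table_consistency` checks to float precision.
The practical point is the converse: predictive values *cannot* be carried
from one population to another without re-applying these equations at the
new prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ContingencyTable, ModelError

__all__ = [
    "BayesInputs",
    "UndefinedValueError",
    "ppv_from_bayes",
    "npv_from_bayes",
    "BayesConsistencyReport",
    "bayes_table_consistency",
]


class UndefinedValueError(ModelError):
    """The Bayes formula denominator vanishes for these inputs."""


def _check_unit(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ModelError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class BayesInputs:
    """Point values (prevalence, sensitivity, specificity) for one group."""

    prev: float
    se: float
    sp: float

    def __post_init__(self) -> None:
        _check_unit(self.prev, "prevalence")
        _check_unit(self.se, "sensitivity")
        _check_unit(self.sp, "specificity")


def ppv_from_bayes(inputs: BayesInputs) -> float:
    """Positive predictive value from (Prev, Se, Sp)."""
    numerator = inputs.prev * inputs.se
    denominator = numerator + (1.0 - inputs.prev) * (1.0 - inputs.sp)
    if denominator == 0.0:
        raise UndefinedValueError(
            "PPV undefined: nobody tests positive for these (prev, se, sp)"
        )
    return numerator / denominator


def npv_from_bayes(inputs: BayesInputs) -> float:
    """Negative predictive value from (Prev, Se, Sp)."""
    numerator = (1.0 - inputs.prev) * inputs.sp
    denominator = inputs.prev * (1.0 - inputs.se) + numerator
    if denominator == 0.0:
        raise UndefinedValueError(
            "NPV undefined: nobody tests negative for these (prev, se, sp)"
        )
    return numerator / denominator


@dataclass(frozen=True)
class BayesConsistencyReport:
    ppv_direct: float
    ppv_bayes: float
    npv_direct: float
    npv_bayes: float

    @property
    def max_abs_discrepancy(self) -> float:
        return max(
            abs(self.ppv_direct - self.ppv_bayes), abs(self.npv_direct - self.npv_bayes)
        )


def bayes_table_consistency(table: ContingencyTable) -> BayesConsistencyReport:
    """Check the algebraic identity between the Bayes route and direct counts.

    Plugging the table's own prevalence, sensitivity and specificity
    estimates into the Bayes equations must reproduce tp/(tp+fp) and
    tn/(tn+fn) up to floating-point rounding.  All four margins must be
    positive for the five proportions to exist.
    """
    margins = {
        "tp+fn": table.tp + table.fn,
        "tn+fp": table.tn + table.fp,
        "tp+fp": table.tp + table.fp,
        "tn+fn": table.tn + table.fn,
    }
    empty = sorted(name for name, value in margins.items() if value == 0)
    if empty:
        raise UndefinedValueError(f"empty margins {empty} leave a proportion undefined")
    inputs = BayesInputs(
        prev=(table.tp + table.fn) / table.total,
        se=table.tp / (table.tp + table.fn),
        sp=table.tn / (table.tn + table.fp),
    )
    return BayesConsistencyReport(
        ppv_direct=table.tp / (table.tp + table.fp),
        ppv_bayes=ppv_from_bayes(inputs),
        npv_direct=table.tn / (table.tn + table.fn),
        npv_bayes=npv_from_bayes(inputs),
    )
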