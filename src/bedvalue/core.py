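"""Domain types and net-benefit primitives for valuing hospital bed-days.

The central objects are a case mix — the patient groups competing for the
same beds — and an economic context carrying the cost-effectiveness
threshold lambda (money per QALY) and the bed occupancy rate.  Everything
here is pure computation; file I/O lives in :mod:`bedvalue.io`.

Conventions
-----------
* ``PatientGroup`` fields are *per patient* (one admission of that group):
  length of stay ``LOS_j`` in bed-days, expenditure ``C_j``, optional
  revenue ``R_j`` and QALY gain ``B_j``.
* ``ChosenOption`` fields are *totals* for the resource consumption being
  valued: ``LOS_i`` bed-days (possibly only the excess part of a stay),
  expenditure ``C_i``, optional variable-cost share ``VC_i``.
* Monetary amounts are plain floats in an arbitrary currency; the context
  carries a currency label for presentation only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import EmptyCaseMixError, InvalidContextError, MissingInputError

logger = logging.getLogger(__name__)

#: Relative tolerance for score comparisons (ties, optimality checks).
REL_TOL = 1e-9

Objective = Literal["throughput", "expenditure", "revenue", "net_revenue", "health", "nmb"]
Perspective = Literal["provider", "payer", "societal"]


class PatientGroup(BaseModel):
    """One alternative use of the beds: a (group of) patient(s) awaiting admission.

    ``los_per_patient`` must be strictly positive — it is the denominator of
    every patient-equivalent calculation.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    los_per_patient: float = Field(gt=0, description="bed-days per patient (LOS_j)")
    expenditure_per_patient: float = Field(ge=0, description="money per patient (C_j)")
    revenue_per_patient: float | None = Field(default=None, ge=0, description="money per patient (R_j)")
    qaly_gain_per_patient: float | None = Field(default=None, description="marginal QALY gain per patient (B_j)")
    n_available: float | None = Field(default=None, ge=0, description="patients awaiting admission")


class ChosenOption(BaseModel):
    """The resource consumption being valued: LOS_i bed-days costing C_i.

    ``los_total`` is the *excess* consumption to be valued, which need not be
    the full length of stay.  ``variable_cost_total`` is the variable share
    of ``expenditure_total`` (cash actually released in the short run).
    """

    model_config = ConfigDict(frozen=True)

    id: str
    los_total: float = Field(ge=0, description="bed-days consumed (LOS_i)")
    expenditure_total: float = Field(ge=0, description="money (C_i)")
    variable_cost_total: float | None = Field(default=None, ge=0, description="money (VC_i)")
    revenue_total: float | None = None
    qaly_gain_total: float | None = None

    @model_validator(mode="after")
    def _variable_within_total(self) -> "ChosenOption":
        if self.variable_cost_total is not None and self.variable_cost_total > self.expenditure_total:
            raise ValueError(
                f"variable_cost_total ({self.variable_cost_total}) exceeds "
                f"expenditure_total ({self.expenditure_total})"
            )
        return self


class EconomicContext(BaseModel):
    """Decision-making context: threshold, occupancy, objective, perspective.

    Under excess demand (waiting lists, unmet demand) every freed bed is
    redeployed, so the effective occupancy factor is forced to 1 regardless
    of ``occupancy_rate``.  ``perspective`` is informational only.
    """

    model_config = ConfigDict(frozen=True)

    threshold: float = Field(gt=0, description="money per QALY (lambda)")
    occupancy_rate: float = Field(default=1.0, gt=0, le=1, description="fraction of freed capacity redeployed (OCR)")
    excess_demand: bool = True
    objective: Objective = "nmb"
    perspective: Perspective = "provider"
    currency: str = "£"

    @property
    def effective_occupancy(self) -> float:
        """Occupancy factor E actually applied: 1 under excess demand, else OCR."""
        return 1.0 if self.excess_demand else self.occupancy_rate


class CaseMix(BaseModel):
    """Patient groups competing for the beds plus the designated chosen use.

    ``chosen`` is either an explicit :class:`ChosenOption` or the id of one
    of the groups; in the latter case the chosen consumption is a single
    admission of that group (its per-patient values taken as totals).
    """

    model_config = ConfigDict(frozen=True)

    options: tuple[PatientGroup, ...] = Field(min_length=1)
    chosen: Union[ChosenOption, str]

    @model_validator(mode="after")
    def _check_ids(self) -> "CaseMix":
        ids = [g.id for g in self.options]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate group ids in case mix: {ids}")
        if isinstance(self.chosen, str) and self.chosen not in ids:
            raise ValueError(f"chosen id {self.chosen!r} not among options {ids}")
        return self

    @property
    def chosen_id(self) -> str:
        return self.chosen if isinstance(self.chosen, str) else self.chosen.id

    def resolve_chosen(self) -> ChosenOption:
        """The chosen consumption as a ChosenOption.

        When ``chosen`` is a group id, the group's per-patient values become
        the totals of one admission (variable-cost share unknown).
        """
        if isinstance(self.chosen, ChosenOption):
            return self.chosen
        g = self.group(self.chosen)
        return ChosenOption(
            id=g.id,
            los_total=g.los_per_patient,
            expenditure_total=g.expenditure_per_patient,
            revenue_total=g.revenue_per_patient,
            qaly_gain_total=g.qaly_gain_per_patient,
        )

    def group(self, group_id: str) -> PatientGroup:
        for g in self.options:
            if g.id == group_id:
                return g
        raise KeyError(group_id)

    def alternatives(self) -> tuple[PatientGroup, ...]:
        """Groups other than the chosen one (the candidate forgone uses)."""
        return tuple(g for g in self.options if g.id != self.chosen_id)


@dataclass(frozen=True)
class Ranking:
    """Case-mix order under an objective, best first.

    ``second_best`` is the highest-scoring group other than the chosen one;
    ``tie_flag`` is set when any two scores coincide within tolerance.
    """

    order: tuple[tuple[str, float], ...]
    best: str
    second_best: str | None
    tie_flag: bool
    objective: Objective


@dataclass(frozen=True)
class OpportunityCostResult:
    """One estimator's output: the value, its unit, and the pieces it used."""

    approach_id: str
    methodology: str  # A, B, C or D
    value: float
    unit: str  # patient_equivalents | treatment_equivalents | money | QALYs
    secondary_value: float | None = None  # bed-days part of the variable-cost split
    components: dict[str, float] = field(default_factory=dict)


def net_monetary_benefit(benefit: float, threshold: float, cost: float) -> float:
    """NMB = B * lambda - C: QALYs valued at the threshold, net of expenditure.

    Sign-preserving: a treatment whose expenditure exceeds the monetary value
    of its health gain has negative net monetary benefit.
    """
    if threshold <= 0:
        raise InvalidContextError(f"cost-effectiveness threshold must be positive, got {threshold}")
    return benefit * threshold - cost


def net_health_benefit(benefit: float, threshold: float, cost: float) -> float:
    """NHB = B - C / lambda, in QALYs; identically NMB / lambda."""
    if threshold <= 0:
        raise InvalidContextError(f"cost-effectiveness threshold must be positive, got {threshold}")
    return benefit - cost / threshold


def _fields_of(obj: PatientGroup | ChosenOption) -> tuple[float, float, float | None, float | None]:
    """(los, expenditure, revenue, qaly_gain) — per patient for groups, totals for chosen."""
    if isinstance(obj, PatientGroup):
        return obj.los_per_patient, obj.expenditure_per_patient, obj.revenue_per_patient, obj.qaly_gain_per_patient
    return obj.los_total, obj.expenditure_total, obj.revenue_total, obj.qaly_gain_total


def score(
    obj: PatientGroup | ChosenOption,
    objective: Objective,
    threshold: float | None = None,
) -> float:
    """Scalar desirability of an option under a maximand; larger is better.

    throughput -> 1/LOS; expenditure -> C (a cost-recovery agent ranks larger
    spend higher); revenue -> R; net_revenue -> R - C; health -> B;
    nmb -> B * lambda - C.
    """
    los, exp, rev, qaly = _fields_of(obj)

    def need(value: float | None, name: str) -> float:
        if value is None:
            raise MissingInputError(f"objective '{objective}' requires field '{name}' on option '{obj.id}'")
        return value

    if objective == "throughput":
        if los <= 0:
            raise MissingInputError(f"objective 'throughput' requires positive length of stay on '{obj.id}'")
        return 1.0 / los
    if objective == "expenditure":
        return exp
    if objective == "revenue":
        return need(rev, "revenue")
    if objective == "net_revenue":
        return need(rev, "revenue") - exp
    if objective == "health":
        return need(qaly, "qaly_gain")
    if objective == "nmb":
        if threshold is None:
            raise InvalidContextError("objective 'nmb' requires a cost-effectiveness threshold")
        return net_monetary_benefit(need(qaly, "qaly_gain"), threshold, exp)
    raise InvalidContextError(f"unknown objective {objective!r}")


def scores_close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=REL_TOL, abs_tol=REL_TOL)


def rank_case_mix(
    case_mix: CaseMix,
    context: EconomicContext,
    objective: Objective | None = None,
) -> Ranking:
    """Rank the case mix by per-patient score under the (context) objective.

    Descending, stable in input order on ties; ``second_best`` is the
    top-ranked group excluding the chosen one.  Ties within relative
    tolerance set ``tie_flag`` and log a warning.
    """
    if not case_mix.options:  # unreachable through the validated model; guards raw use
        raise EmptyCaseMixError("case mix has no patient groups")
    obj = objective or context.objective
    scored = [(g.id, score(g, obj, context.threshold)) for g in case_mix.options]
    order = tuple(sorted(scored, key=lambda pair: -pair[1]))

    tie = any(scores_close(order[k][1], order[k + 1][1]) for k in range(len(order) - 1))
    if tie:
        logger.warning("tie in case-mix ranking under objective %r; input order kept", obj)

    chosen_id = case_mix.chosen_id
    second_best = next((gid for gid, _ in order if gid != chosen_id), None)
    return Ranking(order=order, best=order[0][0], second_best=second_best, tie_flag=tie, objective=obj)
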