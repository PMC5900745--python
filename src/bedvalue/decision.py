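"""Choice logic: optimality assessment, methodology selection, shock adjustment.

The key question for valuing a consumption of bed-days is whether the chosen
use was itself the best one.  If it was, the opportunity cost is the net
benefit of the second-best alternative forgone (Methodology B).  If it was
not, the forgone optimum must be accounted for on top of the expenditure
actually incurred — economic cost (Methodology D).  Both characterisations
of optimality are computed here and agree by construction:

    chosen is optimal
        <=> chosen total NMB >= every alternative's total NMB
        <=> chosen expenditure + highest forgone NMB <= chosen gross benefit
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .approaches import economic_cost, evaluate_all, nmb_forgone
from .core import (
    REL_TOL,
    CaseMix,
    ChosenOption,
    EconomicContext,
    OpportunityCostResult,
    net_monetary_benefit,
)
from .errors import InvalidContextError, MissingInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptionAssessment:
    """Totals for one option over the displaceable patient-equivalents.

    For the chosen option the totals are its realised single consumption
    (n_forgone = 1 by convention); for each alternative, n_forgone is the
    fractional number of its patients the chosen bed-days displace.
    """

    id: str
    n_forgone: float
    expenditure_total: float
    gross_benefit_total: float
    nmb_total: float
    expenditure_plus_highest_forgone_nmb: float
    remainder_bed_days: float | None = None  # only set in integer displacement mode


@dataclass(frozen=True)
class OptimalityAssessment:
    """Per-option totals, the optimal option, and the recommended valuation."""

    options: tuple[OptionAssessment, ...]
    optimal_id: str
    chosen_is_optimal: bool
    recommended_methodology: str  # "B" or "D"
    true_opportunity_cost: float | None  # None when no alternative exists
    tie_flag: bool = False


class ShockRecord(BaseModel):
    """Bed-days attributable to an exogenous shock (epidemic, closure, strike).

    ``beds_consumed_by_cases`` are bed-days occupied treating shock cases, of
    which only ``excess_attribution_fraction`` is truly excess stay (guards
    against time-dependent over-attribution); ``beds_lost_unoccupied`` are
    bed-days lost empty to isolation or ward closure.
    """

    model_config = ConfigDict(frozen=True)

    beds_consumed_by_cases: float = Field(ge=0)
    beds_lost_unoccupied: float = Field(default=0.0, ge=0)
    excess_attribution_fraction: float = Field(default=1.0, ge=0, le=1)


def effective_bed_days(shock: ShockRecord) -> float:
    """Bed-days to value after a shock: attributed excess stay plus beds lost empty."""
    return shock.beds_consumed_by_cases * shock.excess_attribution_fraction + shock.beds_lost_unoccupied


def assess_optimality(
    case_mix: CaseMix,
    context: EconomicContext,
    integer_displacement: bool = False,
) -> OptimalityAssessment:
    """Compare the chosen use against every alternative on total NMB.

    Every alternative needs length of stay, expenditure and QALY gain; the
    chosen option needs its total expenditure and QALY gain.  Alternatives
    displace ``LOS_i / LOS_j * E`` of their patients (floored, with the
    remainder reported, when ``integer_displacement`` is set).

    A chosen option tying the best alternative exactly counts as optimal
    (weak optimality): an equilibrium choice is not declared suboptimal.
    """
    chosen = case_mix.resolve_chosen()
    if chosen.qaly_gain_total is None:
        raise MissingInputError(f"chosen option '{chosen.id}' needs qaly_gain_total for optimality assessment")
    lam = context.threshold
    e_factor = context.effective_occupancy

    chosen_gross = chosen.qaly_gain_total * lam
    chosen_assessment_wo = {
        "id": chosen.id,
        "n_forgone": 1.0,
        "expenditure_total": chosen.expenditure_total,
        "gross_benefit_total": chosen_gross,
        "nmb_total": net_monetary_benefit(chosen.qaly_gain_total, lam, chosen.expenditure_total),
    }

    alt_rows: list[dict] = []
    for g in case_mix.alternatives():
        if g.qaly_gain_per_patient is None:
            raise MissingInputError(f"option '{g.id}' needs qaly_gain_per_patient for optimality assessment")
        n = chosen.los_total / g.los_per_patient * e_factor
        remainder = None
        if integer_displacement:
            whole = math.floor(n)
            remainder = (n - whole) * g.los_per_patient
            n = float(whole)
        exp = n * g.expenditure_per_patient
        gross = n * g.qaly_gain_per_patient * lam
        alt_rows.append({
            "id": g.id,
            "n_forgone": n,
            "expenditure_total": exp,
            "gross_benefit_total": gross,
            "nmb_total": gross - exp,
            "remainder_bed_days": remainder,
        })

    rows = [chosen_assessment_wo] + alt_rows
    # expenditure + highest NMB forgone: own spend plus the best total NMB
    # among the *other* options
    assessments: list[OptionAssessment] = []
    for row in rows:
        others = [r["nmb_total"] for r in rows if r["id"] != row["id"]]
        highest_forgone = max(others) if others else 0.0
        assessments.append(OptionAssessment(
            expenditure_plus_highest_forgone_nmb=row["expenditure_total"] + highest_forgone,
            **row,  # type: ignore[arg-type]
        ))

    nmbs = [a.nmb_total for a in assessments]
    best = max(nmbs)
    optimal_idx = nmbs.index(best)
    tie = sum(math.isclose(v, best, rel_tol=REL_TOL, abs_tol=REL_TOL) for v in nmbs) > 1
    if tie:
        logger.warning("tie on total NMB in optimality assessment; first maximiser kept")

    chosen_nmb = assessments[0].nmb_total
    alt_nmbs = [a.nmb_total for a in assessments[1:]]
    tol = max(1.0, abs(chosen_nmb)) * REL_TOL
    chosen_is_optimal = not any(v > chosen_nmb + tol for v in alt_nmbs)

    true_oc: float | None
    if not alt_nmbs:
        true_oc = None
        methodology = "B"
        chosen_is_optimal = True
    else:
        best_alt_idx = max(range(len(alt_rows)), key=lambda k: alt_rows[k]["nmb_total"])
        best_alt = case_mix.group(alt_rows[best_alt_idx]["id"])
        if chosen_is_optimal:
            methodology = "B"
            true_oc = nmb_forgone(chosen, best_alt, context, "patient_equiv")
        else:
            methodology = "D"
            true_oc = economic_cost(chosen, best_alt, context, "nmb")

    return OptimalityAssessment(
        options=tuple(assessments),
        optimal_id=assessments[optimal_idx].id,
        chosen_is_optimal=chosen_is_optimal,
        recommended_methodology=methodology,
        true_opportunity_cost=true_oc,
        tie_flag=tie,
    )


def _context_with(context: EconomicContext, **updates) -> EconomicContext:
    try:
        return EconomicContext(**{**context.model_dump(), **updates})
    except ValidationError as exc:
        raise InvalidContextError(str(exc)) from exc


def _case_mix_with_group_field(case_mix: CaseMix, group_id: str, fieldname: str, value: float) -> CaseMix:
    try:
        options = tuple(
            g.model_copy(update={fieldname: value}) if g.id == group_id else g
            for g in case_mix.options
        )
        # re-validate through the constructor (model_copy skips validation)
        options = tuple(type(g)(**g.model_dump()) for g in options)
        return CaseMix(options=options, chosen=case_mix.chosen)
    except ValidationError as exc:
        raise InvalidContextError(str(exc)) from exc


def sensitivity_sweep(
    case_mix: CaseMix,
    context: EconomicContext,
    parameter: str,
    grid: Sequence[float],
    approaches: Sequence[str] | None = None,
) -> list[tuple[float, list[OpportunityCostResult]]]:
    """Re-evaluate the catalog at each value of a swept parameter.

    ``parameter`` is ``"lambda"``, ``"occupancy_rate"``, or
    ``"<group_id>.<field>"`` (e.g. ``"P_2.qaly_gain_per_patient"``).
    Sweeping the occupancy rate disables the excess-demand override, since
    under excess demand the occupancy factor is pinned at 1.
    """
    if len(grid) == 0:
        raise InvalidContextError("sensitivity sweep needs a non-empty grid")
    out: list[tuple[float, list[OpportunityCostResult]]] = []
    for value in grid:
        if parameter == "lambda":
            ctx, mix = _context_with(context, threshold=value), case_mix
        elif parameter == "occupancy_rate":
            ctx, mix = _context_with(context, occupancy_rate=value, excess_demand=False), case_mix
        elif "." in parameter:
            group_id, fieldname = parameter.split(".", 1)
            ctx, mix = context, _case_mix_with_group_field(case_mix, group_id, fieldname, value)
        else:
            raise InvalidContextError(
                f"unknown sweep parameter {parameter!r}; use 'lambda', 'occupancy_rate' or '<group>.<field>'"
            )
        out.append((value, evaluate_all(mix, ctx, approaches)))
    return out
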