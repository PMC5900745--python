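"""The fourteen bed-day opportunity-cost estimators and their catalog.

Each estimator is a pure function of the chosen consumption (LOS_i bed-days
at expenditure C_i), a forgone alternative patient group (LOS_j, C_j, R_j,
B_j per patient), and the economic context (threshold lambda, occupancy).
They fall into four methodologies:

A. units of the second-best alternative forgone (patient- or
   treatment-equivalents);
B. the (gross or net) benefit of the second-best alternative forgone,
   in money or in QALYs;
C. the expenditure of the chosen option itself, no alternative involved;
D. economic cost = chosen expenditure plus the highest net benefit forgone.

The occupancy factor E (= occupancy_rate, or 1 under excess demand)
multiplies only the patient-equivalent *flows*: approaches 1 and 3b and the
net-benefit-per-patient-equivalent approaches New1/New3.  Treatment-
equivalent bases (2, New2, New4) carry no occupancy factor: they redeploy
money, not beds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

from .core import (
    CaseMix,
    ChosenOption,
    EconomicContext,
    OpportunityCostResult,
    PatientGroup,
    rank_case_mix,
)
from .errors import (
    DegenerateDenominatorError,
    InvalidContextError,
    MissingAlternativeError,
    MissingInputError,
)

logger = logging.getLogger(__name__)

MonetaryMode = Literal["expenditure", "revenue", "net_revenue"]
Basis = Literal["patient_equiv", "treatment_equiv"]
EconomicCostMode = Literal["net_revenue", "nmb"]


@dataclass(frozen=True)
class ApproachCatalogEntry:
    approach_id: str
    methodology: str
    unit: str
    required_fields: tuple[str, ...]
    description: str


#: The sixteen catalog rows (14 estimators; approach 3 has variants a/b/c),
#: in presentation order grouped by methodology.
CATALOG: tuple[ApproachCatalogEntry, ...] = (
    ApproachCatalogEntry("1", "A", "patient_equivalents", ("los_total", "los_per_patient"),
                         "Patient-equivalents (of second-best patients j) forgone"),
    ApproachCatalogEntry("2", "A", "treatment_equivalents", ("expenditure_total", "expenditure_per_patient"),
                         "Treatment-equivalents forgone for the second-best patients j"),
    ApproachCatalogEntry("3a", "B", "money", ("los_total", "los_per_patient", "expenditure_per_patient"),
                         "Expenditure forgone on the second-best patient-equivalents"),
    ApproachCatalogEntry("3b", "B", "money", ("los_total", "los_per_patient", "revenue_per_patient"),
                         "Revenue forgone from the second-best patient-equivalents"),
    ApproachCatalogEntry("3c", "B", "money",
                         ("los_total", "los_per_patient", "revenue_per_patient", "expenditure_per_patient"),
                         "Net revenue forgone from the second-best patient-equivalents"),
    ApproachCatalogEntry("5", "B", "money", ("los_total", "los_per_patient", "qaly_gain_per_patient"),
                         "Gross monetary benefit forgone for the second-best patient-equivalents"),
    ApproachCatalogEntry("New1", "B", "money",
                         ("los_total", "los_per_patient", "qaly_gain_per_patient", "expenditure_per_patient"),
                         "Net monetary benefit forgone for the second-best patient-equivalents"),
    ApproachCatalogEntry("New2", "B", "money",
                         ("expenditure_total", "expenditure_per_patient", "qaly_gain_per_patient"),
                         "Net monetary benefit forgone for the second-best treatment-equivalents"),
    ApproachCatalogEntry("4", "B", "QALYs", ("los_total", "los_per_patient", "qaly_gain_per_patient"),
                         "Gross health benefit forgone for second-best patient-equivalents"),
    ApproachCatalogEntry("6", "B", "QALYs", ("expenditure_total",),
                         "Health benefit forgone for expected second-best use"),
    ApproachCatalogEntry("New3", "B", "QALYs",
                         ("los_total", "los_per_patient", "qaly_gain_per_patient", "expenditure_per_patient"),
                         "Net health benefit forgone for the second-best patient-equivalents"),
    ApproachCatalogEntry("New4", "B", "QALYs",
                         ("expenditure_total", "expenditure_per_patient", "qaly_gain_per_patient"),
                         "Net health benefit forgone for the second-best treatment-equivalents"),
    ApproachCatalogEntry("7", "C", "money", ("expenditure_total",),
                         "Expenditure for the resource consumption incurred"),
    ApproachCatalogEntry("8", "C", "money", ("variable_cost_total", "los_total"),
                         "Separating variable expenditure and non-monetary resource consumption"),
    ApproachCatalogEntry("9", "D", "money",
                         ("expenditure_total", "los_total", "los_per_patient",
                          "revenue_per_patient", "expenditure_per_patient"),
                         "Expenditure incurred + highest net revenue forgone"),
    ApproachCatalogEntry("New5", "D", "money",
                         ("expenditure_total", "los_total", "los_per_patient",
                          "qaly_gain_per_patient", "expenditure_per_patient"),
                         "Expenditure incurred + highest net monetary benefit forgone"),
)

CATALOG_BY_ID: dict[str, ApproachCatalogEntry] = {e.approach_id: e for e in CATALOG}

#: Methodology section headers, for Table-1-shaped reports.
METHODOLOGY_TITLES: dict[str, str] = {
    "A": "Units of the second-best alternative forgone",
    "B": "Net benefit of the second-best alternative forgone",
    "C": "Expenditure of the alternative chosen",
    "D": "Expenditure of the alternative chosen + highest net benefit forgone",
}


def _require(value: float | None, name: str, owner: str) -> float:
    if value is None:
        raise MissingInputError(f"field '{name}' is required on '{owner}' for this approach")
    return value


def _require_alternative(second_best: PatientGroup | None) -> PatientGroup:
    if second_best is None:
        raise MissingAlternativeError("approach requires a forgone alternative but none resolves")
    return second_best


# ---------------------------------------------------------------------------
# Methodology A — units forgone


def patient_equivalents(chosen: ChosenOption, second_best: PatientGroup | None,
                        context: EconomicContext) -> float:
    """Approach 1: LOS_i / LOS_j * E — alternative patients displaced.

    Fractional values are meaningful (partial displacement) and are not
    floored; flooring is a presentation option only.
    """
    j = _require_alternative(second_best)
    return chosen.los_total * (1.0 / j.los_per_patient) * context.effective_occupancy


def treatment_equivalents(chosen: ChosenOption, second_best: PatientGroup | None) -> float:
    """Approach 2: C_i / C_j — alternative treatments purchasable with the spend."""
    j = _require_alternative(second_best)
    if j.expenditure_per_patient == 0:
        raise DegenerateDenominatorError(
            f"treatment-equivalents undefined: expenditure_per_patient of '{j.id}' is 0"
        )
    return chosen.expenditure_total / j.expenditure_per_patient


# ---------------------------------------------------------------------------
# Methodology B — benefit of the second-best forgone


def monetary_forgone(chosen: ChosenOption, second_best: PatientGroup | None,
                     context: EconomicContext, mode: MonetaryMode) -> float:
    """Approaches 3a/3b/3c: expenditure, revenue or net revenue forgone.

    expenditure -> LOS_i * C_j / LOS_j
    revenue     -> LOS_i * (R_j / LOS_j) * E
    net_revenue -> LOS_i * (R_j - C_j) / LOS_j
    """
    j = _require_alternative(second_best)
    per_day = chosen.los_total / j.los_per_patient
    if mode == "expenditure":
        return per_day * j.expenditure_per_patient
    if mode == "revenue":
        return per_day * _require(j.revenue_per_patient, "revenue_per_patient", j.id) * context.effective_occupancy
    if mode == "net_revenue":
        return per_day * (_require(j.revenue_per_patient, "revenue_per_patient", j.id) - j.expenditure_per_patient)
    raise InvalidContextError(f"unknown monetary mode {mode!r}")


def health_forgone_gross(chosen: ChosenOption, second_best: PatientGroup | None) -> float:
    """Approach 4: LOS_i * B_j / LOS_j — gross QALYs forgone."""
    j = _require_alternative(second_best)
    return chosen.los_total * _require(j.qaly_gain_per_patient, "qaly_gain_per_patient", j.id) / j.los_per_patient


def monetary_benefit_forgone_gross(chosen: ChosenOption, second_best: PatientGroup | None,
                                   context: EconomicContext) -> float:
    """Approach 5: LOS_i * B_j * lambda / LOS_j — gross QALYs forgone, monetised."""
    return health_forgone_gross(chosen, second_best) * context.threshold


def threshold_conversion(chosen: ChosenOption, context: EconomicContext) -> float:
    """Approach 6: C_i / lambda — spend converted to the QALYs it could buy elsewhere."""
    if context.threshold <= 0:
        raise InvalidContextError("threshold conversion requires a positive threshold")
    return chosen.expenditure_total / context.threshold


def nmb_forgone(chosen: ChosenOption, second_best: PatientGroup | None,
                context: EconomicContext, basis: Basis = "patient_equiv") -> float:
    """New1/New2: net monetary benefit forgone on the second-best equivalents.

    patient_equiv   -> LOS_i * (B_j * lambda - C_j) / LOS_j * E
    treatment_equiv -> C_i * (B_j * lambda - C_j) / C_j

    May be negative (second-best with negative NMB); negative values are
    returned unclamped, with a log warning — clamping would break the
    economic-cost decomposition.
    """
    j = _require_alternative(second_best)
    nmb_j = (_require(j.qaly_gain_per_patient, "qaly_gain_per_patient", j.id) * context.threshold
             - j.expenditure_per_patient)
    if basis == "patient_equiv":
        value = chosen.los_total * nmb_j / j.los_per_patient * context.effective_occupancy
    elif basis == "treatment_equiv":
        if j.expenditure_per_patient == 0:
            raise DegenerateDenominatorError(
                f"treatment-equivalent basis undefined: expenditure_per_patient of '{j.id}' is 0"
            )
        value = chosen.expenditure_total * nmb_j / j.expenditure_per_patient
    else:
        raise InvalidContextError(f"unknown basis {basis!r}")
    if value < 0:
        logger.warning("forgone net monetary benefit is negative (%s basis): %.4g", basis, value)
    return value


def nhb_forgone(chosen: ChosenOption, second_best: PatientGroup | None,
                context: EconomicContext, basis: Basis = "patient_equiv") -> float:
    """New3/New4: net health benefit forgone, in QALYs; equals nmb_forgone / lambda."""
    j = _require_alternative(second_best)
    nhb_j = (_require(j.qaly_gain_per_patient, "qaly_gain_per_patient", j.id)
             - j.expenditure_per_patient / context.threshold)
    if basis == "patient_equiv":
        return chosen.los_total * nhb_j / j.los_per_patient * context.effective_occupancy
    if basis == "treatment_equiv":
        if j.expenditure_per_patient == 0:
            raise DegenerateDenominatorError(
                f"treatment-equivalent basis undefined: expenditure_per_patient of '{j.id}' is 0"
            )
        return chosen.expenditure_total * nhb_j / j.expenditure_per_patient
    raise InvalidContextError(f"unknown basis {basis!r}")


# ---------------------------------------------------------------------------
# Methodology C — expenditure of the chosen option


def expenditure_incurred(chosen: ChosenOption) -> float:
    """Approach 7: C_i, the conventional reference-cost valuation."""
    return chosen.expenditure_total


def variable_cost_split(chosen: ChosenOption) -> tuple[float, float]:
    """Approach 8: (VC_i, LOS_i) — variable cash and bed-days, reported separately.

    The pair is never summed: fixed costs release no cash in the short run,
    and bed-days are not money.
    """
    vc = _require(chosen.variable_cost_total, "variable_cost_total", chosen.id)
    return vc, chosen.los_total


# ---------------------------------------------------------------------------
# Methodology D — economic cost


def economic_cost(chosen: ChosenOption, best_forgone: PatientGroup | None,
                  context: EconomicContext, mode: EconomicCostMode = "nmb") -> float:
    """Approach 9 / New5: expenditure incurred plus the highest net benefit forgone.

    ``best_forgone`` must be the greatest-valued forgone alternative under
    the relevant net-benefit notion (net revenue for approach 9, NMB for
    New5) — not necessarily the global second-best.
    """
    if mode == "net_revenue":
        return expenditure_incurred(chosen) + monetary_forgone(chosen, best_forgone, context, "net_revenue")
    if mode == "nmb":
        return expenditure_incurred(chosen) + nmb_forgone(chosen, best_forgone, context, "patient_equiv")
    raise InvalidContextError(f"unknown economic-cost mode {mode!r}")


# ---------------------------------------------------------------------------
# Batch evaluation


def _best_forgone(case_mix: CaseMix, context: EconomicContext, objective: str) -> PatientGroup | None:
    """Highest-scoring non-chosen group under an objective, or None."""
    try:
        ranking = rank_case_mix(case_mix, context, objective)  # type: ignore[arg-type]
    except MissingInputError:
        return None
    if ranking.second_best is None:
        return None
    return case_mix.group(ranking.second_best)


def _components(chosen: ChosenOption, j: PatientGroup | None, context: EconomicContext) -> dict[str, float]:
    comp: dict[str, float] = {
        "LOS_i": chosen.los_total,
        "C_i": chosen.expenditure_total,
        "lambda": context.threshold,
        "E": context.effective_occupancy,
    }
    if chosen.variable_cost_total is not None:
        comp["VC_i"] = chosen.variable_cost_total
    if j is not None:
        comp["LOS_j"] = j.los_per_patient
        comp["C_j"] = j.expenditure_per_patient
        if j.revenue_per_patient is not None:
            comp["R_j"] = j.revenue_per_patient
        if j.qaly_gain_per_patient is not None:
            comp["B_j"] = j.qaly_gain_per_patient
    return comp


def evaluate_approach(approach_id: str, chosen: ChosenOption, second_best: PatientGroup | None,
                      context: EconomicContext) -> OpportunityCostResult:
    """Evaluate a single catalog approach; raises on missing inputs."""
    entry = CATALOG_BY_ID.get(approach_id)
    if entry is None:
        raise InvalidContextError(
            f"unknown approach id {approach_id!r}; known: {', '.join(CATALOG_BY_ID)}"
        )
    def _threshold_conversion() -> tuple[float, float | None]:
        # Methodology B: the conversion presumes an expected second-best use
        # exists, even though its value only enters through the threshold
        _require_alternative(second_best)
        return threshold_conversion(chosen, context), None

    dispatch: dict[str, Callable[[], tuple[float, float | None]]] = {
        "1": lambda: (patient_equivalents(chosen, second_best, context), None),
        "2": lambda: (treatment_equivalents(chosen, second_best), None),
        "3a": lambda: (monetary_forgone(chosen, second_best, context, "expenditure"), None),
        "3b": lambda: (monetary_forgone(chosen, second_best, context, "revenue"), None),
        "3c": lambda: (monetary_forgone(chosen, second_best, context, "net_revenue"), None),
        "4": lambda: (health_forgone_gross(chosen, second_best), None),
        "5": lambda: (monetary_benefit_forgone_gross(chosen, second_best, context), None),
        "6": _threshold_conversion,
        "7": lambda: (expenditure_incurred(chosen), None),
        "8": lambda: variable_cost_split(chosen),
        "9": lambda: (economic_cost(chosen, second_best, context, "net_revenue"), None),
        "New1": lambda: (nmb_forgone(chosen, second_best, context, "patient_equiv"), None),
        "New2": lambda: (nmb_forgone(chosen, second_best, context, "treatment_equiv"), None),
        "New3": lambda: (nhb_forgone(chosen, second_best, context, "patient_equiv"), None),
        "New4": lambda: (nhb_forgone(chosen, second_best, context, "treatment_equiv"), None),
        "New5": lambda: (economic_cost(chosen, second_best, context, "nmb"), None),
    }
    value, secondary = dispatch[approach_id]()
    return OpportunityCostResult(
        approach_id=approach_id,
        methodology=entry.methodology,
        value=value,
        unit=entry.unit,
        secondary_value=secondary,
        components=_components(chosen, second_best, context),
    )


def evaluate_all(
    case_mix: CaseMix,
    context: EconomicContext,
    approaches: Sequence[str] | None = None,
) -> list[OpportunityCostResult]:
    """Evaluate the catalog on a case mix, in presentation order.

    Without an explicit ``approaches`` list, approaches whose inputs are
    absent are skipped with a logged notice (usable on partially specified
    case mixes).  With an explicit list, missing inputs or an unresolvable
    alternative raise.

    The forgone alternative is the second-best under the context objective;
    Methodology D resolves its "greatest-valued forgone alternative" under
    its own net-benefit notion (net revenue for 9, NMB for New5).
    """
    chosen = case_mix.resolve_chosen()
    second_best = _best_forgone(case_mix, context, context.objective)
    explicit = approaches is not None
    ids = list(approaches) if explicit else [e.approach_id for e in CATALOG]
    for aid in ids:
        if aid not in CATALOG_BY_ID:
            raise InvalidContextError(
                f"unknown approach id {aid!r}; known: {', '.join(CATALOG_BY_ID)}"
            )

    alternative_for = {
        "9": _best_forgone(case_mix, context, "net_revenue"),
        "New5": _best_forgone(case_mix, context, "nmb"),
    }

    results: list[OpportunityCostResult] = []
    for aid in ids:
        j = alternative_for.get(aid, second_best)
        try:
            results.append(evaluate_approach(aid, chosen, j, context))
        except (MissingInputError, MissingAlternativeError, DegenerateDenominatorError) as exc:
            if explicit:
                raise
            logger.info("approach %s skipped: %s", aid, exc)
    return results
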