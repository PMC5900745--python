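"""Built-in worked-example fixture and a seeded synthetic case-mix generator.

The worked example is a three-group ward: the chosen admission P_1 consumes
10 bed-days at £7,000 (of which £3,500 variable), against two competing
groups of 5-day patients.  The generator produces case mixes of the same
shape for property-based testing, fully deterministic under its seed.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import CaseMix, ChosenOption, EconomicContext, PatientGroup, score


def table2_fixture() -> tuple[CaseMix, EconomicContext]:
    """The built-in worked example: three patient groups, P_1 chosen.

    lambda = £20,000/QALY, occupancy 1.0 under excess demand;
    P_1: 10 bed-days, £7,000 (£3,500 variable), £9,000 revenue, 1.3 QALYs;
    P_2: 5, £5,000, £6,000, 0.6;  P_3: 5, £5,000, £5,500, 0.4.
    """
    options = (
        PatientGroup(id="P_1", los_per_patient=10, expenditure_per_patient=7_000,
                     revenue_per_patient=9_000, qaly_gain_per_patient=1.3),
        PatientGroup(id="P_2", los_per_patient=5, expenditure_per_patient=5_000,
                     revenue_per_patient=6_000, qaly_gain_per_patient=0.6),
        PatientGroup(id="P_3", los_per_patient=5, expenditure_per_patient=5_000,
                     revenue_per_patient=5_500, qaly_gain_per_patient=0.4),
    )
    chosen = ChosenOption(id="P_1", los_total=10, expenditure_total=7_000,
                          variable_cost_total=3_500, revenue_total=9_000, qaly_gain_total=1.3)
    case_mix = CaseMix(options=options, chosen=chosen)
    context = EconomicContext(threshold=20_000, occupancy_rate=1.0, excess_demand=True,
                              objective="nmb", currency="£")
    return case_mix, context


class GeneratorSpec(BaseModel):
    """Parameters of the synthetic case-mix generator.

    Defaults emulate an acute ward under excess demand: lognormal stays with
    a 5-bed-day median, £800–2,000 per bed-day, modest marginal QALY gains
    (never negative unless ``allow_negative_qaly``), and revenue within
    -10% to +30% of expenditure.  ``p_choose_best`` leaves roughly 15% of
    mixes with a suboptimal chosen option, so both valuation branches
    (second-best net benefit vs economic cost) are exercised.
    """

    model_config = ConfigDict(frozen=True)

    seed: int
    n_groups: int = Field(default=5, ge=1)
    los_median: float = Field(default=5.0, gt=0, description="median bed-days per patient")
    los_sigma: float = Field(default=0.5, gt=0, description="lognormal shape")
    cost_per_day: tuple[float, float] = (800.0, 2_000.0)
    qaly_range: tuple[float, float] = (0.05, 1.2)
    revenue_markup: tuple[float, float] = (-0.10, 0.30)
    variable_share: tuple[float, float] = (0.3, 0.7)
    threshold: float = Field(default=20_000.0, gt=0)
    p_choose_best: float = Field(default=0.85, ge=0, le=1)
    allow_negative_qaly: bool = False

    @model_validator(mode="after")
    def _check_intervals(self) -> "GeneratorSpec":
        for name in ("cost_per_day", "qaly_range", "revenue_markup", "variable_share"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} interval is empty: ({lo}, {hi})")
        lo, hi = self.qaly_range
        if hi > 2:
            raise ValueError("qaly_range must lie within [0, 2] (per-admission marginal gains)")
        if lo < 0 and not self.allow_negative_qaly:
            raise ValueError("negative QALY gains require allow_negative_qaly=True")
        if self.cost_per_day[0] < 0:
            raise ValueError("cost_per_day must be non-negative")
        return self


def generate_case_mix(spec: GeneratorSpec) -> tuple[CaseMix, EconomicContext]:
    """Draw a synthetic case mix; identical spec (incl. seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)
    groups: list[PatientGroup] = []
    for k in range(spec.n_groups):
        los = float(rng.lognormal(math.log(spec.los_median), spec.los_sigma))
        los = max(los, 0.25)  # guard against sub-6-hour stays
        cost_per_day = float(rng.uniform(*spec.cost_per_day))
        expenditure = los * cost_per_day
        markup = float(rng.uniform(*spec.revenue_markup))
        revenue = max(expenditure * (1.0 + markup), 0.0)
        qaly = float(rng.uniform(*spec.qaly_range))
        groups.append(PatientGroup(
            id=f"G{k + 1}",
            los_per_patient=los,
            expenditure_per_patient=expenditure,
            revenue_per_patient=revenue,
            qaly_gain_per_patient=qaly,
        ))

    # "best" in the sense the optimality assessment uses: NMB per bed-day
    # (a fixed consumption displaces LOS_i / LOS_j patients of group j)
    nmb_per_day = [score(g, "nmb", spec.threshold) / g.los_per_patient for g in groups]
    best_idx = int(np.argmax(nmb_per_day))
    if spec.n_groups == 1 or rng.random() < spec.p_choose_best:
        chosen_idx = best_idx
    else:
        others = [k for k in range(spec.n_groups) if k != best_idx]
        chosen_idx = int(rng.choice(others))

    g = groups[chosen_idx]
    variable = g.expenditure_per_patient * float(rng.uniform(*spec.variable_share))
    chosen = ChosenOption(
        id=g.id,
        los_total=g.los_per_patient,
        expenditure_total=g.expenditure_per_patient,
        variable_cost_total=variable,
        revenue_total=g.revenue_per_patient,
        qaly_gain_total=g.qaly_gain_per_patient,
    )
    context = EconomicContext(threshold=spec.threshold, occupancy_rate=1.0,
                              excess_demand=True, objective="nmb")
    return CaseMix(options=tuple(groups), chosen=chosen), context


def generate_many(base_seed: int, n: int, **overrides) -> list[tuple[CaseMix, EconomicContext]]:
    """n case mixes with seeds base_seed..base_seed+n-1 (convenience for sweeps)."""
    return [generate_case_mix(GeneratorSpec(seed=base_seed + k, **overrides)) for k in range(n)]
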