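# Methods

## The model

`bedvalue` treats a hospital bed-day as a constrained resource whose value
is the value of its next-best use forgone. The inputs are a *case mix* —
patient groups `j` characterised per patient by length of stay `LOS_j`
(bed-days), expenditure `C_j`, optional revenue `R_j` and optional marginal
QALY gain `B_j` — together with the *chosen consumption* being valued
(`LOS_i` bed-days at total expenditure `C_i`, optionally split into a
variable share `VC_i`), and an economic context: the cost-effectiveness
threshold `λ` (money per QALY), the occupancy rate `OCR ∈ (0, 1]`, an
excess-demand flag, a decision objective and an (informational)
perspective.

Marginal QALY gains must be gains *from treatment* relative to no
treatment — a healthy person does not benefit from a bed — and are taken as
given; estimating them from disease natural history is out of scope, as is
eliciting `λ` empirically.

Sixteen estimators are organised in four methodologies:

| Methodology | Idea | Estimators |
| --- | --- | --- |
| A | units of the second-best alternative forgone | patient-equivalents, treatment-equivalents |
| B | net benefit of the second-best forgone | expenditure/revenue/net-revenue forgone; gross and net health benefit (QALYs) and their monetised forms; threshold conversion |
| C | expenditure of the chosen option | reference-cost convention; variable-cost/bed-days split |
| D | economic cost = chosen expenditure + highest net benefit forgone | net-revenue and NMB variants |

The net-benefit primitives are `NMB = B·λ − C` and `NHB = B − C/λ`
(`NMB = λ·NHB` exactly). Negative net benefits are legitimate (a forgone
alternative can be a money-loser) and are returned unclamped with a log
warning: clamping would break the decomposition `D = C + B-part` that the
economic-cost estimators rely on.

### Occupancy semantics

The effective occupancy factor `E` equals `OCR` only when there is *no*
excess demand; under excess demand (waiting lists, unmet demand) every
freed bed is redeployed and `E = 1`. `E` multiplies only the
patient-equivalent *flows* — approaches 1 and 3b and the per-patient-
equivalent net-benefit approaches (New1/New3 in the catalog ids) — as a
trailing factor ≤ 1. Treatment-equivalent bases (2, New2, New4) carry no
occupancy factor: they redeploy money, not beds. The two economic-cost
estimators inherit `E` only through their forgone-net-benefit term, so they
are affine, not homogeneous, in `E`.

### Ranking and the second-best

The case mix is ranked by a per-patient score under the declared objective:
`throughput → 1/LOS`, `expenditure → C` (a cost-recovery agent ranks larger
spend higher — the literature names expenditure as a maximand without
fixing a direction, so the direction is made explicit here),
`revenue → R`, `net_revenue → R − C`, `health → B`, `nmb → B·λ − C`.
The second-best is the top-ranked group excluding the chosen one. Ties
within relative tolerance 1e-9 keep input order, set a flag and log a
warning; the engine does not invent a preference between indistinguishable
options. Objectives can genuinely disagree on the second-best; the
objective is therefore an explicit parameter, never inferred.

Methodology D needs the *greatest-valued* forgone alternative under its own
net-benefit notion, which need not be the second-best under the context
objective: approach 9 resolves it by net-revenue ranking and New5 by NMB
ranking. Displacement is single-group: the engine does not solve the
packing problem of filling freed bed-days with a mixture of groups (noted
as an extension).

### Optimality and methodology selection

For the optimality assessment every alternative `j` displaces
`n_j = LOS_i / LOS_j · E` of its patients (fractional by default; an
optional integer mode floors and reports the remaining bed-days). Totals
per option are expenditure `n·C`, gross monetary benefit `n·B·λ` and
`NMB = GMB − expenditure`; the chosen option's totals use its realised
single consumption. Two characterisations of optimality are computed and
agree algebraically: the chosen option maximises total NMB iff its
expenditure plus the highest NMB forgone does not exceed its own gross
benefit. A chosen option tying the best alternative exactly counts as
optimal (weak optimality): an equilibrium choice is not declared
suboptimal. If optimal, the recommended valuation is the forgone
second-best NMB (Methodology B); otherwise the economic cost
(Methodology D). The two recommendations differ by exactly the chosen
expenditure, so the decomposition carries through the decision layer.

### Exogenous shocks

For shock events (epidemics, ward closures, strikes) the bed-days to value
are `consumed × excess_attribution_fraction + lost_unoccupied`: bed-days
lost empty to isolation or closure count in full, while stays of treated
cases are scaled by a fraction in [0, 1] guarding against time-dependent
over-attribution of "excess" stay. Full multistate length-of-stay
modelling is deliberately reduced to this single scalar.

## Parameters that matter

| Parameter | Unit | Default | Why |
| --- | --- | --- | --- |
| `threshold` (`λ`) | money/QALY | none — must be supplied | converting health to money is a policy choice; the worked example uses £20,000/QALY |
| `occupancy_rate` | fraction | 1.0 | full redeployment of freed beds |
| `excess_demand` | flag | true | most acute settings run with waiting lists; forces `E = 1` |
| `objective` | enum | `nmb` | health maximisation within a fixed budget |
| relative tolerance | — | 1e-9 | tie detection and optimality comparisons; values are held as floats and rounded to 2 decimals at presentation only |

## The synthetic generator

`GeneratorSpec` emulates an acute ward under excess demand: lognormal
lengths of stay (median 5 bed-days, shape 0.5), £800–2,000 per bed-day,
marginal QALY gains uniform on [0.05, 1.2] (never negative unless
explicitly enabled for stress tests), revenue within −10% to +30% of
expenditure, and a variable-cost share of 30–70%. The chosen option is the
best alternative by NMB per bed-day with probability 0.85, otherwise a
uniformly random other group, leaving roughly 15% of generated mixes with
a suboptimal chosen option so that both valuation branches (B and D) are
exercised. Generation is fully deterministic under the seed.

What the generator does *not* emulate: patient-level heterogeneity within
groups, correlation between severity, cost and benefit, censored or
time-varying lengths of stay, payer-specific tariff structures, and
capacity constraints other than beds. Passing property tests therefore
demonstrate the algebraic correctness and internal consistency of the
estimators over a wide input range — not that any particular real ward's
case mix is well described by these distributions.

## Numerical choices

- All arithmetic is closed-form; no iteration, optimisation or sampling is
  involved in the estimators themselves.
- Degenerate inputs: zero consumption values to zero everywhere it should;
  a zero-expenditure alternative makes treatment-equivalent bases undefined
  and raises a dedicated error rather than returning infinity; a
  non-positive threshold is rejected at context construction.
- Batch evaluation (`evaluate_all`) skips approaches whose inputs are
  absent, with a logged notice, so partially specified case mixes remain
  usable; requesting an approach explicitly turns the same condition into a
  hard error. The threshold-conversion approach is skipped when no
  alternative exists at all: it presumes an expected second-best use even
  though only `C_i` and `λ` enter its formula.
- Patient-equivalents are kept fractional in all computations; flooring to
  whole displaced patients is a presentation option only.
- Reports are deterministic (byte-identical for identical inputs); money is
  rendered with thousands separators and the context's currency label at
  presentation only.

## Problem sizes

The identity suite checks the decomposition, the `λ` bridges, the
perfect-competition degeneracies and the agreement of the two optimality
characterisations on 10,000 generated case mixes of 4 groups each — large
enough to cover both optimality branches and a wide numeric range, while
the whole suite stays fast enough for routine local runs.

## Known limitations

- Single-group displacement only (no bed-day packing across groups).
- The occupancy factor is a scalar; queueing dynamics, seasonal occupancy
  and non-bed bottlenecks (e.g. theatre slots) are not modelled.
- The perspective field is informational: whether `C_i` means provider
  expenditure or payer reimbursement is encoded by the user's inputs, not
  by the engine.
- Equity weighting, multi-criteria decision analysis and waiting-list
  dynamics are out of scope.
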