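# bedvalue

Opportunity-cost valuation of hospital bed-days.

Hospital beds are a constrained resource: a patient who occupies a bed for
ten days displaces other patients who could have used those bed-days. What
are those ten bed-days *worth*? Costing studies answer this in strikingly
different ways — some count the displaced patients, some the expenditure or
revenue forgone, some simply the expenditure incurred — and the answers can
differ by an order of magnitude on the same inputs. `bedvalue` implements
the full taxonomy of these estimators as a small, exactly-reproducible
costing engine for health-economics analysts:

- **Methodology A — units forgone.** Patient-equivalents
  `LOS_i / LOS_j · E` and treatment-equivalents `C_i / C_j`.
- **Methodology B — net benefit of the second-best alternative forgone.**
  Expenditure, revenue and net revenue forgone; gross health benefit
  `LOS_i · B_j / LOS_j` (QALYs) and its monetised form `· λ`; threshold
  conversion `C_i / λ`; and the net-benefit forms built on the net monetary
  benefit **NMB = B·λ − C**, e.g. forgone NMB per patient-equivalent
  `LOS_i · (B_j·λ − C_j) / LOS_j · E` and its net-health-benefit analogue
  `NHB = NMB / λ`.
- **Methodology C — expenditure of the chosen option.** The reference-cost
  convention `C_i`, or the variable-cash/bed-days pair `(VC_i, LOS_i)`
  reported separately.
- **Methodology D — economic cost.** Expenditure incurred plus the highest
  net benefit (net revenue, or NMB) forgone — the right notion when the
  chosen use was *not* the best one.

Here `LOS` is length of stay in bed-days, `C` expenditure, `R` revenue,
`B` the marginal QALY gain per patient, `λ` the cost-effectiveness
threshold (money per QALY), and `E` the effective occupancy factor
(the occupancy rate, forced to 1 under excess demand). Subscript `i` is the
chosen consumption, `j` the forgone alternative patient group.

On top of the estimators the package ranks a case mix under an explicit
objective (throughput, expenditure, revenue, net revenue, health, NMB),
identifies the second-best alternative, assesses whether the chosen option
was optimal (and hence whether Methodology B or D applies), adjusts
bed-day counts for exogenous shocks such as epidemics or ward closures,
and runs sensitivity sweeps over `λ`, the occupancy rate, or any group
field.

## Worked example

The built-in fixture is a three-group ward under excess demand with
`λ = £20,000/QALY`. The chosen admission `P_1` consumes 10 bed-days at
£7,000 (of which £3,500 variable), gaining 1.3 QALYs; the competing groups
`P_2` and `P_3` each need 5 bed-days at £5,000, gaining 0.6 and 0.4 QALYs
(revenues £6,000 and £5,500).

```python
import bedvalue as bv

case_mix, context = bv.table2_fixture()
for r in bv.evaluate_all(case_mix, context):
    print(r.approach_id, r.value)
```

Or from the shell:

```sh
bedvalue demo
```

which prints the full catalog — patient-equivalents 2, treatment-equivalents
1.4, expenditure/revenue/net-revenue forgone £10,000 / £12,000 / £2,000,
gross benefit forgone 1.2 QALYs (£24,000), threshold conversion 0.35 QALYs,
forgone NMB £14,000 (patient-equivalents) and £9,800
(treatment-equivalents), forgone NHB 0.7 and 0.49 QALYs, expenditure
incurred £7,000, the variable-cost split £3,500 & 10 bed-days, and the two
economic costs £9,000 (net revenue) and £21,000 (NMB) — followed by the
optimality table:

```
Option                                 P_1 (n = 1)  P_2 (n = 2 forgone)  P_3 (n = 2 forgone)
Expenditure (in total)                 £7,000       £10,000              £10,000
Benefit (GMB, in total)                £26,000      £24,000              £16,000
NMB (benefit - expenditure, in total)  £19,000      £14,000              £6,000
Expenditure + highest NMB forgone      £21,000      £29,000              £29,000

Optimal option: P_1
Chosen is optimal: yes
Recommended methodology: B
true opportunity cost: £14,000
```

`P_1` is optimal (its £21,000 of expenditure-plus-best-forgone-NMB is below
its £26,000 gross benefit), so the opportunity cost of the 10 bed-days is
the £14,000 net monetary benefit forgone on the two displaced `P_2`
patients. Had the chosen use been suboptimal, the engine would instead
recommend the economic cost (Methodology D).

Case mixes can also be read from CSV/JSON/YAML files (`bedvalue evaluate
--case-mix ward.csv`), ranked (`bedvalue rank`), swept (`bedvalue sweep
--param ocr --grid 0.75:1.0:0.25 --approach 1`), and generated
synthetically with a seed (`bedvalue generate --seed 3 --n-groups 5 --out
mix.yaml`).

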