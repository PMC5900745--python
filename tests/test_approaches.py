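"""The fourteen estimators: worked-example values, algebraic identities, errors."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bedvalue as bv
from bedvalue import CaseMix, ChosenOption, EconomicContext, PatientGroup
from bedvalue.approaches import CATALOG, evaluate_all, evaluate_approach
from bedvalue.errors import (
    DegenerateDenominatorError,
    InvalidContextError,
    MissingAlternativeError,
    MissingInputError,
)

# Independent oracle: each catalog formula restated as one line of arithmetic
# on raw numbers (LOS_i, C_i, VC_i; LOS_j, C_j, R_j, B_j; lambda, E).
ORACLE = {
    "1": lambda li, ci, vc, lj, cj, rj, bj, lam, e: li / lj * e,
    "2": lambda li, ci, vc, lj, cj, rj, bj, lam, e: ci / cj,
    "3a": lambda li, ci, vc, lj, cj, rj, bj, lam, e: li * cj / lj,
    "3b": lambda li, ci, vc, lj, cj, rj, bj, lam, e: li * rj / lj * e,
    "3c": lambda li, ci, vc, lj, cj, rj, bj, lam, e: li * (rj - cj) / lj,
    "4": lambda li, ci, vc, lj, cj, rj, bj, lam, e: li * bj / lj,
    "5": lambda li, ci, vc, lj, cj, rj, bj, lam, e: li * bj * lam / lj,
    "6": lambda li, ci, vc, lj, cj, rj, bj, lam, e: ci / lam,
    "7": lambda li, ci, vc, lj, cj, rj, bj, lam, e: ci,
    "8": lambda li, ci, vc, lj, cj, rj, bj, lam, e: vc,
    "9": lambda li, ci, vc, lj, cj, rj, bj, lam, e: ci + li * (rj - cj) / lj,
    "New1": lambda li, ci, vc, lj, cj, rj, bj, lam, e: li * (bj * lam - cj) / lj * e,
    "New2": lambda li, ci, vc, lj, cj, rj, bj, lam, e: ci * (bj * lam - cj) / cj,
    "New3": lambda li, ci, vc, lj, cj, rj, bj, lam, e: li * (bj - cj / lam) / lj * e,
    "New4": lambda li, ci, vc, lj, cj, rj, bj, lam, e: ci * (bj - cj / lam) / cj,
    "New5": lambda li, ci, vc, lj, cj, rj, bj, lam, e: ci + li * (bj * lam - cj) / lj * e,
}

TABLE_VALUES = {
    "1": 2, "2": 1.4, "3a": 10_000, "3b": 12_000, "3c": 2_000, "5": 24_000,
    "New1": 14_000, "New2": 9_800, "4": 1.2, "6": 0.35, "New3": 0.7, "New4": 0.49,
    "7": 7_000, "8": 3_500, "9": 9_000, "New5": 21_000,
}


def relaxed(context, ocr):
    return EconomicContext(**{**context.model_dump(), "occupancy_rate": ocr, "excess_demand": False})


class TestWorkedExample:
    @pytest.mark.parametrize("approach_id, expected", sorted(TABLE_VALUES.items()))
    def test_catalog_values(self, chosen, second_best, context, approach_id, expected):
        result = evaluate_approach(approach_id, chosen, second_best, context)
        assert result.value == pytest.approx(expected, rel=1e-12)
        if approach_id == "8":
            assert result.secondary_value == pytest.approx(10)

    def test_full_catalog_order_and_values(self, worked_example):
        case_mix, context = worked_example
        results = evaluate_all(case_mix, context)
        assert [r.approach_id for r in results] == [e.approach_id for e in CATALOG]
        assert [r.value for r in results] == pytest.approx(
            [TABLE_VALUES[r.approach_id] for r in results], rel=1e-12)

    def test_methodology_letters_and_units_follow_catalog(self, worked_example):
        case_mix, context = worked_example
        for r in evaluate_all(case_mix, context):
            entry = next(e for e in CATALOG if e.approach_id == r.approach_id)
            assert (r.methodology, r.unit) == (entry.methodology, entry.unit)


class TestDerivedExamples:
    def test_occupancy_scales_patient_equivalents(self, chosen, second_best, context):
        assert bv.patient_equivalents(chosen, second_best, relaxed(context, 0.75)) == pytest.approx(1.5)

    def test_treatment_equivalents_arithmetic(self, second_best, context):
        big = ChosenOption(id="i", los_total=10, expenditure_total=9_000)
        cheap = PatientGroup(id="j", los_per_patient=5, expenditure_per_patient=4_500)
        assert bv.treatment_equivalents(big, cheap) == pytest.approx(2.0)

    def test_gross_health_linear_in_consumption(self, second_best):
        double = ChosenOption(id="i", los_total=20, expenditure_total=7_000)
        assert bv.health_forgone_gross(double, second_best) == pytest.approx(2.4)

    def test_high_social_value_threshold(self, chosen, second_best, context):
        rich = EconomicContext(**{**context.model_dump(), "threshold": 50_000})
        assert bv.monetary_benefit_forgone_gross(chosen, second_best, rich) == pytest.approx(60_000)

    def test_threshold_conversion_arithmetic(self, context):
        pricey = ChosenOption(id="i", los_total=10, expenditure_total=30_000)
        assert bv.threshold_conversion(pricey, context) == pytest.approx(1.5)

    def test_zero_consumption_gives_zero(self, second_best, context):
        empty = ChosenOption(id="i", los_total=0, expenditure_total=0)
        assert bv.patient_equivalents(empty, second_best, context) == 0
        assert bv.treatment_equivalents(empty, second_best) == 0
        assert bv.expenditure_incurred(empty) == 0
        assert bv.threshold_conversion(empty, context) == 0

    def test_variable_cost_split_edge_shares(self, context):
        all_var = ChosenOption(id="i", los_total=8, expenditure_total=4_000, variable_cost_total=4_000)
        assert bv.variable_cost_split(all_var) == (4_000, 8)
        all_fixed = ChosenOption(id="i", los_total=8, expenditure_total=4_000, variable_cost_total=0)
        assert bv.variable_cost_split(all_fixed) == (0, 8)


class TestErrors:
    def test_missing_alternative(self, chosen, context):
        with pytest.raises(MissingAlternativeError):
            bv.patient_equivalents(chosen, None, context)

    def test_missing_fields_raise_named_error(self, chosen, context):
        bare = PatientGroup(id="j", los_per_patient=5, expenditure_per_patient=5_000)
        with pytest.raises(MissingInputError, match="revenue_per_patient"):
            bv.monetary_forgone(chosen, bare, context, "revenue")
        with pytest.raises(MissingInputError, match="qaly_gain_per_patient"):
            bv.nmb_forgone(chosen, bare, context)
        with pytest.raises(MissingInputError, match="variable_cost_total"):
            bv.variable_cost_split(ChosenOption(id="i", los_total=1, expenditure_total=1))

    def test_zero_expenditure_alternative_degenerates(self, chosen, context):
        free = PatientGroup(id="j", los_per_patient=5, expenditure_per_patient=0, qaly_gain_per_patient=0.5)
        with pytest.raises(DegenerateDenominatorError):
            bv.treatment_equivalents(chosen, free)
        with pytest.raises(DegenerateDenominatorError):
            bv.nmb_forgone(chosen, free, context, "treatment_equiv")

    def test_unknown_approach_id(self, chosen, second_best, context):
        with pytest.raises(InvalidContextError, match="unknown approach"):
            evaluate_approach("42", chosen, second_best, context)


# Strategy over plausible raw inputs for the identity suite.
raw_inputs = st.tuples(
    st.floats(0, 60),          # LOS_i
    st.floats(0, 50_000),      # C_i
    st.floats(0.5, 30),        # LOS_j
    st.floats(1.0, 20_000),    # C_j
    st.floats(0, 30_000),      # R_j
    st.floats(0, 2),           # B_j
    st.floats(1_000, 100_000), # lambda
    st.floats(0.05, 1.0),      # occupancy rate
)


def build(li, ci, lj, cj, rj, bj, lam, ocr, excess=True):
    chosen = ChosenOption(id="i", los_total=li, expenditure_total=ci,
                          variable_cost_total=ci / 2)
    j = PatientGroup(id="j", los_per_patient=lj, expenditure_per_patient=cj,
                     revenue_per_patient=rj, qaly_gain_per_patient=bj)
    ctx = EconomicContext(threshold=lam, occupancy_rate=ocr, excess_demand=excess)
    return chosen, j, ctx


class TestIdentities:
    @settings(max_examples=300, derandomize=True)
    @given(raw=raw_inputs, excess=st.booleans())
    def test_against_one_line_oracle(self, raw, excess):
        """Every estimator matches an independently written arithmetic oracle."""
        li, ci, lj, cj, rj, bj, lam, ocr = raw
        chosen, j, ctx = build(li, ci, lj, cj, rj, bj, lam, ocr, excess)
        e = 1.0 if excess else ocr
        for aid, oracle in ORACLE.items():
            expected = oracle(li, ci, ci / 2, lj, cj, rj, bj, lam, e)
            got = evaluate_approach(aid, chosen, j, ctx).value
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-9), aid

    @settings(max_examples=300, derandomize=True)
    @given(raw=raw_inputs, excess=st.booleans())
    def test_decomposition_and_bridges(self, raw, excess):
        """Economic cost = own expenditure + net benefit forgone; NMB = lambda * NHB."""
        li, ci, lj, cj, rj, bj, lam, ocr = raw
        chosen, j, ctx = build(li, ci, lj, cj, rj, bj, lam, ocr, excess)
        approx = lambda v: pytest.approx(v, rel=1e-9, abs=1e-6)  # noqa: E731

        assert bv.economic_cost(chosen, j, ctx, "net_revenue") == approx(
            bv.expenditure_incurred(chosen) + bv.monetary_forgone(chosen, j, ctx, "net_revenue"))
        assert bv.economic_cost(chosen, j, ctx, "nmb") == approx(
            bv.expenditure_incurred(chosen) + bv.nmb_forgone(chosen, j, ctx, "patient_equiv"))
        for basis in ("patient_equiv", "treatment_equiv"):
            assert bv.nmb_forgone(chosen, j, ctx, basis) == approx(
                lam * bv.nhb_forgone(chosen, j, ctx, basis))
        assert bv.monetary_benefit_forgone_gross(chosen, j, ctx) == approx(
            lam * bv.health_forgone_gross(chosen, j))
        # basis bridge: per-equivalent net benefit times the equivalent count
        nmb_j = bj * lam - cj
        assert bv.nmb_forgone(chosen, j, ctx, "treatment_equiv") == approx(
            bv.treatment_equivalents(chosen, j) * nmb_j)

    @settings(max_examples=200, derandomize=True)
    @given(raw=raw_inputs)
    def test_gross_net_bridge_at_full_redeployment(self, raw):
        """Gross monetary benefit minus expenditure forgone = NMB forgone when E = 1."""
        li, ci, lj, cj, rj, bj, lam, ocr = raw
        chosen, j, ctx = build(li, ci, lj, cj, rj, bj, lam, ocr, excess=True)
        assert (bv.monetary_benefit_forgone_gross(chosen, j, ctx)
                - bv.monetary_forgone(chosen, j, ctx, "expenditure")
                ) == pytest.approx(bv.nmb_forgone(chosen, j, ctx), rel=1e-9, abs=1e-6)

    @settings(max_examples=200, derandomize=True)
    @given(raw=raw_inputs)
    def test_perfect_competition_degeneracies(self, raw):
        """At equilibrium (R_j = C_j, or B_j*lambda = C_j) net approaches vanish."""
        li, ci, lj, cj, rj, bj, lam, ocr = raw
        # revenue equals expenditure: no net revenue forgone
        chosen, j, ctx = build(li, ci, lj, cj, cj, bj, lam, ocr)
        assert bv.monetary_forgone(chosen, j, ctx, "net_revenue") == pytest.approx(0, abs=1e-9)
        assert bv.economic_cost(chosen, j, ctx, "net_revenue") == pytest.approx(ci, rel=1e-9, abs=1e-9)
        # monetised health gain equals expenditure: all net-benefit approaches vanish
        chosen, j, ctx = build(li, ci, lj, cj, rj, cj / lam, lam, ocr)
        for basis in ("patient_equiv", "treatment_equiv"):
            assert bv.nmb_forgone(chosen, j, ctx, basis) == pytest.approx(0, abs=1e-6)
            assert bv.nhb_forgone(chosen, j, ctx, basis) == pytest.approx(0, abs=1e-9)
        assert bv.economic_cost(chosen, j, ctx, "nmb") == pytest.approx(ci, rel=1e-9, abs=1e-6)

    @settings(max_examples=200, derandomize=True)
    @given(raw=raw_inputs, factor=st.floats(0.1, 10))
    def test_linearity_in_consumption(self, raw, factor):
        """All approaches except 7 and 8 scale linearly with the consumption valued."""
        li, ci, lj, cj, rj, bj, lam, ocr = raw
        chosen, j, ctx = build(li, ci, lj, cj, rj, bj, lam, ocr)
        scaled, _, _ = build(li * factor, ci * factor, lj, cj, rj, bj, lam, ocr)
        for aid in ORACLE:
            if aid in {"7", "8"}:
                continue
            base = evaluate_approach(aid, chosen, j, ctx).value
            assert evaluate_approach(aid, scaled, j, ctx).value == pytest.approx(
                factor * base, rel=1e-9, abs=1e-6), aid

    @settings(max_examples=100, derandomize=True)
    @given(raw=raw_inputs)
    def test_occupancy_multiplies_only_patient_equivalent_flows(self, raw):
        li, ci, lj, cj, rj, bj, lam, _ = raw
        full = build(li, ci, lj, cj, rj, bj, lam, 1.0, excess=False)
        half = build(li, ci, lj, cj, rj, bj, lam, 0.5, excess=False)
        affected = {"1", "3b", "New1", "New3"}
        for aid in ORACLE:
            v_full = evaluate_approach(aid, full[0], full[1], full[2]).value
            v_half = evaluate_approach(aid, half[0], half[1], half[2]).value
            if aid in affected:
                assert v_half == pytest.approx(0.5 * v_full, rel=1e-9, abs=1e-9), aid
            elif aid == "New5":  # affine in E through its forgone-NMB term
                new1_full = evaluate_approach("New1", full[0], full[1], full[2]).value
                assert v_half == pytest.approx(ci + 0.5 * new1_full, rel=1e-9, abs=1e-9)
            else:
                assert v_half == pytest.approx(v_full, rel=1e-9, abs=1e-9), aid


class TestEvaluateAll:
    def test_single_group_mix_yields_only_methodology_c(self):
        g = PatientGroup(id="A", los_per_patient=5, expenditure_per_patient=5_000,
                         qaly_gain_per_patient=0.5)
        mix = CaseMix(options=(g,), chosen="A")
        results = evaluate_all(mix, EconomicContext(threshold=20_000))
        assert results and all(r.methodology == "C" for r in results)

    def test_partially_specified_mix_skips_quietly(self, caplog):
        groups = (
            PatientGroup(id="A", los_per_patient=10, expenditure_per_patient=7_000,
                         qaly_gain_per_patient=1.3),
            PatientGroup(id="B", los_per_patient=5, expenditure_per_patient=5_000,
                         qaly_gain_per_patient=0.6),  # no revenue
        )
        mix = CaseMix(options=groups, chosen="A")
        results = evaluate_all(mix, EconomicContext(threshold=20_000))
        ids = {r.approach_id for r in results}
        assert {"3b", "3c", "9", "8"}.isdisjoint(ids)  # revenue/VC approaches skipped
        assert {"1", "2", "3a", "New1", "New5", "7"} <= ids

    def test_explicit_request_with_missing_input_raises(self):
        groups = (
            PatientGroup(id="A", los_per_patient=10, expenditure_per_patient=7_000),
            PatientGroup(id="B", los_per_patient=5, expenditure_per_patient=5_000),
        )
        mix = CaseMix(options=groups, chosen="A")
        ctx = EconomicContext(threshold=20_000, objective="throughput")
        with pytest.raises(MissingInputError):
            evaluate_all(mix, ctx, ["New1"])

    def test_explicit_request_without_alternative_raises(self):
        g = PatientGroup(id="A", los_per_patient=5, expenditure_per_patient=5_000,
                         qaly_gain_per_patient=0.5)
        mix = CaseMix(options=(g,), chosen="A")
        with pytest.raises(MissingAlternativeError):
            evaluate_all(mix, EconomicContext(threshold=20_000), ["1"])
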