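"""Free-energy bookkeeping and the kinetic/thermodynamic constant relations."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smskinetics import (
    BindingEnergyRecord,
    RateConstants,
    ThermoConfig,
    ValidationError,
    K_from_rates,
    K_to_ddG,
    ddG_to_K,
    kon_koff_min_rule,
    pair_ddG,
    rates_from_K,
)
from smskinetics.thermo import read_binding_table, write_binding_table


def _pair(pc, cer, dag, sm, context="membrane"):
    return (
        [BindingEnergyRecord("PC", "WT", context, pc),
         BindingEnergyRecord("Cer", "WT", context, cer)],
        [BindingEnergyRecord("DAG", "WT", context, dag),
         BindingEnergyRecord("SM", "WT", context, sm)],
    )


class TestPairDdG:
    def test_membrane_pair_sums_give_minus_4_9(self):
        reactants, products = _pair(-10.85, -10.85, -13.3, -13.3)
        res = pair_ddG(reactants, products)
        assert res.reactant_sum == pytest.approx(-21.7)
        assert res.product_sum == pytest.approx(-26.6)
        assert res.ddG == pytest.approx(-4.9, abs=1e-12)
        assert not res.context_mismatch

    def test_identical_sums_give_zero_and_unit_K(self):
        reactants, products = _pair(-5.0, -7.0, -4.0, -8.0)
        res = pair_ddG(reactants, products)
        assert res.ddG == 0.0
        assert res.K_thermo == 1.0

    def test_hand_evaluated_exponential(self):
        # RT at 298 K is 0.59219 kcal/mol, so ddG = -0.592 gives K ~ e
        reactants, products = _pair(0.0, 0.0, -0.296, -0.296)
        res = pair_ddG(reactants, products, ThermoConfig(temperature=298.0))
        assert res.K_thermo == pytest.approx(math.e, rel=1e-3)

    def test_mixed_contexts_flagged_not_rejected(self):
        reactants, _ = _pair(-1, -1, -1, -1)
        products = [BindingEnergyRecord("DAG", "WT", "SMS1-P", -2.0),
                    BindingEnergyRecord("SM", "WT", "SMS1", -2.0)]
        assert pair_ddG(reactants, products).context_mismatch

    def test_wrong_record_count_rejected(self):
        reactants, products = _pair(-1, -1, -1, -1)
        with pytest.raises(ValidationError):
            pair_ddG(reactants[:1], products)

    def test_closed_vocabularies_enforced(self):
        with pytest.raises(ValidationError):
            BindingEnergyRecord("PC", "3-OH", "membrane", -1.0)
        with pytest.raises(ValidationError):
            BindingEnergyRecord("PC", "WT", "cytosol", -1.0)


class TestKFromRates:
    def test_published_constants_round_to_035(self):
        K = K_from_rates(RateConstants(0.1, 0.2, 1, 1.43))
        assert K == pytest.approx(0.34965034965, rel=1e-10)
        assert round(K, 2) == 0.35

    def test_unit_constants_give_unity(self):
        assert K_from_rates(RateConstants(1, 1, 1, 1)) == 1.0

    def test_doubled_k2_doubles_K(self):
        assert K_from_rates(RateConstants(0.1, 0.2, 2, 1.43)) == pytest.approx(
            0.699300699, rel=1e-8
        )

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_pairwise_scaling(self, s1, s2):
        base = RateConstants(0.1, 0.2, 1, 1.43)
        scaled = RateConstants(0.1 * s1, 0.2 * s1, 1 * s2, 1.43 * s2)
        assert K_from_rates(scaled) == pytest.approx(K_from_rates(base), rel=1e-9)


class TestMinRule:
    def test_published_constants(self):
        assert kon_koff_min_rule([0.1, 1], [0.2, 1.43]) == (0.1, 0.2)

    def test_singletons_and_plain_minimum(self):
        assert kon_koff_min_rule([3.0], [7.0]) == (3.0, 7.0)
        assert kon_koff_min_rule([3, 2, 5], [1, 4])[0] == 2

    def test_disagrees_with_stepwise_product_on_published_constants(self):
        # the slowest-step heuristic gives 0.5 while the stepwise product
        # gives 0.35 -- both are reported, never interchanged
        kon, koff = kon_koff_min_rule([0.1, 1], [0.2, 1.43])
        assert kon / koff == pytest.approx(0.5)
        assert kon / koff != pytest.approx(K_from_rates(RateConstants(0.1, 0.2, 1, 1.43)))

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            kon_koff_min_rule([], [1.0])


class TestRatesFromK:
    def test_invert_for_k2(self):
        template = RateConstants(0.1, 0.2, 1, 1.43)
        target = 0.699300699300699
        out = rates_from_K(target, template, adjust="k2")
        assert out.k2 == pytest.approx(2.0, rel=1e-9)
        assert (out.k1, out.k1r, out.k2r) == (0.1, 0.2, 1.43)
        assert K_from_rates(out) == pytest.approx(target, rel=1e-12)

    def test_fixed_point(self):
        template = RateConstants(0.1, 0.2, 1, 1.43)
        out = rates_from_K(template.K, template, adjust="k1r")
        assert out.as_tuple() == pytest.approx(template.as_tuple(), rel=1e-12)

    def test_direct_inversion_from_unit_template(self):
        out = rates_from_K(0.35, RateConstants(1, 1, 1, 1), adjust="k1")
        assert out.k1 == pytest.approx(0.35, rel=1e-12)

    def test_reverse_constant_adjustment(self):
        template = RateConstants(1, 1, 1, 1)
        out = rates_from_K(0.5, template, adjust="k2r")
        assert out.k2r == pytest.approx(2.0, rel=1e-12)


class TestThermoKineticLink:
    @given(st.floats(-20, 20))
    @settings(max_examples=100, deadline=None)
    def test_ddG_K_round_trip(self, ddG):
        assert K_to_ddG(ddG_to_K(ddG)) == pytest.approx(ddG, abs=1e-12)

    def test_K_thermo_strictly_decreasing_in_ddG(self):
        values = [ddG_to_K(g) for g in (-5.0, -1.0, 0.0, 1.0, 5.0)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert ddG_to_K(0.0) == 1.0


def test_binding_table_csv_round_trip(tmp_path):
    records = [
        BindingEnergyRecord("PC", "WT", "membrane", -10.85),
        BindingEnergyRecord("Cer", "2R-OH", "SMS2-P", -9.52),
    ]
    path = tmp_path / "table.csv"
    write_binding_table(records, path)
    assert read_binding_table(path) == records
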