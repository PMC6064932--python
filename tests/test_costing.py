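"""Capital annualization, cost allocation, and package unit costs."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uhc_feasim.calibration import calibrate_child_mix, calibrate_maternal_mix
from uhc_feasim.costing import (
    CapitalItem,
    CostingParams,
    FacilityCostLedger,
    ServicePriceList,
    allocate_to_mch,
    annualize_capital,
    child_package_cost,
    combined_unit_cost,
    compute_mch_weight,
    maternal_package_cost,
    read_facility_ledger,
    scale_to_state,
    to_usd,
    unit_component_cost,
    write_facility_ledger,
)
from uhc_feasim.errors import ConfigurationError, DegenerateInputError, InvalidInputError
from uhc_feasim.money import as_rational, round_half_up, to_float
from uhc_feasim.reference import unrounded_unit_cost


def annuity_payment_by_bisection(principal, rate, life, tol=Fraction(1, 10**9)):
    """Oracle: payment P with sum_t P/(1+r)^t = principal, by bisection."""
    r = as_rational(rate)

    def pv(p):
        return sum(p / (1 + r) ** t for t in range(1, life + 1))

    lo, hi = Fraction(0), as_rational(principal)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if pv(mid) < principal:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestAnnualizeCapital:
    def test_straight_line_limit_at_zero_rate(self):
        assert annualize_capital(CapitalItem("building", 100_000, 5), 0) == 20_000
        assert annualize_capital(CapitalItem("building", 100_000, 1), 0) == 100_000

    def test_matches_bisection_oracle(self):
        item = CapitalItem("medical_equipment", 100_000, 5)
        got = annualize_capital(item, "0.03")
        oracle = annuity_payment_by_bisection(100_000, "0.03", 5)
        assert abs(got - oracle) < Fraction(1, 10**6)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            annualize_capital(CapitalItem("other", 1000, 5), "-0.01")

    @settings(derandomize=True)
    @given(
        cost=st.integers(0, 10**8),
        life=st.integers(1, 40),
        rate_bp=st.integers(1, 2000),
    )
    def test_annuity_approaches_straight_line_as_rate_vanishes(self, cost, life, rate_bp):
        item = CapitalItem("transport", cost, life)
        small = Fraction(rate_bp, 10**9)  # rate scaled toward zero
        near = annualize_capital(item, small)
        straight = Fraction(cost, life)
        assert abs(near - straight) <= cost * small  # bounded by O(r) drift
        # annualized cost is increasing in the rate
        assert annualize_capital(item, Fraction(rate_bp, 10**4)) >= straight


class TestAllocationAndUnitCosts:
    @pytest.mark.parametrize("total, w, expected", [(1_000_000, 1, 1_000_000), (1_000_000, 0, 0)])
    def test_allocate_extremes(self, total, w, expected):
        assert allocate_to_mch(total, w) == expected

    def test_allocate_niger_weight_equals_summed_per_visit_allocation(self):
        # weight-then-total equals summing a per-visit attribution
        total, visits_total, visits_mch = as_rational("1234567.89"), 1000, 900
        w = compute_mch_weight(visits_mch, visits_total)
        assert w == Fraction(9, 10)
        per_visit = total / visits_total
        assert allocate_to_mch(total, w) == per_visit * visits_mch

    @pytest.mark.parametrize("mch, tot, expected", [(83, 100, Fraction(83, 100)), (0, 100, 0), (9, 10, Fraction(9, 10))])
    def test_compute_mch_weight(self, mch, tot, expected):
        assert compute_mch_weight(mch, tot) == expected

    def test_weight_degenerate_and_invalid(self):
        with pytest.raises(DegenerateInputError):
            compute_mch_weight(0, 0)
        with pytest.raises(InvalidInputError):
            compute_mch_weight(11, 10)

    def test_unit_component_cost(self):
        assert unit_component_cost(100, 100) == 1
        assert unit_component_cost(0, 50) == 0
        with pytest.raises(DegenerateInputError):
            unit_component_cost(100, 0)

    def test_scale_and_allocate_commute(self):
        x, w, n = as_rational("1088497.9"), Fraction(83, 100), 418
        assert scale_to_state(allocate_to_mch(x, w), n) == allocate_to_mch(scale_to_state(x, n), w)

    def test_scale_to_state_imo_drug_total(self):
        # average facility drug cost x 418 facilities ~ the published total
        got = scale_to_state("1088497.9", 418)
        assert abs(got - 454_991_616) < 3_000  # avg given to 0.1 ₦

    def test_to_usd_display(self):
        assert to_usd("305.5") == 1
        assert to_float(to_usd("2837.6"), 1) == 9.3
        with pytest.raises(InvalidInputError):
            to_usd(100, 0)


class TestPackageCosts:
    def test_maternal_drugs_only_full_weights(self, prices):
        # ANC course + delivery + PNC + FP at weight one, no complications
        got = maternal_package_cost(prices, {"family_planning": 1})
        assert got == as_rational("5046.3")

    def test_maternal_all_prices_zero(self):
        zero = ServicePriceList({s: 0 for s in prices_all()})
        assert maternal_package_cost(zero, {"family_planning": 1}) == 0
        assert child_package_cost(zero, {"child_malaria": 1}) == 0

    def test_maternal_rejects_child_services_in_mix(self, prices):
        with pytest.raises(ConfigurationError):
            maternal_package_cost(prices, {"child_malaria": 1})

    def test_missing_price_is_configuration_error(self):
        partial = ServicePriceList({"anc": 100})
        with pytest.raises(ConfigurationError):
            maternal_package_cost(partial, {})

    def test_child_single_service_mix(self, prices):
        # three visits, all for malaria treatment
        assert child_package_cost(prices, {"child_malaria": 1}) == as_rational("1417.2")

    def test_calibrated_mixes_reproduce_state_unit_costs(self, prices):
        for state, group in [("Imo", "maternal"), ("Kaduna", "maternal"), ("Imo", "child"), ("Niger", "child")]:
            target = unrounded_unit_cost(state, group)
            if group == "maternal":
                mix = calibrate_maternal_mix(target, prices)
                got = maternal_package_cost(prices, mix)
            else:
                mix = calibrate_child_mix(target, prices)
                assert sum(mix.values()) == 1
                assert all(w >= 0 for w in mix.values())
                got = child_package_cost(prices, mix)
            assert got == target  # calibration is exact by construction

    def test_calibrated_imo_values_near_published(self, prices):
        m = maternal_package_cost(prices, calibrate_maternal_mix(unrounded_unit_cost("Imo", "maternal"), prices))
        c = child_package_cost(prices, calibrate_child_mix(unrounded_unit_cost("Imo", "child"), prices))
        assert round_half_up(m) == 4_827
        assert round_half_up(c) == 385

    def test_per_visit_components_accrue_over_contacts(self, prices):
        # full-package cost = drug part + contacts x component sum
        comp = {"capital": as_rational("43.9"), "personnel": as_rational("676.5"), "overhead": as_rational("9.7")}
        drug = maternal_package_cost(prices, {})
        full = maternal_package_cost(prices, {}, per_visit_components=comp)
        assert full - drug == 6 * sum(comp.values())
        child_drug = child_package_cost(prices, {"child_malaria": 1})
        child_full = child_package_cost(prices, {"child_malaria": 1}, per_visit_components=comp)
        assert child_full - child_drug == 3 * sum(comp.values())

    @pytest.mark.parametrize(
        "m, c, expected_display",
        [(4_774, 344, 1_230), (0, 0, 0), (("4758.96", "843.46"), None, 1_627)],
    )
    def test_combined_unit_cost(self, m, c, expected_display):
        if c is None:
            m, c = m
        got = combined_unit_cost(m, c)
        assert round_half_up(got) == expected_display

    def test_combined_exact_interpolation(self):
        got = combined_unit_cost("4758.96", "843.46")
        assert got == as_rational("1626.56")

    @settings(derandomize=True)
    @given(m=st.integers(0, 10**6), c=st.integers(0, 10**6))
    def test_combined_between_maternal_and_child(self, m, c):
        got = combined_unit_cost(m, c)
        assert min(m, c) <= got <= max(m, c)

    @settings(derandomize=True)
    @given(scale=st.fractions(min_value=0, max_value=10))
    def test_package_cost_linear_in_prices(self, scale):
        base = ServicePriceList({"anc": 100, "normal_delivery": 50, "pnc": 25, "family_planning": 10})
        scaled = ServicePriceList({s: p * scale for s, p in base.prices.items()})
        mix = {"family_planning": Fraction(1, 2)}
        assert maternal_package_cost(scaled, mix) == scale * maternal_package_cost(base, mix)


def prices_all():
    from uhc_feasim.costing import KNOWN_SERVICES

    return KNOWN_SERVICES


class TestLedgerIO:
    def test_roundtrip(self, tmp_path, prices):
        ledger = FacilityCostLedger(
            facility_id="f1",
            capital_items=(CapitalItem("building", "250000.5", 30, 2010),),
            personnel_annual="1200000",
            overhead_annual="340000.25",
            drug_line_items=(("anc", 120, "2837.6"), ("child_malaria", 300, "472.4")),
            visits_total=1000,
            visits_mch=850,
        )
        path = tmp_path / "f1.ledger"
        write_facility_ledger(ledger, path)
        assert read_facility_ledger(path) == ledger

    def test_parse_errors_carry_line_numbers(self, tmp_path):
        path = tmp_path / "bad.ledger"
        path.write_text(
            "[capital]\n"
            "category,replacement_cost,useful_life,acquisition_year\n"
            "bogus_cat,1,5,2010\n"
            "[personnel]\n100\n[overhead]\n50\n[drugs]\nservice,quantity,unit_price\n"
            "[visits]\nvisits_total,visits_mch\n10,9\n"
        )
        with pytest.raises(ConfigurationError, match=r"bad\.ledger:3"):
            read_facility_ledger(path)

    def test_missing_sections_rejected(self, tmp_path):
        path = tmp_path / "short.ledger"
        path.write_text("[personnel]\n100\n")
        with pytest.raises(ConfigurationError, match="missing sections"):
            read_facility_ledger(path)
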