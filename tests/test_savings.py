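from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biosavings.aggregate import collapse
from biosavings.cdh_data import DEFAULT_PAIRING, StudyWindow, build_comparator_map
from biosavings.savings import (
    TOTAL,
    DomainError,
    discount,
    province_mean_deltas,
    savings_national,
    savings_stratified,
    scenario_table,
    sensitivity_eligibility,
)
from conftest import oracle_savings, rec


def two_region_records(
    # region -> (orig_price_cents, orig_units, bios_price_cents, bios_units)
    spec={"ON": (1000, 100, 800, 50), "QC": (2000, 100, 1600, 25)},
):
    records = []
    for region, (op, ou, bp, bu) in spec.items():
        records.append(rec(region=region, role="originator", brand="Remicade", dollars_cents=op * ou, units=ou))
        records.append(rec(region=region, role="biosimilar", brand="Inflectra", dollars_cents=bp * bu, units=bu))
    return records


class TestDiscount:
    @pytest.mark.parametrize(
        "op,bp,delta,percent",
        [
            (19.26, 15.19, 4.07, 21.1),  # insulin glargine
            (197.53, 162.36, 35.17, 17.8),  # filgrastim
            (1001.07, 552.54, 448.53, 44.8),  # infliximab
        ],
    )
    def test_published_deltas_and_percents(self, op, bp, delta, percent):
        d = discount(op, bp, convention="cent_rounded")
        assert d.delta == pytest.approx(delta, abs=1e-9)
        assert round(100 * d.percent, 1) == percent

    def test_equal_prices_zero_discount(self):
        d = discount(10.0, 10.0, convention="exact")
        assert d.delta == 0 and d.percent == 0

    def test_dearer_biosimilar_negative_delta_preserved(self):
        d = discount(10.0, 12.0)
        assert d.delta == pytest.approx(-2.0)
        assert d.percent < 0

    def test_nonpositive_price_rejected(self):
        with pytest.raises(DomainError):
            discount(0.0, 1.0)
        with pytest.raises(DomainError):
            discount(1.0, 1.0, convention="half_rounded")


class TestSavingsNational:
    # printed Table-1 savings cells: (molecule, realized, unrealized)
    PRINTED = {
        "insulin glargine": (2_519_961, 29_825_236),
        "filgrastim": (13_443_873, 36_348_476),
        "infliximab": (30_199_524, 982_490_164),
    }

    def test_fixture_reproduces_printed_cells(self, fixture_records):
        cmaps = build_comparator_map(fixture_records)
        table = collapse(fixture_records, "national", "full_window", comparator_maps=cmaps)
        rows = {r.molecule: r for r in savings_national(table, cmaps)}
        for molecule, (realized, unrealized) in self.PRINTED.items():
            assert abs(rows[molecule].realized - realized) <= 2
            assert abs(rows[molecule].unrealized - unrealized) <= 2
        assert abs(rows[TOTAL].realized - 46_163_358) <= 5
        assert abs(rows[TOTAL].unrealized - 1_048_663_876) <= 5

    def test_zero_originator_units_zero_unrealized(self):
        records = [
            rec(role="originator", brand="Remicade", dollars_cents=0, units=0),
            rec(role="biosimilar", brand="Inflectra", dollars_cents=800 * 10, units=10),
        ]
        cmaps = build_comparator_map(records)
        table = collapse(records, "national", "full_window")
        # no originator price -> no delta; flagged, not invented
        rows = {r.molecule: r for r in savings_national(table, cmaps)}
        assert rows["infliximab"].unrealized == 0

    def test_zero_biosimilar_units_flagged(self, caplog):
        records = [
            rec(role="originator", brand="Remicade", dollars_cents=1000 * 10, units=10),
            rec(role="biosimilar", brand="Inflectra", dollars_cents=0, units=0),
        ]
        cmaps = build_comparator_map(records)
        table = collapse(records, "national", "full_window")
        rows = {r.molecule: r for r in savings_national(table, cmaps)}
        assert rows["infliximab"].no_comparator_price
        assert rows["infliximab"].realized == 0 and rows["infliximab"].unrealized == 0

    def test_dearer_biosimilar_negative_savings_not_clamped(self):
        records = [
            rec(role="originator", brand="Remicade", dollars_cents=1000 * 100, units=100),
            rec(role="biosimilar", brand="Inflectra", dollars_cents=1200 * 10, units=10),
        ]
        cmaps = build_comparator_map(records)
        table = collapse(records, "national", "full_window")
        rows = {r.molecule: r for r in savings_national(table, cmaps)}
        assert rows["infliximab"].realized == -20  # -2.00 x 10
        assert rows["infliximab"].unrealized == -200


class TestSavingsStratified:
    def test_single_region_equals_national(self, fixture_records):
        cmaps = build_comparator_map(fixture_records)
        national = collapse(fixture_records, "national", "full_window", comparator_maps=cmaps)
        regional = collapse(fixture_records, "region", "full_window", comparator_maps=cmaps)
        nat = {r.molecule: r for r in savings_national(national, cmaps)}
        strat = savings_stratified(regional, cmaps)
        for row in strat.totals:
            assert row.realized == nat[row.molecule].realized
            assert row.unrealized == nat[row.molecule].unrealized

    def test_two_region_deltas_against_enumeration_oracle(self):
        """Region deltas 2.00 and 4.00 with 100 originator units each give a
        stratified unrealized total of 600; the pooled convention on the same
        records must match the brute-force per-record oracle."""
        records = two_region_records()
        cmaps = build_comparator_map(records)
        regional = collapse(records, "region", "full_window", comparator_maps=cmaps)
        strat = savings_stratified(regional, cmaps)
        total = next(r for r in strat.totals if r.molecule == TOTAL)
        assert total.unrealized == 600  # 2.00x100 + 4.00x100
        assert total.realized == 2 * 50 + 4 * 25

        oracle_strat = oracle_savings(records, DEFAULT_PAIRING, per_region=True)
        assert (total.realized, total.unrealized) == oracle_strat["infliximab"]

        national = collapse(records, "national", "full_window", comparator_maps=cmaps)
        pooled = {r.molecule: r for r in savings_national(national, cmaps)}
        oracle_pooled = oracle_savings(records, DEFAULT_PAIRING, per_region=False)
        assert (pooled["infliximab"].realized, pooled["infliximab"].unrealized) == oracle_pooled["infliximab"]

    def test_region_without_biosimilar_uses_national_delta_fallback(self):
        records = two_region_records(
            {"ON": (1000, 100, 800, 50), "SK": (1000, 40, 0, 0)}
        )
        cmaps = build_comparator_map(records)
        regional = collapse(records, "region", "full_window", comparator_maps=cmaps)
        strat = savings_stratified(regional, cmaps, fallback="national_delta")
        sk = next(r for r in strat.by_region["SK"] if r.molecule == "infliximab")
        assert ("SK", "infliximab") in strat.fallbacks_used
        assert sk.unrealized == 2 * 40  # national delta 2.00 x 40 originator units

        skipped = savings_stratified(regional, cmaps, fallback="skip_region")
        sk2 = next(r for r in skipped.by_region["SK"] if r.molecule == "infliximab")
        assert sk2.no_comparator_price and sk2.unrealized == 0

    def test_province_mean_delta_differs_from_pooled(self):
        records = two_region_records()
        cmaps = build_comparator_map(records)
        regional = collapse(records, "region", "full_window", comparator_maps=cmaps)
        deltas = province_mean_deltas(regional, cmaps)
        assert float(deltas["infliximab"]) == pytest.approx(300.0)  # mean(200, 400) cents
        national = collapse(records, "national", "full_window", comparator_maps=cmaps)
        overridden = {r.molecule: r for r in savings_national(national, cmaps, delta_overrides=deltas)}
        assert overridden["infliximab"].unrealized == 3 * 200  # 3.00 x 200 units


class TestScenariosAndSensitivity:
    def test_conservation_and_linearity(self):
        records = two_region_records()
        cmaps = build_comparator_map(records)
        regional = collapse(records, "region", "full_window", comparator_maps=cmaps)
        strat = savings_stratified(regional, cmaps)
        table = scenario_table(strat, fractions=(0.25, 0.5, 1.0))
        total_row = next(r for r in strat.totals if r.molecule == TOTAL)
        # full conversion cell equals realized + unrealized, exactly
        assert table.loc[1.0, "Total"] == total_row.potential
        # linearity before rounding: 2 x 50% row == 100% row within rounding
        assert (2 * table.loc[0.5] - table.loc[1.0]).abs().max() <= 1
        # total column sums regions
        assert (table["Total"] == table[["ON", "QC"]].sum(axis=1)).all()

    @settings(derandomize=True, max_examples=100)
    @given(potential=st.integers(0, 10**10), f=st.sampled_from([0.25, 0.5, 0.75, 1.0]))
    def test_scenario_cell_is_fraction_of_potential(self, potential, f):
        table = scenario_table({"X": potential}, fractions=(f,))
        assert abs(table.loc[f, "X"] - f * potential) <= 0.5

    def test_fraction_domain(self):
        with pytest.raises(DomainError):
            scenario_table({"X": 100}, fractions=(0.0,))
        with pytest.raises(DomainError):
            scenario_table({"X": 100}, fractions=(1.5,))

    def test_eligibility_is_linear_scaling(self):
        assert sensitivity_eligibility(1_048_663_876, 0.8) == pytest.approx(838_931_100.8)
        assert sensitivity_eligibility(123.0, 0.0) == 0.0
        assert sensitivity_eligibility(123.0, 1.0) == 123.0
        with pytest.raises(DomainError):
            sensitivity_eligibility(123.0, 1.2)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_synthetic_dataset_matches_enumeration(self, seed):
        """Both savings conventions agree with direct per-record enumeration
        to within $1 per molecule on noisy synthetic data (<= 1000 records)."""
        from biosavings.synthetic_cdh import NoiseConfig, default_config, generate_purchases

        cfg = default_config(seed=seed).model_copy(
            update={
                "regions": {"BC": 0.2, "ON": 0.5, "PEI/NL": 0.3},
                "window": StudyWindow("2016-07", "2017-03"),
                "noise": NoiseConfig(price_cv=0.1, unit_dispersion=0.05),
            }
        )
        records = generate_purchases(cfg)
        assert len(records) <= 1000
        cmaps = build_comparator_map(records)
        national = collapse(records, "national", "full_window", comparator_maps=cmaps)
        regional = collapse(records, "region", "full_window", comparator_maps=cmaps)

        pooled = {r.molecule: r for r in savings_national(national, cmaps)}
        oracle_pooled = oracle_savings(records, DEFAULT_PAIRING, per_region=False)
        strat = {r.molecule: r for r in savings_stratified(regional, cmaps).totals}
        oracle_strat = oracle_savings(records, DEFAULT_PAIRING, per_region=True)
        for molecule in DEFAULT_PAIRING:
            assert abs(pooled[molecule].realized - oracle_pooled[molecule][0]) <= 1
            assert abs(pooled[molecule].unrealized - oracle_pooled[molecule][1]) <= 1
            assert abs(strat[molecule].realized - oracle_strat[molecule][0]) <= 1
            assert abs(strat[molecule].unrealized - oracle_strat[molecule][1]) <= 1
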