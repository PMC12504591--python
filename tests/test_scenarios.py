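"""Scenario engine: transforms, MC simulation, sequestration accounting."""

import numpy as np
import pytest

from silvocarbon import (
    AreaTable,
    CarbonDensityRange,
    make_management_scenario,
    run_suite,
    sequestration_percent,
    simulate_scenario,
)
from silvocarbon.errors import ConfigError, CoverageError, UndefinedBaselineError, ValidationError
from silvocarbon.lulc import AGROFORESTRY, ARABLE, MIXED_FOREST
from silvocarbon.scenarios import (
    Scenario,
    ScenarioResult,
    expected_mean_cs,
    make_temporal_scenario,
    results_frame,
)


def table(**areas):
    return AreaTable(epoch="test", entries=areas)


def ranges_for(**bounds):
    return {
        name: CarbonDensityRange(category=name, lower=lo, upper=hi)
        for name, (lo, hi) in bounds.items()
    }


class TestManagementScenarios:
    def test_partial_afforestation_arithmetic(self):
        base = table(**{ARABLE: 1000.0, MIXED_FOREST: 50.0})
        s = make_management_scenario(base, "S_F", fraction=0.10)
        assert s.name == "S_F10"
        assert s.area_table[ARABLE] == pytest.approx(900.0)
        assert s.area_table[MIXED_FOREST] == pytest.approx(150.0)

    def test_zero_fraction_is_identity(self):
        base = table(**{ARABLE: 1000.0})
        s = make_management_scenario(base, "S_F", fraction=0.0)
        assert s.area_table.entries == base.entries

    def test_full_agroforestry_conversion_on_2024(self, epoch_tables):
        s = make_management_scenario(epoch_tables["2024"], "S_AF")
        assert s.area_table[AGROFORESTRY] == pytest.approx(47525.03 + 1730580.29)
        assert s.area_table[ARABLE] == 0.0

    def test_total_area_conserved_exactly(self, epoch_tables):
        base = epoch_tables["2024"]
        for kind, frac in [("S_AF", None), ("S_F", 0.1), ("S_F", 0.25), ("S_F", 1.0)]:
            s = make_management_scenario(base, kind, fraction=frac)
            assert s.area_table.total == base.total

    def test_other_categories_untouched(self, epoch_tables):
        base = epoch_tables["2024"]
        s = make_management_scenario(base, "S_F", fraction=0.2)
        for cat in base.entries:
            if cat not in (ARABLE, MIXED_FOREST):
                assert s.area_table[cat] == base[cat]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            make_management_scenario(table(**{ARABLE: 10.0}), "S_F", fraction=1.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            make_management_scenario(table(**{ARABLE: 10.0}), "S_X")


class TestSimulateScenario:
    def test_degenerate_range_gives_exact_point(self):
        s = Scenario("one", table(Grassland=100.0))
        r = simulate_scenario(s, ranges_for(Grassland=(7.0, 7.0)), n=500, seed=0)
        assert r.mean_cs == 7.0
        assert (r.ci_lower, r.ci_upper) == (7.0, 7.0)

    def test_two_category_weighted_midpoint(self):
        s = Scenario("two", table(**{AGROFORESTRY: 100.0, "Grassland": 100.0}))
        rngs = ranges_for(**{AGROFORESTRY: (0.0, 2.0), "Grassland": (4.0, 6.0)})
        n = 100_000
        r = simulate_scenario(s, rngs, n=n, seed=1)
        # var of each realization's mean = (1/4)(4/12 + 4/12)
        se = np.sqrt((4 / 12 + 4 / 12) / 4) / np.sqrt(n)
        assert r.mean_cs == pytest.approx(3.0, abs=3 * se)

    def test_missing_range_is_coverage_error(self):
        s = Scenario("x", table(**{AGROFORESTRY: 10.0, "Grassland": 5.0}))
        with pytest.raises(CoverageError):
            simulate_scenario(s, ranges_for(**{AGROFORESTRY: (0, 1)}), n=10, seed=0)

    def test_zero_area_category_needs_no_range(self):
        s = Scenario("x", table(**{AGROFORESTRY: 10.0, "Grassland": 0.0}))
        r = simulate_scenario(s, ranges_for(**{AGROFORESTRY: (1, 1)}), n=10, seed=0)
        assert r.mean_cs == 1.0

    def test_label_swap_symmetry(self):
        # swapping two categories' labels (areas and ranges move together)
        a = Scenario("a", table(**{AGROFORESTRY: 300.0, "Grassland": 100.0}))
        b = Scenario("b", table(**{AGROFORESTRY: 100.0, "Grassland": 300.0}))
        ra = ranges_for(**{AGROFORESTRY: (10, 20), "Grassland": (50, 80)})
        rb = ranges_for(**{AGROFORESTRY: (50, 80), "Grassland": (10, 20)})
        n = 50_000
        res_a = simulate_scenario(a, ra, n=n, seed=2)
        res_b = simulate_scenario(b, rb, n=n, seed=3)
        assert res_a.mean_cs == pytest.approx(res_b.mean_cs, abs=0.1)

    def test_monte_carlo_converges_to_weighted_midpoints(self, epoch_tables, density_ranges):
        sc = make_temporal_scenario(epoch_tables["2024"])
        n = 100_000
        r = simulate_scenario(sc, density_ranges, n=n, seed=4)
        closed = expected_mean_cs(sc, density_ranges)
        # exact per-realization variance: sum_i (a_i w_i)^2 / 12 / total^2
        total = sc.area_table.total
        var = sum(
            (sc.area_table[c] * (rg.upper - rg.lower)) ** 2 / 12.0
            for c, rg in density_ranges.items()
        ) / total**2
        se = np.sqrt(var / n)
        assert r.mean_cs == pytest.approx(closed, abs=3 * se)

    def test_seed_determinism(self, epoch_tables, density_ranges):
        sc = make_temporal_scenario(epoch_tables["2024"])
        r1 = simulate_scenario(sc, density_ranges, n=2000, seed=5)
        r2 = simulate_scenario(sc, density_ranges, n=2000, seed=5)
        assert (r1.mean_cs, r1.ci_lower, r1.ci_upper) == (r2.mean_cs, r2.ci_lower, r2.ci_upper)

    def test_af_empirical_resampling_switch(self, epoch_tables, density_ranges):
        sc = make_temporal_scenario(epoch_tables["2024"])
        af = np.full(1000, 75.97)  # degenerate empirical stock sample
        r = simulate_scenario(sc, density_ranges, n=20_000, seed=6, af_sample=af)
        r_uniform = simulate_scenario(sc, density_ranges, n=20_000, seed=6)
        # same expectation either way (75.97 is the range midpoint)
        assert r.mean_cs == pytest.approx(r_uniform.mean_cs, abs=0.2)

    def test_result_invariant_enforced(self):
        with pytest.raises(ValidationError):
            ScenarioResult(name="bad", mean_cs=10.0, ci_lower=11.0, ci_upper=12.0,
                           seq_percent=None, n=1, seed=0)


class TestSequestration:
    def test_identity_zero_percent(self):
        r = ScenarioResult("a", 50.0, 40.0, 60.0, None, 10, 0)
        assert sequestration_percent(r, r) == 0.0

    def test_ten_percent(self):
        ref = ScenarioResult("ref", 50.0, 40.0, 60.0, None, 10, 0)
        tgt = ScenarioResult("tgt", 55.0, 45.0, 65.0, None, 10, 0)
        assert sequestration_percent(tgt, ref) == pytest.approx(10.0)

    def test_zero_reference_rejected(self):
        z = ScenarioResult("z", 0.0, 0.0, 0.0, None, 10, 0)
        t = ScenarioResult("t", 5.0, 4.0, 6.0, None, 10, 0)
        with pytest.raises(UndefinedBaselineError):
            sequestration_percent(t, z)


class TestSuite:
    def test_nine_results_in_reporting_order(self, epoch_tables, density_ranges):
        res = run_suite(epoch_tables, density_ranges, n=5000, seed=7)
        assert [r.name for r in res] == [
            "1929", "1954", "2024", "S_AF", "S_F10", "S_F15", "S_F20", "S_F25", "S_F30",
        ]

    def test_first_epoch_has_no_reference(self, epoch_tables, density_ranges):
        res = run_suite(epoch_tables, density_ranges, n=5000, seed=8)
        assert res[0].seq_percent is None
        assert all(r.seq_percent is not None for r in res[1:])

    def test_references_follow_reporting_convention(self, epoch_tables, density_ranges):
        res = run_suite(epoch_tables, density_ranges, n=20_000, seed=9)
        by = {r.name: r for r in res}
        assert by["1954"].seq_percent == pytest.approx(
            sequestration_percent(by["1954"], by["1929"]))
        assert by["2024"].seq_percent == pytest.approx(
            sequestration_percent(by["2024"], by["1954"]))
        for name in ("S_AF", "S_F10", "S_F30"):
            assert by[name].seq_percent == pytest.approx(
                sequestration_percent(by[name], by["2024"]))

    def test_afforestation_monotone_in_fraction(self, epoch_tables, density_ranges):
        # mixed forest's midpoint (144.0) exceeds arable's (54.3), so mean
        # stock must rise with the afforested fraction
        res = run_suite(epoch_tables, density_ranges, n=50_000, seed=10)
        sf = [r.mean_cs for r in res if r.name.startswith("S_F")]
        assert all(a < b for a, b in zip(sf, sf[1:]))

    def test_degenerate_ranges_zero_width_cis(self, epoch_tables):
        rngs = {
            c: CarbonDensityRange(category=c, lower=0.0 if c == "Water body" else 10.0,
                                  upper=0.0 if c == "Water body" else 10.0)
            for c in epoch_tables["2024"].entries
        }
        res = run_suite(epoch_tables, rngs, n=100, seed=11)
        for r in res:
            assert r.ci_lower == r.ci_upper == pytest.approx(r.mean_cs)

    def test_suite_seed_determinism(self, epoch_tables, density_ranges):
        r1 = run_suite(epoch_tables, density_ranges, n=2000, seed=12)
        r2 = run_suite(epoch_tables, density_ranges, n=2000, seed=12)
        assert all(a.mean_cs == b.mean_cs and a.seq_percent == b.seq_percent
                   for a, b in zip(r1, r2)
                   if a.seq_percent is not None or b.seq_percent is None)

    def test_results_frame_columns(self, epoch_tables, density_ranges):
        df = results_frame(run_suite(epoch_tables, density_ranges, n=500, seed=13))
        assert list(df.columns[:5]) == ["scenario", "mean", "ci_lower", "ci_upper", "seq_percent"]
        assert len(df) == 9


class TestDensityRanges:
    def test_water_body_fixed_at_zero(self, density_ranges):
        assert (density_ranges["Water body"].lower, density_ranges["Water body"].upper) == (0.0, 0.0)

    def test_nonzero_water_body_rejected(self):
        with pytest.raises(ValidationError):
            CarbonDensityRange(category="Water body", lower=1.0, upper=2.0)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValidationError):
            CarbonDensityRange(category="Grassland", lower=5.0, upper=1.0)

    def test_packaged_mixed_forest_range(self, density_ranges):
        r = density_ranges["Mixed Forest"]
        assert (r.lower, r.upper) == (126.88, 161.17)
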