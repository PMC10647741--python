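"""Oracles: lookup semantics, landscape determinism, fixture consistency."""

import numpy as np
import pandas as pd
import pytest

from nloswitch.figures_of_merit import three_state_components
from nloswitch.hrs_response import BetaTensor, orientational_invariants
from nloswitch.property_oracle import (
    LandscapeSpec,
    LookupOracle,
    MissingDataError,
    SwitchEvaluator,
    SyntheticOracle,
    build_fixture_db,
    fixture_landscape_26r,
    fixture_printed_metrics,
    random_landscape,
    separable_landscape,
)
from nloswitch.scaffold_space import enumerate_space, parse_pattern


class TestLookupOracle:
    def test_returns_stored_value_unchanged(self, fixture_db):
        oracle = LookupOracle(fixture_db[fixture_db.source == "table1"])
        assert oracle.evaluate("NH_NH_NH2_CN_NH2", "26R") == 5.99e4
        assert oracle.evaluate("NH_NH_NH2_CN_NH2", "28R") == 0.0

    def test_missing_key_is_an_error_not_zero(self, fixture_db):
        oracle = LookupOracle(fixture_db[fixture_db.source == "table1"])
        with pytest.raises(MissingDataError):
            oracle.evaluate("NH_NH_OH_OH_OH", "26R")

    def test_duplicate_rows_rejected(self):
        table = pd.DataFrame(
            {
                "pattern": ["A", "A"],
                "state": ["ON", "ON"],
                "beta_hrs_au": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError):
            LookupOracle(table)

    def test_tensor_entries_use_the_hrs_layer(self):
        t = BetaTensor.from_flat([0.0] * 26 + [1000.0])
        table = pd.DataFrame(
            {"pattern": ["A"], "state": ["ON"], "beta_hrs_au": [999.0]}
        )
        oracle = LookupOracle(table, tensors={("A", "ON"): t})
        expected = orientational_invariants(t).beta_hrs
        assert oracle.evaluate("A", "ON") == pytest.approx(expected)


class TestSyntheticLandscape:
    def test_bit_identical_determinism(self, scaffold_26r):
        spec = random_landscape(scaffold_26r, seed=11)
        a = SyntheticOracle(spec, scaffold_26r)
        b = SyntheticOracle(random_landscape(scaffold_26r, seed=11), scaffold_26r)
        for name in ("NH_S_NO2_CN_NH2", "NH_NH_NH2_CN_NH2", "NH_O_H_F_CH3"):
            for state in scaffold_26r.states:
                assert a.evaluate(name, state) == b.evaluate(name, state)

    def test_different_seeds_differ(self, scaffold_26r):
        a = SyntheticOracle(random_landscape(scaffold_26r, 1), scaffold_26r)
        b = SyntheticOracle(random_landscape(scaffold_26r, 2), scaffold_26r)
        vals_a = [a.evaluate("NH_NH_NH2_CN_NH2", "26R")]
        vals_b = [b.evaluate("NH_NH_NH2_CN_NH2", "26R")]
        assert vals_a != vals_b

    def test_trivial_spec_base_only(self, scaffold_26r):
        spec = LandscapeSpec(
            seed=0, off_state="28R", base={"26R": 1234.0}, on_cap=None
        )
        oracle = SyntheticOracle(spec, scaffold_26r)
        for name in ("NH_NH_H_H_H", "NH_S_NO2_CN_NH2"):
            assert oracle.evaluate(name, "26R") == 1234.0
            assert oracle.evaluate(name, "28R") == 0.0

    def test_off_regime_mostly_exact_zero(self, scaffold_26r):
        """Default landscapes keep >=90% of OFF states centrosymmetric
        (exactly 0) and the symmetry-broken remainder below ~3e3 a.u."""
        spec = random_landscape(scaffold_26r, seed=5)
        oracle = SyntheticOracle(spec, scaffold_26r)
        offs = np.array(
            [
                oracle.evaluate(p, "28R")
                for p in enumerate_space(scaffold_26r, max_size=2000)
            ]
        )
        assert np.mean(offs == 0.0) >= 0.90
        assert offs.max() <= 3.0e3

    def test_on_responses_within_configured_range(self, scaffold_26r):
        spec = random_landscape(scaffold_26r, seed=5)
        oracle = SyntheticOracle(spec, scaffold_26r)
        ons = np.array(
            [
                oracle.evaluate(p, "26R")
                for p in enumerate_space(scaffold_26r, max_size=2000)
            ]
        )
        assert ons.min() >= 0.0
        assert ons.max() <= 3.0e4

    def test_separable_landscape_has_no_synergy(self, small_scaffold):
        spec = separable_landscape(small_scaffold, seed=3)
        oracle = SyntheticOracle(spec, small_scaffold)
        # response differences from changing site A are independent of site B
        base = oracle.evaluate("H_H_H", "ON")
        d1 = oracle.evaluate("NH2_H_H", "ON") - base
        base2 = oracle.evaluate("H_CN_H", "ON")
        d2 = oracle.evaluate("NH2_CN_H", "ON") - base2
        assert d1 == pytest.approx(d2)


class TestFixtureDatabase:
    def test_row_count_matches_printed_value_pairs(self, fixture_db):
        # 7 build-up patterns x 2 states + 11 three-state patterns x 3
        # states + 3 representative switches x 2 + the 30R optimum x 2
        assert len(fixture_db) == 7 * 2 + 11 * 3 + 3 * 2 + 2

    def test_parent_contrasts_present(self, fixture_db):
        t1 = fixture_db[(fixture_db.source == "table1")]
        parent = t1[(t1.pattern == "NH_NH_H_H_H") & (t1.state == "26R")]
        assert parent.beta_hrs_au.item() == 2.09e3

    def test_two_state_rows_reproduce_printed_contrasts(
        self, fixture_db, printed_tables
    ):
        from nloswitch.figures_of_merit import contrast_revised

        t1_printed, _ = printed_tables
        sub = fixture_db[fixture_db.source == "table1"].pivot(
            index="pattern", columns="state", values="beta_hrs_au"
        )
        for row in t1_printed.itertuples():
            on, off = sub.loc[row.pattern, ["26R", "28R"]]
            assert contrast_revised(on, off) == pytest.approx(row.contrast)

    def test_three_state_rows_reproduce_printed_functions(
        self, fixture_db, printed_tables
    ):
        _, t2_printed = printed_tables
        sub = fixture_db[fixture_db.source == "table2"].pivot(
            index="pattern", columns="state", values="beta_hrs_au"
        )
        for row in t2_printed.itertuples():
            b26, b30, boff = sub.loc[row.pattern, ["26R", "30R", "28R"]]
            comp = three_state_components(b26, b30, boff)
            assert comp.value == pytest.approx(row.function, rel=0.02)
            assert comp.contrast_a == pytest.approx(row.contrast_26, rel=1e-6)
            assert comp.contrast_b == pytest.approx(row.contrast_30, rel=1e-6)

    def test_recovered_off_matches_printed_broken_symmetry_value(
        self, fixture_db
    ):
        """The inversion recovers the independently printed OFF response
        (2.92e3 a.u.) of the noncentrosymmetric NO2 pattern."""
        sub = fixture_db[
            (fixture_db.source == "table2")
            & (fixture_db.pattern == "NH_NH_NO2_CN_NH2")
            & (fixture_db.state == "28R")
        ]
        assert sub.beta_hrs_au.item() == pytest.approx(2.92e3, rel=0.02)

    def test_centrosymmetric_off_recorded_as_exact_zero(self, fixture_db):
        sub = fixture_db[
            (fixture_db.source == "table2")
            & (fixture_db.pattern == "NH_S_H_CN_NH2")
            & (fixture_db.state == "28R")
        ]
        assert sub.beta_hrs_au.item() == 0.0


class TestFixtureLandscape:
    def test_anchors_reproduce_published_contrasts(self, fixture_evaluator_26r):
        t1, _ = fixture_printed_metrics()
        for row in t1.itertuples():
            ev = fixture_evaluator_26r.evaluate(row.pattern)
            assert ev.value == pytest.approx(row.contrast, rel=1e-9)

    def test_only_amino_on_r25_breaks_off_symmetry(self, fixture_oracle_26r):
        oracle, scaffold = fixture_oracle_26r
        assert oracle.evaluate("NH_NH_NH2_H_NH2", "28R") == 0.0
        assert oracle.evaluate("NH_NH_NH2_NH2_NH2", "28R") > 0.0


class TestSwitchEvaluator:
    def test_metric_and_scaffold_arity_checks(self, scaffold_26r, scaffold_three_state):
        oracle = SyntheticOracle(random_landscape(scaffold_26r, 1), scaffold_26r)
        with pytest.raises(ValueError):
            SwitchEvaluator(oracle, scaffold_26r, metric="three_state")
        oracle3 = SyntheticOracle(
            random_landscape(scaffold_three_state, 1), scaffold_three_state
        )
        with pytest.raises(ValueError):
            SwitchEvaluator(oracle3, scaffold_three_state, metric="revised")

    def test_three_state_components_logged(self, scaffold_three_state):
        oracle = SyntheticOracle(
            random_landscape(scaffold_three_state, 1), scaffold_three_state
        )
        ev = SwitchEvaluator(oracle, scaffold_three_state, metric="three_state")
        result = ev.evaluate("NH_S_NO2_CN_NH2")
        assert result.components is not None
        assert result.value == pytest.approx(result.components.value)
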