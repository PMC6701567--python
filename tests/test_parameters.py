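import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quitcea import parameters as par


class TestGenerator:
    def test_defaults_pass_invariants(self, synth_params):
        synth_params.validate()

    def test_deterministic_given_seed(self):
        a = par.generate_synthetic_parameters(1)
        b = par.generate_synthetic_parameters(1)
        for key in a.incidence_smoker:
            np.testing.assert_array_equal(a.incidence_smoker[key], b.incidence_smoker[key])
        assert a.disease_cost == b.disease_cost
        assert a.utility == b.utility

    def test_different_seeds_differ(self):
        a = par.generate_synthetic_parameters(1)
        b = par.generate_synthetic_parameters(2)
        assert a.disease_cost != b.disease_cost

    def test_rr_one_collapses_smoker_to_never(self):
        p = par.generate_synthetic_parameters(
            1, relative_risk={d: 1.0 for d in par.DISEASES}
        )
        for key in p.incidence_never:
            np.testing.assert_allclose(p.incidence_smoker[key], p.incidence_never[key])

    def test_incidence_increases_with_age(self, synth_params):
        for key, arr in synth_params.incidence_never.items():
            assert np.all(np.diff(arr) >= 0), key

    def test_rr_below_one_rejected(self):
        with pytest.raises(par.ParameterError, match="relative_risk"):
            par.generate_synthetic_parameters(1, relative_risk={"copd": 0.5})

    def test_unknown_disease_override_rejected(self):
        with pytest.raises(par.ParameterError, match="unknown disease"):
            par.generate_synthetic_parameters(1, relative_risk={"gout": 2.0})

    def test_negative_seed_rejected(self):
        with pytest.raises(par.ParameterError):
            par.generate_synthetic_parameters(-1)

    def test_decay_starts_at_one_and_declines(self, synth_params):
        for d in par.DISEASES:
            dec = synth_params.decay_fraction[d]
            assert dec[0] == 1.0
            assert np.all(np.diff(dec) <= 1e-12)

    def test_default_horizon_is_95(self, synth_params):
        assert synth_params.max_age == 95
        assert synth_params.ages[0] == 19

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_any_seed_passes_invariants(self, seed):
        par.generate_synthetic_parameters(seed).validate()


class TestScenario:
    def test_identity_scenario_is_noop(self, synth_params):
        out = par.apply_scenario(synth_params, par.SensitivityScenario())
        for key in synth_params.incidence_smoker:
            np.testing.assert_array_equal(
                out.incidence_smoker[key], synth_params.incidence_smoker[key]
            )
        assert out.disease_cost == synth_params.disease_cost
        for sex in par.SEXES:
            np.testing.assert_array_equal(
                out.background_mortality[sex], synth_params.background_mortality[sex]
            )

    def test_published_scenario_scales_costs(self, synth_params):
        out = par.apply_scenario(synth_params, par.LOW_COST_LOW_RISK)
        for d in par.DISEASES:
            assert out.disease_cost[d] == pytest.approx(
                0.75 * synth_params.disease_cost[d]
            )

    def test_excess_risk_scaled_not_baseline(self, synth_params):
        out = par.apply_scenario(synth_params, par.LOW_COST_LOW_RISK)
        for key in synth_params.incidence_never:
            np.testing.assert_array_equal(
                out.incidence_never[key], synth_params.incidence_never[key]
            )
            expected = synth_params.incidence_never[key] + 0.5 * (
                synth_params.incidence_smoker[key] - synth_params.incidence_never[key]
            )
            np.testing.assert_allclose(out.incidence_smoker[key], expected)

    def test_death_risks_scaled(self, synth_params):
        out = par.apply_scenario(synth_params, par.LOW_COST_LOW_RISK)
        for sex in par.SEXES:
            np.testing.assert_allclose(
                out.background_mortality[sex],
                0.9 * synth_params.background_mortality[sex],
            )

    def test_decay_delta_floored_at_zero(self):
        from tests.conftest import make_toy_params

        p = make_toy_params(decay=np.array([1.0, 0.5, 0.05]))
        out = par.apply_scenario(p, par.SensitivityScenario(decay_fraction_delta=0.1))
        np.testing.assert_allclose(out.decay_fraction["copd"], [0.9, 0.4, 0.0])

    def test_original_unchanged(self, synth_params):
        before = dict(synth_params.disease_cost)
        par.apply_scenario(synth_params, par.LOW_COST_LOW_RISK)
        assert synth_params.disease_cost == before

    def test_cost_and_death_multipliers_commute(self, synth_params):
        a = par.apply_scenario(
            par.apply_scenario(synth_params, par.SensitivityScenario(cost_multiplier=0.75)),
            par.SensitivityScenario(death_risk_multiplier=0.9),
        )
        b = par.apply_scenario(
            par.apply_scenario(synth_params, par.SensitivityScenario(death_risk_multiplier=0.9)),
            par.SensitivityScenario(cost_multiplier=0.75),
        )
        for sex in par.SEXES:
            np.testing.assert_allclose(
                a.background_mortality[sex], b.background_mortality[sex]
            )
        for d in par.DISEASES:
            assert a.disease_cost[d] == pytest.approx(b.disease_cost[d])

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(par.ParameterError):
            par.SensitivityScenario(cost_multiplier=0.0)
        with pytest.raises(par.ParameterError):
            par.SensitivityScenario(death_risk_multiplier=1.5)
        with pytest.raises(par.ParameterError):
            par.SensitivityScenario(decay_fraction_delta=1.2)


class TestFixtures:
    def test_table3_per_person_key_rows(self):
        tab = par.load_fixture_table("table3_per_person").set_index(["sex", "age_group"])
        assert tab.loc[("female", "40-44"), "costs_avoided"] == 8532
        assert tab.loc[("female", "40-44"), "qalys_gained"] == 0.71
        assert tab.loc[("male", "40-44"), "costs_avoided"] == 10526
        assert tab.loc[("male", "40-44"), "qalys_gained"] == 1.00

    def test_intervention_costs(self):
        tab = par.load_fixture_table("intervention_costs").set_index("programme")
        assert tab.loc["HIT", "total_specific_cost"] == 117011
        assert tab.loc["LIT", "total_specific_cost"] == 27927

    def test_table1_counts(self):
        tab = par.load_fixture_table("table1_counts").set_index("measure")
        assert tab.loc["sustained_abstinence", "hit"] == 17
        assert tab.loc["sustained_abstinence", "lit"] == 7
        assert tab.loc["continuous_abstinence_1y", "hit"] == 27
        assert tab.loc["continuous_abstinence_1y", "lit"] == 14

    def test_counts_sum_to_arm_totals(self):
        tab = par.load_fixture_table("table3_counts")
        assert tab["n_hit_short"].sum() == 27
        assert tab["n_lit_short"].sum() == 14
        assert tab["n_hit_long"].sum() == 17
        assert tab["n_lit_long"].sum() == 7

    def test_age_bands_non_overlapping(self):
        tab = par.load_fixture_table("table3_per_person")
        for sex, grp in tab.groupby("sex"):
            bounds = sorted(
                tuple(int(x) for x in g.split("-")) for g in grp["age_group"]
            )
            for (lo1, hi1), (lo2, _) in zip(bounds, bounds[1:]):
                assert hi1 < lo2

    def test_unknown_fixture_lists_available(self):
        with pytest.raises(KeyError, match="table3_per_person"):
            par.load_fixture_table("nonexistent")

    @pytest.mark.parametrize("name", par.list_fixtures())
    def test_round_trip_through_csv(self, name, tmp_path):
        tab = par.load_fixture_table(name)
        p = tmp_path / f"{name}.csv"
        tab.to_csv(p, index=False)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(tab, back)


class TestParameterIO:
    def test_round_trip(self, synth_params, tmp_path):
        stem = tmp_path / "params"
        par.write_parameters(synth_params, stem)
        back = par.read_parameters(stem)
        back.validate()
        assert back.discount_rate == synth_params.discount_rate
        assert back.max_age == synth_params.max_age
        assert back.diseases == synth_params.diseases
        for key in synth_params.incidence_smoker:
            np.testing.assert_allclose(
                back.incidence_smoker[key], synth_params.incidence_smoker[key]
            )
        for d in par.DISEASES:
            np.testing.assert_allclose(
                back.decay_fraction[d], synth_params.decay_fraction[d]
            )
            assert back.disease_cost[d] == pytest.approx(synth_params.disease_cost[d])
        assert back.utility == pytest.approx(synth_params.utility)
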