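import numpy as np
import pytest

import ssbtax as st
from ssbtax.cea import (
    DOMINANT,
    NEVER,
    Increments,
    SamplingError,
    draw_at,
    equity_summary,
    icer,
    incremental_analysis,
    probability_cost_effective,
    run_arm,
    run_cea,
    sample_draw,
    sample_draws,
    threshold_effectiveness,
)
from ssbtax.outcomes_costs import ArmResult


class TestSampling:
    def test_degenerate_sds_return_central(self, params_degenerate):
        rng = np.random.default_rng(0)
        draw = sample_draw(params_degenerate, rng)
        assert draw == params_degenerate

    def test_counter_based_reproducibility(self, params):
        a = sample_draws(params, seed=5, n_draws=8)
        b = sample_draws(params, seed=5, n_draws=8)
        from ssbtax.cea import SAMPLED_FIELDS

        for name in SAMPLED_FIELDS:
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
        # draw i is independent of batch size
        solo = draw_at(params, seed=5, index=3).params
        assert solo.teeth_per_case == a.teeth_per_case[3]
        assert solo.dw_caries == a.dw_caries[3]

    def test_moment_matching_dw_caries(self, params):
        draws = sample_draws(params, seed=11, n_draws=10_000)
        se = params.sd_dw_caries / np.sqrt(10_000)
        assert np.mean(draws.dw_caries) == pytest.approx(0.010, abs=3 * se)
        assert np.all(draws.dw_caries >= 0) and np.all(draws.dw_caries <= 1)

    def test_effect_sizes_truncated_at_zero(self, params):
        draws = sample_draws(params, seed=2, n_draws=2000)
        assert np.all(draws.dmft_slope_per_10g >= 0)
        assert np.all(draws.net_consumption_reduction >= 0)

    def test_costs_positive(self, params):
        draws = sample_draws(params, seed=3, n_draws=500)
        for name in ("cost_checkup", "cost_restoration", "cost_denture_pair",
                     "teeth_per_case", "intervention_cost_year1"):
            assert np.all(getattr(draws, name) > 0)

    def test_incompatible_beta_sd_raises(self, params):
        bad = params.with_(sd_dw_caries=0.5)
        with pytest.raises(SamplingError, match="beta"):
            sample_draw(bad, np.random.default_rng(0))


def _arm(societal, healthcare, teeth, dalys):
    z = np.zeros((1, 1))
    return ArmResult(
        horizon=1,
        societal_cost_cycle=z, healthcare_cost_cycle=z,
        time_travel_cost_cycle=z, teeth_cycle=z, daly_cycle=z,
        total_societal_cost=np.asarray(societal, dtype=float),
        total_healthcare_cost=np.asarray(healthcare, dtype=float),
        total_decayed_teeth=np.asarray(teeth, dtype=float),
        total_dalys=np.asarray(dalys, dtype=float),
        total_societal_cost_undisc=np.asarray(societal, dtype=float),
        total_healthcare_cost_undisc=np.asarray(healthcare, dtype=float),
        total_decayed_teeth_undisc=np.asarray(teeth, dtype=float),
        total_dalys_undisc=np.asarray(dalys, dtype=float),
    )


class TestIncrementalAnalysis:
    def test_dominant_when_saving_and_averting(self):
        control = _arm(63.5e6, 42.2e6, 5e5, 98.1)
        interv = _arm(0.0, 0.0, 0.0, 0.0)
        inc = incremental_analysis(interv, control, wtp=50_000)
        assert icer(inc) == DOMINANT
        assert np.all(inc.nmb > 0)

    def test_wtp_boundary(self):
        # net cost 50,000 for one DALY averted: ICER sits exactly at WTP
        interv = _arm(50_000.0, 50_000.0, 0.0, -1.0)
        control = _arm(0.0, 0.0, 0.0, 0.0)
        inc = incremental_analysis(interv, control, wtp=50_000)
        assert inc.societal_savings == pytest.approx(-50_000)
        assert inc.dalys_averted == pytest.approx(1.0)
        assert icer(inc) == pytest.approx(50_000)
        assert inc.nmb == pytest.approx(0.0)

    def test_zero_effect_costly_intervention_not_cost_effective(self):
        interv = _arm(1e6, 1e6, 0.0, 0.0)
        control = _arm(0.0, 0.0, 0.0, 0.0)
        inc = incremental_analysis(interv, control, wtp=50_000)
        assert np.all(inc.nmb < 0)
        assert icer(inc) == "dominated-or-undefined"


class TestProbabilityCostEffective:
    def test_all_positive(self):
        inc = Increments(
            societal_savings=np.ones(10), healthcare_savings=np.ones(10),
            teeth_averted=np.ones(10), dalys_averted=np.ones(10),
            nmb=np.ones(10), wtp=50_000,
        )
        prob, _, _ = probability_cost_effective(inc)
        assert prob == 1.0

    def test_symmetric_half(self):
        savings = np.r_[np.full(500, 1.0), np.full(500, -1.0)]
        inc = Increments(
            societal_savings=savings, healthcare_savings=savings,
            teeth_averted=np.zeros(1000), dalys_averted=np.zeros(1000),
            nmb=savings, wtp=50_000,
        )
        prob, _, _ = probability_cost_effective(inc)
        assert prob == pytest.approx(0.5)

    def test_matches_brute_force_indicator(self):
        rng = np.random.default_rng(4)
        inc = Increments(
            societal_savings=rng.normal(0, 1e6, 300),
            healthcare_savings=np.zeros(300),
            teeth_averted=np.zeros(300),
            dalys_averted=rng.normal(1, 1, 300),
            nmb=np.zeros(300), wtp=50_000,
        )
        prob, _, _ = probability_cost_effective(inc, wtp=50_000)
        brute = sum(
            1 for s, d in zip(inc.societal_savings, inc.dalys_averted)
            if 50_000 * d + s > 0
        ) / 300
        assert prob == brute

    def test_ceac_monotone_when_all_dalys_positive(self):
        rng = np.random.default_rng(9)
        inc = Increments(
            societal_savings=rng.normal(0, 1e5, 400),
            healthcare_savings=np.zeros(400),
            teeth_averted=np.zeros(400),
            dalys_averted=rng.uniform(0.1, 2.0, 400),
            nmb=np.zeros(400), wtp=50_000,
        )
        _, grid, ceac = probability_cost_effective(inc)
        assert np.all(np.diff(ceac) >= 0)
        assert 0.0 in grid and 50_000.0 in grid


class TestRunCea:
    def test_degenerate_psa_equals_deterministic(self, params_degenerate,
                                                 schedule, profiles, population):
        settings = st.ModelSettings(horizon_years=10, n_psa_draws=10, seed=1)
        res = run_cea(params_degenerate, schedule, profiles, population, settings)
        det_i = run_arm("intervention", params_degenerate, schedule, profiles,
                        population, settings)
        det_c = run_arm("no_intervention", params_degenerate, schedule,
                        profiles, population, settings)
        det_saving = det_c.total_societal_cost - det_i.total_societal_cost
        assert np.all(res.increments.societal_savings == det_saving)
        assert res.summaries["societal_savings"]["ui_low"] == pytest.approx(
            det_saving, rel=1e-12
        )

    def test_fixture_run_is_dominant(self, params, schedule, profiles,
                                     population, settings_10y):
        res = run_cea(params, schedule, profiles, population, settings_10y)
        assert res.icer == DOMINANT
        assert 0.0 <= res.prob_cost_effective <= 1.0
        assert res.summaries["dalys_averted"]["mean"] > 0

    def test_quintile_results_scale_with_share(self, params, schedule,
                                               profiles, population):
        # one-fifth of the population accrues about one-fifth of the burden
        settings = st.ModelSettings(horizon_years=10, n_psa_draws=5, seed=2)
        total = run_cea(params, schedule, profiles, population, settings,
                        quintile="total")
        q3 = run_cea(params, schedule, profiles, population, settings,
                     quintile=3)
        ratio = (
            q3.summaries["total_dalys"]["mean"]
            / total.summaries["total_dalys"]["mean"]
        )
        assert ratio == pytest.approx(0.2, rel=1e-6)


class TestThreshold:
    @pytest.fixture()
    def det_settings(self):
        return st.ModelSettings(horizon_years=10, n_psa_draws=1, seed=1)

    def test_nmb_monotone_in_decay(self, params_degenerate, schedule, profiles,
                                   population, det_settings):
        control = run_arm("no_intervention", params_degenerate, schedule,
                          profiles, population, det_settings)
        nmbs = []
        for decay in np.linspace(0, 1, 21):
            interv = run_arm("intervention", params_degenerate, schedule,
                             profiles, population, det_settings, decay=decay)
            inc = incremental_analysis(interv, control, wtp=50_000)
            nmbs.append(float(np.mean(inc.nmb)))
        assert np.all(np.diff(nmbs) > 0)

    def test_free_intervention_threshold_zero(self, params_degenerate, schedule,
                                              profiles, population,
                                              det_settings):
        free = params_degenerate.with_(
            intervention_cost_year1=0.0, intervention_cost_subsequent=0.0
        )
        th = threshold_effectiveness(free, schedule, profiles, population,
                                     det_settings, criterion="nmb")
        assert th == 0.0

    def test_never_cost_effective_sentinel(self, params_degenerate, schedule,
                                           profiles, population, det_settings):
        ruinous = params_degenerate.with_(
            intervention_cost_year1=1e12, intervention_cost_subsequent=1e12
        )
        th = threshold_effectiveness(ruinous, schedule, profiles, population,
                                     det_settings, criterion="nmb")
        assert th == NEVER

    def test_bisection_reproducible_and_interior(self, params_degenerate,
                                                 schedule, profiles, population,
                                                 det_settings):
        # dial up ongoing costs until full effectiveness is barely worth it,
        # so the threshold lies strictly inside (0, 1)
        costly = params_degenerate.with_(
            intervention_cost_year1=5e6, intervention_cost_subsequent=5e6
        )
        a = threshold_effectiveness(costly, schedule, profiles, population,
                                    det_settings, criterion="nmb")
        b = threshold_effectiveness(costly, schedule, profiles, population,
                                    det_settings, criterion="nmb")
        assert isinstance(a, float) and 0.0 < a < 1.0
        assert a == b


class TestEquity:
    def _results(self, params, schedule, profiles, population, n_draws=5):
        settings = st.ModelSettings(horizon_years=10, n_psa_draws=n_draws, seed=3)
        return {
            q: run_cea(params, schedule, profiles, population, settings,
                       quintile=q)
            for q in range(1, 6)
        }

    def test_fixture_gradient_ratio_above_one(self, params_degenerate, schedule,
                                              profiles, population):
        res = self._results(params_degenerate, schedule, profiles, population,
                            n_draws=1)
        summ = equity_summary(res)
        assert summ.daly_ratio is not None and summ.daly_ratio > 1.0
        assert summ.teeth_ratio > 1.0
        assert len(summ.table) == 5

    def test_identical_quintiles_unit_ratios(self, params_degenerate, schedule,
                                             population):
        flat = [
            st.QuintileProfile(q, 0.372, 1.07, 0.2) for q in range(1, 6)
        ] + [st.QuintileProfile("total", 0.372, 1.07, 1.0)]
        settings = st.ModelSettings(horizon_years=10, n_psa_draws=1, seed=3)
        res = {
            q: run_cea(params_degenerate, schedule, flat, population, settings,
                       quintile=q)
            for q in range(1, 6)
        }
        summ = equity_summary(res)
        assert summ.daly_ratio == pytest.approx(1.0, rel=1e-9)
        assert summ.savings_ratio == pytest.approx(1.0, rel=1e-9)

    def test_missing_quintile_rejected(self, params_degenerate, schedule,
                                       profiles, population):
        res = self._results(params_degenerate, schedule, profiles, population,
                            n_draws=1)
        del res[4]
        with pytest.raises(ValueError, match="missing"):
            equity_summary(res)
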