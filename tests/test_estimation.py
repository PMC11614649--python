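import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from poppk import (CohortConfig, CovariateEffect, EventRecord, PopulationModel,
                   RandomEffects, TDMDataset, conditional_modes, fit,
                   generate_cohort, individual_objective, ofv,
                   stepwise_covariate_search, typical_parameters)
from poppk.estimation import FitConfig
from poppk.structural import Regimen, conc_multi_dose


def one_subject(d_values, times, dose=300.0, weight=70.0, flu=0, dul=0,
                interval=12.0, n_doses=6, sid="s1"):
    records = [EventRecord(sid, k * interval, True, amount=dose, weight=weight,
                           flu=flu, dul=dul) for k in range(n_doses)]
    for t, d in zip(times, d_values):
        records.append(EventRecord(sid, t, False, concentration=d,
                                   weight=weight, flu=flu, dul=dul))
    return TDMDataset(records)


def structural_prediction(m, weight, flu, dul, eta, times, dose=300.0,
                          interval=12.0, n_doses=6):
    typ = typical_parameters(weight, flu, dul, m)
    from poppk import individual_parameters
    ind = individual_parameters(typ, RandomEffects(eta))
    reg = Regimen(dose, interval, n_doses)
    return np.array([conc_multi_dose(reg, ind, t) for t in times])


@pytest.fixture
def plain_model():
    return PopulationModel(theta_cl=118.0, theta_v=2460.0, ka_fixed=1.46,
                           omega2_cl=0.333, sigma2_prop=0.05, sigma2_add=4.0)


class TestIndividualObjective:
    def test_zero_residual_leaves_log_variance(self, plain_model):
        m = replace(plain_model, omega2_cl=np.inf, sigma2_prop=0.0,
                    sigma2_add=4.0)
        times = [61.0]
        f = structural_prediction(m, 70.0, 0, 0, 0.0, times)
        ds = one_subject(f, times)
        value = individual_objective(ds, m, RandomEffects(0.0))
        assert value == pytest.approx(np.log(4.0), abs=1e-10)

    def test_square_law_in_residual(self, plain_model):
        m = replace(plain_model, omega2_cl=np.inf, sigma2_prop=0.0,
                    sigma2_add=4.0)
        times = [61.0]
        f = structural_prediction(m, 70.0, 0, 0, 0.0, times)
        v1 = individual_objective(one_subject(f + 1.0, times), m, 0.0)
        v2 = individual_objective(one_subject(f + 2.0, times), m, 0.0)
        assert v2 - v1 == pytest.approx(3.0 * 1.0 / 4.0, abs=1e-8)

    def test_matches_gaussian_density_oracle(self, plain_model, rng):
        m = plain_model
        eta = 0.37
        times = [49.0, 61.0, 66.5]
        f = structural_prediction(m, 80.0, 0, 0, eta, times)
        d = f * (1 + rng.normal(0, 0.1, len(f)))
        ds = one_subject(d, times, weight=80.0)
        got = individual_objective(ds, m, RandomEffects(eta))
        g2 = m.sigma2_prop * f ** 2 + m.sigma2_add
        loglik = stats.norm.logpdf(d, loc=f, scale=np.sqrt(g2)).sum()
        loglik += stats.norm.logpdf(eta, 0.0, np.sqrt(m.omega2_cl))
        expected = -2.0 * loglik - (len(times) + 1) * np.log(2 * np.pi)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_singular_omega_with_nonzero_eta(self, plain_model):
        m = replace(plain_model, omega2_cl=0.0)
        times = [61.0]
        f = structural_prediction(m, 70.0, 0, 0, 0.0, times)
        with pytest.raises(ZeroDivisionError):
            individual_objective(one_subject(f, times), m, 0.5)


class TestConditionalModes:
    def test_noise_free_data_gives_zero_eta(self, plain_model):
        # additive-only error keeps g2 independent of eta, so the mode of
        # the conditional objective sits exactly at the generating eta = 0
        m = replace(plain_model, sigma2_prop=0.0)
        times = [49.0, 61.0]
        f = structural_prediction(m, 70.0, 0, 0, 0.0, times)
        eta = conditional_modes(one_subject(f, times), m)
        assert abs(eta.eta_cl) < 1e-4

    def test_recovers_simulated_eta_rich_design(self, plain_model):
        m = replace(plain_model, sigma2_prop=1e-6, sigma2_add=1e-4,
                    omega2_cl=1.0)
        times = list(np.linspace(60.5, 71.5, 8))
        f = structural_prediction(m, 70.0, 0, 0, 0.5, times)
        eta = conditional_modes(one_subject(f, times), m)
        assert 0.45 < eta.eta_cl < 0.55

    def test_matches_grid_search_oracle(self, plain_model, rng):
        times = [50.0, 62.0]
        f = structural_prediction(plain_model, 90.0, 0, 0, 0.3, times)
        d = f * (1 + rng.normal(0, 0.15, len(f)))
        ds = one_subject(d, times, weight=90.0)
        eta_hat = conditional_modes(ds, plain_model).eta_cl
        grid = np.arange(-3.0, 3.0, 1e-3)
        values = [individual_objective(ds, plain_model, e) for e in grid]
        assert abs(grid[int(np.argmin(values))] - eta_hat) <= 1.5e-3


class TestOfv:
    def test_zero_omega_matches_closed_form(self, plain_model):
        ds = generate_cohort(CohortConfig(n_subjects=10, seed=21,
                                          obs_per_subject=2, sampling="mixed"))
        m = replace(plain_model, omega2_cl=0.0, sigma2_prop=0.267,
                    sigma2_add=29.917)
        got = ofv(ds, m)
        # independently coded heteroscedastic fixed-effects -2LL
        expected = 0.0
        for sid in ds.subjects():
            recs = ds.subject_records(sid)
            doses = [(r.time, r.amount) for r in recs if r.is_dose]
            typ = typical_parameters(recs[0].weight, int(recs[0].flu),
                                     int(recs[0].dul), m)
            for r in recs:
                if r.is_dose:
                    continue
                from poppk import conc_single_dose
                f = sum(conc_single_dose(a, typ, max(r.time - t0, 0.0))
                        for t0, a in doses)
                g2 = m.sigma2_prop * f ** 2 + m.sigma2_add
                expected += (r.concentration - f) ** 2 / g2 + np.log(g2)
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-6)

    def test_additivity_of_duplicate_observation(self, plain_model):
        m = replace(plain_model, omega2_cl=0.0)
        times = [49.0, 61.0]
        f = structural_prediction(m, 70.0, 0, 0, 0.0, times)
        d = f * 1.1
        ds1 = one_subject(d, times)
        ds2 = one_subject(list(d) + [d[1]], times + [times[1]])
        g2 = m.sigma2_prop * f[1] ** 2 + m.sigma2_add
        contribution = (d[1] - f[1]) ** 2 / g2 + np.log(g2)
        assert ofv(ds2, m) - ofv(ds1, m) == pytest.approx(contribution,
                                                          abs=1e-8)

    def test_invariant_to_subject_order(self, small_cohort, ref_model):
        sids = list(small_cohort.subjects())
        shuffled = small_cohort.subset(sids[::-1])
        assert ofv(small_cohort, ref_model) == pytest.approx(
            ofv(shuffled, ref_model), abs=1e-8)


class TestFit:
    def test_refit_is_fixed_point(self, small_cohort, ref_model):
        cfg = FitConfig(compute_se=False)
        first = fit(small_cohort, ref_model, cfg)
        second = fit(small_cohort, first.estimates, cfg)
        assert abs(second.ofv - first.ofv) < 1e-4

    def test_nested_model_ofv_ordering(self, small_cohort, ref_model):
        cfg = FitConfig(compute_se=False)
        full = fit(small_cohort, ref_model, cfg)
        reduced = fit(small_cohort, replace(ref_model, theta_flu=None,
                                            theta_dul=None), cfg)
        assert full.ofv <= reduced.ofv + 1e-4

    def test_degenerate_single_subject_is_flagged(self):
        ds = one_subject([50.0, 50.0], [49.0, 61.0])
        initial = PopulationModel(theta_cl=100.0, theta_v=2000.0,
                                  omega2_cl=0.3, sigma2_prop=0.1,
                                  sigma2_add=5.0)
        result = fit(ds, initial, FitConfig(compute_se=True))
        flagged = (not result.converged) or \
            any(se is None for se in result.se_percent.values())
        assert flagged

    def test_eta_hat_present_for_every_subject(self, small_cohort, ref_model):
        result = fit(small_cohort, ref_model, FitConfig(compute_se=False))
        assert set(result.eta_hat) == set(small_cohort.subjects())

    def test_serialisation_round_trip(self, small_cohort, ref_model):
        result = fit(small_cohort, ref_model, FitConfig(compute_se=False))
        from poppk.estimation import FitResult
        back = FitResult.from_dict(result.to_dict())
        assert back.estimates == result.estimates
        assert back.ofv == pytest.approx(result.ofv)


class TestStepwise:
    def test_empty_candidates_leave_structure(self, small_cohort):
        base = PopulationModel(theta_cl=118.0, theta_v=2460.0,
                               omega2_cl=0.333, sigma2_prop=0.267,
                               sigma2_add=29.917)
        result = stepwise_covariate_search(small_cohort, base, [])
        assert result.model.theta_flu is None
        assert result.model.theta_dul is None
        assert [e["step"] for e in result.trace] == ["base"]

    def test_strong_effect_selected(self):
        ds = generate_cohort(CohortConfig(
            n_subjects=48, obs_per_subject=2, flu_prevalence=0.5,
            dul_prevalence=0.0, sampling="mixed", seed=6))
        base = PopulationModel(theta_cl=118.0, theta_v=2460.0,
                               omega2_cl=0.333, sigma2_prop=0.267,
                               sigma2_add=29.917)
        cand = CovariateEffect("cl", "FLU", "linear", 0.0, estimated=True)
        result = stepwise_covariate_search(ds, base, [cand])
        assert result.model.theta_flu is not None
        assert result.model.theta_flu < -0.3
        accepted = [e for e in result.trace
                    if e["step"] == "forward" and e["accepted"]]
        assert len(accepted) == 1
        assert accepted[0]["delta_ofv"] > 3.84
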