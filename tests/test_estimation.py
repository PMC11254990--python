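"""Likelihood machinery: paired residual density, Laplace OFV, fitting, LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from odoxpk import (PKDataset, PopulationModel, StructuralParams, apply_m6,
                    censor_blq, fit_population, generate_trial_dataset,
                    lrt_improved, population_ofv, residual_pair_loglik)
from odoxpk.estimation import _subject_blocks, _subject_loglik
from odoxpk.synthetic_data import COLUMNS, TrialDesign, default_trial_design


def _toy_params():
    return StructuralParams(cl_u=10.0, v1_u=50.0, ka=1.0)


def _toy_dataset(obs, sigma_pop=None):
    """One subject, one IV occasion (100 mg over 1 h), total obs at given (t, dv)."""
    rows = [dict(ID=1, OCC=1, ROUTE="iv_infusion", EVID=1, TIME=0.0, AMT=100.0,
                 RATE=100.0, DV=np.nan, OBS=".", BLQ=0, LLOQ=np.nan, L2=-1, MDV=1)]
    for t, dv in obs:
        rows.append(dict(ID=1, OCC=1, ROUTE="iv_infusion", EVID=0, TIME=t,
                         AMT=0.0, RATE=0.0, DV=dv, OBS="total", BLQ=0,
                         LLOQ=2.0, L2=-1, MDV=0))
    return PKDataset(pd.DataFrame(rows, columns=COLUMNS))


class TestResidualPairLoglik:
    def test_matches_multivariate_normal_oracle(self, theta):
        pop = PopulationModel(theta=theta,
                              sigma_add={"total": 0.4, "unbound": 0.01},
                              sigma_prop={"total": 0.15, "unbound": 0.2},
                              rho_l2=0.6)
        obs, pred = (105.0, 0.9), (100.0, 1.0)
        s1 = float(pop.residual_sd("total", pred[0]))
        s2 = float(pop.residual_sd("unbound", pred[1]))
        cov = np.array([[s1 ** 2, 0.6 * s1 * s2], [0.6 * s1 * s2, s2 ** 2]])
        oracle = stats.multivariate_normal(mean=pred, cov=cov).logpdf(obs)
        assert residual_pair_loglik(obs, pred, pop) == pytest.approx(oracle, abs=1e-10)

    def test_rho_zero_reduces_to_univariate_sum(self, theta):
        pop = PopulationModel(theta=theta,
                              sigma_add={"total": 0.4, "unbound": 0.01},
                              sigma_prop={"total": 0.15, "unbound": 0.2},
                              rho_l2=0.0)
        obs, pred = (95.0, 1.1), (100.0, 1.0)
        expected = (stats.norm(pred[0], pop.residual_sd("total", pred[0])).logpdf(obs[0])
                    + stats.norm(pred[1], pop.residual_sd("unbound", pred[1])).logpdf(obs[1]))
        assert residual_pair_loglik(obs, pred, pop) == pytest.approx(expected, abs=1e-12)

    def test_lone_observation_uses_univariate_model(self, theta):
        pop = PopulationModel(theta=theta, sigma_prop={"total": 0.2, "unbound": 0.2},
                              rho_l2=0.9)
        val = residual_pair_loglik((95.0, None), (100.0, None), pop)
        oracle = stats.norm(100.0, 20.0).logpdf(95.0)
        assert val == pytest.approx(oracle, abs=1e-12)
        assert residual_pair_loglik((None, None), (None, None), pop) == 0.0

    def test_degenerate_variance_rejected(self, theta):
        pop = PopulationModel(theta=theta)  # all sigma zero
        with pytest.raises(ValueError):
            residual_pair_loglik((1.0, 1.0), (1.0, 1.0), pop)


class TestPopulationOFV:
    def test_no_random_effects_is_analytic(self):
        pop = PopulationModel(theta=_toy_params(),
                              sigma_add={"total": 1.0, "unbound": 0.0},
                              sigma_prop={"total": 0.1, "unbound": 0.0})
        data = _toy_dataset([(2.0, 1500.0), (6.0, 700.0)])
        subjects = _subject_blocks(data)
        expected = -2.0 * _subject_loglik(subjects[0], pop.theta, pop)
        assert population_ofv(pop, data) == pytest.approx(expected, abs=1e-10)

    def test_laplace_matches_quadrature_on_toy(self):
        """1 subject, 2 observations, 1 random effect: Laplace within 0.1 of
        brute-force numerical integration of the marginal likelihood."""
        omega = 0.3
        pop = PopulationModel(theta=_toy_params(), omega_sd={"cl_u": omega},
                              sigma_add={"total": 1.0, "unbound": 0.0},
                              sigma_prop={"total": 0.15, "unbound": 0.0})
        data = _toy_dataset([(2.0, 1500.0), (6.0, 700.0)])
        subj = _subject_blocks(data)[0]

        def integrand(eta):
            params = pop.individual_from_etas({"cl_u": eta})
            return np.exp(_subject_loglik(subj, params, pop)
                          + stats.norm(0, omega).logpdf(eta))

        marginal, _ = integrate.quad(integrand, -8 * omega, 8 * omega, limit=200)
        ofv_quad = -2.0 * np.log(marginal)
        ofv_laplace = population_ofv(pop, data)
        assert ofv_laplace == pytest.approx(ofv_quad, abs=0.1)

    def test_laplace_continuous_at_vanishing_omega(self):
        data = _toy_dataset([(2.0, 1500.0), (6.0, 700.0)])
        sig = dict(sigma_add={"total": 1.0, "unbound": 0.0},
                   sigma_prop={"total": 0.15, "unbound": 0.0})
        exact = population_ofv(PopulationModel(theta=_toy_params(), **sig), data)
        tiny = population_ofv(
            PopulationModel(theta=_toy_params(), omega_sd={"cl_u": 1e-8}, **sig), data)
        assert tiny == pytest.approx(exact, abs=1e-3)

    def test_row_order_invariance(self, pop):
        ds = apply_m6(censor_blq(generate_trial_dataset(pop, n_subjects=3, seed=8)))
        shuffled = PKDataset(ds.df.sample(frac=1.0, random_state=0))
        small = PopulationModel(theta=pop.theta, omega_sd={"cl_u": 0.3},
                                sigma_add=pop.sigma_add, sigma_prop=pop.sigma_prop,
                                rho_l2=pop.rho_l2)
        assert population_ofv(small, ds) == pytest.approx(
            population_ofv(small, shuffled), abs=1e-6)

    def test_empty_dataset_rejected(self, pop):
        rows = [dict(ID=1, OCC=1, ROUTE="oral", EVID=1, TIME=0.0, AMT=100.0,
                     RATE=0.0, DV=np.nan, OBS=".", BLQ=0, LLOQ=np.nan, L2=-1, MDV=1)]
        data = PKDataset(pd.DataFrame(rows, columns=COLUMNS))
        with pytest.raises(ValueError):
            population_ofv(pop, data)


ALL_SIGMA = {"sigma_add.total", "sigma_add.unbound",
             "sigma_prop.total", "sigma_prop.unbound", "rho_l2"}
THETA_NAMES = tuple(f"theta.{k}" for k in
                    ("cl_u", "v1_u", "v2_u", "v3_u", "q2_u", "q3_u",
                     "ka", "tlag", "f_oral", "fu_iv", "fu_po"))


class TestFitPopulation:
    def test_all_fixed_rejected(self, pop):
        ds = generate_trial_dataset(pop, n_subjects=1, seed=0)
        with pytest.raises(ValueError):
            fit_population(ds, pop, fixed=set(THETA_NAMES)
                           | {f"omega.{k}" for k in pop.omega_sd} | ALL_SIGMA)

    def test_truth_is_local_optimum(self, theta):
        """With low noise and init at truth the fit stays within 1% and beats
        10%-perturbed parameter vectors."""
        truth = PopulationModel(theta=theta,
                                sigma_add={"total": 0.05, "unbound": 0.001},
                                sigma_prop={"total": 0.02, "unbound": 0.02},
                                rho_l2=0.0)
        # uncensored data: the check is that the optimizer finds the truth
        # under the model's own data-generating process, without the small
        # deterministic shift that LLOQ/2 imputation of pre-dose samples adds
        ds = generate_trial_dataset(truth, n_subjects=6, seed=21)
        free = {"theta.cl_u", "theta.v1_u", "theta.f_oral"}
        fixed = (set(THETA_NAMES) | ALL_SIGMA) - free
        res = fit_population(ds, truth, fixed=fixed, compute_se=False)
        est = res.estimates.theta
        for name in ("cl_u", "v1_u", "f_oral"):
            assert getattr(est, name) == pytest.approx(getattr(theta, name), rel=0.01)
        subjects = _subject_blocks(ds)
        for name, factor in (("cl_u", 1.1), ("v1_u", 0.9), ("f_oral", 1.1)):
            perturbed = PopulationModel(
                theta=est.with_updates(**{name: getattr(est, name) * factor}),
                sigma_add=truth.sigma_add, sigma_prop=truth.sigma_prop,
                rho_l2=truth.rho_l2)
            assert res.ofv <= population_ofv(perturbed, subjects) + 1e-6

    def test_structural_parameter_recovery(self, theta):
        """50 subjects on a rich design (unbound assayed at every sample):
        every structural parameter recovered within 15% relative bias."""
        truth = PopulationModel(theta=theta,
                                sigma_add={"total": 0.5, "unbound": 0.02},
                                sigma_prop={"total": 0.20, "unbound": 0.25},
                                rho_l2=0.5)
        base = default_trial_design()
        rich = TrialDesign(unbound_subset_iv=base.iv_sample_times,
                           unbound_subset_oral=base.oral_sample_times)
        ds = apply_m6(censor_blq(generate_trial_dataset(truth, rich,
                                                        n_subjects=50, seed=42)))
        mult = {n: (1.2 if i % 2 == 0 else 0.85) for i, n in enumerate(THETA_NAMES)}
        updates = {n.split(".")[1]: getattr(theta, n.split(".")[1]) * mult[n]
                   for n in THETA_NAMES}
        init = PopulationModel(theta=theta.with_updates(**updates),
                               sigma_add=truth.sigma_add,
                               sigma_prop=truth.sigma_prop, rho_l2=truth.rho_l2)
        res = fit_population(ds, init, fixed=ALL_SIGMA, compute_se=False)
        assert res.converged
        for name in THETA_NAMES:
            key = name.split(".")[1]
            est, true = getattr(res.estimates.theta, key), getattr(theta, key)
            assert est == pytest.approx(true, rel=0.15), name

    def test_nested_model_never_fits_worse(self, theta):
        """Freeing an extra parameter cannot increase the minimized OFV."""
        truth = PopulationModel(theta=theta,
                                sigma_add={"total": 0.5, "unbound": 0.02},
                                sigma_prop={"total": 0.2, "unbound": 0.25},
                                rho_l2=0.5)
        ds = apply_m6(censor_blq(generate_trial_dataset(truth, n_subjects=4, seed=17)))
        free_small = {"theta.cl_u"}
        fixed_small = (set(THETA_NAMES) | ALL_SIGMA) - free_small
        fixed_big = fixed_small - {"theta.v1_u"}
        small = fit_population(ds, truth, fixed=fixed_small, compute_se=False)
        big = fit_population(ds, truth, fixed=fixed_big, compute_se=False)
        assert big.ofv <= small.ofv + 1e-6

    def test_standard_errors_reported(self, theta):
        truth = PopulationModel(theta=theta,
                                sigma_add={"total": 0.5, "unbound": 0.02},
                                sigma_prop={"total": 0.2, "unbound": 0.25},
                                rho_l2=0.5)
        ds = apply_m6(censor_blq(generate_trial_dataset(truth, n_subjects=5, seed=3)))
        free = {"theta.cl_u", "theta.v1_u"}
        res = fit_population(ds, truth, fixed=(set(THETA_NAMES) | ALL_SIGMA) - free)
        for name in free:
            assert res.standard_errors[name] is not None
            assert res.rse_percent[name] is not None and res.rse_percent[name] >= 0


class TestLRT:
    def test_threshold_for_one_df(self):
        assert lrt_improved(100.0, 96.0, 1)      # drop of 4.0 > 3.84
        assert not lrt_improved(100.0, 97.0, 1)  # drop of 3.0 < 3.84

    def test_multi_df_uses_chi2_quantile(self):
        crit2 = stats.chi2.ppf(0.95, 2)
        assert lrt_improved(100.0, 100.0 - crit2 - 0.01, 2)
        assert not lrt_improved(100.0, 100.0 - crit2 + 0.01, 2)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            lrt_improved(100.0, 96.0, 0)
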