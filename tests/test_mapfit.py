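import math

import numpy as np
import pytest
from scipy.optimize import brentq

from efalss.mapfit import (
    MapResult,
    fit_dataset,
    fit_map,
    fit_subject,
    map_objective,
    predict_exposure,
)
from efalss.pkmodel import PopPKParams, Regimen, conc_ss, individual_params
from efalss.trial import (
    Observation,
    ObservationSet,
    from_nonmem,
    get_strategies,
    simulate_observations,
    to_nonmem,
)


def brute_force_objective(eta, obs, weight, asian, regimen, params):
    """Plain-math reimplementation of the MAP objective, kept independent
    of the package's vectorized code path."""
    omega = np.asarray(params.omega, dtype=float)
    inv = np.linalg.inv(omega)
    total = (eta[0] * (inv[0, 0] * eta[0] + inv[0, 1] * eta[1])
             + eta[1] * (inv[1, 0] * eta[0] + inv[1, 1] * eta[1]))
    rel = weight / params.wt_ref
    cl = params.tvcl * rel**params.cl_wt_exp * math.exp(eta[0])
    if asian:
        cl *= params.asian_cl_factor
    v = params.tvv * rel**params.v_wt_exp * math.exp(eta[1])
    k = cl / v
    d = regimen.infusion_duration
    r0 = regimen.dose / d
    denom = 1.0 - math.exp(-k * regimen.tau)
    for o in obs.observations:
        t = o.time
        if t < d:
            f = (r0 / cl) * ((1.0 - math.exp(-k * t))
                             + math.exp(-k * t) * (1.0 - math.exp(-k * d))
                             * math.exp(-k * (regimen.tau - d)) / denom)
        else:
            f = (r0 / cl) * (1.0 - math.exp(-k * d)) \
                * math.exp(-k * (t - d)) / denom
        s = params.sigma_prop**2 * f * f + params.sigma_add**2
        if o.bloq:
            z = (params.loq - f) / math.sqrt(s)
            phi = 0.5 * math.erfc(-z / math.sqrt(2.0))
            total += -2.0 * math.log(phi)
        else:
            total += (o.value - f) ** 2 / s + math.log(2.0 * math.pi * s)
    return total


@pytest.fixture()
def toy_obs():
    return ObservationSet((
        Observation(0.3, 150.0, False, 1.0),
        Observation(120.0, 20.0, False, 1.0),
        Observation(167.0, 12.0, False, 1.0),
    ))


@pytest.fixture()
def reg72():
    return Regimen(dose=3600.0, tau=168.0, infusion_duration=0.1, weight=72.0)


class TestMapObjective:
    def test_empty_data_prior_only(self, default_params, reg72):
        assert map_objective(np.zeros(2), None, 72.0, False, reg72,
                             default_params) == 0.0
        val = map_objective([0.3, -0.2], None, 72.0, False, reg72,
                            default_params)
        inv = np.linalg.inv(default_params.omega)
        eta = np.array([0.3, -0.2])
        assert val == pytest.approx(float(eta @ inv @ eta), rel=1e-12)

    def test_single_bloq_at_prediction_equal_to_loq(self, default_params,
                                                    subject_factory):
        # 250 IU in a 72-kg adult crosses 1 IU/dL inside the interval
        subject = subject_factory(dose=250.0)
        t_star = brentq(
            lambda t: conc_ss(subject.pk, subject.regimen, t) - 1.0,
            1.0, 168.0, xtol=1e-14)
        obs = ObservationSet((Observation(t_star, None, True, 1.0),))
        val = map_objective(np.zeros(2), obs, 72.0, False, subject.regimen,
                            default_params)
        assert val == pytest.approx(-2.0 * math.log(0.5), abs=1e-9)

    def test_matches_brute_force_on_grid(self, default_params, toy_obs,
                                         reg72):
        obs = ObservationSet(toy_obs.observations[:2]
                             + (Observation(166.5, None, True, 1.0),))
        for e1 in (-0.5, -0.1, 0.0, 0.3):
            for e2 in (-0.3, 0.0, 0.4):
                eta = np.array([e1, e2])
                expected = brute_force_objective(eta, obs, 72.0, True,
                                                 reg72, default_params)
                got = map_objective(eta, obs, 72.0, True, reg72,
                                    default_params)
                assert got == pytest.approx(expected, abs=1e-10)

    def test_gradient_matches_finite_differences(self, default_params,
                                                 reg72, toy_obs):
        from efalss.mapfit import _inv_omega, _objective_parts

        obs = ObservationSet(toy_obs.observations
                             + (Observation(167.5, None, True, 1.0),))
        inv = _inv_omega(default_params)
        base = individual_params(default_params, 72.0, False)
        eta = np.array([0.25, -0.15])
        _, grad = _objective_parts(eta, obs, base.cl, base.v, reg72,
                                   default_params, inv)
        h = 1e-6
        for i in range(2):
            e = np.zeros(2)
            e[i] = h
            up = _objective_parts(eta + e, obs, base.cl, base.v, reg72,
                                  default_params, inv)[0]
            dn = _objective_parts(eta - e, obs, base.cl, base.v, reg72,
                                  default_params, inv)[0]
            assert grad[i] == pytest.approx((up - dn) / (2 * h), rel=1e-5)

    def test_singular_omega_rejected(self, default_params, toy_obs, reg72):
        params = PopPKParams(omega=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            map_objective(np.zeros(2), toy_obs, 72.0, False, reg72, params)


class TestFitMap:
    def test_no_observations_returns_prior_mode(self, default_params, reg72):
        res = fit_map(None, 60.0, True, reg72, default_params)
        assert isinstance(res, MapResult)
        assert np.array_equal(res.eta_hat, np.zeros(2))
        expected = individual_params(default_params, 60.0, True)
        assert res.pk_hat.cl == pytest.approx(expected.cl)
        assert res.converged and res.n_obs == 0

    def test_two_noise_free_points_recover_generating_parameters(
            self, default_params, subject_factory):
        # diffuse prior and a constant residual variance reduce MAP to
        # least squares, whose optimum is the exact two-point interpolant;
        # a prediction-dependent (proportional) variance would shift the
        # optimum through the ln sigma^2(f) term
        truth = subject_factory(eta=(0.35, -0.25))
        diffuse = PopPKParams(omega=default_params.omega * 1e6,
                              sigma_prop=0.0, sigma_add=0.5)
        obs = ObservationSet(tuple(
            Observation(t, conc_ss(truth.pk, truth.regimen, t), False, 1.0)
            for t in (24.0, 168.0)))
        res = fit_map(obs, truth.weight, truth.asian, truth.regimen, diffuse)
        assert res.converged
        assert res.pk_hat.cl == pytest.approx(truth.pk.cl, rel=1e-4)
        assert res.pk_hat.v == pytest.approx(truth.pk.v, rel=1e-4)

    def test_single_late_bloq_implies_faster_clearance(self, default_params,
                                                       subject_factory):
        subject = subject_factory()   # typical adult, trough ~13.8 IU/dL
        obs = ObservationSet((Observation(167.0, None, True, 1.0),))
        res = fit_map(obs, 72.0, False, subject.regimen, default_params)
        typical = individual_params(default_params, 72.0, False)
        assert res.pk_hat.cl >= typical.cl
        # grid-search oracle: the fit is at least as good as any grid point
        grid = np.linspace(-2.0, 2.0, 81)
        best = min(map_objective((a, b), obs, 72.0, False, subject.regimen,
                                 default_params)
                   for a in grid for b in grid)
        assert res.objective <= best + 1e-8

    def test_shrinkage_toward_prior_with_sparse_data(self, default_params,
                                                     subject_factory):
        subject = subject_factory()
        obs = ObservationSet((Observation(120.0, 30.0, False, 1.0),))
        res_map = fit_map(obs, 72.0, False, subject.regimen, default_params)
        diffuse = PopPKParams(omega=default_params.omega * 1e6)
        res_ml = fit_map(obs, 72.0, False, subject.regimen, diffuse)
        assert np.linalg.norm(res_map.eta_hat) <= \
            np.linalg.norm(res_ml.eta_hat) + 1e-8

    def test_objective_decreases_along_accepted_iterates(self, default_params,
                                                         reg72, toy_obs):
        from scipy.optimize import minimize

        from efalss.mapfit import _LBFGSB_OPTS, _inv_omega, _objective_parts

        inv = _inv_omega(default_params)
        base = individual_params(default_params, 72.0, False)

        def fun(eta):
            return _objective_parts(eta, toy_obs, base.cl, base.v, reg72,
                                    default_params, inv)

        trace = []
        minimize(fun, np.zeros(2), jac=True, method="L-BFGS-B",
                 bounds=[(-6, 6)] * 2, options=_LBFGSB_OPTS,
                 callback=lambda x: trace.append(fun(x)[0]))
        assert len(trace) >= 2
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_converged_fit_has_small_gradient(self, default_params, reg72,
                                              toy_obs):
        res = fit_map(toy_obs, 72.0, False, reg72, default_params)
        assert res.converged
        assert res.grad_norm < 1e-6


class TestPredictExposure:
    def test_prior_mode_gives_typical_exposure(self, default_params):
        reg = Regimen(dose=3600.0, tau=168.0, infusion_duration=1e-6)
        res = fit_map(None, 72.0, False, reg, default_params)
        m = predict_exposure(res, reg)
        assert m.c_trough == pytest.approx(13.83, abs=5e-3)
        assert m.t_above_5 >= m.t_above_10 >= m.t_above_40

    def test_perfect_recovery_reproduces_true_metrics(self, default_params,
                                                      subject_factory):
        from efalss.pkmodel import exposure_metrics

        truth = subject_factory(eta=(0.2, 0.1))
        diffuse = PopPKParams(omega=default_params.omega * 1e6,
                              sigma_prop=0.0, sigma_add=0.5)
        obs = ObservationSet(tuple(
            Observation(t, conc_ss(truth.pk, truth.regimen, t), False, 1.0)
            for t in (0.5, 48.0, 120.0, 168.0)))
        res = fit_map(obs, truth.weight, truth.asian, truth.regimen, diffuse)
        got = predict_exposure(res, truth.regimen)
        want = exposure_metrics(truth.pk, truth.regimen)
        assert got.c_trough == pytest.approx(want.c_trough, rel=1e-4)
        assert got.t_above_40 == pytest.approx(want.t_above_40, rel=1e-4)


class TestFitFromDataset:
    def test_dataset_fits_match_direct_fits(self, default_params,
                                            subject_factory):
        subjects = [subject_factory(subject_id=i, weight=w)
                    for i, w in enumerate((55.0, 72.0, 95.0))]
        strat = get_strategies(["LSS3"])[0]
        rng = np.random.default_rng(21)
        obsets = [simulate_observations(s, strat, default_params, rng)
                  for s in subjects]
        records = from_nonmem(to_nonmem(subjects, obsets))
        by_id = fit_dataset(records, default_params)
        for s, obs in zip(subjects, obsets):
            direct = fit_subject(s, obs, default_params)
            assert by_id[s.id].eta_hat == pytest.approx(direct.eta_hat,
                                                        abs=1e-8)
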