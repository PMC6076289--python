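"""Posterior-predictive summaries, dose response, wash-out and modality."""

import numpy as np
import pytest

from mrafit.abc_smc import ParticleEnsemble
from mrafit.objective import ResponseSet
from mrafit.ode_models import (
    MAPK_EGF_NGF_PARAM_NAMES,
    MAPK_EGF_PARAM_NAMES,
    MAPK_EGF_PARAMS,
    build_mapk_egf_model,
    build_mapk_egf_ngf_model,
)
from mrafit.posterior_analysis import (
    dose_response,
    fit_sigmoid,
    modality_analysis,
    predict_features,
    ssq_fit_error,
    washout_timecourse,
)

THETA_TRUE = np.array([MAPK_EGF_PARAMS[n] for n in MAPK_EGF_PARAM_NAMES])


def true_particle_ensemble(n=3):
    particles = np.tile(THETA_TRUE, (n, 1))
    return ParticleEnsemble(1, particles, np.full(n, 1 / n), np.zeros(n), 1.0,
                            tuple(MAPK_EGF_PARAM_NAMES))


def egf_builder(theta, dose):
    return build_mapk_egf_model(dict(zip(MAPK_EGF_PARAM_NAMES, theta)), egf=dose)


NGF_PARAMS = {name: 2.0 for name in MAPK_EGF_NGF_PARAM_NAMES}
NGF_PARAMS["kd_egf"] = NGF_PARAMS["kd_ngf"] = 0.2
NGF_TOTALS = {"RAF_TOT": 25.0, "MEK_TOT": 100.0, "ERK_TOT": 400.0}


def egf_ngf_builder(theta, dose):
    return build_mapk_egf_ngf_model(dict(zip(MAPK_EGF_NGF_PARAM_NAMES, theta)),
                                    NGF_TOTALS, "EGF", dose)


class TestPredictFeatures:
    def test_identical_particles_have_zero_spread(self):
        ens = true_particle_ensemble()
        pred = predict_features(ens, egf_builder, [("lo", 0.1), ("hi", 1.0)])
        assert np.allclose(pred.lrc_se["lo"], 0.0, atol=1e-9)
        assert np.allclose(pred.ratio_se["hi"], 0.0, atol=1e-9)

    def test_predicted_diagonal_is_minus_one(self):
        ens = true_particle_ensemble()
        pred = predict_features(ens, egf_builder, [("lo", 0.1)])
        assert np.array_equal(np.diag(pred.lrc_mean["lo"]), -np.ones(3))

    def test_empty_ensemble_rejected(self):
        ens = true_particle_ensemble()
        with pytest.raises(ValueError):
            predict_features(ens, egf_builder, [])


class TestSsqFitError:
    def test_identical_sets_score_zero(self):
        rs = ResponseSet(lrc={"a": -np.eye(3) + 0.3}, ratios={"b": np.ones(3)})
        assert ssq_fit_error(rs, rs) == 0.0

    def test_direct_substitution(self):
        obs = ResponseSet(lrc={}, ratios={"a": np.array([1.0, 2.0])})
        sim = ResponseSet(lrc={}, ratios={"a": np.array([0.0, 0.0])})
        assert ssq_fit_error(obs, sim) == pytest.approx(5.0)

    def test_shape_mismatch_rejected(self):
        obs = ResponseSet(lrc={"a": -np.eye(3)})
        sim = ResponseSet(lrc={"a": -np.eye(2)})
        with pytest.raises(ValueError):
            ssq_fit_error(obs, sim)


class TestDoseResponse:
    def test_zero_dose_gives_zero_activation(self):
        frame, _ = dose_response(true_particle_ensemble(1), egf_builder, [0.0])
        assert frame["mean"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_mean_erk_monotone_in_dose(self):
        """Steady aERK rises with EGF over the printed prediction grid."""
        doses = [0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8, 25.6, 51.2, 102.4]
        frame, _ = dose_response(true_particle_ensemble(1), egf_builder, doses)
        assert np.all(np.diff(frame["mean"]) > -1e-9)

    def test_sigmoid_fits_better_than_line(self):
        doses = np.array([0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8, 25.6, 51.2, 102.4])
        frame, _ = dose_response(true_particle_ensemble(1), egf_builder, doses)
        y = frame["mean"].to_numpy()
        _, ssq_sig = fit_sigmoid(doses, y)
        lin = np.polyfit(doses, y, 1)
        ssq_lin = float(np.sum((np.polyval(lin, doses) - y) ** 2))
        assert ssq_sig < ssq_lin

    def test_percentile_band_ordering(self):
        rng = np.random.default_rng(0)
        jitter = THETA_TRUE * np.exp(rng.normal(0, 0.05, (20, 16)))
        ens = ParticleEnsemble(1, jitter, np.full(20, 1 / 20), np.zeros(20), 1.0)
        frame, _ = dose_response(ens, egf_builder, [0.5, 2.0])
        assert (frame["lo"] <= frame["mean"] + 1e-9).all()
        assert (frame["mean"] <= frame["hi"] + 1e-9).all()


class TestWashout:
    def test_immediate_neutralisation_stays_flat(self):
        theta = np.array([NGF_PARAMS[n] for n in MAPK_EGF_NGF_PARAM_NAMES])
        ens = ParticleEnsemble(1, theta[None, :], np.ones(1), np.zeros(1), 1.0)
        t, mean, se = washout_timecourse(ens, egf_ngf_builder, dose=1.0,
                                         neutralize_at=0.0,
                                         t_grid=np.linspace(0, 30, 16))
        assert np.allclose(mean, 0.0, atol=1e-8)

    def test_trajectory_continuous_at_switch(self):
        theta = np.array([NGF_PARAMS[n] for n in MAPK_EGF_NGF_PARAM_NAMES])
        ens = ParticleEnsemble(1, theta[None, :], np.ones(1), np.zeros(1), 1.0)
        grid = np.linspace(0, 40, 161)  # includes the switch at t = 10
        t, mean, se = washout_timecourse(ens, egf_ngf_builder, dose=1.0,
                                         neutralize_at=10.0, t_grid=grid)
        jumps = np.abs(np.diff(mean))
        i_switch = np.searchsorted(grid, 10.0)
        local = jumps[max(i_switch - 2, 0): i_switch + 2]
        assert np.all(local < 5 * (np.median(jumps) + 1e-6))

    def test_erk_decays_after_washout_once_input_gone(self):
        """Post-washout, with the RAS pulse cut, aERK relaxes downward."""
        theta = np.array([NGF_PARAMS[n] for n in MAPK_EGF_NGF_PARAM_NAMES])
        ens = ParticleEnsemble(1, theta[None, :], np.ones(1), np.zeros(1), 1.0)
        grid = np.linspace(0, 120, 61)
        t, mean, se = washout_timecourse(ens, egf_ngf_builder, dose=1.0,
                                         neutralize_at=10.0, t_grid=grid)
        tail = mean[t >= 30]
        assert np.all(np.diff(tail) <= 1e-6)


class TestModality:
    def test_unimodal_sample_gives_one_mode(self):
        rng = np.random.default_rng(0)
        report = modality_analysis(rng.normal(0, 1, 1000))
        assert report["n_modes"] == 1

    def test_separated_mixture_gives_two_modes(self):
        rng = np.random.default_rng(1)
        draws = np.concatenate([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        report = modality_analysis(draws)
        assert report["n_modes"] == 2
        modes = sorted(report["modes"])
        assert modes[0] == pytest.approx(0.0, abs=1.0)
        assert modes[-1] == pytest.approx(10.0, abs=1.0)

    def test_two_component_fit_never_worse(self):
        rng = np.random.default_rng(2)
        report = modality_analysis(rng.normal(0, 1, 1000))
        assert report["ssq"][2] <= report["ssq"][1] + 1e-9

    def test_degenerate_readouts_rejected(self):
        with pytest.raises(ValueError):
            modality_analysis(np.full(100, 3.0))

    def test_too_few_readouts_rejected(self):
        with pytest.raises(ValueError):
            modality_analysis(np.random.default_rng(0).normal(size=10))

    def test_density_normalised(self):
        rng = np.random.default_rng(3)
        report = modality_analysis(rng.normal(0, 1, 500))
        area = np.trapezoid(report["density"], report["grid"])
        assert area == pytest.approx(1.0, abs=1e-3)
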