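"""Michaelis-Menten primitives and the two MAPK cascade models."""

import numpy as np
import pytest
import sympy as sp

from mrafit.ode_models import (
    DEFAULT_TOTALS,
    MAPK_EGF_NGF_PARAM_NAMES,
    MAPK_EGF_PARAM_NAMES,
    MAPK_EGF_PARAMS,
    ModelConfigurationError,
    build_mapk_egf_model,
    build_mapk_egf_ngf_model,
    michaelis_activation,
    michaelis_decay,
    ras_input,
)

NGF_PARAMS = {name: 2.0 for name in MAPK_EGF_NGF_PARAM_NAMES}
NGF_PARAMS["kd_egf"] = NGF_PARAMS["kd_ngf"] = 0.2
NGF_TOTALS = {"RAF_TOT": 25.0, "MEK_TOT": 100.0, "ERK_TOT": 400.0}


@pytest.mark.parametrize("k,K,S,M,expected", [
    (1.0, 10.0, 10.0, 1.0, 0.5),
    (1.0, 10.0, 0.0, 5.0, 0.0),
    (0.1, 10.0, 90.0, 2.0, 0.18),
])
def test_michaelis_activation_values(k, K, S, M, expected):
    assert michaelis_activation(k, K, S, M) == pytest.approx(expected)


@pytest.mark.parametrize("V,K,S,expected", [
    (2.0, 10.0, 10.0, 1.0),   # half-saturation at S = K
    (10.0, 10.0, 0.0, 0.0),
    (10.0, 10.0, 90.0, 9.0),
])
def test_michaelis_decay_values(V, K, S, expected):
    assert michaelis_decay(V, K, S) == pytest.approx(expected)


@pytest.mark.parametrize("func", [
    lambda: michaelis_activation(1.0, 0.0, 1.0, 1.0),
    lambda: michaelis_activation(1.0, -2.0, 1.0, 1.0),
    lambda: michaelis_decay(1.0, 0.0, 1.0),
])
def test_nonpositive_michaelis_constant_rejected(func):
    with pytest.raises(ValueError):
        func()


class TestRasInput:
    def test_zero_at_time_zero(self):
        assert ras_input(1.0, 1.0, 0.0) == 0.0

    def test_peak_at_five_over_kd(self):
        t = np.linspace(0.01, 30, 3000)
        for kd in (0.5, 1.0, 2.0):
            curve = ras_input(1.0, kd, t)
            assert t[np.argmax(curve)] == pytest.approx(5.0 / kd, rel=0.01)

    def test_value_at_peak(self):
        # (1/2) * 5^5 * exp(-5), evaluated independently
        assert ras_input(1.0, 1.0, 5.0) == pytest.approx(0.5 * 3125 * np.exp(-5.0))
        assert ras_input(1.0, 1.0, 5.0) == pytest.approx(10.528, abs=5e-3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ras_input(1.0, 1.0, -1.0)


class TestEgfModel:
    def test_has_sixteen_free_parameters(self):
        model = build_mapk_egf_model(egf=0.1)
        assert len(model.parameters) == 16
        assert set(model.parameters) == set(MAPK_EGF_PARAM_NAMES)

    def test_starved_state_without_ligand_is_fixed_point(self):
        model = build_mapk_egf_model(egf=0.0)
        assert np.allclose(model.rate(np.zeros(3), 0.0), 0.0)

    def test_missing_parameter_rejected(self):
        params = dict(MAPK_EGF_PARAMS)
        params.pop("k_f1")
        with pytest.raises(ModelConfigurationError, match="k_f1"):
            build_mapk_egf_model(params)

    def test_negative_parameter_rejected(self):
        params = dict(MAPK_EGF_PARAMS, k_f1=-1.0)
        with pytest.raises(ModelConfigurationError):
            build_mapk_egf_model(params)

    def test_analytic_jacobian_matches_symbolic(self):
        """Hand-coded Jacobian against a sympy-differentiated oracle."""
        araf, amek, aerk = sp.symbols("araf amek aerk", positive=True)
        p = MAPK_EGF_PARAMS
        tot = DEFAULT_TOTALS
        egf = 0.7
        iraf, imek, ierk = (tot["RAF_TOT"] - araf, tot["MEK_TOT"] - amek,
                            tot["ERK_TOT"] - aerk)
        f = sp.Matrix([
            p["k_f1"] * iraf * egf / (p["K_mf1"] + iraf)
            - p["k_r1"] * araf * aerk / (p["K_mr1"] + araf)
            - p["V_m1"] * araf / (p["K_m1"] + araf),
            p["k_f2"] * imek * araf / (p["K_mf2"] + imek)
            - p["k_r2"] * amek * aerk / (p["K_mr2"] + amek)
            - p["V_m2"] * amek / (p["K_m2"] + amek),
            p["k_f3"] * ierk * amek / (p["K_mf3"] + ierk)
            - p["V_m3"] * aerk / (p["K_m3"] + aerk),
        ])
        jac_sym = sp.lambdify((araf, amek, aerk),
                              f.jacobian([araf, amek, aerk]), "numpy")
        model = build_mapk_egf_model(egf=egf)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0.5, 60.0, size=3)
            expected = np.asarray(jac_sym(*x), dtype=float)
            got = model.jacobian(x, 0.0)
            assert np.allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_trajectories_stay_in_box(self):
        """Activation vanishes as pools empty, decay as active forms empty."""
        from scipy.integrate import solve_ivp

        rng = np.random.default_rng(42)
        for _ in range(5):
            params = {n: float(np.exp(rng.normal(np.log(2.3), 1.0)))
                      for n in MAPK_EGF_PARAM_NAMES}
            model = build_mapk_egf_model(params, egf=float(rng.uniform(0.1, 5)))
            x0 = rng.uniform(0, 1, 3) * model.totals
            sol = solve_ivp(lambda t, y: model.rate(y, t), (0, 200), x0,
                            method="LSODA", rtol=1e-8, atol=1e-10)
            assert sol.success
            assert np.all(sol.y >= -1e-6)
            assert np.all(sol.y <= model.totals[:, None] + 1e-6)

    def test_finite_difference_matches_analytic_derivative(self):
        model = build_mapk_egf_model(egf=1.0)
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.uniform(1.0, 80.0, 3)
            num = np.empty((3, 3))
            for j in range(3):
                h = 1e-6 * max(abs(x[j]), 1.0)
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                num[:, j] = (model.rate(xp, 0) - model.rate(xm, 0)) / (2 * h)
            assert np.allclose(num, model.jacobian(x, 0), rtol=1e-5, atol=1e-7)


class TestEgfNgfModel:
    def test_twenty_seven_unknowns_including_totals(self):
        model = build_mapk_egf_ngf_model(NGF_PARAMS, NGF_TOTALS, "NGF", 1.0)
        assert len(model.parameters) + len(model.totals) == 27

    def test_ngf_specific_terms_vanish_under_egf(self):
        """With b_n = 0 the k_f14 and k_f32 terms contribute exactly zero."""
        strong = dict(NGF_PARAMS, k_f14=50.0, k_f32=50.0)
        m1 = build_mapk_egf_ngf_model(NGF_PARAMS, NGF_TOTALS, "EGF", 1.0)
        m2 = build_mapk_egf_ngf_model(strong, NGF_TOTALS, "EGF", 1.0)
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.uniform(0, 20, 3)
            t = float(rng.uniform(0, 30))
            assert np.allclose(m1.rate(x, t), m2.rate(x, t))

    def test_zero_dose_starved_state_stays_flat(self):
        model = build_mapk_egf_ngf_model(NGF_PARAMS, NGF_TOTALS, "EGF", 0.0)
        for t in (0.0, 1.0, 10.0, 60.0):
            assert np.allclose(model.rate(np.zeros(3), t), 0.0)

    def test_unknown_ligand_rejected(self):
        with pytest.raises(ModelConfigurationError):
            build_mapk_egf_ngf_model(NGF_PARAMS, NGF_TOTALS, "FGF", 1.0)
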