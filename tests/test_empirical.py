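"""Closed-form scattering models, angle averaging, correlation, sweeps."""

import numpy as np
import pytest

from smtoptics import (
    EmpiricalInputs,
    A_reflection,
    A_transmission,
    R_model,
    T_model,
    angle_average,
    fit_affine,
    fit_linear_form,
    fit_sigmoid_form,
    run_sweep,
    sigma_reflection,
    sigma_transmission,
    spearman_rank,
)
from smtoptics.empirical import TRANSMITTANCE_SIGMOID, _sigmoid_eval

# Independently coded one-line evaluations of the six closed forms,
# used as the literal-formula oracle.
_ORACLES = {
    "A_refl": lambda u, wv, Is: Is * ((0.0023 - 0.0016 * wv) * u - 0.00029),
    "sig_refl": lambda u, wv: 1.0 / ((0.006 - 0.0007 * wv) * u - 0.009),
    "A_trans": lambda u, wv, Is, th: Is * (1 - wv) * (
        (0.028 * np.cos(np.radians(th)) - 0.0196) * u
        + 0.0493 * (1 - np.cos(np.radians(th)))),
    "sig_trans": lambda u, wv, th: 1.0 / ((1 - 0.71 * wv) * (
        (0.089 * np.cos(np.radians(th)) - 0.0604) * u
        + 0.23 * (1 - np.cos(np.radians(th))))),
    "R": lambda th, u: 1 - (0.00016 + 0.97 / u) / (
        1 + np.exp((0.11 - 0.26 / u) * (th - (87.44 + 107.15 / u)))),
    "T": lambda th, u: (0.94 - 0.44 / u) / (
        1 + np.exp((0.32 - 2.00 / u) * (th - (44.28 + 61.57 / u)))),
}


class TestClosedForms:
    def test_reflection_amplitude_hand_value(self):
        # (0.0023 - 0.0016*0.11)*25 - 0.00029 = 0.05281
        got = A_reflection(EmpiricalInputs(u_ratio=25, wv_ratio=0.11, I_s=1))
        assert got == pytest.approx(0.05281, abs=1e-12)

    def test_reflection_amplitude_root_and_linearity(self):
        wv = 0.2
        u0 = 0.00029 / (0.0023 - 0.0016 * wv)
        assert A_reflection(EmpiricalInputs(u_ratio=u0, wv_ratio=wv)) == pytest.approx(0.0, abs=1e-15)
        a1 = A_reflection(EmpiricalInputs(u_ratio=20, wv_ratio=wv, I_s=1.0))
        a2 = A_reflection(EmpiricalInputs(u_ratio=20, wv_ratio=wv, I_s=2.0))
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_reflection_width_hand_value(self):
        got = sigma_reflection(EmpiricalInputs(u_ratio=25, wv_ratio=0.11))
        assert got == pytest.approx(1.0 / 0.139075, rel=1e-9)

    def test_inverse_width_affine_and_decreasing(self):
        us = np.array([12.0, 15.0, 19.0, 25.0])
        inv = np.array([1.0 / sigma_reflection(EmpiricalInputs(u_ratio=u, wv_ratio=0.11))
                        for u in us])
        # 1/sigma affine in u => second differences of equally spaced pts vanish
        slope, _, r2 = fit_affine(us, inv)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope > 0
        sig = 1.0 / inv
        assert np.all(np.diff(sig) < 0)

    def test_reflection_width_undefined_bracket(self):
        with pytest.raises(ValueError, match="sigma undefined"):
            sigma_reflection(EmpiricalInputs(u_ratio=1.0, wv_ratio=0.11))

    def test_transmission_amplitude_normal_incidence_reduction(self):
        # cos 0 = 1: A = I_s (1 - wv) * 0.0084 * u
        inp = EmpiricalInputs(u_ratio=20, wv_ratio=0.15, I_s=2.0, theta_i_deg=0.0)
        assert A_transmission(inp) == pytest.approx(2.0 * 0.85 * 0.0084 * 20, rel=1e-12)

    def test_transmission_amplitude_45deg_hand_value(self):
        inp = EmpiricalInputs(u_ratio=25, wv_ratio=0.11, I_s=1.0, theta_i_deg=45.0)
        c = np.cos(np.radians(45.0))
        expected = 0.89 * ((0.028 * c - 0.0196) * 25 + 0.0493 * (1 - c))
        assert A_transmission(inp) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0172788, abs=1e-6)

    def test_transmission_amplitude_vanishes_at_full_furrow(self):
        inp = EmpiricalInputs(u_ratio=20, wv_ratio=1.0 - 1e-12, theta_i_deg=30.0)
        assert A_transmission(inp) == pytest.approx(0.0, abs=1e-10)

    def test_literal_formula_property(self):
        """All six closed forms agree with independent one-liners, 1e-12."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            u = rng.uniform(10, 38)
            wv = rng.uniform(0.06, 0.55)
            th = rng.uniform(0, 90)
            Is = rng.uniform(0.5, 2.0)
            assert A_reflection(EmpiricalInputs(u, wv, Is)) == pytest.approx(
                _ORACLES["A_refl"](u, wv, Is), abs=1e-12)
            assert sigma_reflection(EmpiricalInputs(u, wv)) == pytest.approx(
                _ORACLES["sig_refl"](u, wv), abs=1e-12)
            assert A_transmission(EmpiricalInputs(u, wv, Is, th)) == pytest.approx(
                _ORACLES["A_trans"](u, wv, Is, th), abs=1e-12)
            # the transmission width bracket goes negative near grazing
            # incidence; evaluate the oracle only on its positive domain
            th_n = rng.uniform(0, 40)
            assert sigma_transmission(EmpiricalInputs(u, wv, theta_i_deg=th_n)) == pytest.approx(
                _ORACLES["sig_trans"](u, wv, th_n), abs=1e-12)
            assert float(R_model(th, u)) == pytest.approx(_ORACLES["R"](th, u), abs=1e-12)
            assert float(T_model(th, u)) == pytest.approx(_ORACLES["T"](th, u), abs=1e-12)

    def test_range_warning_outside_ensemble(self):
        with pytest.warns(UserWarning, match="u_ratio"):
            A_reflection(EmpiricalInputs(u_ratio=100.0, wv_ratio=0.11))


class TestSigmoidModels:
    def test_reflectance_hand_value_at_normal_incidence(self):
        # 1 - 0.03896 / (1 + e^(0.0996 * (0 - 91.726)))
        assert float(R_model(0.0, 25.0)) == pytest.approx(0.96104, abs=1e-4)

    def test_reflectance_monotone_in_angle(self):
        th = np.linspace(0, 90, 500)
        for u in (11.8, 18.0, 25.0):
            r = R_model(th, u)
            assert np.all(np.diff(r) >= -1e-12)

    def test_reflectance_large_ratio_limit(self):
        # numerator -> 0.00016 as u -> infinity
        val = float(R_model(0.0, 1e9))
        assert 1.0 - val == pytest.approx(0.00016, rel=1e-3)

    def test_transmittance_hand_values(self):
        assert float(T_model(0.0, 11.8)) == pytest.approx(0.902, abs=1e-3)
        assert float(T_model(90.0, 11.8)) < 0.01

    def test_transmittance_decreasing_in_angle(self):
        th = np.linspace(0, 90, 500)
        t = T_model(th, 11.8)
        assert np.all(np.diff(t) <= 1e-12)


class TestAngleAverage:
    def test_constant_model_is_exact(self):
        assert angle_average(lambda th, u: np.full_like(np.asarray(th, float), 0.37),
                             u_ratio=1.0) == pytest.approx(0.37, abs=1e-12)

    def test_published_transmittance_averages(self):
        assert angle_average(T_model, 11.8) == pytest.approx(0.495, abs=0.005)
        assert angle_average(T_model, 25.0) == pytest.approx(0.479, abs=0.005)

    def test_average_transmittance_strictly_decreasing(self):
        us = np.linspace(11.8, 25.0, 8)
        vals = [angle_average(T_model, u, 0.05) for u in us]
        assert np.all(np.diff(vals) < 0)

    def test_resolution_guard(self):
        with pytest.raises(ValueError):
            angle_average(T_model, 11.8, resolution_deg=1.0)


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        rho, p = spearman_rank(x, [2, 4, 9, 16, 30])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rank(x, [-1, -5, -6, -9, -20])
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_mid_rank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [10.0, 9.0, 7.0, 7.0, 4.0, 1.0]

        def midranks(v):
            v = np.asarray(v)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman_rank(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rank([1, 1, 1], [1, 2, 3])

    def test_exact_permutation_small_n(self):
        rho, p = spearman_rank([1, 2, 3, 4], [1, 3, 2, 4], exact=True)
        assert -1 <= rho <= 1 and 0 < p <= 1


class TestSweepFits:
    def test_linear_form_self_consistency(self):
        """Records generated directly from the amplitude formula are
        recovered to machine precision."""
        us = [10, 14, 18, 22, 26, 30]
        wvs = [0.08, 0.15, 0.25]
        rows = []
        for wv in wvs:
            for u in us:
                rows.append({
                    "u_ratio": u, "wv_ratio": wv,
                    "A": _ORACLES["A_refl"](u, wv, 1.0),
                    "sigma_deg": _ORACLES["sig_refl"](u, wv),
                })
        import pandas as pd
        df = pd.DataFrame(rows)
        co = fit_linear_form(df, "A")
        assert co["a"] == pytest.approx(0.0023, abs=1e-9)
        assert co["b"] == pytest.approx(0.0016, abs=1e-9)
        assert co["c"] == pytest.approx(0.00029, abs=1e-9)
        cs = fit_linear_form(df, "sigma")
        assert cs["a"] == pytest.approx(0.006, abs=1e-9)
        assert cs["b"] == pytest.approx(0.0007, abs=1e-9)
        assert cs["c"] == pytest.approx(0.009, abs=1e-9)

    def test_linear_form_rank_deficient_design_rejected(self):
        import pandas as pd
        df = pd.DataFrame({
            "u_ratio": [10, 14, 18, 22], "wv_ratio": [0.11] * 4,
            "A": [1, 2, 3, 4], "sigma_deg": [4, 3, 2, 1],
        })
        with pytest.raises(ValueError, match="wv_ratio"):
            fit_linear_form(df, "A")

    def test_sigmoid_form_self_consistency(self):
        import pandas as pd
        rows = []
        for u in (11.8, 15.2, 21.9, 25.0):
            for th in np.linspace(0, 88, 23):
                rows.append({
                    "u_ratio": u, "theta_i_deg": th,
                    "R_or_T": float(T_model(th, u)),
                })
        df = pd.DataFrame(rows)
        co = fit_sigmoid_form(df, mode="transmission")
        # the refit must reproduce the generating curve
        for u in (11.8, 25.0):
            th = np.linspace(0, 90, 50)
            np.testing.assert_allclose(
                _sigmoid_eval(th, u, co), T_model(th, u), atol=1e-6)
        np.testing.assert_allclose(
            co.as_array(), TRANSMITTANCE_SIGMOID.as_array(), rtol=1e-3)

    def test_single_grid_point_sweep(self):
        df = run_sweep([15.0], (0.11,), (45.0,), ray_count=5000, seed=1)
        assert len(df) == 1
        assert {"u_ratio", "A", "sigma_deg", "R_or_T"} <= set(df.columns)
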