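"""Compartment-model macro rates, impulse response and tissue curve.

The independent oracle throughout is the two-tissue ODE system

    dC_E/dt = K1*C_B - (k2+k3)*C_E + k4*C_M
    dC_M/dt = k3*C_E - k4*C_M

integrated numerically (or via the matrix exponential for an impulse),
against which the analytic bi-exponential convolution is checked.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

import liverkin as lk
from liverkin.tac import DomainError

rates = st.floats(0.0, 5.0)


class TestMacroRates:
    def test_irreversible_limit_k4_zero(self):
        mr = lk.macro_rates(1.0, 0.0, 0.0)
        assert mr.t1 == 0.0 and mr.t2 == pytest.approx(1.0)
        mr = lk.macro_rates(2.0, 0.05, 0.0)
        assert mr.t1 == 0.0 and mr.t2 == pytest.approx(2.05)

    def test_against_quadratic_root_oracle(self):
        k2, k3, k4 = 1.84, 0.046, 0.021
        mr = lk.macro_rates(k2, k3, k4)
        # roots of lambda^2 - (k2+k3+k4) lambda + k2*k4
        roots = np.sort(np.roots([1.0, -(k2 + k3 + k4), k2 * k4]))
        assert mr.t1 == pytest.approx(roots[0], rel=1e-12)
        assert mr.t2 == pytest.approx(roots[1], rel=1e-12)
        assert mr.t1 == pytest.approx(0.0205, abs=5e-5)
        assert mr.t2 == pytest.approx(1.8865, abs=5e-5)

    @given(k2=rates, k3=rates, k4=rates)
    def test_sum_and_product_identities(self, k2, k3, k4):
        mr = lk.macro_rates(k2, k3, k4)
        s = k2 + k3 + k4
        assert 0.0 <= mr.t1 <= mr.t2
        assert mr.t1 + mr.t2 == pytest.approx(s, rel=1e-10, abs=1e-12)
        assert mr.t1 * mr.t2 == pytest.approx(k2 * k4, rel=1e-10, abs=1e-12)

    def test_negative_rates_rejected(self):
        with pytest.raises(DomainError):
            lk.macro_rates(-0.1, 0.0, 0.0)


class TestImpulseResponse:
    def test_initial_value_is_k1(self, hcc_params):
        h0 = lk.impulse_response(hcc_params, np.array([0.0]))[0]
        assert h0 == pytest.approx(hcc_params.k1, rel=1e-12)

    def test_one_compartment_limit(self):
        p = lk.KineticParams(0.8, 1.5, 0.0, 0.0, 0.5, 0.0)
        t = np.linspace(0, 3, 20)
        assert np.allclose(
            lk.impulse_response(p, t), 0.8 * np.exp(-1.5 * t), rtol=1e-12
        )

    def test_against_matrix_exponential_oracle(self, hcc_params):
        """Impulse response equals the matrix-exponential solution of the
        two-tissue ODE system started from a K1-sized bolus in C_E."""
        p = hcc_params
        M = np.array([[-(p.k2 + p.k3), p.k4], [p.k3, -p.k4]])
        for t in (0.25, 1.0, 4.0):
            state = expm(M * t) @ np.array([p.k1, 0.0])
            assert lk.impulse_response(p, np.array([t]))[0] == pytest.approx(
                state.sum(), rel=1e-10
            )

    def test_repeated_root_branch_continuous(self):
        # k3 = (sqrt(k2) - sqrt(k4))^2 makes the discriminant vanish
        k2, k4 = 1.0, 0.25
        k3 = (np.sqrt(k2) - np.sqrt(k4)) ** 2
        p_rep = lk.KineticParams(1.0, k2, k3, k4, 0.5, 0.0)
        p_near = lk.KineticParams(1.0, k2, k3 + 1e-9, k4, 0.5, 0.0)
        t = np.linspace(0, 5, 30)
        assert np.allclose(
            lk.impulse_response(p_rep, t), lk.impulse_response(p_near, t), rtol=1e-5
        )


def _ode_tissue(p, cb, t_s, rtol=1e-9):
    """Independent tissue-curve oracle by direct ODE integration."""
    def rhs(tm, y):
        c = float(cb(np.array([tm * 60.0]))[0])
        return [
            p.k1 * c - (p.k2 + p.k3) * y[0] + p.k4 * y[1],
            p.k3 * y[0] - p.k4 * y[1],
        ]

    sol = solve_ivp(
        rhs, (0.0, t_s[-1] / 60.0), [0.0, 0.0], t_eval=t_s / 60.0,
        rtol=rtol, atol=1e-12, max_step=1.0 / 60.0,
    )
    ci = sol.y[0] + sol.y[1]
    return (1.0 - p.vb) * ci + p.vb * np.asarray(cb(t_s), dtype=float)


class TestTissueCurve:
    def test_blood_only_voxel(self):
        p = lk.KineticParams(0.0, 1.0, 0.0, 0.0, 0.5, 1.0)
        cb = lambda t: np.where(np.asarray(t, float) >= 0, 5.0, 0.0)
        t = np.arange(0.0, 61.0, 1.0)
        assert np.allclose(lk.tissue_curve(p, cb, t), 5.0)

    def test_no_uptake_leaves_blood_fraction(self):
        p = lk.KineticParams(0.0, 1.0, 0.0, 0.0, 0.5, 0.1)
        cb = lambda t: np.where(np.asarray(t, float) >= 0, 5.0, 0.0)
        t = np.arange(0.0, 61.0, 1.0)
        assert np.allclose(lk.tissue_curve(p, cb, t), 0.5)

    def test_exponential_input_closed_form_convolution(self):
        """h conv e^(-beta t) has the closed form
        sum_i c_i (e^(-beta t) - e^(-T_i t)) / (T_i - beta)."""
        p = lk.KineticParams(1.2, 1.5, 0.08, 0.03, 0.5, 0.0)
        beta = 0.7  # 1/min, distinct from both macro rates
        mr = lk.macro_rates(p.k2, p.k3, p.k4)
        c1 = p.k1 * (p.k3 + p.k4 - mr.t1) / (mr.t2 - mr.t1)
        c2 = p.k1 * (mr.t2 - (p.k3 + p.k4)) / (mr.t2 - mr.t1)
        t = np.arange(0.0, 301.0, 0.5)
        tm = t / 60.0
        expected = c1 * (np.exp(-beta * tm) - np.exp(-mr.t1 * tm)) / (mr.t1 - beta) \
            + c2 * (np.exp(-beta * tm) - np.exp(-mr.t2 * tm)) / (mr.t2 - beta)
        cb = lambda ts: np.where(
            np.asarray(ts, float) >= 0, np.exp(-beta * np.asarray(ts, float) / 60.0), 0.0
        )
        got = lk.tissue_curve(p, cb, t)
        assert np.max(np.abs(got - expected)) / np.max(expected) < 1e-3

    def test_matches_ode_oracle_on_random_draws(self, arterial, portal):
        """Ten random parameter draws; the dedicated acceptance test runs
        one hundred over the full short-term grid."""
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 301.0, 0.5)
        for _ in range(10):
            p = lk.KineticParams(
                k1=rng.uniform(0.2, 2.5), k2=rng.uniform(0.3, 2.5),
                k3=rng.uniform(0.0, 0.2), k4=rng.uniform(0.0, 0.1),
                hpi=rng.uniform(0.05, 0.95), vb=rng.uniform(0.0, 0.3),
            )
            cb = lk.dual_input_curve(arterial, portal, p.hpi)
            got = lk.tissue_curve(p, cb, t, check_causal=False)
            want = _ode_tissue(p, cb, t)
            assert np.max(np.abs(got - want)) / np.max(want) < 1e-3

    def test_pointwise_monotone_in_k1(self, arterial, portal):
        t = np.arange(0.0, 301.0, 1.0)
        cb = lk.dual_input_curve(arterial, portal, 0.6)
        lo = lk.tissue_curve(
            lk.KineticParams(0.5, 1.0, 0.05, 0.01, 0.6, 0.05), cb, t, check_causal=False
        )
        hi = lk.tissue_curve(
            lk.KineticParams(1.5, 1.0, 0.05, 0.01, 0.6, 0.05), cb, t, check_causal=False
        )
        assert np.all(hi >= lo - 1e-12)

    def test_steady_state_with_constant_input(self):
        # k3 = k4 = 0, constant input c: C_I -> K1*c/k2
        p = lk.KineticParams(0.9, 1.0, 0.0, 0.0, 0.5, 0.0)
        c = 2.0
        cb = lambda t: np.where(np.asarray(t, float) >= 0, c, 0.0)
        t_end = 20.0 / p.k2 * 60.0  # 20 time constants, in seconds
        t = np.arange(0.0, t_end + 1.0, 1.0)
        ct = lk.tissue_curve(p, cb, t)
        assert ct[-1] == pytest.approx(p.k1 * c / p.k2, rel=1e-4)

    def test_non_causal_input_rejected(self):
        p = lk.KineticParams(1.0, 1.0, 0.0, 0.0, 0.5, 0.0)
        t = np.arange(0.0, 61.0, 1.0)
        with pytest.raises(DomainError):
            lk.tissue_curve(p, lambda ts: np.ones_like(np.asarray(ts, float)), t)

    def test_coarse_grid_warns(self):
        p = lk.KineticParams(1.0, 1.0, 0.0, 0.0, 0.5, 0.0)
        cb = lambda t: np.where(np.asarray(t, float) >= 0, 1.0, 0.0)
        with pytest.warns(UserWarning, match="grid step"):
            lk.tissue_curve(p, cb, np.arange(0.0, 61.0, 2.0))
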