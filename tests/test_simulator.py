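"""Integration correctness: closed forms, reduction, superposition, resets."""

from dataclasses import replace

import numpy as np
import pytest

from eomvisc.base_models import (
    DEFAULT_TAUS,
    BaseModelParams,
    LengthTension,
    RelaxationSpectrum,
)
from eomvisc.attenuation import AttenuationParams
from eomvisc.protocols import (
    ElongationProtocol,
    concatenate,
    make_ramp,
    make_saccadic,
    make_step,
)
from eomvisc.simulator import simulate, steady_state_force

G = (0.30, 0.25, 0.20, 0.15, 0.12, 0.10, 0.08)


def dyn(res, lt):
    return res.F_total - lt.force(res.L)


class TestEquilibrium:
    def test_constant_length_yields_static_force(self, qlv_synth):
        p = make_ramp(1.0, 0.0, start_length=3.0, hold_duration=2.0)
        res = simulate(qlv_synth, None, p)
        np.testing.assert_allclose(res.F_total,
                                   qlv_synth.lt.force(3.0) * np.ones(p.n),
                                   atol=1e-12)

    def test_relaxation_converges_to_length_tension(self, linear_qlv):
        # short tau ladder so ten times the slowest constant stays cheap
        taus = tuple(t / 16 for t in DEFAULT_TAUS)
        params = replace(linear_qlv,
                         spectrum=RelaxationSpectrum(tau=taus, g=G, alpha=1.0))
        p = make_step(0.5, hold_duration=10 * taus[-1])
        res = simulate(params, None, p)
        peak_dyn = np.max(np.abs(dyn(res, params.lt)))
        final_err = abs(res.F_total[-1] - params.lt.force(res.L[-1]))
        assert final_err < 0.01 * peak_dyn
        assert steady_state_force(params, 0.5) == pytest.approx(
            float(params.lt.force(0.5)))

    def test_steady_state_monotone_in_length(self, qlv_synth):
        L = np.linspace(0, 8, 50)
        F = steady_state_force(qlv_synth, L)
        assert np.all(np.diff(F) > 0)


class TestClosedForms:
    def test_step_response_matches_exponential_sum(self, linear_qlv):
        """Fast rise (1 ms << min tau): post-step decay is sum of exponentials."""
        T = 1e-3
        p = make_step(0.5, rise_time=T, hold_duration=5.0, dt=1e-4)
        res = simulate(linear_qlv, None, p)
        k0 = res.index_at(2 * T)  # one rise-time after the end of the rise
        tt = res.t[k0:]
        d = dyn(res, linear_qlv.lt)[k0:]
        c1 = linear_qlv.lt.c1
        pred = sum(g * c1 * 0.5 * np.exp(-(tt - T / 2) / tau)
                   for g, tau in zip(G, DEFAULT_TAUS))
        assert np.max(np.abs(d - pred) / np.abs(pred)) < 5e-3

    def test_ramp_response_matches_closed_form(self, linear_qlv):
        """Constant drive: F_dyn(t) = sum g_i c1 v tau_i (1 - exp(-t/tau_i))."""
        p = make_ramp(10.0, 4.0, hold_duration=1.0)
        res = simulate(linear_qlv, None, p)
        ke = res.index_at(p.elongation_end())
        v = p.v[0]
        tt = res.t[1:ke]
        d = dyn(res, linear_qlv.lt)[1:ke]
        pred = sum(g * linear_qlv.lt.c1 * v * tau * (1 - np.exp(-tt / tau))
                   for g, tau in zip(G, DEFAULT_TAUS))
        assert np.max(np.abs(d - pred) / np.abs(pred)) < 5e-3

    def test_grid_refinement_convergence(self, fx_qlv_m4lr):
        """Halving dt moves the force by < 0.1% sup-norm (fastest protocol)."""
        p = make_saccadic(4.0, 160.0, hold_duration=2.0)
        for atten in (None, fx_qlv_m4lr.atten):
            coarse = simulate(fx_qlv_m4lr.base, atten, p)
            fine = simulate(fx_qlv_m4lr.base, atten, p, dt=p.dt / 2)
            rel = (np.abs(fine.F_total[::2] - coarse.F_total).max()
                   / np.abs(coarse.F_total).max())
            assert rel < 1e-3


class TestReduction:
    def test_kd_zero_is_bit_identical_to_base(self, fx_qlv_m4lr):
        inert = replace(fx_qlv_m4lr.atten, k_d=0.0)
        p = make_saccadic(3.0, 130.0, hold_duration=3.0)
        base = simulate(fx_qlv_m4lr.base, None, p)
        anlv = simulate(fx_qlv_m4lr.base, inert, p)
        np.testing.assert_array_equal(base.F_total, anlv.F_total)

    def test_decomposition_identity(self, fx_aqlv_m4lr):
        p = make_ramp(80.0, 8.0, hold_duration=2.0)
        res = simulate(fx_aqlv_m4lr.base, fx_aqlv_m4lr.atten, p)
        rebuilt = (res.F_elastic + (res.beta * res.F_processes).sum(axis=0)
                   + res.F_viscous)
        assert np.max(np.abs(rebuilt - res.F_total)) < 1e-10

    def test_base_run_reports_unit_gains(self, qlv_synth):
        p = make_step(0.5, hold_duration=0.5)
        res = simulate(qlv_synth, None, p)
        assert np.all(res.beta == 1.0)
        assert np.ptp(res.lam) == 0.0


class TestSuperposition:
    """Linear-limit double-step behaviour: the structural failure the
    attenuation was designed to produce."""

    @staticmethod
    def _double_and_singles(linear_qlv, isi, atten=None, rise=20e-3):
        dt = 1e-3
        step0 = make_step(0.5, rise_time=rise, hold_duration=0.0, dt=dt)
        step1 = make_step(0.5, rise_time=rise, hold_duration=4.0, dt=dt)
        double = concatenate([step0, step1], isi=isi)
        total = double.t[-1]
        single = make_step(0.5, rise_time=rise, hold_duration=total - rise, dt=dt)
        r_double = simulate(linear_qlv, atten, double)
        r_single = simulate(linear_qlv, None, single)
        return r_double, r_single, step0.t[-1] + isi

    def test_base_model_superposes(self, linear_qlv):
        r_double, r_single, t2 = self._double_and_singles(linear_qlv, isi=1.0)
        d_double = dyn(r_double, linear_qlv.lt)
        d_single = dyn(r_single, linear_qlv.lt)
        k2 = r_double.index_at(t2)
        expected = d_single[:r_double.t.size].copy()
        expected[k2:] += d_single[:r_double.t.size - k2]
        assert np.max(np.abs(d_double - expected)) < 1e-8

    @pytest.mark.parametrize("isi", [0.01, 0.1, 1.0])
    def test_anlv_violates_superposition(self, linear_qlv, fx_qlv_m4lr, isi):
        atten = fx_qlv_m4lr.atten
        r_double, r_single, t2 = self._double_and_singles(
            linear_qlv, isi=isi, atten=atten, rise=5e-3)
        d_double = dyn(r_double, linear_qlv.lt)
        d_single = dyn(r_single, linear_qlv.lt)
        k2 = r_double.index_at(t2)
        expected = d_single[:r_double.t.size].copy()
        expected[k2:] += d_single[:r_double.t.size - k2]
        dev = np.max(np.abs(d_double - expected))
        assert dev > 0.01 * np.max(np.abs(expected))

    def test_reset_restores_base_behaviour(self, linear_qlv, fx_qlv_m4lr):
        """With a 20 ms rise the 0.5 mm step stays in the unattenuated
        regime (lambda never crosses 1), so the ANLV double-step with a
        reset equals the base model bit for bit, and the second step obeys
        linear superposition against an independent single-step run."""
        atten = fx_qlv_m4lr.atten
        dt = 1e-3
        step0 = make_step(0.5, rise_time=20e-3, hold_duration=0.0, dt=dt)
        step1 = make_step(0.5, rise_time=20e-3, hold_duration=4.0, dt=dt)
        double = concatenate([step0, step1], isi=45.0, reset_before_second=True)
        r_anlv = simulate(linear_qlv, atten, double)
        assert r_anlv.lam.min() >= 1.0  # scenario precondition
        r_base = simulate(linear_qlv, None, double)
        np.testing.assert_array_equal(r_anlv.F_total, r_base.F_total)
        # second step superposes on the tail of the first
        single = make_step(0.5, rise_time=20e-3, hold_duration=50.0, dt=dt)
        r_single = simulate(linear_qlv, None, single)
        t2 = step0.t[-1] + 45.0
        k2 = r_anlv.index_at(t2)
        d_double = dyn(r_anlv, linear_qlv.lt)
        d_single = dyn(r_single, linear_qlv.lt)
        expected = d_single[:r_anlv.t.size].copy()
        expected[k2:] += d_single[:r_anlv.t.size - k2]
        assert np.max(np.abs(d_double - expected)) < 1e-8


class TestGuards:
    def test_inconsistent_protocol_refused(self, qlv_synth):
        p = make_ramp(10.0, 4.0, hold_duration=0.5)
        bad = ElongationProtocol(t=p.t, L=p.L, v=p.v * 1.01,
                                 phase_marks=p.phase_marks)
        with pytest.raises(ValueError, match="inconsistent"):
            simulate(qlv_synth, None, bad)
        simulate(qlv_synth, None, bad, check_consistency=False)  # opt-out works

    def test_bad_dt_rejected(self, qlv_synth):
        p = make_step(0.5, hold_duration=0.1)
        with pytest.raises(ValueError, match="divide"):
            simulate(qlv_synth, None, p, dt=p.dt / 2.5)

    def test_initial_states_chain_simulations(self, linear_qlv):
        p1 = make_step(0.5, hold_duration=1.0)
        r1 = simulate(linear_qlv, None, p1)
        # continue from the end states on a pure hold at the final length
        hold = make_ramp(1.0, 0.0, start_length=float(r1.L[-1]),
                         hold_duration=1.0)
        r2 = simulate(linear_qlv, None, hold,
                      initial_states=r1.F_processes[:, -1])
        joint = concatenate([p1, make_step(0.0, hold_duration=1.0)])
        r_joint = simulate(linear_qlv, None, joint)
        k = r1.t.size - 1
        np.testing.assert_allclose(r_joint.F_total[k:k + r2.t.size],
                                   r2.F_total, atol=1e-9)
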