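"""Time-domain integration of the QLV / AQLV / ANLV models along a protocol.

The seven relaxation processes form a linear state space driven by the
elongation rate: with drive ``u_i(t)`` (stiffness gain times v), process
``i`` obeys ``dx_i/dt = -x_i / tau_i + u_i``, integrated with the exact
exponential update for drive held constant over each step::

    x_i  <-  x_i * exp(-dt/tau_i) + u_i * tau_i * (1 - exp(-dt/tau_i))

where ``u_i`` is the trapezoidal average of the drive over the step
(second-order accurate for smooth elongations, exact for piecewise-constant
drive).

Because the attenuation gains ``beta_i`` act on the process *outputs* (they
scale stiffness and viscosity together, leaving tau_i untouched), the
process states never depend on lambda; they are computed in one vectorised
pass (an IIR filter per process).  Only the scalar lambda recursion is
sequential, since its breakdown rate depends on the total force.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .attenuation import AttenuationParams
from .base_models import BaseModelParams, N_PROCESSES
from .protocols import ElongationProtocol, validate_consistency

__all__ = ["SimulationResult", "simulate", "steady_state_force"]


@dataclass(frozen=True)
class SimulationResult:
    """Force trace with full decomposition and internal-state traces.

    The identity ``F_total = F_elastic + sum_i beta_i * F_processes_i +
    F_viscous`` holds exactly at every sample (it is how F_total is
    assembled).  For base-model runs ``beta`` is identically 1 and ``lam``
    constant.
    """

    t: np.ndarray
    L: np.ndarray
    v: np.ndarray
    F_total: np.ndarray
    F_elastic: np.ndarray
    F_processes: np.ndarray  # shape (7, n): per-process forces before the gain
    beta: np.ndarray         # shape (7, n): per-process gain traces
    F_viscous: np.ndarray
    lam: np.ndarray
    protocol: ElongationProtocol = field(repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def elongation_end(self) -> float:
        return self.protocol.elongation_end()

    def index_at(self, time: float) -> int:
        if time < self.t[0] - 1e-12 or time > self.t[-1] + 1e-12:
            raise ValueError(f"time {time} outside record")
        return int(round((time - self.t[0]) / self.dt))

    def to_frame(self):
        """Tabular view matching the trace CSV schema."""
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.t,
            "length_mm": self.L,
            "velocity_mm_s": self.v,
            "force_gf": self.F_total,
            "f_elastic_gf": self.F_elastic,
            "f_visco_gf": (self.beta * self.F_processes).sum(axis=0),
            "f_viscous_gf": self.F_viscous,
            "lambda": self.lam,
        })


def _refine(protocol: ElongationProtocol, m: int) -> ElongationProtocol:
    """Linearly interpolate the protocol onto a grid m times finer."""
    n_fine = (protocol.n - 1) * m + 1
    t = protocol.t[0] + np.arange(n_fine) * (protocol.dt / m)
    L = np.interp(t, protocol.t, protocol.L)
    v = np.interp(t, protocol.t, protocol.v)
    return replace(protocol, t=t, L=L, v=v)


def _process_states(taus, drive: np.ndarray, dt: float, x0=None) -> np.ndarray:
    """Exact-exponential integration of all process states, vectorised.

    ``drive`` has shape (7, n).  Returns states of the same shape, with
    ``x[:, 0] = x0`` (default zero: muscle equilibrated at start length).
    """
    n = drive.shape[1]
    x = np.empty_like(drive)
    for i, tau in enumerate(taus):
        a = np.exp(-dt / tau)
        b = tau * (1.0 - a)
        # x[k] = a * x[k-1] + b * drive[k-1]
        x[i] = lfilter([0.0, b], [1.0, -a], drive[i])
        if x0 is not None and x0[i] != 0.0:
            x[i] += x0[i] * a ** np.arange(n)
    return x


try:  # optional JIT of the sequential recursion; pure-Python fallback below
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _njit = None


def _lambda_kernel_py(v, dt, S1, S2, E, lam0, kd, ne, kf, reset_mask, lam_init):
    n = v.size
    lam = np.empty(n)
    cur = lam_init
    for k in range(n):
        if reset_mask[k]:
            cur = lam0
        lam[k] = cur
        if k == n - 1:
            break
        vk = v[k]
        if vk > 0.0 and kd > 0.0:
            le = cur if cur < 1.0 else 1.0
            F = E[k] + S1[k] + le * S2[k]
            if F < 0.0:
                F = 0.0
            cur *= np.exp(-kd * vk ** ne * dt / (1.0 + kf * F))
    return lam


_lambda_kernel = (_njit(cache=True)(_lambda_kernel_py)
                  if _njit is not None else _lambda_kernel_py)


def _lambda_trace(atten: AttenuationParams, v, dt, S1, S2, E, reset_idx,
                  lam_init: float) -> np.ndarray:
    """Sequential lambda recursion; returns the lambda trace.

    The total force needed by the force modulation is reconstructed from the
    split sums ``S1 = sum_i (1 - gamma_i) x_i`` and ``S2 = sum_i gamma_i x_i``
    so the inner loop stays scalar.  The default (rational) force modulation
    runs through a compiled kernel when numba is present; other modulation
    strategies use the generic Python loop.
    """
    import math

    n = v.size
    reset_mask = np.zeros(n, dtype=np.bool_)
    for i in reset_idx:
        reset_mask[int(i)] = True
    if atten.force_modulation == "rational":
        return _lambda_kernel(np.ascontiguousarray(v, dtype=np.float64), dt,
                              S1, S2, E, atten.lambda0, atten.k_d, atten.n,
                              atten.k_f, reset_mask, lam_init)
    lam = np.empty(n)
    cur = lam_init
    kd, ne = atten.k_d, atten.n
    mod = atten.modulation
    for k in range(n):
        if reset_mask[k]:
            cur = atten.lambda0
        lam[k] = cur
        if k == n - 1:
            break
        vk = v[k]
        if vk > 0.0 and kd > 0.0:
            le = cur if cur < 1.0 else 1.0
            F = E[k] + S1[k] + le * S2[k]
            cur *= math.exp(-kd * vk ** ne * mod(F) * dt)
    return lam


def simulate(params: BaseModelParams, atten: AttenuationParams | None,
             protocol: ElongationProtocol, dt: float | None = None,
             initial_states=None, initial_lambda: float | None = None,
             check_consistency: bool = True) -> SimulationResult:
    """Integrate the model along a protocol.

    Parameters
    ----------
    params : BaseModelParams
        QLV or AQLV base model.
    atten : AttenuationParams or None
        ANLV attenuation block; ``None`` runs the pure base model.
    dt : float, optional
        Integration step; must equal the protocol's dt or divide it evenly
        (the protocol is then linearly interpolated onto the finer grid).
    initial_states : array of 7 floats, optional
        Initial process states, gf (default zero: equilibrated muscle).
    initial_lambda : float, optional
        Starting lambda (default ``atten.lambda0``); lets simulations chain.
    check_consistency : bool
        Refuse protocols whose velocity integral disagrees with the length
        trace (such mismatches create artifactual relaxation cross-overs).
    """
    if check_consistency:
        report = validate_consistency(protocol)
        if not report.passed:
            raise ValueError(
                "inconsistent protocol: integral of v deviates from length "
                f"change by {report.max_rel_discrepancy:.2%} "
                f"(tolerance {report.rel_tol:.2%}); rescale the velocity or "
                "pass check_consistency=False")
    if dt is not None and abs(dt - protocol.dt) > 1e-12:
        ratio = protocol.dt / dt
        m = int(round(ratio))
        if m < 1 or abs(ratio - m) > 1e-9:
            raise ValueError(f"dt={dt} must equal or evenly divide protocol dt={protocol.dt}")
        protocol = _refine(protocol, m)

    t, L, v = protocol.t, protocol.L, protocol.v
    h = protocol.dt
    n = t.size

    drive = params.drive_gains(L) * v           # (7, n)
    # trapezoidal drive: average over each step (second order for smooth v,
    # exact for piecewise-constant drive)
    dmid = drive.copy()
    dmid[:, :-1] = 0.5 * (drive[:, :-1] + drive[:, 1:])
    x = _process_states(params.taus, dmid, h, initial_states)
    F_el = np.asarray(params.lt.force(L), float)
    F_visc = (params.viscosity.eta(L) * v if params.viscous_enabled
              else np.zeros(n))

    reset_idx = [protocol.index_at(r) for r in protocol.reset_marks]

    if atten is None or atten.k_d == 0.0:
        lam0 = atten.lambda0 if atten is not None else 1.0
        lam = np.full(n, lam0)
        beta = np.ones((N_PROCESSES, n))
    else:
        gamma = np.asarray(atten.gamma)
        S1 = ((1.0 - gamma)[:, None] * x).sum(axis=0)
        S2 = (gamma[:, None] * x).sum(axis=0)
        lam_init = atten.lambda0 if initial_lambda is None else initial_lambda
        vmid = v.copy()
        vmid[:-1] = 0.5 * (v[:-1] + v[1:])  # midpoint rate over each step
        lam = _lambda_trace(atten, vmid, h, S1, S2, F_el + F_visc, reset_idx,
                            lam_init)
        lam_eff = np.minimum(lam, 1.0)
        beta = 1.0 - gamma[:, None] * (1.0 - lam_eff)

    F_total = F_el + (beta * x).sum(axis=0) + F_visc
    meta = {
        "kind": params.kind if atten is None else f"anlv({params.kind})",
        "dt": h,
        "n": n,
        "attenuated": atten is not None,
    }
    return SimulationResult(t=t, L=L, v=v, F_total=F_total, F_elastic=F_el,
                            F_processes=x, beta=beta, F_viscous=F_visc,
                            lam=lam, protocol=protocol, meta=meta)


def steady_state_force(params: BaseModelParams, L):
    """Equilibrium force at a held length: the static length-tension value."""
    return params.lt.force(L)
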