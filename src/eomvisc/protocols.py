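"""Elongation protocol generators.

A protocol is a uniformly sampled trajectory of imposed muscle elongation
``L(t)`` (mm, relative to the shortest length tested) and elongation rate
``v(t)`` (mm/s).  Only lengthening is modelled, so ``v >= 0`` everywhere.

All generators construct ``v`` first, rescale it so that its trapezoidal
integral equals the commanded amplitude exactly, and then obtain ``L`` as the
cumulative trapezoidal integral of ``v``.  Length and velocity are therefore
mutually consistent by construction; ``validate_consistency`` checks the same
property on arbitrary (e.g. file-loaded) trajectories, where small
length/velocity mismatches are known to corrupt relaxation ordering
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "ElongationProtocol",
    "ConsistencyReport",
    "make_step",
    "make_saccadic",
    "make_ramp",
    "concatenate",
    "validate_consistency",
]

#: phase labels carried by :class:`ElongationProtocol`
PHASE_ELONGATION = "elongation"
PHASE_HOLD = "hold"
PHASE_ISI = "isi"

_DT_DEFAULT = 1e-3  # s; resolves the fastest (50 ms) ramp with >= 50 samples


@dataclass(frozen=True)
class ElongationProtocol:
    """Sampled elongation trajectory with phase annotations.

    Attributes
    ----------
    t : ndarray
        Time grid, seconds, uniform spacing.
    L : ndarray
        Elongation, mm, relative to the slack reference length; includes
        ``start_length``.
    v : ndarray
        Elongation rate, mm/s, non-negative.
    phase_marks : list of (start, end, label)
        Annotated phases; labels are ``elongation``, ``hold`` or ``isi``.
    reset_marks : tuple of float
        Times at which the attenuation state is to be reset to lambda_0.
    """

    t: np.ndarray
    L: np.ndarray
    v: np.ndarray
    phase_marks: tuple = ()
    reset_marks: tuple = ()

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        L = np.asarray(self.L, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if not (t.shape == L.shape == v.shape) or t.ndim != 1 or t.size < 2:
            raise ValueError("t, L, v must be 1-d arrays of equal length >= 2")
        dts = np.diff(t)
        if np.any(dts <= 0) or np.ptp(dts) > 1e-12:
            raise ValueError("time grid must be strictly increasing with uniform dt")
        if np.any(v < 0):
            raise ValueError("negative elongation rate: only lengthening is modelled")
        for start, end, label in self.phase_marks:
            if not (t[0] - 1e-12 <= start <= end <= t[-1] + 1e-12):
                raise ValueError(f"phase mark ({start}, {end}, {label}) outside record")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "phase_marks", tuple(self.phase_marks))
        object.__setattr__(self, "reset_marks", tuple(self.reset_marks))

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return int(self.t.size)

    def elongation_phases(self) -> list[tuple[float, float]]:
        """(start, end) of every elongation phase, in time order."""
        return [(s, e) for s, e, lab in self.phase_marks if lab == PHASE_ELONGATION]

    def elongation_end(self) -> float:
        """End time of the last elongation phase."""
        phases = self.elongation_phases()
        if not phases:
            raise ValueError("protocol has no elongation phase")
        return phases[-1][1]

    def index_at(self, time: float) -> int:
        """Index of the grid sample nearest to ``time``."""
        if time < self.t[0] - 1e-12 or time > self.t[-1] + 1e-12:
            raise ValueError(f"time {time} outside record [{self.t[0]}, {self.t[-1]}]")
        return int(round((time - self.t[0]) / self.dt))


@dataclass(frozen=True)
class ConsistencyReport:
    """Outcome of the length/velocity consistency check."""

    max_rel_discrepancy: float
    rel_tol: float
    passed: bool
    rescaled: ElongationProtocol | None = field(default=None, repr=False)


def _grid(duration: float, dt: float) -> np.ndarray:
    n = int(round(duration / dt))
    return np.arange(n + 1) * dt


def _assemble(v: np.ndarray, dt: float, amplitude: float, start_length: float,
              elong_end: float, phase_marks) -> ElongationProtocol:
    """Rescale v to integrate exactly to ``amplitude`` and integrate it to L."""
    t = np.arange(v.size) * dt
    integral = float(np.trapezoid(v, dx=dt))
    if amplitude > 0.0:
        if integral <= 0.0:
            raise ValueError("velocity waveform integrates to zero; cannot rescale")
        v = v * (amplitude / integral)
    L = start_length + cumulative_trapezoid(v, dx=dt, initial=0.0)
    return ElongationProtocol(t=t, L=L, v=v, phase_marks=tuple(phase_marks))


def make_step(amplitude: float, rise_time: float = 5e-3, hold_duration: float = 10.0,
              start_length: float = 0.0, dt: float = _DT_DEFAULT) -> ElongationProtocol:
    """Quick step-wise elongation: half-sinusoid velocity rise, then hold.

    Parameters
    ----------
    amplitude : float
        Step size, mm (0.5 mm in the experimental battery).
    rise_time : float
        Duration of the rise, s.  Must satisfy ``dt <= rise_time / 4``.
    hold_duration : float
        Constant-length period after the rise, s.
    """
    if dt <= 0 or rise_time <= 0:
        raise ValueError("dt and rise_time must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if dt > rise_time / 4 + 1e-15:
        raise ValueError(f"dt={dt} too coarse for rise_time={rise_time}: need dt <= rise_time/4")
    t = _grid(rise_time + hold_duration, dt)
    v = np.zeros_like(t)
    if amplitude > 0:
        peak = np.pi * amplitude / (2.0 * rise_time)
        rising = t <= rise_time + 1e-15
        v[rising] = peak * np.sin(np.pi * t[rising] / rise_time)
        v = np.clip(v, 0.0, None)
    marks = [(0.0, rise_time, PHASE_ELONGATION), (rise_time, t[-1], PHASE_HOLD)]
    return _assemble(v, dt, amplitude, start_length, rise_time, marks)


def make_saccadic(amplitude: float, peak_speed: float, start_length: float = 0.0,
                  hold_duration: float = 10.0, dt: float = _DT_DEFAULT) -> ElongationProtocol:
    """Saccade-like elongation: half-sinusoid velocity profile.

    ``v(t) = peak_speed * sin(pi t / T)`` on ``[0, T]`` with
    ``T = pi * amplitude / (2 * peak_speed)`` so that the integral of v is
    the commanded amplitude.
    """
    if amplitude <= 0 or peak_speed <= 0:
        raise ValueError("amplitude and peak_speed must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    T = np.pi * amplitude / (2.0 * peak_speed)
    if T < 4 * dt:
        raise ValueError(
            f"saccadic duration T={T:.4g}s under-resolved at dt={dt}: need T >= 4 dt")
    # snap elongation end to the grid
    T_grid = round(T / dt) * dt
    t = _grid(T_grid + hold_duration, dt)
    v = np.zeros_like(t)
    rising = t <= T
    v[rising] = peak_speed * np.sin(np.pi * t[rising] / T)
    v = np.clip(v, 0.0, None)
    marks = [(0.0, T_grid, PHASE_ELONGATION), (T_grid, t[-1], PHASE_HOLD)]
    return _assemble(v, dt, amplitude, start_length, T_grid, marks)


def make_ramp(speed: float, total_range: float, start_length: float = 0.0,
              hold_duration: float = 10.0, dt: float = _DT_DEFAULT) -> ElongationProtocol:
    """Constant-speed stretch over ``total_range`` mm, then hold.

    The elongation phase lasts ``total_range / speed`` seconds (80 s at
    0.1 mm/s over 8 mm; 50 ms at 160 mm/s).
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if total_range < 0:
        raise ValueError("total_range must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if total_range == 0.0:
        t = _grid(max(hold_duration, dt), dt)
        L = np.full_like(t, start_length)
        v = np.zeros_like(t)
        return ElongationProtocol(t=t, L=L, v=v,
                                  phase_marks=((0.0, t[-1], PHASE_HOLD),))
    T = total_range / speed
    T_grid = max(round(T / dt), 1) * dt
    t = _grid(T_grid + hold_duration, dt)
    v = np.where(t <= T_grid + 1e-15, speed, 0.0)
    marks = [(0.0, T_grid, PHASE_ELONGATION), (T_grid, t[-1], PHASE_HOLD)]
    return _assemble(v, dt, total_range, start_length, T_grid, marks)


def concatenate(protocols, isi: float = 0.0,
                reset_before_second: bool = False) -> ElongationProtocol:
    """Join protocols with an ``isi``-long hold between consecutive items.

    The length trace is continuous: each subsequent protocol is re-based so
    that it starts at the end length of the previous one.  If
    ``reset_before_second`` is set, a reset mark is placed at the onset of
    every protocol after the first (the attenuation state is restored to
    lambda_0 there, mimicking a long recovery).
    """
    protocols = list(protocols)
    if not protocols:
        raise ValueError("need at least one protocol")
    if isi < 0:
        raise ValueError("isi must be non-negative")
    dt = protocols[0].dt
    for p in protocols[1:]:
        if abs(p.dt - dt) > 1e-12:
            raise ValueError("protocols must share the same dt")
    if len(protocols) == 1 and isi == 0.0:
        return protocols[0]

    n_gap = int(round(isi / dt))
    t_parts, L_parts, v_parts = [], [], []
    marks, resets = [], []
    t_off = 0.0
    L_end = None
    for j, p in enumerate(protocols):
        if j > 0:
            if n_gap > 0:
                gap_t = t_off + np.arange(1, n_gap + 1) * dt
                t_parts.append(gap_t)
                L_parts.append(np.full(n_gap, L_end))
                v_parts.append(np.zeros(n_gap))
                marks.append((t_off, t_off + n_gap * dt, PHASE_ISI))
                t_off = t_off + n_gap * dt
            if reset_before_second:
                resets.append(t_off)
        base = p.L[0] if j == 0 else p.L[0] - L_end
        sl = slice(None) if j == 0 else slice(1, None)
        t_parts.append(p.t[sl] + t_off)
        L_parts.append(p.L[sl] - (0.0 if j == 0 else base))
        v_parts.append(p.v[sl])
        marks.extend((s + t_off, e + t_off, lab) for s, e, lab in p.phase_marks)
        resets.extend(r + t_off for r in p.reset_marks)
        L_end = L_parts[-1][-1]
        t_off = t_parts[-1][-1]
    return ElongationProtocol(
        t=np.concatenate(t_parts), L=np.concatenate(L_parts), v=np.concatenate(v_parts),
        phase_marks=tuple(marks), reset_marks=tuple(resets))


def validate_consistency(p: ElongationProtocol, rel_tol: float = 2e-3) -> ConsistencyReport:
    """Check that the trapezoidal integral of v matches L(t) - L(0).

    The maximum discrepancy is taken over the whole record and expressed
    relative to the total elongation range (or to 1 mm for near-constant
    protocols).  The returned report carries a rescaled copy of the protocol
    whose velocity integrates exactly to the measured length change.
    """
    integ = cumulative_trapezoid(p.v, dx=p.dt, initial=0.0)
    dL = p.L - p.L[0]
    scale = max(float(np.max(np.abs(dL))), 1.0)
    max_rel = float(np.max(np.abs(integ - dL)) / scale)

    rescaled = None
    total = float(integ[-1])
    if total > 0 and float(dL[-1]) > 0:
        v_scaled = p.v * (float(dL[-1]) / total)
        L_new = p.L[0] + cumulative_trapezoid(v_scaled, dx=p.dt, initial=0.0)
        rescaled = replace(p, v=v_scaled, L=L_new)
    return ConsistencyReport(max_rel_discrepancy=max_rel, rel_tol=rel_tol,
                             passed=max_rel <= rel_tol, rescaled=rescaled)
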