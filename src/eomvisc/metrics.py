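"""Diagnostic quantities for comparing relaxation behaviour across traces.

These are the measures used to characterise how real muscle departs from
classical viscoelastic predictions:

* **dynamic force** — force minus the static length-tension force at the
  instantaneous length;
* **data/model viscoelastic ratio** — purely viscoelastic force of a
  "data" trace over that of a "model" trace at the end of the elongation
  (ratios below one quantify how much a model overestimates the muscle);
* **cross-over detection** — does the force ranking across a family of
  stretches sharing a final length reverse between the end of the
  elongation and some probe time later?
* **convergence time** — how soon after the elongation the traces of a
  family collapse onto each other.

Traces are aligned on each member's own end-of-elongation time, so families
may mix stretches of very different durations (e.g. constant-speed ramps at
0.1–160 mm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base_models import LengthTension

__all__ = [
    "MeasuredTrace",
    "TraceFamily",
    "CrossoverReport",
    "dynamic_force",
    "viscoelastic_ratio",
    "detect_crossover",
    "convergence_time",
    "NOT_REACHED",
]

#: sentinel returned by convergence_time when the family never converges
NOT_REACHED = float("inf")


@dataclass(frozen=True)
class MeasuredTrace:
    """Minimal force trace: time grid, total force, length, elongation end.

    Adapter type for measured or constructed records; simulation results
    satisfy the same interface natively.
    """

    t: np.ndarray
    F_total: np.ndarray
    L: np.ndarray
    _elong_end: float

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, float))
        object.__setattr__(self, "F_total", np.asarray(self.F_total, float))
        object.__setattr__(self, "L", np.asarray(self.L, float))

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def elongation_end(self) -> float:
        return self._elong_end

    def index_at(self, time: float) -> int:
        if time < self.t[0] - 1e-12 or time > self.t[-1] + 1e-12:
            raise ValueError(f"time {time} outside record")
        return int(round((time - self.t[0]) / self.dt))


@dataclass(frozen=True)
class TraceFamily:
    """Labelled traces sharing a final length, aligned on elongation end."""

    labels: tuple
    traces: tuple
    final_length_rtol: float = 0.01

    def __post_init__(self):
        if len(self.labels) != len(self.traces):
            raise ValueError("labels and traces must pair up")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "traces", tuple(self.traces))
        if len(self.traces) >= 2:
            finals = [float(tr.L[tr.index_at(tr.elongation_end())]) for tr in self.traces]
            spread = max(finals) - min(finals)
            scale = max(abs(max(finals)), 1.0)
            if spread > self.final_length_rtol * scale:
                raise ValueError(
                    f"traces do not share a final length: {finals} "
                    f"(spread {spread:.3g} mm)")
        dts = {round(tr.dt, 12) for tr in self.traces}
        if len(dts) > 1:
            raise ValueError("traces must share the sampling interval")

    def __len__(self) -> int:
        return len(self.traces)

    def aligned_decay(self):
        """Common relaxation-time grid and force matrix.

        Returns ``(s, F)`` where ``s`` is time since each member's own
        elongation end and ``F[j]`` is member ``j``'s force on that grid,
        truncated to the shortest post-elongation record.
        """
        dt = self.traces[0].dt
        chunks = []
        for tr in self.traces:
            k0 = tr.index_at(tr.elongation_end())
            chunks.append(np.asarray(tr.F_total, float)[k0:])
        m = min(len(c) for c in chunks)
        if m < 2:
            raise ValueError("post-elongation record too short to align")
        s = np.arange(m) * dt
        return s, np.vstack([c[:m] for c in chunks])


@dataclass(frozen=True)
class CrossoverReport:
    """Outcome of cross-over detection on a trace family."""

    crossover: bool
    order_at_end: tuple
    order_at_probe: tuple
    t_probe: float
    pair_crossing_times: dict = field(default_factory=dict)


def dynamic_force(trace, lt: LengthTension, at_time: float) -> float:
    """Force above the static length-tension curve at ``at_time``, gf."""
    k = trace.index_at(at_time)
    return float(trace.F_total[k] - lt.force(trace.L[k]))


def viscoelastic_ratio(data_trace, model_trace, lt: LengthTension,
                       floor: float = 1e-6) -> float:
    """Data/model viscoelastic ratio at the end of the elongation.

    Both traces must share the elongation end time and final length.  The
    numerator and denominator are each trace's force at that instant minus
    the static force at the final length; the LT offset and any common
    constant cancel.  A model denominator below ``floor`` (gf) makes the
    ratio meaningless and raises.
    """
    te_d = data_trace.elongation_end()
    te_m = model_trace.elongation_end()
    if abs(te_d - te_m) > data_trace.dt / 2:
        raise ValueError("traces do not share the elongation end time")
    kd_ = data_trace.index_at(te_d)
    km_ = model_trace.index_at(te_m)
    L_end_d = float(data_trace.L[kd_])
    L_end_m = float(model_trace.L[km_])
    if abs(L_end_d - L_end_m) > 0.01 * max(abs(L_end_d), 1.0):
        raise ValueError("traces do not share the final length")
    num = float(data_trace.F_total[kd_] - lt.force(L_end_d))
    den = float(model_trace.F_total[km_] - lt.force(L_end_m))
    if abs(den) < floor:
        raise ZeroDivisionError(
            f"model purely viscoelastic force {den:.3g} gf below floor {floor} gf")
    return num / den


def _ranking(values: np.ndarray) -> tuple:
    """Indices sorted by descending value (ties broken by index)."""
    return tuple(int(i) for i in np.lexsort((np.arange(len(values)), -values)))


def detect_crossover(family: TraceFamily, t_probe: float = 1.0) -> CrossoverReport:
    """Compare force rankings at elongation end vs. ``t_probe`` later.

    Also reports, per pair, the first post-elongation time at which the two
    force traces cross (None if they never do within the record).
    """
    if len(family) < 2:
        raise ValueError("need at least two traces")
    s, F = family.aligned_decay()
    k_probe = min(int(round(t_probe / family.traces[0].dt)), len(s) - 1)
    order_end = _ranking(F[:, 0])
    order_probe = _ranking(F[:, k_probe])
    crossings = {}
    nmem = len(family)
    for a in range(nmem):
        for b in range(a + 1, nmem):
            diff = F[a] - F[b]
            sign0 = np.sign(diff[0])
            if sign0 == 0:
                crossings[(family.labels[a], family.labels[b])] = None
                continue
            flipped = np.nonzero(np.sign(diff) == -sign0)[0]
            crossings[(family.labels[a], family.labels[b])] = (
                float(s[flipped[0]]) if flipped.size else None)
    return CrossoverReport(
        crossover=order_end != order_probe,
        order_at_end=tuple(family.labels[i] for i in order_end),
        order_at_probe=tuple(family.labels[i] for i in order_probe),
        t_probe=float(s[k_probe]),
        pair_crossing_times=crossings)


def convergence_time(family: TraceFamily, tol: float) -> float:
    """First post-elongation time after which all traces stay within ``tol``.

    Returns the smallest ``s`` such that the maximum pairwise force
    difference is below ``tol`` (gf) from ``s`` to the end of the shared
    record; ``NOT_REACHED`` (inf) if no such time exists.
    """
    if len(family) < 2:
        raise ValueError("need at least two traces")
    s, F = family.aligned_decay()
    spread = F.max(axis=0) - F.min(axis=0)
    below = spread < tol
    # last index where the spread is still >= tol
    above_idx = np.nonzero(~below)[0]
    if above_idx.size == 0:
        return 0.0
    k = above_idx[-1] + 1
    if k >= len(s):
        return NOT_REACHED
    return float(s[k])
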