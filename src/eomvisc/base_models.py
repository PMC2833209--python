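"""QLV and AQLV constitutive laws for passive extraocular muscle.

Both models share the same three-term structure::

    F(t) = LT(L)  +  sum_i x_i(t)  +  eta(L) * v

* ``LT`` — static length-tension relationship (4 DOF): the equilibrium
  force when a length is held for a very long time.
* seven first-order relaxation processes with fixed time constants tau_i;
  process ``i`` integrates a drive proportional to the elongation rate with
  leak ``1/tau_i``.  In the QLV model the drive is
  ``alpha * g_i * LT'(L) * v`` (8 DOF: the moduli g_i and the scale alpha);
  in the AQLV model each process has its own length-dependent stiffness
  ``k_i(L)`` sampled at four knots (28 DOF).
* a pure viscous force ``eta(L) * v`` with quadratic ``eta`` (3 DOF).

Totals: 15 DOF (QLV), 35 DOF (AQLV).  The time constants are fixed by
experiment design, not fitted, and default to a geometric ladder reaching
~41 s (slow relaxation processes with time constants of 40 s or more are
present in this tissue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GF_TO_N",
    "DEFAULT_TAUS",
    "N_PROCESSES",
    "LengthTension",
    "RelaxationSpectrum",
    "StiffnessProfile",
    "ViscosityLaw",
    "BaseModelParams",
    "lt_force",
    "lt_slope",
    "process_drive",
    "viscous_force",
    "dof_count",
]

#: gram-force to newton conversion (muscle force is traditionally in gf)
GF_TO_N = 0.0098

#: number of parallel relaxation processes
N_PROCESSES = 7

#: default relaxation time constants, s (geometric ladder, ratio 4)
DEFAULT_TAUS = (0.01, 0.04, 0.16, 0.64, 2.56, 10.24, 40.96)

#: working elongation range, mm (full oculomotor range is ~8 mm)
WORKING_RANGE = (0.0, 8.0)


@dataclass(frozen=True)
class LengthTension:
    """Static length-tension curve ``c0 + c1*L + c2*(exp(c3*L) - 1)``.

    Essentially linear for small elongations (slope c1) with accelerating
    stiffness beyond; monotone non-decreasing over the working range.
    """

    c0: float = 0.0  # offset force at L = 0, gf
    c1: float = 0.0  # linear stiffness, gf/mm
    c2: float = 0.0  # exponential amplitude, gf
    c3: float = 0.0  # exponential rate, 1/mm

    def __post_init__(self):
        if self.c1 < 0:
            raise ValueError("c1 must be non-negative")
        if self.c2 * self.c3 < 0:
            raise ValueError("c2*c3 must be non-negative (monotone length-tension)")

    def force(self, L):
        return self.c0 + self.c1 * np.asarray(L, float) + self.c2 * (
            np.expm1(self.c3 * np.asarray(L, float)))

    def slope(self, L):
        return self.c1 + self.c2 * self.c3 * np.exp(self.c3 * np.asarray(L, float))


@dataclass(frozen=True)
class RelaxationSpectrum:
    """QLV relaxation spectrum: seven (tau_i, g_i) pairs plus the scale alpha."""

    tau: tuple = DEFAULT_TAUS
    g: tuple = (0.0,) * N_PROCESSES
    alpha: float = 1.0

    def __post_init__(self):
        tau = tuple(float(x) for x in self.tau)
        g = tuple(float(x) for x in self.g)
        if len(tau) != N_PROCESSES or len(g) != N_PROCESSES:
            raise ValueError(f"spectrum needs exactly {N_PROCESSES} processes")
        if any(x <= 0 for x in tau) or any(b <= a for a, b in zip(tau, tau[1:])):
            raise ValueError("tau must be positive and strictly increasing")
        if any(x < 0 for x in g):
            raise ValueError("moduli g must be non-negative")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "g", g)


@dataclass(frozen=True)
class StiffnessProfile:
    """AQLV per-process stiffness k_i(L): piecewise-linear through 4 knots,
    constant beyond the outer knots."""

    knot_lengths: tuple = (0.0, 8.0 / 3.0, 16.0 / 3.0, 8.0)
    knot_stiffness: tuple = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        kl = tuple(float(x) for x in self.knot_lengths)
        ks = tuple(float(x) for x in self.knot_stiffness)
        if len(kl) != 4 or len(ks) != 4:
            raise ValueError("stiffness profile needs exactly 4 knots")
        if any(b <= a for a, b in zip(kl, kl[1:])):
            raise ValueError("knot lengths must be strictly increasing")
        if any(x < 0 for x in ks):
            raise ValueError("knot stiffness must be non-negative")
        object.__setattr__(self, "knot_lengths", kl)
        object.__setattr__(self, "knot_stiffness", ks)

    def stiffness(self, L):
        return np.interp(np.asarray(L, float), self.knot_lengths, self.knot_stiffness)


@dataclass(frozen=True)
class ViscosityLaw:
    """Length-dependent viscosity ``eta(L) = w0 + w1*L + w2*L**2`` (clipped at 0)."""

    w0: float = 0.0
    w1: float = 0.0
    w2: float = 0.0

    def eta(self, L):
        L = np.asarray(L, float)
        return np.clip(self.w0 + self.w1 * L + self.w2 * L * L, 0.0, None)


@dataclass(frozen=True)
class BaseModelParams:
    """Full parameter set of a QLV or AQLV model.

    ``kind`` is ``"qlv"`` or ``"aqlv"``.  QLV carries a
    :class:`RelaxationSpectrum`; AQLV carries seven
    :class:`StiffnessProfile` objects.  ``viscous_enabled`` ablates the pure
    viscous term (dropping its 3 DOF).
    """

    kind: str
    lt: LengthTension
    spectrum: RelaxationSpectrum | None = None
    profiles: tuple = ()
    viscosity: ViscosityLaw = field(default_factory=ViscosityLaw)
    viscous_enabled: bool = True

    def __post_init__(self):
        kind = self.kind.lower()
        if kind not in ("qlv", "aqlv"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        object.__setattr__(self, "kind", kind)
        if kind == "qlv":
            if self.spectrum is None:
                raise ValueError("QLV requires a relaxation spectrum")
        else:
            profiles = tuple(self.profiles)
            if len(profiles) != N_PROCESSES:
                raise ValueError(f"AQLV requires {N_PROCESSES} stiffness profiles")
            if self.spectrum is None:
                raise ValueError("AQLV requires a spectrum to carry the tau ladder")
            object.__setattr__(self, "profiles", profiles)

    @property
    def taus(self) -> tuple:
        return self.spectrum.tau

    def drive_gains(self, L):
        """Per-process drive per unit elongation rate at length(s) L.

        Returns an array of shape ``(7,) + shape(L)``: the quantity that
        multiplies v to form each process's drive.
        """
        L = np.asarray(L, float)
        if self.kind == "qlv":
            sl = self.lt.slope(L)
            g = np.asarray(self.spectrum.g)
            return self.spectrum.alpha * g.reshape((N_PROCESSES,) + (1,) * L.ndim) * sl
        return np.stack([p.stiffness(L) for p in self.profiles])


def lt_force(lt: LengthTension, L):
    """Static (equilibrium) force at elongation L, gf."""
    return lt.force(L)


def lt_slope(lt: LengthTension, L):
    """Analytic derivative of the length-tension curve, gf/mm."""
    return lt.slope(L)


def process_drive(params: BaseModelParams, i: int, L, v):
    """Drive feeding relaxation process ``i`` (1-based), gf/s.

    QLV: ``alpha * g_i * LT'(L) * v``; AQLV: ``k_i(L) * v``.
    """
    if not 1 <= i <= N_PROCESSES:
        raise IndexError(f"process index {i} out of range 1..{N_PROCESSES}")
    v = np.asarray(v, float)
    if params.kind == "qlv":
        gain = params.spectrum.alpha * params.spectrum.g[i - 1] * params.lt.slope(L)
    else:
        gain = params.profiles[i - 1].stiffness(L)
    return gain * v


def viscous_force(law: ViscosityLaw, L, v):
    """Pure viscous force ``eta(L) * v``, gf."""
    return law.eta(L) * np.asarray(v, float)


def dof_count(params: BaseModelParams) -> int:
    """Number of free parameters exposed to the fitter.

    15 for QLV (4 LT + 8 spectrum + 3 viscosity), 35 for AQLV
    (4 LT + 7*4 stiffness knots + 3 viscosity).  Disabling the viscous term
    removes its 3 DOF.
    """
    n = 4  # length-tension
    if params.kind == "qlv":
        n += N_PROCESSES + 1  # moduli g_i and alpha
    else:
        n += N_PROCESSES * 4  # 4 stiffness knots per process
    if params.viscous_enabled:
        n += 3
    return n
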