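"""Thixotropy-style attenuation of the viscoelastic force (the ANLV extension).

A structural parameter ``lambda`` tracks how "built up" the tissue
microstructure is.  Imposed elongation breaks the structure down::

    d(lambda)/dt = -k_d * v**n * m(F) * lambda          (no rebuilding at rest)

where ``m(F)`` modulates breakdown by the overall muscle force (default
``m(F) = 1 / (1 + k_f * F)``: attenuation is weaker when the force — hence
the length — is larger).  The rebuilding term of classic thixotropy theory
is deliberately absent: the available data do not constrain it, so lambda
only ever decreases between explicit resets.

``lambda`` is initialised at ``lambda_0 > 1`` and clipped at 1 before use, so
short elongations (≈ the first 0.5 mm) see no attenuation at all.  The
effective (clipped) lambda drives one gain per relaxation process::

    beta_i = 1 - gamma_i * (1 - min(lambda, 1)),   gamma_i in [0, 1]

``gamma_i = 1`` passes the full attenuation to process ``i``; ``gamma_i = 0``
leaves it untouched.  The gains multiply each process's force output — both
its stiffness and its viscosity are scaled, so the time constants do not
change and post-elongation decays remain exponential.

The extension adds 10 parameters: ``k_d, n, lambda_0, k_f`` and the seven
``gamma_i`` (the published account bounds the gamma_i to [0, 1] and counts
them as six extra DOF; no reproducible normalisation accompanies that count,
so all seven are treated as free here and ``dof()`` reports 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .base_models import N_PROCESSES

__all__ = [
    "AttenuationParams",
    "AttenuationState",
    "FORCE_MODULATIONS",
    "lambda_update",
    "effective_lambda",
    "beta_gains",
    "reset",
]


def _mod_rational(kf: float, F: float) -> float:
    return 1.0 / (1.0 + kf * max(F, 0.0))


def _mod_exponential(kf: float, F: float) -> float:
    return math.exp(-kf * max(F, 0.0))


#: pluggable force-modulation strategies m(F) for the breakdown rate
FORCE_MODULATIONS = {
    "rational": _mod_rational,
    "exponential": _mod_exponential,
}


@dataclass(frozen=True)
class AttenuationParams:
    """Parameters of the breakdown/attenuation law (10 DOF)."""

    k_d: float = 0.0        # breakdown rate coefficient, (mm/s)^-n / s
    n: float = 1.0          # breakdown speed exponent
    lambda0: float = 1.0    # initial structural parameter, >= 1
    k_f: float = 0.0        # force-modulation coefficient, 1/gf
    gamma: tuple = (0.0,) * N_PROCESSES  # per-process attenuation factors
    force_modulation: str = "rational"

    def __post_init__(self):
        if self.k_d < 0:
            raise ValueError("k_d must be non-negative")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.lambda0 < 1:
            raise ValueError("lambda0 must be >= 1")
        if self.k_f < 0:
            raise ValueError("k_f must be non-negative")
        gamma = tuple(float(x) for x in self.gamma)
        if len(gamma) != N_PROCESSES:
            raise ValueError(f"gamma needs exactly {N_PROCESSES} entries")
        if any(not 0.0 <= x <= 1.0 for x in gamma):
            raise ValueError("gamma factors must lie in [0, 1]")
        if self.force_modulation not in FORCE_MODULATIONS:
            raise ValueError(
                f"unknown force modulation {self.force_modulation!r}; "
                f"options: {sorted(FORCE_MODULATIONS)}")
        object.__setattr__(self, "gamma", gamma)

    def modulation(self, F: float) -> float:
        """Breakdown-rate modulation m(F) at total force F."""
        return FORCE_MODULATIONS[self.force_modulation](self.k_f, F)

    @staticmethod
    def dof() -> int:
        return 10

    def initial_state(self) -> "AttenuationState":
        return AttenuationState(lam=self.lambda0)


@dataclass(frozen=True)
class AttenuationState:
    """Current structural parameter lambda, in (0, lambda_0]."""

    lam: float

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must stay positive")


def lambda_update(state: AttenuationState, params: AttenuationParams,
                  v: float, F: float, dt: float) -> AttenuationState:
    """One integration step of the breakdown ODE.

    The ODE is linear in lambda with v and F frozen over the step, so the
    exponential update ``lambda *= exp(-k_d * v**n * m(F) * dt)`` is exact
    for the frozen inputs and keeps lambda strictly positive.  At rest
    (v = 0) lambda is unchanged: there is no rebuilding.
    """
    if v < 0:
        raise ValueError("negative elongation rate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if v == 0.0 or params.k_d == 0.0:
        return state
    rate = params.k_d * v ** params.n * params.modulation(F)
    return AttenuationState(lam=state.lam * math.exp(-rate * dt))


def effective_lambda(state: AttenuationState) -> float:
    """The attenuation actually applied: the smaller of lambda and one."""
    return min(state.lam, 1.0)


def beta_gains(params: AttenuationParams, lam_eff: float) -> np.ndarray:
    """Per-process gains ``beta_i = 1 - gamma_i * (1 - lam_eff)``.

    Each beta_i lies in [lam_eff, 1]; lam_eff is the lowest gain (maximum
    attenuation) across processes, attained where gamma_i = 1.
    """
    if not 0.0 <= lam_eff <= 1.0:
        raise ValueError(f"effective lambda {lam_eff} outside [0, 1]")
    return 1.0 - np.asarray(params.gamma) * (1.0 - lam_eff)


def reset(state: AttenuationState, params: AttenuationParams) -> AttenuationState:
    """Restore lambda to its initial value lambda_0 (e.g. after a long rest)."""
    return AttenuationState(lam=params.lambda0)
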