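"""Synthetic "recordings" emulating in-vivo passive-muscle measurements.

Real recordings of this preparation are contaminated by heartbeat- and
respiration-locked force oscillations plus a small wideband instrumentation
noise.  The generator adds those artifacts to a ground-truth model force::

    F_noisy = F_model + A_h sin(2 pi f_h t + phi_h)
                      + A_r sin(2 pi f_r t + phi_r) + N(0, sd^2)

with phases drawn from a seeded generator (same seed, same realisation).
The de-noising procedure applied to the real data is not modelled here —
only the artifact's existence is emulated, so recovery experiments can show
robustness to it.

``generate_battery`` assembles the full experimental protocol battery:
constant-speed ramps at 0.1/1/10/80/160 mm/s over the ~8 mm elongation
range, saccade-like elongations of 1–4 mm at main-sequence peak speeds
(60–160 mm/s) from several start lengths, and double steps / double
saccades at inter-stimulus intervals of 0.01/0.1/1/45 s (the attenuation
state is reset before the second elongation at the 45 s interval,
emulating full recovery over a long rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .attenuation import AttenuationParams
from .base_models import BaseModelParams
from .protocols import ElongationProtocol, concatenate, make_ramp, make_saccadic, make_step
from .simulator import SimulationResult, simulate

__all__ = [
    "NoiseSpec",
    "Recording",
    "DatasetItem",
    "SyntheticDataset",
    "BatteryOptions",
    "generate_recording",
    "generate_battery",
    "MAIN_SEQUENCE",
]

#: amplitude (mm) -> peak speed (mm/s) pairing for saccade-like elongations
MAIN_SEQUENCE = {1.0: 60.0, 2.0: 100.0, 3.0: 130.0, 4.0: 160.0}


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-artifact model; amplitudes in gf, frequencies in Hz."""

    heartbeat_amp: float = 0.1
    heartbeat_freq: float = 2.0
    resp_amp: float = 0.2
    resp_freq: float = 0.3
    white_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.heartbeat_amp, self.resp_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.heartbeat_freq <= 0 or self.resp_freq <= 0:
            raise ValueError("noise frequencies must be positive")

    @property
    def silent(self) -> bool:
        return self.heartbeat_amp == 0 and self.resp_amp == 0 and self.white_sd == 0

    def zeroed(self) -> "NoiseSpec":
        return replace(self, heartbeat_amp=0.0, resp_amp=0.0, white_sd=0.0)


@dataclass(frozen=True)
class Recording:
    """One synthetic recording: ground-truth simulation plus noisy force."""

    clean: SimulationResult
    F_noisy: np.ndarray
    noise: NoiseSpec

    @property
    def t(self) -> np.ndarray:
        return self.clean.t

    @property
    def protocol(self) -> ElongationProtocol:
        return self.clean.protocol


def _noise_realisation(noise: NoiseSpec, t: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    phi_h, phi_r = rng.uniform(0.0, 2 * np.pi, size=2)
    out = noise.heartbeat_amp * np.sin(2 * np.pi * noise.heartbeat_freq * t + phi_h)
    out += noise.resp_amp * np.sin(2 * np.pi * noise.resp_freq * t + phi_r)
    out += rng.normal(0.0, noise.white_sd, size=t.size)
    return out


def generate_recording(params: BaseModelParams, atten: AttenuationParams | None,
                       protocol: ElongationProtocol, noise: NoiseSpec,
                       rng: np.random.Generator | None = None) -> Recording:
    """Simulate the model on ``protocol`` and overlay measurement artifacts.

    With all noise amplitudes zero the noisy trace *is* the simulation
    output, bit for bit.
    """
    clean = simulate(params, atten, protocol)
    if noise.silent:
        F_noisy = clean.F_total.copy()
    else:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        F_noisy = clean.F_total + _noise_realisation(noise, clean.t, rng)
    return Recording(clean=clean, F_noisy=F_noisy, noise=noise)


@dataclass(frozen=True)
class DatasetItem:
    name: str
    protocol: ElongationProtocol
    clean: SimulationResult
    F_noisy: np.ndarray


@dataclass(frozen=True)
class SyntheticDataset:
    """Battery of synthetic recordings with their ground-truth parameters."""

    items: tuple
    base_params: BaseModelParams
    atten: AttenuationParams | None
    noise: NoiseSpec

    def __len__(self) -> int:
        return len(self.items)

    def names(self) -> list[str]:
        return [it.name for it in self.items]

    def __getitem__(self, key):
        if isinstance(key, str):
            for it in self.items:
                if it.name == key:
                    return it
            raise KeyError(key)
        return self.items[key]


@dataclass(frozen=True)
class BatteryOptions:
    """Composition and sampling of the protocol battery."""

    dt: float = 1e-3
    hold_duration: float = 20.0     # post-elongation record, s
    range_mm: float = 8.0           # full elongation range, mm
    ramp_speeds: tuple = (0.1, 1.0, 10.0, 80.0, 160.0)
    saccade_amplitudes: tuple = (1.0, 2.0, 3.0, 4.0)
    saccade_start_lengths: tuple = (1.0, 4.0)
    step_amplitude: float = 0.5
    step_rise_time: float = 5e-3    # lengthened automatically if dt is coarse
    double_amplitude: float = 1.6
    isis: tuple = (0.01, 0.1, 1.0, 45.0)
    reset_isi: float = 45.0         # ISI at/above which the attenuation resets
    include: tuple = ("ramps", "saccades", "double_steps", "double_saccades")


def _double(maker, isi: float, opts: BatteryOptions) -> ElongationProtocol:
    first = maker(hold_duration=0.0)
    second = maker(hold_duration=opts.hold_duration)
    return concatenate([first, second], isi=isi,
                       reset_before_second=isi >= opts.reset_isi)


def generate_battery(params: BaseModelParams, atten: AttenuationParams | None,
                     noise: NoiseSpec,
                     options: BatteryOptions | None = None) -> SyntheticDataset:
    """Generate the full synthetic battery (ground truth stored alongside)."""
    opts = options or BatteryOptions()
    rng = np.random.default_rng(noise.seed)
    protocols: list[tuple[str, ElongationProtocol]] = []

    if "ramps" in opts.include:
        for speed in opts.ramp_speeds:
            protocols.append((
                f"ramp_{speed:g}mms",
                make_ramp(speed, opts.range_mm, start_length=0.0,
                          hold_duration=opts.hold_duration, dt=opts.dt)))
    if "saccades" in opts.include:
        for amp in opts.saccade_amplitudes:
            peak = MAIN_SEQUENCE.get(amp, 40.0 * amp + 20.0)
            for start in opts.saccade_start_lengths:
                if start + amp > opts.range_mm + 1e-9:
                    continue
                protocols.append((
                    f"saccade_{amp:g}mm_from{start:g}mm",
                    make_saccadic(amp, peak, start_length=start,
                                  hold_duration=opts.hold_duration, dt=opts.dt)))
    if "double_steps" in opts.include:
        for isi in opts.isis:
            protocols.append((
                f"double_step_isi{isi:g}s",
                _double(lambda hold_duration: make_step(
                    opts.step_amplitude,
                    rise_time=max(opts.step_rise_time, 4 * opts.dt),
                    hold_duration=hold_duration, dt=opts.dt),
                    isi, opts)))
    if "double_saccades" in opts.include:
        peak = MAIN_SEQUENCE.get(2.0, 100.0)
        for isi in opts.isis:
            protocols.append((
                f"double_saccade_isi{isi:g}s",
                _double(lambda hold_duration: make_saccadic(
                    opts.double_amplitude, peak, hold_duration=hold_duration,
                    dt=opts.dt), isi, opts)))

    items = []
    for name, protocol in protocols:
        rec = generate_recording(params, atten, protocol, noise, rng=rng)
        items.append(DatasetItem(name=name, protocol=protocol,
                                 clean=rec.clean, F_noisy=rec.F_noisy))
    return SyntheticDataset(items=tuple(items), base_params=params,
                            atten=atten, noise=noise)
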