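"""Packaged end-to-end benchmarks.

The recovery benchmark measures whether the system-identification pipeline
can recover known attenuation parameters from a noise-free synthetic
battery.  Its conditions are fixed here so that tests, scripts and users
all run the same experiment:

* ground truth: the published attenuation parameter set of muscle m2SR
  (the column whose three most-attenuated processes are separated from the
  fourth by a wide margin, making the "top-3" identity well-posed) over the
  synthetic QLV base model;
* battery: constant-speed ramps at 1/10/80 mm/s over 6 mm plus 2 mm and
  4 mm saccade-like elongations, 2 ms sampling, 15 s post-elongation
  records (long enough to separate the slow relaxation processes), no
  measurement noise;
* search: the reduced evolutionary budget (15 generations x 30 designs)
  with the default multi-start local polish.
"""

from __future__ import annotations

from .fitting import FitConfig, FitResult, fit_attenuation, objective, recovery_report
from .io_cli import load_fixture
from .synthetic_data import BatteryOptions, NoiseSpec, SyntheticDataset, generate_battery

__all__ = ["RECOVERY_OPTIONS", "recovery_benchmark_dataset", "run_recovery_benchmark"]

RECOVERY_OPTIONS = BatteryOptions(
    dt=2e-3, hold_duration=15.0, range_mm=6.0,
    ramp_speeds=(1.0, 10.0, 80.0),
    saccade_amplitudes=(2.0, 4.0),
    saccade_start_lengths=(1.0,),
    include=("ramps", "saccades"),
)


def recovery_benchmark_dataset(noise_seed: int = 3):
    """The benchmark's zero-noise battery and its ground truth.

    Returns ``(dataset, base_params, truth_atten)``.  The noise seed is
    irrelevant to the force values (all amplitudes are zero) but is kept in
    the dataset record for provenance.
    """
    fx = load_fixture("qlv_anlv", "m2SR")
    dataset = generate_battery(fx.base, fx.atten,
                               NoiseSpec(seed=noise_seed).zeroed(),
                               RECOVERY_OPTIONS)
    return dataset, fx.base, fx.atten


def run_recovery_benchmark(seed: int = 0, generations: int = 15,
                           population: int = 30) -> dict:
    """Fit the benchmark battery and report recovery diagnostics.

    Returns a dict with the FitResult, the recovery report, the ground
    truth's own objective value and the dataset used.
    """
    dataset, base, truth = recovery_benchmark_dataset()
    truth_objective = objective(base, truth, dataset)
    config = FitConfig(generations=generations, population=population, seed=seed)
    fit = fit_attenuation(dataset, base, config=config)
    report = recovery_report(fit, truth, truth_objective=truth_objective)
    return {
        "fit": fit,
        "report": report,
        "truth": truth,
        "truth_objective": truth_objective,
        "dataset": dataset,
        "n_scored_windows": 8 * len(dataset),
    }
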