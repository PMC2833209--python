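"""Objective arithmetic, GA determinism/elitism, and null-model feasibility."""

import numpy as np
import pytest

from eomvisc.attenuation import AttenuationParams
from eomvisc.fitting import (
    DEFAULT_BOUNDS,
    FitConfig,
    _FastObjective,
    atten_to_vector,
    fit_attenuation,
    objective,
    recovery_report,
    vector_to_atten,
)
from eomvisc.protocols import make_ramp, make_saccadic
from eomvisc.simulator import simulate
from eomvisc.synthetic_data import (
    BatteryOptions,
    DatasetItem,
    NoiseSpec,
    SyntheticDataset,
    generate_battery,
)

SHORT_TAUS = (0.005, 0.01, 0.02, 0.05, 0.1, 0.25, 0.5)  # windows fit a 2 s hold

TINY_OPTS = BatteryOptions(dt=2e-3, hold_duration=3.0, range_mm=4.0,
                           ramp_speeds=(10.0, 80.0), include=("ramps",))


def _offset_dataset(params, atten, protocols, deltas):
    """Dataset whose recordings are the model plus constant offsets."""
    items = []
    for p, d in zip(protocols, deltas):
        clean = simulate(params, atten, p)
        items.append(DatasetItem(name=f"d{d}", protocol=p, clean=clean,
                                 F_noisy=clean.F_total + d))
    return SyntheticDataset(items=tuple(items), base_params=params,
                            atten=atten, noise=NoiseSpec().zeroed())


class TestObjective:
    def test_perfect_model_scores_zero(self, fx_qlv_m4lr):
        ds = generate_battery(fx_qlv_m4lr.base, fx_qlv_m4lr.atten,
                              NoiseSpec().zeroed(), TINY_OPTS)
        assert objective(fx_qlv_m4lr.base, fx_qlv_m4lr.atten, ds) == pytest.approx(
            0.0, abs=1e-18)

    def test_constant_offset_gives_eight_delta_squared(self, qlv_synth):
        """1 elongation window + 7 full relaxation windows, each MSE = d^2."""
        p = make_saccadic(2.0, 100.0, hold_duration=2.0, dt=2e-3)
        ds = _offset_dataset(qlv_synth, None, [p], [0.3])
        got = objective(qlv_synth, None, ds, taus=SHORT_TAUS)
        assert got == pytest.approx(8 * 0.3**2, rel=1e-12)

    def test_additive_over_elongations(self, qlv_synth):
        p1 = make_saccadic(2.0, 100.0, hold_duration=2.0, dt=2e-3)
        p2 = make_ramp(10.0, 3.0, hold_duration=2.0, dt=2e-3)
        ds = _offset_dataset(qlv_synth, None, [p1, p2], [0.3, 0.5])
        got = objective(qlv_synth, None, ds, taus=SHORT_TAUS)
        assert got == pytest.approx(8 * (0.3**2 + 0.5**2), rel=1e-12)

    def test_nonnegative_and_zero_iff_equal(self, qlv_synth):
        p = make_ramp(10.0, 3.0, hold_duration=1.0, dt=2e-3)
        ds = _offset_dataset(qlv_synth, None, [p], [0.0])
        assert objective(qlv_synth, None, ds, taus=SHORT_TAUS) == 0.0
        ds2 = _offset_dataset(qlv_synth, None, [p], [1e-3])
        assert objective(qlv_synth, None, ds2, taus=SHORT_TAUS) > 0.0

    def test_fast_path_matches_full_simulation(self, fx_qlv_m4lr):
        """The cached evaluator used inside the GA is an exact factorisation
        of the simulator, not an approximation."""
        ds = generate_battery(fx_qlv_m4lr.base, fx_qlv_m4lr.atten,
                              NoiseSpec().zeroed(), TINY_OPTS)
        taus = fx_qlv_m4lr.base.taus
        fast = _FastObjective(ds, fx_qlv_m4lr.base, taus)
        for atten in (fx_qlv_m4lr.atten,
                      AttenuationParams(k_d=0.5, n=1.1, lambda0=1.2,
                                        gamma=(0.3,) * 7)):
            full = objective(fx_qlv_m4lr.base, atten, ds, taus=taus)
            assert fast(atten) == pytest.approx(full, rel=1e-9, abs=1e-12)


class TestVectorMapping:
    def test_round_trip(self, fx_aqlv_m4lr):
        a = fx_aqlv_m4lr.atten
        vec = atten_to_vector(a)
        assert vector_to_atten(vec) == a

    def test_partial_free_set_uses_template(self, fx_qlv_m4lr):
        a = vector_to_atten([0.7], free=("k_d",), template=fx_qlv_m4lr.atten)
        assert a.k_d == 0.7
        assert a.gamma == fx_qlv_m4lr.atten.gamma


@pytest.fixture(scope="module")
def tiny_dataset(fx_qlv_m4lr):
    return generate_battery(fx_qlv_m4lr.base, fx_qlv_m4lr.atten,
                            NoiseSpec().zeroed(), TINY_OPTS)


class TestFitAttenuation:
    def test_default_budget_matches_protocol(self):
        cfg = FitConfig()
        assert cfg.generations == 50
        assert cfg.population == 75

    def test_reproducible_for_fixed_seed(self, tiny_dataset, fx_qlv_m4lr):
        cfg = FitConfig(generations=3, population=8, seed=13, polish=False)
        f1 = fit_attenuation(tiny_dataset, fx_qlv_m4lr.base, config=cfg)
        f2 = fit_attenuation(tiny_dataset, fx_qlv_m4lr.base, config=cfg)
        assert f1.best_objective == f2.best_objective
        assert f1.best_params == f2.best_params
        assert f1.generation_best == f2.generation_best

    def test_elitist_trace_never_increases(self, tiny_dataset, fx_qlv_m4lr):
        cfg = FitConfig(generations=6, population=10, seed=3, polish=False)
        fit = fit_attenuation(tiny_dataset, fx_qlv_m4lr.base, config=cfg)
        trace = np.asarray(fit.generation_best)
        assert np.all(np.diff(trace) <= 0)
        assert fit.best_objective == trace[-1]

    def test_evaluation_budget(self, tiny_dataset, fx_qlv_m4lr):
        cfg = FitConfig(generations=4, population=9, seed=1, polish=False)
        fit = fit_attenuation(tiny_dataset, fx_qlv_m4lr.base, config=cfg)
        assert fit.n_evaluations <= 4 * 9 + 9
        assert fit.n_polish_evaluations == 0
        assert fit.meta["operators"]["elitism"] == 1

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(bounds={**DEFAULT_BOUNDS, "k_d": (1.0, 0.5)})
        with pytest.raises(ValueError):
            FitConfig(bounds={**DEFAULT_BOUNDS, "lambda0": (0.5, 2.0)})

    def test_empty_dataset_rejected(self, fx_qlv_m4lr):
        ds = SyntheticDataset(items=(), base_params=fx_qlv_m4lr.base,
                              atten=None, noise=NoiseSpec())
        with pytest.raises(ValueError, match="empty"):
            fit_attenuation(ds, fx_qlv_m4lr.base)

    def test_null_attenuation_dataset_is_feasible(self, qlv_synth):
        """Data generated with no attenuation: the fit reaches ~zero error
        and the fitted model's output is indistinguishable from the base."""
        opts = BatteryOptions(dt=2e-3, hold_duration=3.0, range_mm=4.0,
                              ramp_speeds=(10.0,), include=("ramps",))
        ds = generate_battery(qlv_synth, None, NoiseSpec().zeroed(), opts)
        cfg = FitConfig(generations=8, population=16, seed=5,
                        polish_starts=2, polish_maxfev=3000)
        fit = fit_attenuation(ds, qlv_synth, config=cfg)
        item = ds[0]
        fitted = simulate(qlv_synth, fit.best_params, item.protocol)
        base = simulate(qlv_synth, None, item.protocol)
        peak_dyn = np.max(np.abs(base.F_total - qlv_synth.lt.force(base.L)))
        assert np.max(np.abs(fitted.F_total - base.F_total)) < 0.01 * peak_dyn


class TestRecoveryReport:
    def test_truth_reports_zero_errors(self, fx_qlv_m4lr):
        from eomvisc.fitting import FitResult
        fit = FitResult(best_params=fx_qlv_m4lr.atten, best_objective=0.0,
                        generation_best=(0.0,), n_evaluations=1,
                        n_polish_evaluations=0)
        rep = recovery_report(fit, fx_qlv_m4lr.atten, truth_objective=0.0)
        assert all(v["abs_error"] == 0.0 for v in rep["parameters"].values())
        assert rep["kd_within_tol"]
        assert rep["top3_gamma_match"]
        assert rep["objective_gap"] == 0.0

    def test_report_lists_all_ten_parameters(self, fx_qlv_m4lr):
        from eomvisc.fitting import FitResult
        fit = FitResult(best_params=fx_qlv_m4lr.atten, best_objective=0.0,
                        generation_best=(0.0,), n_evaluations=1,
                        n_polish_evaluations=0)
        rep = recovery_report(fit, fx_qlv_m4lr.atten)
        assert len(rep["parameters"]) == 11  # 4 kinetic + 7 gamma entries
        assert AttenuationParams.dof() == 10  # gamma counted once as a block
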