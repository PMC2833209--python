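# Methods

## The model family

Passive extraocular muscle held at length `L` for a long time settles to a
static **length-tension** force `LT(L)`. During and after imposed
elongations (only lengthening is modelled) a large additional force
appears, carried by seven parallel first-order relaxation processes and a
small pure viscosity. All three model variants share the structure

    F(t) = LT(L) + Σᵢ βᵢ(t)·xᵢ(t) + η(L)·v,      i = 1…7
    ẋᵢ = −xᵢ/τᵢ + uᵢ(L, v)

with elongation `L` in mm, rate `v = L̇ ≥ 0` in mm/s, forces in gram-force
(1 gf = 0.0098 N).

* **QLV** (15 DOF): `uᵢ = α·gᵢ·LT′(L)·v`. The viscoelastic drive is
  proportional to the slope of the static curve, so a linear length-tension
  curve makes the whole viscoelastic part a linear system. Free parameters:
  4 (LT) + 8 (moduli gᵢ and scale α) + 3 (viscosity).
* **AQLV** (35 DOF): `uᵢ = kᵢ(L)·v` with each process's stiffness `kᵢ`
  a 4-knot piecewise-linear function of length (constant beyond the outer
  knots). 4 + 7·4 + 3 parameters.
* **ANLV** (base + 10 DOF): the base model with per-process output gains
  `βᵢ = 1 − γᵢ·(1 − min(λ, 1))` driven by a thixotropy-style structural
  parameter

      λ̇ = − k_d · vⁿ · λ / (1 + k_f·F),     λ(0) = λ₀ ≥ 1.

  λ only decreases (no rebuilding is modelled; the data that would
  constrain a recovery term do not exist), except at explicit protocol
  reset marks where it returns to λ₀, representing full recovery after a
  long rest. Initialising above 1 and clipping at 1 gives small
  elongations (≈ the first 0.5 mm) an unattenuated regime. The gains act
  on the process **outputs**: stiffness and viscosity are scaled together,
  so time constants are untouched and post-elongation decays remain sums
  of exponentials. Neither the static curve nor the pure viscous term is
  attenuated.

The force modulation `1/(1 + k_f·F)` (breakdown weaker at higher force) is
a reconstruction; it is pluggable (`force_modulation="exponential"` swaps
in `exp(−k_f·F)`) without touching the integrator.

The seven γᵢ are bounded to [0, 1] and all treated as free parameters in
the fitter. The published account counts them as six degrees of freedom
via a constraint that is not recoverable from the text;
`AttenuationParams.dof()` reports the published total of 10.

## Fixed (non-fitted) structure

* **Time constants**: geometric ladder `τ = 0.01 · 4ᵏ` s, k = 0…6
  (0.01 … 40.96 s). The slowest process ≈ 41 s matches the observation of
  relaxation on 40-s-plus time scales; fully configurable.
* **Length-tension form**: `c0 + c1·L + c2·(exp(c3·L) − 1)` — essentially
  linear up to ~3 mm with accelerating stiffness beyond, over the ~8 mm
  working range (the full oculomotor range).
* **Viscosity**: `η(L) = w0 + w1·L + w2·L²`, clipped at zero.
* The packaged base-model coefficients (`synthetic_base_model`) are
  synthetic fixtures producing plausible gf-scale forces; the muscle-specific
  base-model values behind the published attenuation fits were reported
  elsewhere and are not transcribed here. The packaged attenuation values
  (`load_fixture`) are the published per-muscle fits.

## Numerics

* **Process states**: exact exponential update per step,
  `x ← x·e^(−dt/τ) + u·τ·(1 − e^(−dt/τ))`, with `u` the trapezoidal
  average of the drive over the step — exact for piecewise-constant drive
  (ramps, holds), second-order for smooth profiles. Because the gains act
  on outputs, states never depend on λ and are computed vectorised (one
  IIR filter per process).
* **λ recursion**: exponential (positivity-preserving) update
  `λ ← λ·exp(−k_d·v̄ⁿ·m(F)·dt)` with midpoint rate `v̄` and the total
  force of the current sample (explicit coupling; the error is O(dt) on a
  term that is itself a small correction). Halving `dt` moves the force by
  < 0.1% sup-norm on the fastest protocols.
* **Default sampling**: `dt` = 1 ms, resolving the fastest protocol (50 ms
  ramp) with 50 samples; generators refuse under-resolved requests
  (saccadic duration < 4·dt, step rise < 4·dt).
* **Consistency guard**: generators build `v` first, rescale it so its
  trapezoidal integral equals the commanded amplitude exactly, and
  integrate it to `L`; the simulator refuses protocols whose `∫v dt`
  deviates from ΔL by more than 0.2% (such mismatches are enough to create
  artifactual relaxation cross-overs).
* Simulations start from zero process states (muscle equilibrated at the
  start length); states and λ can be passed in to chain runs.

## Synthetic recordings

`generate_recording` overlays heartbeat-like (0.1 gf at 2 Hz),
respiration-like (0.2 gf at 0.3 Hz) and white (SD 0.02 gf) noise on the
model force, phases drawn from a seeded generator. These defaults are
declared assumptions (no quantitative noise characterisation exists for
the original recordings) chosen as plausible for an anesthetized macaque
preparation with a small residual instrumentation floor.
`generate_battery` assembles the protocol battery: ramps at
0.1/1/10/80/160 mm/s over 8 mm, saccadic elongations 1–4 mm paired with
main-sequence peak speeds 60–160 mm/s from several start lengths, and
double steps (0.5 mm) / double saccades (1.6 mm) at inter-stimulus
intervals 0.01/0.1/1/45 s, with the attenuation reset marked at the 45 s
interval.

What the generator does **not** emulate: preconditioning history effects,
inter-animal variability, force-dependent noise, tissue deterioration, and
the de-noising pipeline applied to real recordings. Passing tests
therefore demonstrate internal consistency and recoverability under the
model's own assumptions, not validity on new muscle data.

## System identification

The objective for each elongation is the mean squared model−data error
over the elongation phase plus seven MSEs over relaxation windows
`[t_end, t_end + 3τᵢ]` (truncated at the record end), summed over
elongations. Using *mean* rather than summed squares keeps the slow
processes from dominating by window length alone.

The search is a seeded elitist GA over the ten attenuation parameters
(bounds: k_d ∈ [0,2], n ∈ [0.5,3], λ₀ ∈ [1,4], k_f ∈ [0,0.1],
γᵢ ∈ [0,1], bracketing all published values): scrambled-Sobol seed
population, tournament selection (k=3), blend crossover (α=0.5, rate 0.9),
bounded Gaussian mutation (rate 0.25, SD 12% of span), one elite carried
over — the per-generation best never increases. Base-model parameters are
held fixed by default, mirroring the two-stage identification (base models
from step data first).

A multi-start Powell polish then refines up to six mutually distant
designs mined from *all* evaluated designs (the Sobol seeding guarantees
spread-out candidates; polishing only the converged final population
proved basin-fragile). Because processes with neighbouring time constants
produce near-symmetric local optima under exchanges of their γ factors —
the analogue of label switching in mixture fitting — the polish ends with
adjacent-pair γ-swap moves, each given a short re-polish so the kinetic
parameters can re-adjust before the swap is judged. GA and polish
evaluation counts are reported separately in `FitResult`. The candidate
evaluation reuses the simulator's factorisation (process states are
independent of the attenuation parameters and are precomputed once per
dataset); the sequential λ recursion is JIT-compiled when numba is
available, with an identical pure-Python fallback.

The packaged recovery benchmark (`eomvisc.benchmarks`) fits a zero-noise
battery (ramps 1/10/80 mm/s over 6 mm + 2/4 mm saccades, 2 ms sampling,
15 s holds — long enough to separate the slow processes) generated from
the m2SR attenuation values, whose three most-attenuated processes are
separated from the fourth by a wide γ margin, making the top-3 identity
well-posed. The reduced budget is 15 generations × 30 designs. On this
benchmark the fit reproduces k_d to a few percent and recovers the top-3
attenuated-process identity; the ground truth attains the global objective
minimum (zero) by construction and the fit comes within a slack equivalent
to 0.02 gf RMS per scored window — the declared instrumentation-noise
floor.

## Known limitations

* Rebuilding/recovery kinetics are absent; sequences of large elongations
  at short intervals are systematically under-predicted by construction
  (the API reserves the reset hook but no build-up law is implemented or
  tested).
* The exact algebraic forms of the attenuation equations are
  reconstructions of a verbal description; alternatives (e.g. a different
  force modulation) fit behind the same interface.
* γ factors of fast processes are weakly identifiable from slow protocols;
  the benchmark's claims are about the well-separated slow processes.
* Shortening (v < 0) is outside the model's domain and rejected by type
  invariants rather than extrapolated.
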