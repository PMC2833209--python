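# eomvisc

Viscoelasticity of passive extraocular muscle: simulation, diagnostics and
system identification for the QLV, AQLV and ANLV model family.

Passive eye muscle exerts large, slowly relaxing forces whenever it is
stretched — forces that matter throughout the oculomotor range, not just at
its edges. Classical viscoelastic models fitted to small step elongations
(Fung's quasi-linear viscoelastic model, **QLV**, and its
length-adaptive extension, **AQLV**) grossly overestimate the force during
the smooth, large elongations a muscle experiences during real eye
movements, and cannot reproduce the characteristic relaxation behaviour:
after stretches ending at a common length, faster stretches end with
*higher* force but relax to *lower* force within a second (a cross-over),
and all traces collapse within ~100 ms. The **ANLV** (attenuated nonlinear
viscoelastic) model repairs this with a thixotropy-style structural
parameter λ that breaks down under imposed elongation and attenuates each
relaxation process through a per-process gain.

This package is aimed at oculomotor and tissue-rheology modellers who want
to simulate these models, reproduce their qualitative phenomenology, and
run identification experiments on synthetic recordings.

## The model

All variants share (units: mm, mm/s, s, gram-force):

```
F(t) = LT(L) + Σᵢ βᵢ(t)·xᵢ(t) + η(L)·v          i = 1…7
ẋᵢ   = −xᵢ/τᵢ + uᵢ(L, v)
```

- `LT(L) = c0 + c1·L + c2·(e^{c3·L} − 1)` — static length-tension curve;
- QLV drive `uᵢ = α·gᵢ·LT′(L)·v` (15 DOF total); AQLV drive
  `uᵢ = kᵢ(L)·v`, 4-knot piecewise-linear stiffness per process (35 DOF);
- `η(L)·v` — pure viscous force, quadratic η (3 of the DOF above);
- ANLV gains `βᵢ = 1 − γᵢ·(1 − min(λ, 1))` with breakdown kinetics
  `λ̇ = −k_d·vⁿ·λ/(1 + k_f·F)`, `λ(0) = λ₀ ≥ 1` — ten extra parameters
  (`k_d, n, λ₀, k_f, γ₁…γ₇`, the bounded γ counting as six), no
  attenuation on `LT` or the viscous term, λ reset to λ₀ only at explicit
  protocol reset marks (long rests).

Published attenuation parameter sets for four muscles ship as fixtures
(`load_fixture("qlv_anlv" | "aqlv_anlv", "m2SR" | "m3LR" | "m3SR" | "m4LR")`)
over clearly-labelled synthetic base models. See `docs/methods.md` for
assumptions, numerics and limitations.

## Worked example

```python
from eomvisc import (load_fixture, make_ramp, make_saccadic, simulate,
                     TraceFamily, detect_crossover, viscoelastic_ratio)

fx = load_fixture("aqlv_anlv", "m2SR")
speeds = (1.0, 10.0, 80.0, 160.0)
family = TraceFamily(
    labels=tuple(f"{s:g} mm/s" for s in speeds),
    traces=tuple(simulate(fx.base, fx.atten, make_ramp(s, 8.0, hold_duration=5.0))
                 for s in speeds))
rep = detect_crossover(family, t_probe=1.0)
print("force ranking at end of ramp :", " > ".join(rep.order_at_end))
print("force ranking 1 s later      :", " > ".join(rep.order_at_probe))

p = make_saccadic(3.0, 130.0, start_length=3.0, hold_duration=2.0)
anlv = simulate(fx.base, fx.atten, p)
base = simulate(fx.base, None, p)
print(f"viscoelastic ratio: {viscoelastic_ratio(anlv, base, fx.base.lt):.3f}")
```

prints

```
force ranking at end of ramp : 160 mm/s > 80 mm/s > 10 mm/s > 1 mm/s
force ranking 1 s later      : 1 mm/s > 10 mm/s > 80 mm/s > 160 mm/s
viscoelastic ratio: 0.451
```

At the end of a constant-speed stretch over the full 8 mm range, faster
stretches produce larger forces; one second into relaxation the ordering
has fully reversed — the attenuated model's cross-over. Without
attenuation the ordering never reverses. The viscoelastic ratio says the
attenuated model's purely viscoelastic force at the end of a 3 mm saccadic
elongation is 45% of the base model's prediction: exactly the kind of
overestimation the attenuation corrects.

A CLI mirrors the library (`eomvisc protocols make-ramp ...`,
`eomvisc simulate`, `eomvisc generate`, `eomvisc fit`, `eomvisc evaluate`).

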