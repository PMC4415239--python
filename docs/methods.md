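# Methods

## Mechanical model

The vessel phantom is treated as a thick-walled, incompressible elastic
cylinder. Hoop stress at radius r under internal pressure q₁ and external
pressure q₂ is the classical Lamé solution (tension positive):

    sigma_theta(r) = (r0^2/r^2 + 1)/(r0^2/ri^2 - 1) * q1
                   - (1 + ri^2/r^2)/(1 - ri^2/r0^2) * q2

Two consequences used as correctness anchors throughout the tests:
hydrostatic loading q₁ = q₂ = q gives σ_θ = −q at every radius, and in the
thin-wall limit h/r_m → 0 the inner-wall stress approaches the textbook
q₁·r_m/h (matched within 1% for h/r_m < 0.01).

The loaded geometry comes from two relations rather than a constitutive law:

1. **Compliance fit.** Loaded external diameter versus transmural pressure
   p = q₁ − q₂ is an empirical quartic, d₀(p) = a + b p + c p² − d p³ + e p⁴
   with the cubic coefficient stored positive and *subtracted* (the sign
   convention in which the coefficients were reported). The fit is a
   measured property of the mounted silicone tube; it is an input here,
   never re-fitted.
2. **Incompressibility.** λ_z·(r₀² − r_i²) = R₀² − R_i² with λ_z the
   longitudinal stretch of the mounted tube. With the default geometry
   (R₀ = 2.465 mm, R_i = 2.165 mm, λ_z = 1.2) the constant
   k = (R₀² − R_i²)/λ_z equals 1.1575 mm².

Eliminating r_i gives the inner-wall closed form
σ_θ = (2r₀² − k)/k · q₁ − 2r₀²/k · q₂, which the tests verify against the
general Lamé expression at r = r_i to 1e-12 relative tolerance.

**Units.** The compliance coefficients are interpreted with p in mmHg and d₀
in mm. This is an assumption, carried explicitly as `fit.pressure_unit`: in
mmHg the fit predicts ≈0.2 mm of distension over 0–120 mmHg, plausible for a
4.91 mm silicone tube, whereas a kPa reading would make the tube implausibly
stiff. Stress comes out in the unit of the input pressures;
`mmhg_to_kpa` (1 mmHg = 0.133322 kPa) converts.

**Fit validity.** Quartics extrapolate badly, so the fit declares a validity
range, default p ∈ [−20, 160] mmHg — generously covering the physiological
pressures the rig sweeps. Evaluation outside warns but does not fail
(negative transmural pressure is admissible; the fit is empirical).

**Degenerate inputs.** r₀² ≤ k has no real internal radius (the wall volume
cannot fit); this raises `CollapsedWallError`, and the pipeline reports the
first failing sample index. Radii outside [r_i, r₀] are rejected.

**Scope.** The closed form applies where the cross-section stays nearly
circular — the proximal and distal segments. Inside the compressed bridge
segment itself the lumen deforms strongly and the formula does not apply;
the package deliberately computes no stress there.

## Synthetic pressure channels

No channel recordings from the physical rig are available, so
`device_waveforms` emulates its three measured channels. This is a
phenomenological waveform model, not fluid dynamics: no Navier–Stokes or
lumped-parameter derivation, and no model of the rig's air-tank/valve
control loop.

- **Baseline wave.** Period 60/heart-rate; during the systolic fraction
  (default 0.35) a half-sine rises from diastolic to systolic and back;
  the remainder of the cycle relaxes exponentially to diastolic from the
  end-systolic value. Because the half-sine ends exactly at diastolic, the
  relaxation segment is the constant diastolic pressure — chosen so the wave
  is continuous and its extrema are exactly the configured 120/80 mmHg
  (the property the summaries rely on), at the cost of a flat diastole with
  no dicrotic notch.
- **Compression and water hammer.** The bridge engages within systole
  (onset phase 0, duration 0.35 of the cycle by default, validated to fit
  inside systole). The proximal channel adds a damped rectified sinusoid,
  gain·level·exp(−damping·τ)·|sin(2π·freq·τ)| with τ the time since
  compression onset; defaults gain 35 mmHg, damping 12 s⁻¹, frequency 8 Hz.
  Amplitude is linear in the oppression degree `level` ∈ [0, 1]; the rig's
  0/50/80/100% presets are the default sweep grid, not the only admissible
  values. The distal channel is the unmodified baseline (downstream pressure
  is unaffected by the bridge in the regime modelled). The overshoot
  parameters are free: no numeric overshoot amplitudes are published for the
  rig, so they are config-exposed defaults chosen to give a visible
  early-systolic transient that still rings near peak pressure — which is
  what makes the proximal peak, and hence the oscillatory value, strictly
  monotone in level.
- **Chamber pressure.** q₂ is a constant setpoint (the rig regulates it);
  non-negative by contract.
- **Noise and determinism.** Optional i.i.d. Gaussian measurement noise
  (mmHg) per internal channel from `numpy.random.default_rng(seed)`;
  identical parameters and seed give bitwise-identical output. The gate that
  activates the overshoot uses a 1e-9·period tolerance so float-mod jitter
  cannot flip boundary samples between cycles; without it, summaries over
  different cycle windows differ at ~1e-3 instead of ~1e-12.

Defaults: 5 s at 1000 Hz (5000 samples, sub-second runs, resolves the 8 Hz
overshoot with ~125 samples per ring period).

What passing tests show — and don't: the generator reproduces the *trends*
of bridge compression (proximal-only mean and oscillatory stress increase;
stress decreasing in chamber pressure) by construction. Real rig data add
reflected waves, pump harmonics, sensor drift and a possibly attenuated
distal wave at full occlusion; agreement here says the analysis pipeline is
correct, not that the waveform model is physiologic.

## Summaries and sweeps

A stress series is summarized by its arithmetic mean and its *oscillatory
value* (maximum − minimum) over the last `window` complete cardiac cycles
(default 2), discarding the startup portion; for noise-free periodic input
the summaries are invariant to the window length and to whole-cycle phase
shifts (tested at 1e-9).

Two standard sweeps, each returning per-condition, per-site summaries plus
named boolean verdicts:

- **Compression sweep** over oppression degrees (default 0, 0.5, 0.8, 1.0 at
  q₂ = 0): proximal mean strictly increasing; distal mean varying < 2%
  across levels ("unchanged" is stated qualitatively for the rig, so 2% is
  this package's operational threshold); proximal oscillatory strictly
  increasing; proximal oscillatory exceeding distal at every engaged level.
- **External-pressure sweep** over q₂ setpoints (default 0–60 mmHg in 10;
  the rig's tested range is not published, so the grid is a config default)
  at fixed compression (default 0): mean stress strictly decreasing in q₂
  at both sites.

Verdicts on noise-free runs use strict inequalities; with noise enabled,
each condition is averaged over 5 independent seeds first, since the trends
are statements about per-condition expectations. A trend over fewer than two
conditions is reported as `None` (not evaluable). The q₂ grid must be
strictly increasing; compression levels are taken as given (a repeated level
legitimately fails the strict-increase verdicts).

Each site uses its own internal pressure (proximal: chamber inlet, distal:
chamber outlet) against the common chamber pressure, mirroring the rig's two
measuring points.

## Numerical choices

- Algebraic identities (inner-wall form vs general Lamé, incompressibility)
  are held to 1e-12 relative; composed floating-point paths (pipeline vs
  naive per-sample oracle, window stability) to 1e-9.
- The derived constant k is computed from the geometry, never hard-coded;
  with the default geometry it reproduces 1.1575 mm² to machine precision.
- Sample counts per cycle are rounded from period × rate; summaries index
  whole cycles from the end of the record.

## Limitations

- The compliance quartic and its mmHg interpretation are tied to one
  silicone tube; other phantoms need their own coefficients.
- Linear-elastic Lamé superposition is assumed per sample (quasi-static);
  inertial wall dynamics and viscoelasticity are ignored.
- The generator's overshoot shape and gains are plausible but uncalibrated;
  only qualitative trends, never absolute stress magnitudes, should be
  compared against rig measurements.
- Mean flow (205 ml/min) and fluid viscosity (3.8×10⁻³ Pa·s) are carried as
  metadata only; the stress chain is purely pressure-driven.
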