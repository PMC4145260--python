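# Methods

## Model overview

The package simulates a motion-sensitized driven-equilibrium preparation as a
sequence of instantaneous RF rotations separated by free intervals. Between
rotations, magnetization relaxes (Mxy·e^(−dt/T2), Mz → M0 + (Mz−M0)·e^(−dt/T1))
and precesses by the gradient phase a spin at constant position x and velocity
v accrues in that interval, φ = 2π·γ̄·∫G(t)(x + v·t)dt with γ̄ = 42.577 kHz/mT.
Refocusing-pulse sign inversion is not imposed by hand: the 180° rotations act
on the transverse components and produce it. A perfect spoiler nulls the
transverse magnetization after the tip-up pulse.

Under ideal pulses this propagator reduces exactly to the two closed forms the
rest of the package is organized around:

- static tissue: final Mz/M0 = e^(−T_iMSDE/T2), independent of T1, because any
  longitudinal recovery during the preparation is returned to the transverse
  plane by the −90° pulse and spoiled;
- a constant-velocity spin: final Mz/M0 = e^(−T_iMSDE/T2)·cos(2π·γ̄·m₁·v),
  where m₁ is the first moment of the sign-weighted waveform.

Both reductions are verified to 1e−9 by the test suite, which is the main
internal-consistency check between the event-level propagator and the moment
calculus.

## Timing conventions

Hard-pulse durations scale with flip angle, calibrated at 0.4 ms per 90°, so
the composite −90° ([−360°, 270°], same phase axis as the simple −90°) lasts
2.8 ms and the composite 180° (90°x–180°y–90°x) 1.6 ms. Each rotation is
applied at the *end* of its pulse duration and T_iMSDE runs from the tip-down
rotation to the tip-up rotation. This convention makes the preparation-time
bookkeeping exact: swapping the hard −90° for the composite −90° lengthens
T_iMSDE by exactly 2.4 ms, and T_iMSDE equals the total transverse-decay
interval of the propagator. Pulse durations contribute only to timing; no
relaxation or off-resonance evolution is modeled *within* a pulse (durations
≤ 2.8 ms are small against the T2 values of interest).

## Gradient layout and design

The default layout places four identical-magnitude lobes sequentially around
the two refocusing pulses — one lobe in each outer segment, two in the middle
segment — with a fixed 0.1 ms gap between adjacent events and physical
polarities (+, −, +, −); combined with the two sign flips this yields a
balanced waveform (m₀ = 0) with a large velocity sensitivity. The time origin
is the center of the 90° pulse, which makes m₁ the velocity-phase coefficient
of the whole preparation (the choice of origin is immaterial once m₀ = 0).

The designer pins the amplitude at the hardware maximum (default 20 mT/m for
trapezoids, ramp 0.5 ms ≙ 40 mT/m/ms slew) and solves the lobe duration by
Brent root finding to 1e−4 relative tolerance; m₁ is strictly increasing in
lobe duration in this layout. Targets below the reach of the shortest
admissible lobe are met by pinning the duration and scaling the amplitude
(m₁ is exactly linear in amplitude at fixed geometry). Infeasible targets
raise an error naming the binding constraint.

With these defaults the achieved preparation durations across the published
first-moment grid 181–3108 mT·ms²/m (CP180 permutation) are 10.1, 13.7, 17.3,
21.1, 24.9 and 28.5 ms — within ~0.1 ms of the protocol durations reported
for this grid (10.0–28.4 ms), a residual attributable to unspecified
vendor-specific gaps. Exact reproduction of the published (G, d, duration)
triplets is not claimed; the published table's values are not exactly mutually
consistent under any single gap choice.

**Shape comparison rule.** Comparisons of trapezoidal versus sinusoidal lobes
are made at matched m₁ *and matched lobe duration*: the trapezoid is designed
minimum-time, and the half-sine is given the same duration with its amplitude
solved (always below ~31.4 mT/m = π/2 × the trapezoid amplitude). When the
solved sinusoid amplitude would exceed the slew cap (only at the smallest
first moments, where the trapezoid is nearly triangular), the half-sine is
lengthened to its slew-limited minimum duration instead. This mirrors
published protocol tables, in which both shapes share one duration column and
the sinusoid carries the higher amplitude (26–30 vs 20 mT/m). Designing the
sinusoid by pinning its amplitude at the cap and solving duration would make
it shorter and steeper than the trapezoid at low m₁ and invert the expected
eddy-current ordering.

## Eddy-current model

The eddy model is explicitly phenomenological: a first-order
linear-time-invariant response residual(t) = −a·∫(dG/dt')·e^(−(t−t')/τ)dt'
with defaults a = 0.005 and τ = 1 ms, discretized at 2 µs as a one-pole IIR
filter. Because the residual is unbalanced across the sign flips, a static
off-center spin acquires a position-dependent phase error; averaging
cos(φ(x)) over a 0.2 m object extent converts this into a retention loss. The
defaults were chosen once so that the trapezoid–sinusoid retention gap at the
top of the m₁ grid is of the order of the in-vivo gap reported for these
protocols (~15%); this is a calibration of scale, not a fit, and no claim is
made that a and τ describe any particular scanner.

## Flow and blood model

The lumen is modeled as laminar (Poiseuille) flow in a circular cross
section: v(r) = 2·v̄·(1 − r²/R²) with uniform spin density, mean velocity
v̄ = 0.1 m/s, giving a velocity distribution uniform on [0, 2v̄]. The voxel
signal is the magnitude of the weighted complex sum over a 201-point radial
quadrature (annulus-area weights); at the largest m₁ in the grid this
quadrature is converged to ~0.4% against the closed-form sinc average. Blood
relaxation defaults are T1 = 1200 ms, T2 = 250 ms (1.5 T scale). Velocity is
constant during the preparation (≤ 28.4 ms): no acceleration (m₂) term, no
pulsatile waveform and no wall motion. Plug flow at a velocity where
φ = 2πk rephases coherently — a documented caveat of velocity-encoding
suppression, exercised in the tests. The "suppressed" threshold for the
plateau report is 5% of M0 (configurable); no numeric criterion exists in the
literature for this.

## RF permutations and B1

B1+ miscalibration is a scalar factor on every flip angle. At nominal B1 the
composite pulses equal their hard counterparts exactly; off-nominal, the
composite 180° has strictly higher spin-echo refocusing efficiency |β| (the
coefficient of the conjugating pathway m̄ → m′) than the hard 180°. Note that
the Frobenius deviation of the full net rotation operator from the ideal
180°y does *not* distinguish the two pulses — their net rotation-angle errors
are identical — so the package quantifies robustness by |β| and, at sequence
level, by the mean static-tissue retention over b1 ∈ [0.7, 1.3], where the
composite-refocused preparations rank above the all-hard ones despite being
1.6 ms longer. The composite −90° on a single phase axis has the same B1
sensitivity as a hard −90° and only adds 2.4 ms of decay, consistent with the
observation that it does not improve uniformity; its sub-pulse phases are
configurable since they are not published.

## Metrics

SNR uses the phased-array background-noise correction 0.695·S/σ (four-channel
value, configurable). The CNR-efficiency denominator is √T_sl·SL_th — the
published rendering is typographically ambiguous, and this reading is adopted
because efficiency conventionally scales with the square root of scan time
and because it inverts the published patient-study T1-weighted rows to a
single consistent scan time (~0.51 min/slice); the alternatives
√(T_sl·SL_th) and T_sl·SL_th are available behind a switch. The synthetic
fixture image uses Gaussian noise on a magnitude image; Rician bias is out of
scope since the noise estimate mimics a background-SD measurement.

## Simplified comparators

The DIR comparator is deliberately minimal: residual =
(1−f)·1 + f·|1 − 2e^(−TI/T1) + e^(−TR/T1)|, where f is the fraction of lumen
blood replenished during TI. It exists to exhibit the linear dependence on
(1−f) that iMSDE does not share, not to reproduce DIR protocol SNR. The
prepared-FSE signal model is single-echo, S = prep·(1−e^(−TR/T1))·e^(−TE/T2)
with the TE-compensation rule; echo-train weighting, variable-flip-angle 3D
readouts and their intrinsic black-blood effect are out of scope.

## What the synthetic studies do and do not show

The in-silico sweeps reproduce the *mechanistic* findings: retention follows
e^(−T/T2) exactly in the ideal case, the shorter-T2 compartment always loses
more, suppression saturates well below the top of the m₁ grid, sinusoids
retain at least as much as trapezoids under any non-zero eddy model with a
gap that widens with m₁, and the composite-180° permutation is the most
B1-robust. They do not reproduce in-vivo medians: real data add coil
profiles, pulsatile and turbulent flow, motion, Rician noise and
scanner-specific eddy spectra, none of which are modeled. Passing tests
therefore validate the implementation and the orderings, not absolute in-vivo
signal levels.

## Numerical choices

Moments use closed forms for the (symmetric) lobe shapes with adaptive
quadrature as the cross-check and the fallback for lobes split by a sign
flip; the two agree to 1e−6 relative. The design solver tolerance is 1e−4
relative; rotation operators are orthogonal to 1e−12; norm preservation of
relaxation-free propagation is 1e−12. Sweep outputs carry a provenance block
(config SHA-256, seed, γ̄) and deterministic paths are bit-reproducible. All
Monte-Carlo randomness (the fixture image) flows through an explicit
`numpy.random.default_rng` seed.
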