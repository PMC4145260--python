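# imsde — design and simulation of iMSDE black-blood preparations

`imsde` is a design toolkit and Bloch simulator for the improved
motion-sensitized driven-equilibrium (iMSDE) magnetization preparation used in
black-blood vessel-wall MRI, most prominently for carotid plaque imaging.
Black-blood contrast requires suppressing the signal of flowing luminal blood
so the wall–lumen boundary is conspicuous; iMSDE achieves this by dephasing
moving spins rather than by inversion-recovery nulling, so it does not depend
on blood being replenished between pulses — the failure mode of
double-inversion-recovery (DIR) in slow or recirculating flow.

The preparation is the event train

```
90°x —[G]— 180°y —[G][G]— 180°y —[G]— (−90°x) — spoiler
```

where the four gradient lobes `[G]` (trapezoidal or half-sine) around the two
refocusing pulses give the effective waveform a first moment

m₁ = ∫ s(t)·G(t)·t dt  (mT·ms²/m),

with s(t) the phase-sign profile flipped by each 180°. A spin moving with
velocity v acquires the phase φ = 2π·γ̄·m₁·v (γ̄ = 42.577 kHz/mT), so a voxel
of laminar blood (velocity spread ~10 cm/s) dephases and its magnitude signal
collapses, while static tissue refocuses completely and pays only the T2
decay e^(−T_iMSDE/T2) over the preparation interval T_iMSDE. The package
implements:

- **waveforms** — trapezoid/half-sine lobe synthesis, zeroth/first moments
  with refocusing sign inversion (closed form + quadrature), and a solver
  that designs the four-lobe set to a target m₁ under amplitude/slew limits;
- **rf_pulses** — hard and composite pulses (composite −90° = [−360°, 270°],
  composite 180° = 90°x–180°y–90°x), their rotation operators under B1+
  miscalibration, and the four preparation permutations NOCP / CP90 / CP180 /
  CP180_90;
- **bloch** — propagation of magnetization through a preparation timeline
  (rotations, relaxation, gradient phase for moving spins, spoiling) and
  voxel ensemble averaging over a laminar flow profile;
- **prep_sequences** — full preparation assembly, the TE-compensation rule
  (prescribed TE = TE_eff − T_iMSDE), a single-echo prepared-FSE signal
  model, and a minimal DIR comparator;
- **metrics** — SNR = 0.695·S/σ (four-channel coil correction), CNR
  efficiency (SNR_a − SNR_lumen)/(√T_sl·SL_th), theoretical retention and
  percent change;
- **experiments** — phantom-style retention sweeps for two gel T2 values
  (50/89 ms), sinusoid-vs-trapezoid comparison under a first-order
  eddy-current model, B1-uniformity maps across RF permutations,
  blood-suppression-vs-m₁ curves, and a seeded synthetic-image generator for
  the ROI metrics pipeline.

## Worked example

```python
from imsde import build_imsde, SpinState, propagate_prep
from imsde.experiments import residual_lumen_signal

prep = build_imsde(487.0, permutation="CP180", shape="sinusoid",
                   max_amplitude=30.0)
print(f"t_imsde = {prep.t_imsde:.2f} ms, |m1| = {abs(prep.m1_effective):.1f}")

tissue = propagate_prep(SpinState(T2=50.0), prep)
print(f"static retention (T2=50 ms): {tissue.M[2]:.4f}")
print(f"laminar lumen residual:      {residual_lumen_signal(prep):.4f}")
```

prints

```
t_imsde = 13.69 ms, |m1| = 487.0
static retention (T2=50 ms): 0.7605
laminar lumen residual:      0.0291
```

i.e. a 487 mT·ms²/m preparation costs static short-T2 tissue about 24% of its
signal through T2 decay while already suppressing laminar blood to ~3% of M0 —
the quantitative core of why a small m₁ suffices for T1-weighted imaging,
while T2-weighted protocols can absorb the preparation time into the
effective TE (`prescribed_te(50.0, 17.2)` → `32.8` ms) at no contrast cost.

The same experiments are scriptable from the shell:

```bash
imsde design --target-m1 487 --shape sinusoid
imsde sweep-phantom
imsde sweep-suppression
imsde b1-map
```

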