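# Methods

## Model

`intermtr` models brain tissue as two proton pools. The free water pool has
ordinary Bloch dynamics (T1_f, T2_f) and carries all observable signal. The
restricted (macromolecular) pool has a transverse lifetime of order 10 µs, so
only its longitudinal magnetization `Mz_r` is tracked; it relaxes with T1_r,
exchanges longitudinal magnetization with the free pool at the
pseudo-first-order rate `k_r` (weighted by the pool-size ratio
`F = M0_r/M0_f`), and is saturated by RF at the rate
`W(t) = π γ² b1²(t) G(Δ)`.

During a pulse the four-state system (Mx_f, My_f, Mz_f, Mz_r) is integrated
in the frame rotating at the free-pool Larmor frequency, with the RF field
written explicitly as a field rotating at the carrier offset
`Δω = ω_RF − ω_0,f`; the RF phase enters as a constant angle added to the
carrier. MT asymmetry is not modelled: the restricted-pool resonance is taken
equal to the free-pool resonance.

`G` is the super-Lorentzian absorption lineshape,

```
G(ω) = sqrt(2/π) · T2_r · ∫₀¹ du / |3u²−1| · exp(−2 (ω T2_r / (3u²−1))²),
```

the orientation average of Gaussian lines over the angle between the
inter-proton vector and B0. The integral diverges as ω → 0; following the
standard convention for on-resonance MT in balanced SSFP, offsets below
1 kHz return the finite value `G(0) = 1.4×10⁻⁵ s` (a per-tissue parameter).
The clamp is safe here because every interslice offset of interest is
≥ 2.5 kHz and the only sub-kilohertz use is the on-resonance readout itself.
`G(0)` is stored in seconds: an absorption lineshape has units of time, even
though it is sometimes printed as s⁻¹. Each pulse uses the single lineshape
value at its carrier offset (the usual pulsed-MT approximation) rather than
an instantaneous spectral decomposition.

## Sequence simulation

One slice acquisition is `n_dummy_pe + n_pe_steps` repetitions of
{shaped pulse, free evolution to the end of TR}. The same engine plays two
roles:

- **Saturation slice** (a neighbour being imaged): the pulse is applied at
  the interslice offset `δₙ = −BW·(1 + GAP/THK)·n·sign(GRAD)·ORD`, and the
  free-pool transverse magnetization is zeroed after every repetition. The
  imaging gradients dephase transverse magnetization completely at
  multi-kilohertz offsets, so only the longitudinal MT effect survives; this
  spoiling choice keeps the saturation train purely longitudinal, matching
  the physical picture of excitation pulses acting as saturation pulses for
  future slices.
- **Imaging slice**: on-resonance pulses with 180° RF phase alternation and
  retained transverse magnetization (balanced SSFP during its transient
  approach to steady state). `|Mxy_f|` is recorded at the echo time TE
  (measured from the pulse center) of each acquired repetition. The image
  signal is the trace value at the k-space center line: the first acquired
  line for centric ordering, line `⌈N·pf/2⌉` (partial Fourier fraction `pf`)
  for linear ordering.

An MT-weighted acquisition starts from thermal equilibrium, plays the
`n_prior_slices` neighbouring slices farthest-offset first (the slice
acquired earliest sits farthest away) with zero delay between slices, then
reads out. A reference acquisition either starts from equilibrium (the
fully-relaxed sentinel, `FULL_RELAXATION`) or plays the same prior slices
with a recovery delay after each, which is how the delay dependence of MTR
is swept. Dummy phase-encode pulses are included in prior slices as well,
since the scanner plays them; this is configurable through `n_dummy_pe`.

No α/2 preparation is modelled for the readout: the startup dummy
phase-encode pulses serve as the transient catch, as in the acquisitions the
presets describe.

## Numerical choices

- **Pulse integration**: adaptive Dormand–Prince 4(5) with scaled-RMS error
  control, default relative tolerance 1e-8 (absolute tolerance
  `1e-8 × M0_f`), initial step bounded by the carrier period so
  multi-kilohertz offsets are resolved from the first step. The stepper is
  compiled with numba because one experiment integrates thousands of pulses;
  step-size underflow raises rather than silently degrading. Tests verify it
  against a fixed-step RK4 oracle built on the public pure-Python right-hand
  side at 10× refinement (1e-4 relative agreement) and against an
  off-the-shelf adaptive RK45 solver.
- **Free evolution** is closed form: transverse decay `exp(−t/T2_f)` and the
  2×2 matrix exponential of the coupled longitudinal relaxation/exchange
  system, whose fixed point is thermal equilibrium. The per-TR propagators
  are precomputed once per slice train.
- **Pulse shape**: Gaussian-windowed sinc with time-bandwidth product
  `duration × bandwidth` and window σ = duration/3 truncated at the edges
  (a reproducible, conventional parametrization — acquisition protocols
  state only the shape family, bandwidth and duration). Peak amplitude is
  calibrated so `γ ∫ b1 dt` equals the nominal flip angle; a rectangular
  envelope is available for hard-pulse limits. RF durations in the presets
  (1.0/1.2/1.5 ms) pair with the stated bandwidths to give a time-bandwidth
  product ≈ 1.6 throughout.
- **Lineshape quadrature**: adaptive quadrature with the removable singular
  point u = 1/√3 declared as a breakpoint; results are cached per
  (offset, T2_r). Convergence is enforced at 1e-6 relative.
- **MTR map guard**: reference intensities below `1e-6 × robust max` (99th
  percentile, hot-pixel resistant) give NaN, excluded from ROI statistics so
  means stay unbiased. MTR maps are therefore ≤ 100% by construction.
- γ = 2.675×10⁸ rad s⁻¹ T⁻¹, fixed.

## Phantom generator

The generator emulates the study objects: cylinders (140 mm agar analogue,
120 mm saline control) and a brain-like slab — per-slice irregular ellipses
with a white-matter core, gray-matter ribbon and CSF border, boundary
wobble drawn from a seeded low-order Fourier series. Rendering assigns each
label the simulator's center-of-k-space MT-weighted and reference signals
(no k-space synthesis — the same convention used to analyse the
simulations), appends noise-only dummy slices at the first-acquired end per
protocol, and adds seeded Gaussian or Rician noise scaled to the mean object
signal.

The phantoms deliberately omit coil sensitivities, B0/B1 inhomogeneity,
banding, slice-profile effects and realistic anatomy. Passing end-to-end
tests therefore demonstrates the correctness of the signal model and the
image pipeline, not robustness to those real-world confounds.

The agar preset carries T1 = 1.7 s, T2 = 36 ms; its MT parameters
(F = 0.10, k_r = 40 s⁻¹, T2_r = 10 µs) are synthetic placeholders giving a
strong homogeneous MT effect, since agar exchange parameters were not
measured here.

## Problem sizes and defaults

Protocol presets carry the full acquisition sizes (128/256 phase-encode
steps, 30 dummy pulses, six prior slices); simulations at these sizes run in
seconds thanks to the compiled integrator, and the acceptance script uses
them unreduced. Generic property tests use shortened trains (32–64 PE steps,
2 prior slices) where the property under test is size-independent. Phantom
grids in tests are small (16×16×3) because rendering cost is dominated by
per-label simulation, not grid size.

## Known limitations

- MTR from the transient centric readout depends on where the center line
  falls; real partial-Fourier reconstruction is not modelled beyond the
  center-line index.
- The saturated-slice spoiling model (transverse zeroed each TR) is a
  deliberate idealization; any residual transverse coherence pathways at
  large offsets are neglected.
- Whether dummy phase-encode pulses are played in prior slices is
  scanner-dependent; the default includes them.
- The brain slab is a topological cartoon: suitable for contrast ordering
  and pipeline tests, not for anatomy-dependent effects.
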