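# intermtr

Simulation and analysis toolkit for **interslice magnetization-transfer (MT)
ratio imaging** of the brain with sequential multi-slice SSFP.

## The problem

In 2D multi-slice imaging, the excitation pulse of each slice irradiates every
other slice off resonance. Macromolecular (restricted-pool) protons have an
absorption spectrum several tens of kilohertz wide, so these off-resonance
pulses saturate them; exchange with free water then lowers the water signal.
A slice acquired immediately after its neighbours is therefore intrinsically
MT-weighted — no dedicated saturation pulse is needed. Acquiring the same
stack again with a long interslice delay (full T1 recovery) gives a reference,
and the pair yields a magnetization-transfer ratio map,

```
MTR = (I_ref − I_MT) / I_ref × 100%.
```

`intermtr` is aimed at sequence developers and quantitative-MRI researchers
who want to predict and analyse this effect: it provides

- a **two-pool Bloch–McConnell physics core**: free pool (Mx, My, Mz) plus a
  longitudinal-only restricted pool coupled by first-order exchange
  (pool-size ratio `F`, rate `k_r`), saturated at rate
  `W(t) = π γ² b1²(t) G(Δ)` with a super-Lorentzian lineshape `G`
  (on-resonance convention `G(0) = 1.4×10⁻⁵ s`), integrated with an adaptive
  Dormand–Prince 4(5) solver over shaped (Gaussian-windowed sinc) pulses;
- a **sequence simulator** for the multi-slice SSFP experiment: interslice
  offsets `δₙ = −BW·(1 + GAP/THK)·n·sign(GRAD)·ORD`, prior-slice saturation
  trains, a balanced readout with 180° phase alternation and centric or
  linear phase encoding, flip-angle/delay sweeps, and MT-accumulation
  analysis;
- an **image pipeline** (NIfTI-1 in/out): dummy-slice discard, slice
  interleaving, head masks, pixel-wise MTR maps, ROI statistics and
  difference-image SNR;
- a **digital-phantom generator** (agar/saline cylinders, brain-like
  WM/GM/CSF slabs) rendering MT-weighted and reference volumes with seeded
  noise, so the whole pipeline is testable without scanner data.

## Worked example

Simulate white matter under the whole-brain bSSFP protocol (flip 50°, TR
4.56 ms, 256 phase-encode steps, RF bandwidth 1600 Hz, 3 mm slices with
4.2 mm gap, six prior slices, 6 s reference delay):

```python
from intermtr import (get_protocol, get_tissue, mtr_percent,
                      simulate_mt_weighted, simulate_reference)

wm = get_tissue("white_matter")
protocol = get_protocol("whole_brain_bssfp")
mt  = simulate_mt_weighted(wm, protocol).center_k_signal
ref = simulate_reference(wm, protocol).center_k_signal
print(f"MT-weighted {mt:.4f}, reference {ref:.4f}, MTR {mtr_percent(mt, ref):.1f}%")
```

prints

```
MT-weighted 0.2670, reference 0.3761, MTR 29.0%
```

i.e. the six preceding slices (offsets 3840 … 23040 Hz) depress the
white-matter center-of-k-space signal by about 29% — the interslice MT
effect. The same from the command line, with a CSV table and a parameter
log:

```bash
intermtr simulate --protocol whole_brain_bssfp --tissue white_matter --out out/
intermtr sweep --kind flip --tissue wm --values 15,30,45,60,75,90 --out out/
intermtr make-phantom --kind brain_slab --protocol phantom --out out/
intermtr mtr-map out/phantom_mt.nii.gz out/phantom_ref.nii.gz --out out/map
```

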