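# Acquisition protocol presets for sequential multi-slice SSFP MTR imaging.
# Times in seconds, frequencies in Hz, lengths in mm, angles in degrees.
# reference_delay = inf means the reference slice starts from thermal
# equilibrium (fully relaxed, no prior-slice saturation).

[phantom]
tr = 4.56e-3
te = 2.28e-3
flip_deg = 50.0
n_pe_steps = 256
n_dummy_pe = 30
pe_order = "centric"
rf_duration = 1.0e-3
rf_bandwidth_hz = 1600.0
slice_thickness_mm = 4.0
interslice_gap_mm = 5.6
slice_order = "descending"
gradient_polarity = 1
n_prior_slices = 6
n_dummy_slices = 6
interslice_delay = 0.0
reference_delay = 6.0
partial_fourier = 1.0

[flip_angle_experiment]
tr = 4.11e-3
te = 2.06e-3
flip_deg = 50.0
n_pe_steps = 128
n_dummy_pe = 30
pe_order = "centric"
rf_duration = 1.5e-3
rf_bandwidth_hz = 1067.0
slice_thickness_mm = 5.0
interslice_gap_mm = 7.0
slice_order = "descending"
gradient_polarity = 1
n_prior_slices = 6
n_dummy_slices = 8
interslice_delay = 0.0
reference_delay = inf
partial_fourier = 1.0

[whole_brain_bssfp]
tr = 4.56e-3
te = 2.28e-3
flip_deg = 50.0
n_pe_steps = 256
n_dummy_pe = 30
pe_order = "centric"
rf_duration = 1.0e-3
rf_bandwidth_hz = 1600.0
slice_thickness_mm = 3.0
interslice_gap_mm = 4.2
slice_order = "descending"
gradient_polarity = 1
n_prior_slices = 6
n_dummy_slices = 6
interslice_delay = 0.0
reference_delay = 6.0
partial_fourier = 1.0

[meningioma]
tr = 4.15e-3
te = 2.08e-3
flip_deg = 60.0
n_pe_steps = 128
n_dummy_pe = 30
pe_order = "centric"
rf_duration = 1.2e-3
rf_bandwidth_hz = 1333.3333333333333
slice_thickness_mm = 5.0
interslice_gap_mm = 7.0
slice_order = "descending"
gradient_polarity = 1
n_prior_slices = 6
n_dummy_slices = 9
interslice_delay = 0.0
reference_delay = 5.0
partial_fourier = 0.75
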