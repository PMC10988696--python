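# Donor-only vs donor+acceptor fusion validation experiment.
# EGFP donor lifetime 2.44 ns; the fusion construct is fully bound with a
# true FRET efficiency of 0.25, so its quenched lifetime is 1.83 ns.

seed = 42
output_dir = "scratch/example_run"

[acquisition]
n_channels = 1024
channel_width_ns = 0.048828125
repetition_period_ns = 50.0
image_shape = [32, 32]

[irf]
center_ns = 2.0
fwhm_ns = 0.1

[fit]
tail_start_offset_ns = 0.200
chi2_threshold = 1.1
model_order = 2
min_photons = 400
include_offset = false

[groups]
donor = "EGFP"
sample = "mCherry-EGFP"

[[phantoms]]
label = "donor_cell_1"
group = "EGFP"
rect = [2, 2, 6, 6]
photons_per_pixel = 2500.0
tau_donor_ns = 2.44

[[phantoms]]
label = "donor_cell_2"
group = "EGFP"
rect = [2, 12, 6, 6]
photons_per_pixel = 2500.0
tau_donor_ns = 2.44

[[phantoms]]
label = "donor_cell_3"
group = "EGFP"
rect = [2, 22, 6, 6]
photons_per_pixel = 2500.0
tau_donor_ns = 2.44

[[phantoms]]
label = "donor_cell_4"
group = "EGFP"
rect = [12, 2, 6, 6]
photons_per_pixel = 2500.0
tau_donor_ns = 2.44

[[phantoms]]
label = "fusion_cell_1"
group = "mCherry-EGFP"
rect = [12, 12, 6, 6]
photons_per_pixel = 2500.0
tau_donor_ns = 2.44
e_true = 0.25
bound_fraction = 1.0

[[phantoms]]
label = "fusion_cell_2"
group = "mCherry-EGFP"
rect = [12, 22, 6, 6]
photons_per_pixel = 2500.0
tau_donor_ns = 2.44
e_true = 0.25
bound_fraction = 1.0

[[phantoms]]
label = "fusion_cell_3"
group = "mCherry-EGFP"
rect = [22, 2, 6, 6]
photons_per_pixel = 2500.0
tau_donor_ns = 2.44
e_true = 0.25
bound_fraction = 1.0

[[phantoms]]
label = "fusion_cell_4"
group = "mCherry-EGFP"
rect = [22, 12, 6, 6]
photons_per_pixel = 2500.0
tau_donor_ns = 2.44
e_true = 0.25
bound_fraction = 1.0
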