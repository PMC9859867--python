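# Demo cohort: 58 synthetic subjects emulating a single-centre stroke cohort
# (dynamic CTP at 2 s intervals over 58 s plus bolus-tracked three-phase CTA).
n_subjects: 58
seed: 7
out_dir: results
phantom:
  grid_shape: [64, 64, 32]
  voxel_size_mm: [2.0, 2.0, 4.0]
  frame_interval_s: 2.0
  duration_s: 58.0
  aif_t0_s: 8.0
  aif_alpha: 3.0
  aif_beta_s: 2.0
  aif_amplitude_hu: 350.0
  venous_delay_s: 6.5
  noise_sd_hu: 5.0
  baseline_hu: 40.0
segmentation:
  enhancement_threshold_hu: 50.0
  baseline_frames: 2
extraction:
  blood_hu: 40.0
  arrival_delta_hu: 10.0
  smoothing_window: 3
alignment_grid_step_s: 0.1
aspects_noise_sd: 1.0
nihss_noise_sd: 3.0
log_level: WARNING
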