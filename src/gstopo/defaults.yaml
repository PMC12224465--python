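# Generator and analysis constants. Every tunable the package uses lives here;
# RunConfig (gstopo.config) validates and overrides these values.
cohort:
  n_subjects: 60
  age_min: 6.0
  age_max: 85.0
  male_fraction: 0.4        # 240 male / 601 in the reference cohort
  fd_age_slope: 0.35        # standardized regression of mean FD on age
  fd_mean: 0.20             # mm, cohort-level location of mean FD
  fd_sd: 0.07               # mm, cohort-level spread of mean FD
  fd_min: 0.03              # mm, floor after clipping
  fd_max: 0.49              # mm, QC admission requires mean FD < 0.5
  fd_frame_loc: 0.18        # mm, location of non-spike per-frame FD
  fd_frame_sd: 0.08         # mm, spread of non-spike per-frame FD
  fd_spike_prob: 0.015      # per-frame probability of a motion spike (scaled by subject FD)
  fd_spike_floor: 0.55      # mm, spikes start above the 0.5 mm scrub threshold
  fd_spike_sd: 0.25         # mm, heavy tail of spike sizes
  scan_start_min: 480.0     # minutes from midnight (08:00)
  scan_start_max: 1080.0    # minutes from midnight (18:00)
  sleep_score_mean: 5.0     # Poisson mean of the sleep-quality summary score

grid:
  shape: [24, 24, 24]
  voxel_size: 3.0           # mm

bold:
  tr: 1.4                   # s
  t_frames: 200
  band_low: 0.01            # Hz, neural band
  band_high: 0.1
  local_amplitude: 0.5      # region-local signal SD (units of the unit-SD latent)
  white_noise_sd: 0.5       # iid thermal voxel noise SD
  background_noise_sd: 2.5  # spatially smooth, neural-band spontaneous fluctuations
  noise_smooth_fwhm: 6.0    # mm; spatial correlation scale of background noise
  respiratory_amplitude: 0.8
  respiratory_band: [0.15, 0.3]   # Hz
  brainstem_amplitude: 1.3
  brainstem_band: [0.03, 0.15]    # Hz
  motion_amplitude: 5.0     # striped artifact SD per mm of framewise displacement
  spike_amplitude: 3.0      # added at frames with FD > 0.5 mm

coupling:
  # name: [w0, w1, w2] with w(a) = w0 + w1*z(a) + w2*z(a)^2
  thalamus: [1.0, 0.35, 0.0]
  putamen: [1.0, -0.35, 0.0]
  sensorimotor: [1.0, -0.25, 0.0]
  nucleus_basalis: [1.0, 0.0, 0.3]
  fpn: [1.0, 0.0, 0.3]
  dan: [1.0, 0.0, 0.3]
  mpfc_caudate_visual: [1.0, 0.0, -0.3]
  gray_background: [1.0, 0.0, 0.0]

preprocess:
  fd_threshold: 0.5         # mm, scrubbing rule (strict >)
  min_retained: 20          # frames required for any regression
  gm_threshold: 0.2         # gray-matter probability mask (strict >)
  smooth_fwhm: 6.0          # mm

ica:
  k_sica: 125               # full-scale spatial components
  k_tica: 75                # full-scale temporal components
  desk_k_sica: 12           # desk-scale profile for synthetic grids
  desk_k_tica: 8
  tau_edge: 0.35            # noise if spatial energy outside gray exceeds this
  tau_hf: 0.5               # noise if time-course power above 0.1 Hz exceeds this
  tau_spike: 5.0            # noise if max |z| of time-course increments exceeds this
  tau_stripe: 0.5           # noise if negative lag-1 spatial autocorrelation exceeds this
  match_threshold: 0.4      # |r| for matching components to generator latents
  treat_global_negative_as_noise: true   # the "overall cortical negativity" toggle

glm:
  voxel_p: 0.001
  cluster_p: 0.05
  connectivity: 26          # 26 or 6
  z_cap: 8.2                # |z| ceiling for infinite statistics
  z_dialect: tcdf           # tcdf (t -> normal quantile) or fisher

qc:
  n_perm: 500               # desk profile (5000 at full scale)
  n_boot: 500
  parcel_block: 6           # voxels per side of the gridded parcellation blocks
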