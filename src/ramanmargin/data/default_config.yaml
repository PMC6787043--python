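# Default end-to-end run configuration.
# Every numeric default used by the pipeline code appears here; a run
# manifest records the hash of the resolved configuration.
seed: 0
excitation_nm: 785
out_dir: runs/demo

simulate:
  n_healthy: 28
  n_tumor: 29
  n_mixed: 0
  transit: null          # e.g. [healthy, healthy, mixed, tumor, tumor]
  noise_sd: 0.3          # cps, iid channel noise
  amp_cv: 0.015          # per-band lognormal jitter cv
  pool_cv: 0.22          # shared biochemical-pool factor cv
  cosmic_ray_rate: 0.1   # expected Poisson spikes per spectrum
  dye_probability: 0.0   # chance a spectrum carries surgical-ink peaks
  dye_amplitude: 15.0    # cps
  mixed_fraction: 0.5    # tumor fraction of mixed-label sites

preprocess:
  despike_window: 7      # channels, odd
  z_threshold: 10.0      # robust sds from the running median
  rel_threshold: 0.5     # fraction of the local median level
  window_width: 200.0    # cm^-1, baseline anchor window
  step: 100.0            # cm^-1, window shift
  quantile: 0.10         # low-quantile anchor fraction
  max_iter: 20
  tol: 1.0e-3            # relative baseline change to declare convergence
  region: null           # null -> instrument normalization region

bands:
  source: reference      # reference | select
  level: 0.95            # confidence level of the class envelopes
  min_width: null        # null -> 2x channel spacing
  merge_gap: null        # null -> 2x channel spacing
  top_k: null
  apply_dye_exclusion: true
  dye_centers: [693.0, 1260.0, 1348.0, 1398.0, 1541.0, 1597.0]
  dye_tolerance: 10.0    # cm^-1

classify:
  k: 3                   # principal components fed to the discriminant
  scale: false           # false -> covariance PCA, true -> correlation PCA
  refit_pca_per_fold: true

transit:
  threshold: 0.5         # posterior(tumor) call threshold
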