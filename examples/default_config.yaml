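# Default run configuration for the trusteeg pipeline.
# Load with:  trusteeg run-all --config examples/default_config.yaml --seed 1
# or in Python:  RunConfig.from_yaml("examples/default_config.yaml")
# Every field shown here at its shipped default.

experiment:
  n_participants: 110        # cohort size
  n_trials_per_scl: 60       # trials per source-credibility level
  scl_levels: [50, 70, 90]   # displayed credibility scores (%)
  sfreq: 500.0               # sampling rate (Hz); must tile 10 ms bins
  epoch_window_ms: [-200.0, 1000.0]   # stimulus at 0 ms
  n_channels: 64             # electrodes (256 supported; 64 is desk scale)
  seed: 0                    # overridden by --seed

choice:                      # P(trust | SCL); nondecreasing in SCL
  p_trust_by_scl: {50: 0.50, 70: 0.72, 90: 0.90}

effects:                     # condition-locked source effects
  - target_areas:            # the 28 credibility-loop parcels
      [S_subparietal-lh, S_subparietal-rh, G_Ins_lg_and_S_cent_ins-rh,
       G_and_S_cingul-Mid-Ant-lh, S_circular_insula_sup-rh,
       G_insular_short-lh, S_circular_insula_sup-lh, S_postcentral-rh,
       S_orbital_med-olfact-lh, Lat_Fis-post-rh, G_rectus-lh,
       G_and_S_cingul-Mid-Post-lh, S_precentral-sup-part-rh, G_orbital-lh,
       S_front_sup-lh, G_temp_sup-G_T_transv-rh, S_orbital-H_Shaped-lh,
       S_temporal_sup-lh, S_intrapariet_and_P_trans-lh, G_front_sup-lh,
       G_and_S_cingul-Ant-rh, G_front_inf-Opercular-rh, S_suborbital-lh,
       G_rectus-rh, G_front_inf-Opercular-lh, G_orbital-rh,
       G_temp_sup-G_T_transv-lh, G_precentral-rh]
    window_ms: [372.0, 796.0]   # post-stimulus latency of the effect
    amplitude: 0.15             # nA*m per dipole on trusting trials
    waveform: raised_cosine
    decision: trust
    scl_gain: {50: 0.8, 70: 1.0, 90: 1.2}   # mild SCL modulation
  - target_areas:            # same topography, weaker on distrust
      [S_subparietal-lh, S_subparietal-rh, G_Ins_lg_and_S_cent_ins-rh,
       G_and_S_cingul-Mid-Ant-lh, S_circular_insula_sup-rh,
       G_insular_short-lh, S_circular_insula_sup-lh, S_postcentral-rh,
       S_orbital_med-olfact-lh, Lat_Fis-post-rh, G_rectus-lh,
       G_and_S_cingul-Mid-Post-lh, S_precentral-sup-part-rh, G_orbital-lh,
       S_front_sup-lh, G_temp_sup-G_T_transv-rh, S_orbital-H_Shaped-lh,
       S_temporal_sup-lh, S_intrapariet_and_P_trans-lh, G_front_sup-lh,
       G_and_S_cingul-Ant-rh, G_front_inf-Opercular-rh, S_suborbital-lh,
       G_rectus-rh, G_front_inf-Opercular-lh, G_orbital-rh,
       G_temp_sup-G_T_transv-lh, G_precentral-rh]
    window_ms: [372.0, 796.0]
    amplitude: 0.0525           # 0.35 x the trusting amplitude
    waveform: raised_cosine
    decision: distrust
    scl_gain: {50: 0.8, 70: 1.0, 90: 1.2}

noise:
  source_noise_sd: 1.2       # per-dipole background current (nA*m)
  sensor_noise_sd: 3.0       # per-electrode white noise (uV)
  noise_color: white         # or one_over_f

n_dipoles: 2048              # source grid (>= 148; ~14 per parcel)
inverse_alpha: null          # null -> 1% of trace(G G^T)/channels
n_cognitive: 26              # cognitive-electrode subset size
artifact_threshold_uv: 100.0 # peak-amplitude trial rejection
baseline_window_ms: [-200.0, 0.0]
scan_alpha: 0.01             # per-bin significance level
scan_span_ms: [250.0, 800.0]
scan_correction: null        # or bh (Benjamini-Hochberg)
mec_window_ms: [500.0, 750.0]      # decoder feature window
mec_baseline_ms: [-200.0, 0.0]     # area-current noise-floor correction
n_boot: 10000                # bootstrap resamples for coefficient CIs
top_k: 28                    # reduced-model area count
test_fraction: 0.2           # holdout fraction of participants (22 of 110)
k_folds: 10                  # grouped cross-validation folds
l2_c: 1.0                    # inverse L2 penalty strength
out_dir: null
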