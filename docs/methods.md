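# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `trusteeg` pipeline.  It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## 1. Experimental design being emulated

Each participant answers 180 two-alternative questions, 60 at each
source-credibility level (SCL ∈ {50, 70, 90} %), and either trusts or
distrusts the displayed hint.  Trials are grouped into six basic cases
(T₅₀, D₅₀, T₇₀, D₇₀, T₉₀, D₉₀) and their unions A_s = T_s ∪ D_s,
T = ∪T_s, D = ∪D_s.  All condition logic goes through a single
`CaseLabel` predicate (SCL or ANY × decision or ANY), so every hypothesis
contrast is two case selections and no contrast has special-cased code.

The cohort defaults to **110 participants**.  Decisions are Bernoulli with
P(trust | SCL) = 0.50 / 0.72 / 0.90.  The 50 % level is a fair coin by
design (an uninformative source); the 70/90 values were fixed once so that
the trust rate roughly tracks the displayed score, which reproduces the
qualitative rate-vs-credibility relationship the behavioural test (χ² and
one-sided Cochran–Armitage trend) is meant to detect.

## 2. Forward model

A current dipole inside a homogeneous conducting sphere (radius 9 cm,
conductivity 0.33 S/m, insulating exterior) has an exact surface potential;
`headmodel.py` derives it by summing the interior Legendre expansion in
closed form (the module docstring gives the expression).  The test suite
checks the implementation against an independently coded truncated series
to 1e-8 relative.

* Electrodes: quasi-uniform (Fibonacci) points on the upper hemisphere;
  64 by default, 256 supported.  Gain columns are average-referenced.
* Sources: 2,048 radially oriented dipoles on a shell at 0.8 R, grouped
  into 148 labeled parcels (74 Destrieux-style structures × hemisphere)
  realised as jittered angular patches.  Geometry is schematic — only the
  label structure carries meaning downstream — with one deliberate
  exception: the 28 "credibility loop" parcels (the default effect
  targets) are placed beneath the vertex so that effects injected there
  are visible in the cognitive-electrode average, as they must be for the
  interval scans to have a ground truth.  Patch jitter is drawn from a
  fixed internal seed: the head is part of the model, not of the
  experimental randomness.
* The cognitive-electrode subset defaults to the 26 channels nearest the
  vertex.  Note that a 26-of-32 subset of an average-referenced montage is
  nearly the global mean (≈ 0); the subset is only meaningful against a
  denser montage, which is why effect-sensitive tests run at 64 channels.

## 3. Epoch generation

Per trial: condition effect + background + sensor noise, sampled at 500 Hz
over [−200, 1000) ms (600 samples), stored float32 in µV.

* **Effects.**  A raised-cosine waveform over a latency window (default
  [372, 796) ms) applied with equal amplitude to every dipole of the
  target parcels and projected through the gain.  Defaults: trusting
  trials 0.15 nA·m per dipole, distrusting trials 0.35×, both scaled
  ×0.8/1.0/1.2 at SCL 50/70/90.  The amplitude was set so that the summed
  projection peaks near 4 µV in the cognitive ERP — the size of a healthy
  late positive component — against ~10 µV single-trial background.  This
  gives every contrast the analysis tests (T vs D, and between SCL levels
  within a decision) a nonzero ground truth.
* **Background.**  White per-dipole current noise (1.2 nA·m) projected
  through the gain, plus white 3 µV sensor noise.  The projected-noise
  distribution is sampled directly in sensor space through a Cholesky
  factor of its exact covariance σ²GGᵀ + σₑ²I — distribution-identical to
  materializing dipole noise, without trials × dipoles × samples arrays.
  An optional 1/f spectral shaping reweights the noise in frequency while
  preserving total power.  `project_sources` exposes the raw linear map so
  superposition is testable exactly.
* **Determinism.**  Draws are keyed by (experiment seed, participant id,
  stream), so simulating the cohort at once or streaming it participant by
  participant is bit-identical — the pipeline exploits this to keep memory
  flat at full cohort size.

What the generator does **not** emulate: ocular/muscle artifacts (trial
rejection is exercised by injected spikes in tests instead), volume
conduction through realistic skull/scalp layers, between-participant
anatomical variability, latency jitter, and temporally autocorrelated
effect shapes.  Passing tests therefore demonstrate the statistical
machinery, not robustness to real-world EEG pathology.

## 4. Preprocessing and ERPs

Trials whose absolute amplitude exceeds 100 µV are dropped (a
deterministic stand-in for interactive artifact screening); per-trial,
per-channel baseline means over [−200, 0) ms are subtracted; case ERPs are
pointwise trial means.  The cognitive ERP averages the 26-channel subset.

## 5. Inverse solution and area currents

`M = Gᵀ(GGᵀ + αH)⁺` with H the average-reference centering matrix, so the
regularizer acts in the rank-deficient sensor space.  Default
α = 0.01 · trace(GGᵀ)/n_channels; α = 0 gives the pure pseudo-inverse with
sLORETA's exact zero-localization-error property (verified for all 148
parcels, and for sources simulated on a finer grid than the operator's —
no shared-lead-field shortcut).  Standardization divides dipole j by
√(MG)ⱼⱼ, clipped below at 1e-12 of its maximum.  Parcel current is the
mean |standardized current| over the parcel's dipoles (magnitudes, so
opposing orientations cannot cancel); point-source *localization* uses the
peak dipole instead, since a parcel mean dilutes a sharp peak.

## 6. MEC features and the noise-floor correction

μ_b(t₁,t₂) is the trapezoidal integral of parcel b's current over the
closed sample span of the half-open interval [t₁,t₂) (10 ms grid, so
adjacent intervals add exactly).  Decoder features use μ_b(500, 750),
computed from the averaged ERP of each (participant, SCL, decision) cell;
empty cells are simply absent.

The magnitude aggregation has a positive noise floor proportional to the
cell average's residual noise, i.e. ∝ 1/√(trials in the cell).  Because
trial counts differ systematically between cells (a distrust cell at
SCL 90 averages ~6 trials, a trust cell ~54), raw charges would encode
*how many trials a cell has* — which correlates with the decision label —
rather than how active a parcel is; a decoder fed raw charges decodes the
design, not the brain.  Two corrections make the feature pivotal under the
null:

1. each parcel's mean pre-stimulus current level is subtracted, scaled by
   √((1+1/m)/(1−1/m)) to undo the variance deflation/inflation that
   sensor-space baseline correction (over the same m samples) imprints on
   pre- vs post-stimulus noise;
2. the corrected current is divided by the cell's grand-mean baseline
   level, expressing it in units of the cell's own noise floor (akin to
   noise-normalized source estimates).

Under the null the resulting feature vector's distribution is independent
of the cell's trial count, so zero-effect cohorts decode at chance; the
suite verifies that the chance-level accuracy estimated over 20 seeded
null cohorts lies in [0.40, 0.60] (single-seed values fluctuate by
several percent because the 148-feature model freely anti-learns noise).  Corrected
charges can be negative.  The raw (uncorrected) chain remains available
via `baseline_ms=None` and is exactly linear in the input amplitude; the
corrected chain is scale-invariant instead — both properties are tested.

## 7. Interval scan

Per 10 ms bin of [250, 800) ms, the per-trial cognitive-ERP bin means of
two cases are compared with a two-sided Mann–Whitney U test: exact null
enumeration for pooled samples ≤ 12 without ties, tie-corrected normal
approximation otherwise.  Bins with p ≤ α (default 0.01) are flagged;
maximal runs of consecutive flagged bins are reported with the run's
maximum per-bin p as its (conservative) summary.  No multiple-testing
correction is applied by default — each scan probes one hypothesis at
different latencies — but Benjamini–Hochberg is available.  Type-I
calibration of the per-bin rate (0.01 ± 0.01 under null scans across 100
seeds) is part of the suite.

Per-trial values (rather than per-participant means) are used as the
scan's samples: they carry the degrees of freedom that per-case averaged
signals imply, and they keep the scan defined for cases that exist only
within one participant.

## 8. Decoder

Observations: MEC rows with SCL ∈ {70, 90} (SCL 50 is the chance
baseline and is excluded), label = decision, group = participant.  The
model is logistic regression on train-standardized features with an L2
penalty (inverse strength C = 1): with 148 features against ~350 rows an
unpenalized fit is ill-conditioned.  The fit is verified against an
independent Newton/IRLS solver of the same objective to 1e-6.

* **Uncertainty:** nonparametric bootstrap over observations (default
  ×10,000; any resample missing a class is redrawn), reporting mean β and
  2.5/97.5 percentile intervals per area.  On label-permuted data ≥ 90 %
  of the 148 intervals cover zero.
* **Reduced model:** the k = 28 areas with largest mean |β| (ties broken
  by the fixed parcel order), refit and evaluated alongside the full
  model.
* **Validation:** a 20 %-of-participants holdout (22 of 110 → 352/88
  observation rows when all cells are present) and 10-fold
  participant-grouped cross-validation with pooled out-of-fold metrics
  (accuracy, F1, precision, recall, AUC, and raw plus row-normalized
  confusion matrices).  Participants never straddle a split.

## 9. Problem sizes and determinism

The full default configuration (110 participants × 180 trials, 64
channels, 2,048 dipoles) runs end-to-end in a few minutes on one CPU; the
test suite exercises scaled versions (296–592 dipoles, 32–64 channels,
4–36 participants) chosen to probe the same properties at desk scale, with
the zero-effect chance check at 36 participants/32 channels and the
headline decoder check at the full cohort.  Every stage is deterministic
given (config, seed); two runs with the same seed produce byte-identical
artifacts, and the run manifest records the config hash, seed and library
versions.

## 10. Known limitations

* The spherical single-shell head and schematic parcel geometry make
  localization easier than with realistic anatomy; the zero-error and
  top-3 recovery results should be read as algebra checks, not anatomical
  claims.
* The synthetic effect is identical across participants; decoding
  performance at the default settings sits near ceiling, unlike real
  cohorts where between-participant variability dominates.  The
  interesting regimes are reachable by lowering `amplitude` or raising
  the noise fields in the config.
* Per-cell averaged ERPs mean the decoder sees at most four observations
  per participant; single-trial decoding is out of scope.
* The bootstrap treats observations as exchangeable rows and ignores the
  participant grouping when resampling.
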