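# trusteeg

EEG analysis of **source-credibility evaluation**: from epoched EEG with
trust/distrust decision labels to event-related potentials, distributed
source imaging, per-area charge features, significant-interval scanning,
and a decoder of trusting vs distrusting decisions.

## The scientific problem

When people weigh advice from a source of known reliability — here, a
"hinting student" whose overall test score (the source-credibility level,
SCL = 50/70/90 %) is displayed on every trial — their decision to trust or
distrust the hint leaves a measurable electrophysiological trace.  The
questions this package operationalizes:

1. Does the trust rate rise with SCL? (χ² independence and
   Cochran–Armitage trend tests on the decision-by-SCL counts.)
2. *When* does cortical activity differ between experimental cases
   (T₅₀…D₉₀ and their unions A_s = T_s ∪ D_s, T, D)?  The **cognitive
   ERP** — the ERP averaged over a 26-electrode subset — is compared
   bin-by-bin on a 10 ms grid with two-sided Mann–Whitney U tests; maximal
   runs of consecutive significant bins are the *longest joint intervals*
   of a contrast.
3. *Where* and *how strongly*?  Sensor ERPs are mapped to 2,048 cortical
   dipoles with **sLORETA**: the minimum-norm estimate
   `ŝ = Gᵀ(GGᵀ + αH)⁺ x` standardized dipole-wise by the resolution-matrix
   diagonal, `ŝⱼ/√(MG)ⱼⱼ`, which localizes noiseless point sources with
   zero error.  Currents are aggregated to the 148 Destrieux-style parcels.
4. Can the decision be decoded?  The **mean electric charge (MEC)**
   `μ_b(t₁,t₂)` — the time integral of parcel *b*'s mean current over
   `[t₁,t₂)` on the 10 ms grid, 500–750 ms by default — yields one
   148-feature row per (participant, SCL, decision) cell.  An
   L2-regularized logistic regression with bootstrap coefficient intervals
   (×10,000 by default) classifies trust vs distrust, evaluated by a
   participant-grouped holdout and 10-fold grouped cross-validation; a
   reduced model keeps the 28 areas with the largest |β|.

Because no public recordings exist for this paradigm, the package includes
a first-class **synthetic cohort generator**: an analytic
dipole-in-a-sphere forward model, SCL-dependent Bernoulli decisions, and
condition-locked effect waveforms injected in named parcels over a chosen
latency window, plus realistic background noise.  Every stage of the
analysis is therefore testable end-to-end against known ground truth.

## Worked example

`examples/04_mec_decoding.py` runs the whole feature chain on a
16-participant cohort at 64 channels and decodes the decisions:

```
64 observations (SCL 70/90 cells), 148 features
holdout:  accuracy 1.000  F1 1.000  AUC 1.000
grouped CV: accuracy 1.000  F1 1.000
top 5 areas by |beta| (effects were injected in the credibility loop):
  G_rectus-lh
  G_temp_sup-G_T_transv-rh
  S_subparietal-rh
  Lat_Fis-post-rh
  S_temporal_sup-lh
```

Observations are per-cell averaged ERPs (SCL 50 % — the random-response
baseline — is excluded), so 16 participants × 2 levels × 2 decisions give
up to 64 rows.  The decoder saturates because the synthetic effect is
clean and cell averages are low-noise; the informative areas it ranks
highest are exactly the parcels the generator injected.  With zero
injected effects the same pipeline stays at chance (see
`tests/test_acceptance.py`).

Other examples: `01_simulate_cohort.py` (behavioural trend),
`02_interval_scan.py` (longest significant interval recovery),
`03_source_localization.py` (zero localization error),
`05_full_pipeline.py` (one `run_all` writing every artifact).

A thin CLI mirrors the stages:

```bash
trusteeg run-all --config examples/default_config.yaml --seed 1 --out out/
trusteeg simulate|erp|scan|localize|mec|classify --out out/
```

## Layout

```
src/trusteeg/
  labels.py          148-parcel nomenclature; credibility-loop list
  headmodel.py       analytic spherical lead field (closed form)
  synthdata.py       decisions + forward-modeled epochs
  containers.py      EpochSet + HDF5/CSV round-trips
  erp.py             case algebra, rejection, baseline, (cognitive) ERP
  inverse.py         sLORETA operator, area currents, localization
  mec.py             mean-electric-charge features
  scanstats.py       Mann-Whitney interval scan, trust-rate tests
  decision_model.py  bootstrap logistic decoder, grouped CV, metrics
  pipeline.py        RunConfig + run_all orchestration
  cli.py             thin click wrapper
docs/methods.md      model, parameters, design decisions, limitations
examples/            one short narrative script per capability
```
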