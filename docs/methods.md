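# Methods and design notes

## The analysis pipeline

The pipeline turns (signals, annotations) into per-seizure features and
then into statistics and predictions:

1. **Periods.** Per seizure: ictal = [onset, offset]; near-seizure = up to
   600 s before onset, truncated at the previous seizure's offset (and the
   recording start). A zero-length near-seizure window is legal and yields
   no segments.
2. **Montage.** Bipolar derivation over consecutive contacts within each
   electrode array. The default layout (2 assemblies × 2 arrays ×
   4 contacts = 16 contacts) gives 4 arrays × 3 pairs = 12 bipolar
   channels. No further artifact rejection is applied; the bipolar montage
   itself suppresses common-mode artifacts.
3. **Segments.** Windows are filtered with zero-phase (forward–backward)
   order-2 Butterworth band-passes into δ(0.5–4), θ(4–8), α(8–12),
   β(12–25), γ(25–45) Hz, then cut into non-overlapping 2.5 s segments
   tiled from the onset boundary — backward from onset for the near-seizure
   period, forward from onset for the ictal period — so a segment edge
   always coincides with the onset sample; the partial remainder at the far
   end is dropped (n_segments = ⌊window/2.5 s⌋). Each (segment, channel,
   band) series is normalized to zero mean, unit variance. Segments
   containing a constant series are flagged invalid and excluded (never
   NaN-propagated); seizures shorter than 2.5 s therefore contribute no
   ictal segments.
4. **REN.** For each segment, band and unordered channel pair (66 pairs
   for 12 channels), amplitude histograms are built on shared equal-width
   bins spanning the pooled min–max of the two series, and
   REN = max(KL(p‖q), KL(q‖p)) in nats. Since every series is normalized,
   REN responds to distribution *shape* (tails, skew, multimodality), not
   scale. Grand-average REN = mean over all pairs and segments of a
   (seizure, band, period); the 5×2 grand averages are the 10 features.
5. **Taxonomy.** Consecutive seizures whose offset-to-onset gap is ≤ the
   ISI cutoff (24 h default; 8 h for robustness) share a cluster; isolated
   seizures have no neighbour within the cutoff on either side. Cluster
   members split into cluster-last and cluster-non-last; the first member
   additionally carries the cluster-first flag (in a 2-seizure cluster the
   first member is both cluster-first and cluster-non-last).
6. **Statistics.** Per patient, band and period, isolated seizures are
   compared against cluster-first, cluster-non-last and cluster-last with
   two-sided Wilcoxon rank-sum tests; all cells across patients, bands,
   periods and comparisons form one pooled Benjamini–Hochberg family at
   q = 0.05 (per-patient familying available). Significant cells are
   tallied by which group's median was higher.
7. **Prediction.** Per patient and task: outer 5-fold stratified CV; inner
   5-fold stratified grid search on the outer-training portion selecting
   hyperparameters by mean validation AUC; inverse-class-frequency
   weighting during fitting; positive-class precision/recall/F1 and AUC
   from continuous scores on the outer test folds. Tasks: *next seizure*
   (positive = cluster-non-last; negative = isolated + cluster-last, all
   seizures included) and *cluster onset* (positive = cluster-first,
   negative = isolated, others excluded). Patients with fewer than 10
   members in either task class are excluded from that task.

## Analytic baselines

With positive-class prevalence r and a chance predictor that predicts
positive with probability q (default 0.5): precision = r for both
baselines; recall = q (chance) or 1 (always-positive); F1 = 2rq/(r+q) and
2r/(r+1); AUC = 0.5 for the chance predictor and undefined for the
constant predictor. These follow from expectations of the confusion-matrix
entries and bound what class imbalance alone can achieve; the
always-positive baseline can post a high F1 at high prevalence while
producing nothing but false alarms on the negative class.

## The synthetic cohort generator

The generator emulates the structure of a chronic ambulatory iEEG study:

- **Schedules** by an alternating-renewal process: blocks (one isolated
  seizure, or a cluster of ≥ 2) separated by gaps of cutoff + Exp(126 h);
  within clusters, offset-to-onset intervals Exp(2 h) truncated to
  [72 s, 0.95 × cutoff]. Because gaps straddle the cutoff by construction,
  threshold labelling must recover the generated categories *exactly* —
  this is tested, not assumed. Cluster sizes are 1 + Geometric(p = 0.15)
  capped at 30 (mean ≈ 7.7); block-type rates default to ≈ 0.075 isolated
  events and ≈ 0.085 clusters per patient-day; durations are log-normal
  with mean 39 s, SD 63.6 s, clipped to [1, 300] s. These defaults follow
  the per-patient event statistics reported for long ambulatory
  monitoring of refractory epilepsy.
- **Signals**: each contact is a sum of independent band-limited Gaussian
  noise components (one per physiologic band, 1/f-like amplitudes) — the
  simplest background whose band decomposition is controllable. Ictal
  stretches get a 2–5× amplitude ramp so they are visibly distinct; no
  spike morphology is modelled because REN does not require it.
- **Type effects**: within 0.25 s blocks, every contact's band component
  is multiplied by an independent log-normal gain with unit mean and
  log-spread σ (baseline σ₀ = 0.30). The segment amplitude distribution is
  then a Gaussian scale mixture whose tail weight grows with σ, and
  independent per-contact draws make channel *shapes* diverge — exactly the
  channel REN reads, and the only channel that survives per-segment
  normalization (mean shifts and common gains do not). Cluster seizures
  get σ₀(1 + effect_near) near seizure in the effect bands (β, γ by
  default); cluster-non-last seizures get σ₀/(1 + effect_ictal) ictally —
  the ictal reduction is confined to non-last members because no ictal
  difference is expected between isolated and cluster-last seizures. With
  both effects zero, the two types are generated by identical code paths
  and are statistically indistinguishable.
- The "large" effect used in the validation suite is effect_near = 2.0
  (spread ratio 3×) with effect_ictal = 1.0, fixed by a Monte-Carlo over
  replicate seeds before the test suite was frozen: at these values the
  near-seizure group difference is detected at p < 1e-10 with ~20 isolated
  vs ~150 cluster seizures, and the measured group difference grows
  monotonically over effect_near ∈ {0, 0.5, 2.0}.

What the generator does **not** emulate: physiologic waveform morphology,
spatially correlated contacts, non-stationary background, telemetry
drop-outs, or circadian structure in seizure timing. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that a
distribution-shape effect of the stated size is recoverable; they say
nothing about effect sizes in real recordings. Signals are materialized
only around the analysis windows (sparse chunks on the absolute timeline);
reads outside them return deterministic background fill.

## Numerical choices

- **REN estimator**: 10 equal-width bins over the pooled range (≈ 100
  expected counts per bin for 1000-sample segments); 1e-10
  pseudo-probability per bin before renormalization avoids infinite KL
  from empty bins; natural logs (nats). All three are configurable; pooled
  min–max shared edges make REN(x, x) exactly 0 and symmetric by
  construction. The all-pairs sweep sorts each channel once and histograms
  via order statistics — bit-identical to `np.histogram` on the same edges
  (verified against an independent brute-force implementation to 1e-12).
- **Filtering** is applied once per window and then segmented, rather than
  per segment, to avoid filter edge transients inside every 2.5 s segment;
  zero-phase application avoids latency misalignment with onset.
- **Rank tests**: exact enumeration for tie-free samples with min(n) ≤ 20,
  a seeded permutation null for small tied samples, tie-corrected normal
  approximation otherwise. Gaps exactly at the ISI cutoff count as
  clustered (≤); the ISI is measured offset→onset by default with
  onset→onset available in configuration, since either convention is
  defensible.
- **Prediction**: features standardized per outer-training fold for
  scale-sensitive models (logistic regression, SVM, k-NN); k-NN has no
  weighting notion and is fit unweighted; hyperparameter grids are small
  standard grids sized to tens–hundreds of samples (C over 10^{-2..2},
  k ∈ {3,5,7,11,15}, tree depth ∈ {2,3,5,8,∞}, forest {100,300} trees ×
  depth {3,8,∞}). AUC is flagged undefined on single-class test folds.
  Feature rows missing any of the 10 features (e.g. sub-2.5 s seizures)
  are dropped from prediction, not imputed.
- **Sample-size sweeps** hold a fixed stratified 20 % test split, draw
  stratified training subsets ({20..100} % or 2^{4..9} samples, capped at
  the pool), repeat 5× per size with a fixed model seed (so the 100 %
  subset has zero repeat-SD), and report mean ± SD test AUC.
- **Seeds**: a single global seed deterministically derives per-stage
  seeds; identical configuration reproduces annotations, signals and
  evaluation reports bit-for-bit.

## Problem sizes in the test suite

The validation suite runs the full signal pipeline at reduced scale:
60 s near-seizure windows (600 s in the library default), cohorts of
~150–300 seizures per patient, and statistics calibration over 200
replicate null families drawn at the grand-average-feature level (rank
tests are distribution-free, so feature-level nulls calibrate the
Wilcoxon + BH machinery; a full signal-level null cohort additionally
backs the chance-level prediction check). The zero-effect AUC check
averages over three replicate ~200-seizure cohorts to control the
per-cohort sampling error of cross-validated AUC (≈ ±0.07 at that size).

## Known limitations

- Grand averaging deliberately discards within-seizure REN trajectories.
- The threshold taxonomy ignores differences in individual baseline
  seizure rates; statistical cluster detectors are out of scope.
- Real EDF recordings are read via `io_edf.read_edf` (requires `mne`), but
  the writing side of the package uses the documented raw float32 + JSON
  sidecar format only.
- Probability outputs of the classifiers are not calibrated; AUC and the
  threshold-based metrics at the default decision threshold are reported.
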