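# Methods

`dbserp` implements an EEG-based localization analysis for deep-brain-stimulation
(DBS) leads around the subthalamic nucleus (STN).  During low-frequency
stimulation (LFS; 3 or 5 Hz) each pulse evokes a scalp potential whose latency
and topography depend on where the stimulating contact sits: in the zona
incerta above the STN (ZI), the dorso-lateral motor STN (DLR) or the
ventro-medial associative-limbic STN (VMR).  The package turns a raw,
artifact-contaminated recording into an evoked response potential (ERP),
summarizes it with engineered features, and localizes the contact with
single-feature biomarkers and a linear-SVM classifier.  Because clinical
recordings of this kind are not freely available, a synthetic-data generator
reproduces the statistical structure of such sessions so that the whole chain
is testable end to end.

## Cleaning chain

Four steps, in order:

1. **DC removal** — subtract each channel's mean.
2. **Stimulus-artifact removal** — the biphasic stimulus transient is
   synchronous on all electrodes, so detection runs on the across-channel mean
   signal m(t): samples with |m − mean(m)| > 3·SD(m) are flagged, runs are
   extended by ±2 ms and merged, and every channel is linearly interpolated
   (first-degree fit) between the last clean sample before and the first clean
   sample after each span.  The SD is computed over the whole recording.  The
   ±2 ms margin and the channel-mean detection domain are package conventions;
   the detector threshold (3 SD) is exposed in `PipelineConfig`.
3. **Average re-referencing** — subtract the instantaneous channel mean.
4. **Zero-phase band-pass** — windowed-sinc FIR, 0.5–40 Hz, transition widths
   0.5 Hz (low edge) and 5 Hz (high edge), applied forward and backward
   ("two-way") via FFT convolution on reflection-padded signals.  Zero phase
   means smooth peaks do not shift (< 1 ms), at the price of the well-known
   acausal smearing of the interpolated artifact region: cleaned signals can
   "rise" slightly before stimulus onset.  Tests therefore never assert strict
   pre-stimulus silence.

Recordings from a 128-channel net are reduced to the 64-channel layout by
inverse-distance-weighted interpolation over the k = 3 nearest electrodes.

## ERP, ROIs and features

Epochs span −50 to +150 ms around each pulse (half-open, 200 samples at
1 kHz); the ERP is the plain average over the up-to-2,400 trials of a session,
with the (n−1)-SD standard error.  The 64 channels are grouped into nine ROIs
(frontal / fronto-central / occipito-parietal × left / medial / right); ROI
traces are unweighted member means.  Per-channel z-scoring over the epoch time
course is available; features are computed on raw (non-normalized) ERPs by
default, with a config switch, because the source analysis does not state
which feeds the feature stage.

Seven engineered features are computed per location (64 channels + 9 ROIs)
and per window — very early (5–25 ms), early (45–55 ms), middle (50–100 ms),
late (100–149 ms), all half-open, overlapping by design: max/min peak
amplitude (µV), max/min peak latency (ms after onset, earliest sample on
ties), peak-to-peak, signed trapezoidal area (µV·ms), and energy.  "Energy"
is ambiguous between the conventional ∫x²dt and the literal (∫x dt)²; the
default is `integral_of_square`, the alternative is one config value away.
A full extraction is 7 × 4 × 73 = 2,044 features per session.

## Single-feature biomarkers

For a region pair, a feature is evaluated with a pooled-variance two-sided
t-test (Welch optional) and as a one-dimensional classifier: the ROC curve
over thresholds (oriented so AUC ≥ 0.5), a Youden-J-optimal cutoff (ties →
lower threshold), and stratified 5-fold cross-validation in which the cutoff
is fitted per training fold and applied to the held-out fold.  Precision,
recall, accuracy and AUC are reported as mean ± SD over folds, for train and
test sides.  The trapezoidal AUC is checked in the test suite against
exhaustive Mann–Whitney pair counting (ties ½).

## MRMR + linear SVM

MRMR selection uses plug-in mutual information on equal-frequency 3-bin
discretizations (values at a bin edge fall in the lower bin), making the
ranking invariant to monotone feature transforms and to column order.  The
criterion is the mutual-information difference (MID): step j maximizes
relevance(f) − mean redundancy(f, selected); MIQ (the quotient) is available.
Selection runs inside each training fold by default (leakage-safe); whole-table
selection is an option, since the source protocol is ambiguous on this point.

Classification is a linear SVM on the top-k features (default k = 25, grid
{5,…,80} available), standardized with training-fold statistics.  C is chosen
from {0.001, 0.01, 0.1, 0.5, 1, 2} as the single grid value with the best
mean validation accuracy across the 5 folds (ties → smaller C), and that C's
fold metrics are reported, matching the convention of one C per analysis.
Multiclass uses one-vs-rest or one-vs-one; precision/recall are
macro-averaged (the averaging convention is not stated in the source).  Five
standard analyses are emitted: ZI/VMR, ZI/DLR, DLR/VMR, and both multiclass
decompositions.

## Synthetic cohorts

A session is background + evoked field + artifact:

- **Stimulus schedule** — 5 Hz for 480 s or 3 Hz for 800 s, 2,400 pulses
  either way; recordings carry a short lead-in and an epoch-length tail so
  every pulse supports a full epoch.
- **Evoked components** — per (region, ROI), a Gaussian-windowed cosine at
  20 Hz (the "natural frequency" of STN-cortical evoked oscillations) whose
  positive peak sits at the configured latency.  Default latencies are the
  reported region medians (medial fronto-central 77/69/67 ms for ZI/DLR/VMR,
  right fronto-central 73.5/62/64 ms, occipital 80/71/92 ms); the left
  frontal ROI is silent (contralateral to stimulation).  The envelope width
  (20 ms SD) keeps the component's spectrum inside the 0.5–40 Hz analysis
  band.  Microvolt amplitudes for such recordings are not reported,
  so amplitudes are package conventions: ~5 µV raw at the medial
  fronto-central maximum, graded down to < 1 µV occipitally, chosen so the
  full 2,400-trial ERP resolves peak latency to ~1 ms.
- **Spatial model** — each ROI's waveform spreads to its member channels with
  weight 1 at the ROI centroid falling to 0.5 at the ROI edge; the summed
  scalp field is then projected to zero mean across channels at every
  instant.  Scalp potentials carry no net monopole, and only a zero-sum field
  is invariant under average re-referencing — without the projection, the
  reference step would cancel most of an all-positive topography.  A session's
  ground truth is therefore the *net* injected ROI trace (exposed on
  `SimulatedSession`), which is what the pipeline can actually recover.
- **Artifact** — a biphasic ±275 µV transient (~50× the largest evoked
  amplitude) over 2 ms at every onset, identical on all channels.
- **Background** — three independent Gaussian processes per channel, sampled
  jointly from their summed power spectrum: 1/f (12 µV, exponent 1), a 10 Hz
  alpha bump (6 µV, 1 Hz width) and white noise (10 µV).  Channels are
  spatially independent, which real EEG is not; tests that rely on ROI
  averaging therefore understate the spatial correlation of real noise.
- **Cohort** — 61 sessions (ZI 20 / DLR 23 / VMR 18), grouped four per
  virtual patient, generated lazily (a materialized full cohort would need
  ~15 GB).  Between-session variability is an amplitude gain uniform in
  ±20 %, a global latency shift (SD 3 ms), and independent per-ROI latency
  scatter: 6–9 ms SD over frontal/fronto-central ROIs and 20 ms SD over the
  occipito-parietal row.  The per-ROI scatter is calibrated so the simulated
  between-session effect sizes reproduce the reported t-statistics of the
  three headline comparisons (t ≈ −4 for ZI/VMR medially, −2.3 for ZI/DLR on
  the right, 2.9 for DLR/VMR occipitally); a single global 3 ms jitter would
  make the occipital 21 ms DLR–VMR gap trivially separable and invert the
  observed difficulty ordering of the region pairs.  `effect_scale=0`
  collapses all regions onto the mean template for null experiments.

### What the generator does and does not emulate

It reproduces: pulse-locked evoked components with region-dependent latency
and amplitude, realistic artifact-to-signal ratios, 1/f + alpha spectra,
trial-count SNR scaling, and cohort-level effect sizes.  It does not model:
volume conduction (spatially correlated noise, true dipolar topographies),
antidromic vs orthodromic response components, non-stationarity (drowsiness,
electrode drift), or patient-level correlation beyond the session grouping.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour at realistic SNR, not clinical performance on patient data; the
reported headline accuracies were measured on 61 clinical sessions that are
not publicly deposited.

## Numerical choices

- Intervals are half-open, times are reported in ms relative to stimulus
  onset, internal indexing is 0-based.
- Extremum ties resolve to the earliest sample; C-grid ties to the smaller C;
  MRMR ties to the earlier column.
- The EDF writer zero-pads to whole seconds and uses one symmetric physical
  range per channel (quantization error ≤ max|x|/32767); it inverts MNE's
  EDF affine exactly, so write→read round-trips to quantization precision.
- Stratified folds are seeded; every stochastic stage consumes an explicit
  seed, and identical seeds give identical outputs.  An optional
  group-by-patient fold mode avoids leakage between contacts of one patient.
- Problem sizes in the test suite: end-to-end cohort checks run 61 sessions
  of 120 s (600 trials) — the stability analysis shows feature estimates are
  stable well below 600 trials — while protocol-count checks (2,400 epochs,
  61 full sessions) and the stability analysis itself run at the full 480 s.

## Known limitations

- The detector's channel-mean statistic assumes artifact synchrony; lead
  artifacts affecting single channels would need a per-channel variant.
- Session-level z-score pooling across conditions ("for all conditions") is
  approximated by per-session normalization with a pooling flag.
- The ROC cutoff model uses a single threshold; features whose class
  distributions differ in spread rather than location are poorly served.
- With 61 sessions, CV metrics carry fold noise of several percentage points;
  reports always include the per-fold SD.
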