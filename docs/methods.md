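# Methods

This note documents the models, defaults and numerical choices behind the
`srk` package, in the order the pipeline runs them, and states what the
synthetic-data experiments do and do not establish.

## Behavioural scoring

The four accuracy formulas are implemented exactly as stated in the README.
Choices that were genuinely open:

- **Skill formula parse.** The product form
  `[1 − (L − L_opt)/L] · [err_MAX/(err_MAX + err)] · 100`, clipped to
  [0, 100], was adopted because it is the only reading in which both named
  comparisons — path length and lateral error — reduce the score and a
  perfect run yields exactly 100. The relative-length factor is normalized by
  `L` (not `L_opt`); the alternative differs only in second order for small
  excess lengths.
- **Degenerate perfect run.** `err = err_MAX = 0` would make the error factor
  0/0; it is defined as 1. Distances below `1e-9 · max(1, L_opt)` are snapped
  to zero so a floating-point retrace of the ideal polyline scores exactly
  100.
- **`err_MAX` scope** is per run (the maximum over that run's samples), and
  distances are Euclidean point-to-polyline (closest segment) in screen
  units, since both trajectory and track are polylines.
- **Altitude weight `w`.** No functional form is specified for the
  consecutive-target discount, so `w` is a caller-supplied per-slot weight in
  (0, 1], default 1.
- **Cohen's d** uses the pooled standard deviation with n−1 denominators and
  raises on zero pooled SD rather than returning an arbitrary value.

## Preprocessing

Order is fixed — band-pass filter, optional EOG regression, 1-s epoching,
amplitude gate — because the stages do not commute (filtering after epoching
would ring across epoch edges; gating before filtering would act on drifts
the filter removes).

- **Filter**: 5th-order Butterworth, 2–45 Hz, applied zero-phase
  (forward–backward) by default; a causal mode exists. Offline analysis
  favours zero phase distortion; the effective magnitude response is squared.
- **Blink handling**: a per-channel least-squares regression of the EOG trace
  is provided as an optional linear blink-correction hook, off by default.
  The published online correction algorithm used by the original protocol is
  proprietary to its source and is out of scope here.
- **Artifact gate**: an epoch is flagged iff any channel sample *strictly*
  exceeds ±80 µV ("exceeding" is read as strict; a boundary sample at exactly
  80 µV passes). Rejection is idempotent and the flagged fraction is logged.
- **Channel exclusion** for the cortical path removes the Fp, FC, C, CP, T
  and TP groups by longest-prefix matching over the montage's group
  vocabulary, so "C" never captures "CP" and "T" never captures "FT"/"TP";
  on the 61-channel montage exactly 28 channels are removed and 33 remain.
  Whether FT7/FT8 belong in the exclusion set is ambiguous in the protocol's
  wording; the set is configurable and FT is kept by default.
  Classification keeps all 61 channels.

## Spectral features

- **PSD**: one Hanning-windowed periodogram per 1-s epoch (250 samples at
  250 Hz), giving exactly 1 Hz bins; power is Parseval-consistent (bin sums
  reproduce windowed mean-square power). No within-epoch Welch averaging —
  the 1 Hz resolution statement pins the estimator.
- **IAF**: mean PSD over clean rest epochs of the posterior (P, PO, O)
  groups; the IAF is the maximal 1-Hz bin in 7–13 Hz. If the peak is less
  than 1.2× the median in-range power, a warning is issued and the
  population default of 10 Hz is used.
- **Band scheme** (anchored to the IAF; edges configurable): Delta [2,
  IAF−6), Theta [IAF−6, IAF−2), Alpha High [IAF, IAF+2), Beta1 [IAF+2,
  IAF+11), Beta2 [IAF+11, IAF+16), Beta3 [IAF+16, IAF+20), Gamma [IAF+20,
  45]. The Alpha-Low gap [IAF−2, IAF) is deliberately left out, and edges are
  clipped to [2, 45] Hz with a warning. Seven bands are computed but only six
  enter matrices and classification; Delta is excluded from analysis by
  default (the 66 × 6 grid has no Delta column).
- **GFP**: no formula is fixed by the source protocol for per-band GFP; the
  adopted definition is the channel mean of band power per 1-s epoch — a
  global, channel-collapsed index in µV².
- **REF z-scoring**: per feature, `z = (x − mean_REF)/SD_REF` using the REF
  condition's clean epochs; features with zero REF SD are flagged degenerate
  and excluded with a warning. The transform is invertible given the stored
  normalization.

## Lead field and inverse solution

- **Forward model**: a desk-scale stand-in for a realistic BEM head model.
  Default geometry is a homogeneous conducting unit sphere with 660 radially
  oriented dipoles on a shell at radius 0.85 (quasi-uniform Fibonacci
  lattice, compressed toward the upper hemisphere like cortex), evaluated
  with the classical Legendre-series solution truncated at 80 terms
  (converged to ~1e-5 at this eccentricity). Electrode positions come from
  the standard 10-05 montage, recentred and normalized to the unit sphere.
  Columns are unit-normalized. A seeded smooth random matrix is available
  for tests. The inverse and statistics machinery is model-agnostic, which
  is why a single-shell analytic model suffices here.
- **sLORETA**: with `H = I − 11ᵀ/m` the average-reference centering
  operator, `T = Aᵀ(AAᵀ + λH)⁺` and `S = TA`; standardized power of source
  *l* is `(Tb)_l² / S_ll`. By Cauchy–Schwarz on the positive-semidefinite
  `S`, a noise-free point source is always the argmax — the zero-
  localization-error property the module's headline test verifies. λ is
  expressed relative to the mean eigenvalue of `AAᵀ` (default 1e-8).
- **λ cross-validation** is leave-one-electrode-out: each electrode is
  predicted from a minimum-norm fit of the others over a λ grid. The CV runs
  on *unreferenced* data deliberately: under an average reference the
  held-out channel equals minus the sum of the others, so λ → 0 would
  reconstruct it exactly and the criterion would degenerate.
- **Per-band source power** is computed by projecting each epoch's Hann rFFT
  through `T` and summing `|·|²/S_ll` over the band's bins — by Parseval
  identical to band-pass filtering in time and inverting per sample, but one
  matrix product per epoch.

## Brodmann-area maps and statistics

- **Atlas**: 66 parcels = 33 Brodmann numbers × 2 hemispheres (the grid
  size, not the anatomy, is contract-bearing at desk scale; the label set is
  configurable). Parcel centroids are mirror-symmetric across the
  mid-sagittal plane and each source joins its nearest centroid, giving
  compact patches of ~10 sources.
- **Aggregation**: mean standardized power over a parcel's sources, per
  epoch and band, then z-scored to REF per (parcel, band).
- **Per-cell tests**: Kolmogorov–Smirnov normality gate at 0.05 (against a
  normal with the sample's moments), then Student's t if normal, otherwise
  the rank-based analogue (Wilcoxon signed-rank one-sample,
  Mann–Whitney two-sample — the two-group special case of Kruskal–Wallis).
  Cells with fewer than 8 epochs or constant values are marked untestable.
  No multiplicity correction by default (the tests are run separately per
  band and region by design); Benjamini–Hochberg FDR is available behind a
  flag.
- **Contrast choice**: the pipeline tests condition epochs *against REF
  epochs* (two-sample) rather than condition z-values against zero. The REF
  normalization's own sampling error is shared by every condition epoch of a
  subject, so the one-sample test is anticonservative and — because both
  repetitions share the same REF — its false positives survive the
  repetition intersection. The two-sample contrast restores calibration.
  Both contrasts remain selectable on `test_activation`.
- **Intersection**: a cell enters a level map iff significant in both
  repetitions with agreeing signs; the reported statistic is the mean of the
  two mean z values and the p-value is the larger of the two.

## Synthetic sessions

The generator's defaults are the study conditions: 250 Hz, 61 channels,
60 s per segment (the protocol states only ~30 min total, so per-segment
durations are free parameters; 60 s gives the 60 clean epochs per condition
the recovery analyses use), IAF 10 Hz, background RMS 10 µV per channel,
blink rate 2/min, gross artifacts off unless requested.

- **Background** is 1/f (pink) noise generated independently at all 660
  sources and projected through the lead field (plus 2 µV sensor pink
  noise), so REF and task segments share one spatially correlated generative
  process.
- **Rest** adds a constant-amplitude sinusoid at the configured IAF,
  posterior-weighted, to a channel-level pink background (the rest segment
  only feeds IAF estimation). At `noise_level=0` the spectrum is a pure
  line.
- **Planted parcel effects** (`effect_map`) are band-limited oscillations at
  the sources of the designated parcels (integer band-centre frequency; the
  spatial weights and global phase are drawn once per (parcel, band), so
  both repetitions of a level share the same generator — the scientific
  assumption that a cognitive state reactivates the same sources). In the
  default `effect_space="ba"` the per-source weights are the parcel's *most
  detectable mode* — the generalized eigenvector maximizing the parcel's own
  standardized-power response per unit electrode power. This matters:
  arbitrary phase patterns can nearly self-cancel through the inverse, in
  which case hitting the target shift would require sensor amplitudes large
  enough to trip the ±80 µV artifact gate. With `effect_space="channel"` the
  in-phase patch is used and the calibration targets the pattern's peak
  electrode in the 61-channel feature space instead. In both spaces the
  amplitudes solve, per band, the realized quadratic
  `2 Σ_j a_j L_rj + Σ_jk a_j a_k Q_rjk = z_r·SD_REF,r − (μ_cond − μ_REF)_r`
  where `Q` is the oscillation Gram through the measurement path and `L` the
  cross term with *this realization's* background — exact targeting that
  also accounts for leakage between simultaneously planted parcels.
  `effect_map` sizes are positive z-shifts (an additive oscillation cannot
  remove power).
- **Planted state shifts** (`state_map`) model a whole-cortex spectral
  difference: for each (condition, band) entry, every channel's band
  spectrum is scaled so its band-power feature moves by exactly z REF-SDs
  (per-channel gains `g_c² = (μ_R + z·SD_R)/μ_C`, refined by a two-point
  linear solve that absorbs Hann leakage across band edges). This is the
  ground truth used for classification experiments, because a
  distance-based classifier in a 366-feature space can only detect
  *distributed* differences — a handful of shifted cells, however clean, is
  swamped by the remaining noise dimensions (a linear model separates such
  cohorts easily; KNN does not). Multiplicative gains also represent power
  decreases (negative z).
- **Calibration reference**: all REF statistics used by the calibrations
  come from the full REF recording, blinks included, so the calibration's
  normalizers are the ones downstream z-scoring will actually estimate;
  blinks are added to a segment before the effect calibration for the same
  reason. Gross-amplitude events are added last — the pipeline rejects
  those epochs, so they must not influence the targeted means.
- **Artifacts**: blinks are 400 ms raised-cosine transients (160 µV on the
  paired EOG trace, propagated at 0.35/0.20/0.08 to the Fp/AF/F groups);
  gross events are 200 ms ±150 µV pulses on three random channels. Both are
  Poisson-placed and recorded in the session truth with their affected
  epochs.
- **Behaviour**: tracking samples the ideal zig-zag polyline (vertices
  included, so zero jitter retraces it exactly) with Gaussian jitter; rule
  outcomes are Bernoulli per slot; Knowledge logs draw exponential extra
  times. The "perfect" parameter setting scores exactly 100 at every level.
- **Determinism**: every stream derives from `(seed, stream-id)` with fixed
  integer stream ids, so identical configurations are byte-identical across
  processes.
- The default planted configuration for Knowledge-specific activity
  (`knowledge_effect_map`) is bilateral frontal BA8 Theta and BA10 Gamma at
  z = 1.5 — the frontal theta/gamma signature expected during deliberate
  problem solving, placed in well-separated parcels.

### What the synthetic experiments show — and what they do not

The generator emulates spatially correlated 1/f background, a realistic
alpha peak, stereotyped artifacts and level-specific oscillatory sources. It
does **not** emulate a realistic head (single-shell sphere, radial dipoles),
non-stationarity, eye movements beyond stereotyped blinks, muscle artifacts,
or inter-subject anatomical variability. Passing recovery tests therefore
demonstrates that the *pipeline machinery* is correct and calibrated —
formulas exact, localization exact in the noise-free case, planted effects
recovered at their designed size, null cohorts at the nominal false-positive
level — not that the original experiment's effect sizes or accuracies would
replicate on real EEG. One known mild deviation: 1/f background makes
consecutive 1-s epochs weakly dependent, so per-map null counts sit in the
upper half of the binomial band around α·396.

## Classification protocol

- **Features**: REF-z-scored channel × band power, all 61 channels
  (366 features). Z-units were chosen over raw power for cross-session
  comparability; a config switch restores raw power.
- **PCA**: fitted on the training pair only; keeps the smallest k with
  cumulative explained variance ≥ the threshold (0.90 default). The
  selection is implemented as an explicit cumulative scan because the
  obvious library shortcut uses a strict inequality and returns k+1 when the
  cumulative variance hits the threshold exactly.
- **Model zoo and grids**: DT, RF, RF-Easy (n-estimators and max-depth
  only), KNN (neighbours 5–100, uniform/distance weights, leaf size 2–150,
  Euclidean/Manhattan/Minkowski/Chebyshev metrics) and XGBoost, each tuned
  by randomized search over its published ranges with stratified 5-fold CV
  on the training pair, hard-capped at 200 sampled points. The XGBoost
  booster grid omits `gblinear` because it silently ignores the
  tree-structure parameters the rest of the grid varies. Class imbalance
  (2:1 for S+R vs K) is left uncorrected by default; a class-weight option
  exists.
- **Window voting**: overlapping windows, step 1 epoch (the stride is not
  specified upstream; 1 maximizes the number of decisions), window label =
  modal label, ties resolved by the window's most recent epoch — a
  deterministic, causal rule. The true label of a window is the mode of the
  true epoch labels under the same tie rule.
- **Metrics**: classical confusion-matrix definitions with class 0 = S+R and
  class 1 = K; per-class precision, recall, specificity and F1 plus overall
  accuracy, evaluated on the windowed predictions.
- A `merge_skill_rule=False` flag keeps the three original labels and runs
  the identical machinery as a 3-class problem; its metrics report remains
  binary-only by design.

## Orchestration

`RunConfig` is schema-validated (unknown keys rejected). Characterization
runs simulate → preprocess → features → inverse/maps → intersection in fixed
order and aborts naming the failing stage; classification verifies
session-level train/test disjointness and raises on violation. Every run
writes a manifest (config hash, seeds, library versions, per-stage counts)
from which the outputs are reproducible.

## Problem sizes used in the shipped experiments

Recovery and calibration experiments use 60 one-second epochs per condition
segment; 11 subjects for activation-map recovery (plus 3 zero-effect
subjects); 10 subjects for classifier recovery (plus 3 zero-effect
subjects); 20 seeds for IAF recovery and for sLORETA localization. These
sizes were chosen to estimate each rate with useful precision on a single
CPU.

## Known limitations

- The spherical forward model cannot address anatomical questions; parcels
  are geometric patches, not cytoarchitectonic areas.
- sLORETA's low spatial resolution at 33 electrodes spreads a planted
  parcel's power into neighbouring parcels; the recovery experiments count
  those neighbours as spurious cells, and the observed ~7–8% spurious rate
  is a property of the inverse, not of the statistics.
- EEG export is limited to the package's plain binary + JSON sidecar fixture
  format; BrainVision and EDF are read (via mne) but not written.
- Negative `effect_map` sizes (parcel-level power decreases) are not
  supported by the additive-oscillation mechanism; use `state_map` for
  decreases, at whole-cortex granularity.
- Compact planted parcel effects at z ≈ 1.5 are recoverable by the
  activation-map statistics but *not* by the distance-based classifier —
  the classification experiments therefore plant distributed state
  differences, and their results say nothing about detecting focal effects
  with KNN.
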