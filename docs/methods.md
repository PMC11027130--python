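# Methods

This note documents the models, estimators and numerical choices behind the
`smd` package: a pipeline for decoding speech kinematic information from
sensorimotor mu/beta rhythms recorded with MEG while articulator movements
are tracked by an MEG-compatible articulograph. Because no public recordings
exist for this paradigm, every stage is validated against a synthetic-session
generator with exact ground truth; this note also states precisely what that
generator does and does not emulate.

## The experimental model

The pipeline targets a reiterated-nonword paradigm: a speaker produces a
disyllabic V1CV2 nonword (/ipa/ or /api/) continuously for a ~12 s breath
group ("trial set"), about ten productions per normal-rate set, with rest
periods between sets, while coil tracks of the upper lip (UL), lower lip
(LL), tongue body (TB) and reference/fiducial coils are recorded alongside
~10^2 MEG channels and an acoustic channel captured on both acquisition
computers (whose clocks differ by an unknown offset).

Analysis proceeds in four phases:

1. **Kinematics** — gestural signals are formed as two-dimensional Euclidean
   inter-coil distances (bilabial closure BC = UL-LL aperture; tongue-body
   constriction TB = TB-to-nasal-reference distance) after a rigid transform
   into the occlusal-plane head frame. Alternating signal extrema segment
   opening and closing movements; within each movement the 10% and 90%
   amplitude-level times are interpolated to sub-sample precision and stored
   as landmarks. Each movement is summarised by amplitude A (excursion
   between bounding extrema), duration D (extremum-to-extremum by default;
   the 10-90% landmark span is also emitted since conventions differ), peak
   velocity v (maximum |dx/dt|, 5-point central difference on the same
   smoothed signal used for extremum detection, so landmarks and velocities
   are mutually consistent) and stiffness k = v / A. Two profiles summarise
   the trial ensemble: v vs A (least-squares line; empirically near-linear)
   and k vs D (power-law segment continuing into a plateau, fitted by
   nonlinear least squares; empirically decreasing and flattening beyond
   roughly 200 ms).
2. **Alignment and source localisation** — the articulograph-to-MEG clock
   offset is the argmax of the normalized cross-correlation of the two
   acoustic channels, computed on rectified low-passed envelopes (robust to
   waveform mismatch between microphones); a single global lag is assumed,
   as sessions are short enough that clock drift is negligible. Landmarks
   map to MEG samples, data are zero-phase filtered (4th-order Butterworth,
   two-pass; 0-100 Hz band plus 50 Hz notch) and epoched. Speech motor
   cortex is localised with a SAM-style beamformer: per grid point the
   dipole orientation maximises output power against projected noise
   (largest generalized eigenvector of (L'C^-1 L, L'C^-2 L)), weights are
   w = C^-1 l / (l'C^-1 l) with unit gain at the target, and the contrast
   statistic is the pseudo-T (P_active - P_baseline) / (2 sigma^2 ||w||^2),
   with sigma^2 the smallest covariance eigenvalue (projected sensor-noise
   convention). Active power is averaged over ten 1 s windows sliding in
   200 ms steps over the first 2 s of the trial set against a fixed 2 s
   rest baseline, in an 18-22 Hz band. Since speech *suppresses* beta, the
   localiser extremum is the most negative pseudo-T. Group maps are
   thresholded by the omnibus max-statistic sign-flip permutation test.
3. **Time-frequency MVPA** — per-trial Morlet spectrograms (7-cycle
   wavelets) of the virtual-sensor time series feed a searchlight
   classification of speech vs rest epochs at every (time, frequency) cell
   (features: the 3x3 cell neighborhood by default; radius 0 gives
   single-pixel decoding), and a frequency-generalisation analysis (train
   at one frequency on its within-epoch power time course, test at every
   other frequency on matched held-out trials). The classifier everywhere
   is binary LDA with Ledoit-Wolf shrinkage of the pooled within-class
   covariance toward a scaled identity, evaluated by stratified 5-fold
   cross-validation repeated 5 times with seeded fold assignment. It is
   implemented in-package as a batched estimator (one covariance solve per
   fold for all cells simultaneously), which is what makes the error-rate
   studies below tractable on one CPU; scikit-learn's equivalent LDA serves
   as an independent oracle in the tests, never as the implementation.
4. **RSA** — trials are ordered along the first principal direction of the
   z-scored profile cloud and cut into 10 contiguous equal-count partitions;
   the behavioural RDM holds Euclidean distances between partition means
   (computed on per-axis z-scored coordinates so mm and s scales are
   commensurable). For each of the 45 partition pairs, cross-validated LDA
   accuracy at each time-frequency cell gives the neural dissimilarity,
   rectified as max(accuracy - 0.5, 0) by default: accuracy above chance
   *is* a dissimilarity, and rectification avoids treating below-chance
   noise as similarity structure (the literal
   distance-between-accuracy-scores variant |accuracy - 0.5| is available
   by flag). Spearman correlation (Pearson by flag) between the behavioural
   and neural lower triangles yields an RSA map per subject. Group
   inference band-averages the maps (mu 8-12, beta 13-30, gamma 60-80 Hz),
   restricts to a 1 s window centred on the BC opening onset, forms
   clusters at per-timepoint sign-flip permutation p < 0.05, and compares
   each cluster's |t| mass with the permutation null of the maximum cluster
   mass taken across signs, runs *and bands* — a global max statistic, so
   the probability of any false cluster anywhere is at most alpha before
   the final Benjamini-Hochberg FDR step across clusters, which only
   tightens it. Signed clusters are reported: pre-movement positive and
   post-movement negative couplings are distinct findings.

## Synthetic data: what it emulates

The movement primitive is a raised cosine: x(t) = A/2 (1 - cos(pi t / D)).
All its kinematics are closed-form — peak velocity A pi / (2D), stiffness
pi / (2D), and 10%/90% crossings at acos(0.8)/pi ~ 0.2048 and 0.7952 of D —
which provides exact oracles for the whole phase-1 chain. Amplitudes are
jittered strongly (default SD 2 mm about a 10 mm mean) while durations are
jittered weakly (lognormal sigma 0.06 about the half-period): speech is
approximately isochronous across productions of one rate condition, and this
is what makes the amplitude/peak-velocity profile close to linear (default
sessions reach r >= 0.9). Stiffness = pi/(2D) follows from the primitive and
is automatically a decreasing, plateauing function of duration; no separate
stiffness model is imposed. For /ipa/ the bilabial closure falls on the
descending limb of the TB gesture and for /api/ on the ascending limb,
implemented by a +-quarter-cycle phase offset of the TB waveform relative to
the BC cycle phase.

The MEG-like session projects a single cortical source through a
magnetostatic-dipole leadfield (sensors on an upper hemisphere with
near-radial orientations and realistic mounting scatter — an exactly radial
array would be blind to radial dipole components). The source carries
band-limited Gaussian noise in the beta band (optionally mu) whose amplitude
drops by `erd_depth` (default 0.5) during trial sets and rebounds at rest;
movement-locked broadband artifact is injected as *independent* >50 Hz
bursts on every sensor (muscle artifact is high-rank, so a beamformer cannot
spatially null it; default amplitude twice the sensor noise makes it
prominent, as overt-speech recordings show); the acoustic envelope (Gaussian
bursts at each closure) is embedded in the MEG recording with a configurable
integer clock lag. Optional trial-wise coupling multiplies the source's
coupling-band amplitude by (1 + gain * z_i) in a window starting 90 ms
(configurable) before each opening-movement onset, where z_i maps the
trial's kinematic parameter monotonely onto [-1, 1].

Source and artifact amplitudes (defaults 2.0 and 2.0 in units of sensor
noise SD) are set so that single-trial beta decoding is strong but
unsaturated — with a much stronger source, Morlet spectral leakage from the
band edges alone would classify perfectly far outside the source band, which
real recordings do not show.

What the generator does **not** emulate: vocal-tract acoustics (the acoustic
channel is an envelope, not audio), head movement and coil drift,
multi-subject anatomical variability (all simulated subjects share the grid
geometry), 1/f background spectra and non-stationary ongoing rhythms, and
correlated multi-source configurations. Passing tests therefore demonstrate
that the estimators recover what they claim from data obeying the stated
model, with correct error rates under its null — not that real recordings
satisfy that model.

A reduced-scale generator (`simulate_trial_band_power`) emits band-averaged
per-trial power matrices directly (log-normal baseline, same coupling
injection) for the Monte-Carlo studies of the RSA chain, where thousands of
simulated subjects are needed; the full sensor-level chain is exercised at
session scale by the localisation and decoding studies.

## Statistical calibration studies

Three studies calibrate the inferential machinery (they are recomputed from
scratch by `scripts/acceptance.py`):

- **Classifier chance level**: 100 replicate null datasets (two classes from
  the same 9-dimensional standard normal, 100 trials each); the mean 5x5
  cross-validated accuracy sits at 0.5 within +-0.02.
- **Omnibus FWER**: 200 null groups of 10 subjects with 500-voxel i.i.d.
  Gaussian maps; the 1024-permutation max-statistic threshold at alpha=0.05
  yields a family-wise false-positive fraction at or below the nominal
  level. With 10 subjects the 2^10 = 1024 flip patterns are enumerated
  exhaustively, making the test exact.
- **RSA cluster error rate**: 200 null-coupling groups (10 subjects, 50 time
  points, 3 band means, 10 partitions x 15 trials); the fraction of groups
  with any significant cluster stays at or below alpha.

Problem sizes follow the reduced-resolution design above; the recovery study
(criterion-level, in the test suite) uses 101 time points over the 3 s epoch
so that the -90 ms coupling onset falls exactly on a grid point, and detects
it as a pre-movement positive beta cluster in >= 90% of 20 simulated groups
with zero-gain controls clean.

## Numerical choices and conventions

- **Filters**: 4th-order Butterworth, applied forward-backward
  (`sosfiltfilt`), everywhere; corner frequencies are the only quantities a
  user needs to state.
- **Sign-flip permutations** are drawn *without replacement* from the flip
  universe (exhaustively when 2^S fits the permutation budget). Duplicate
  identity permutations under with-replacement sampling inflate the
  attainable p floor noticeably at group sizes near 10; distinct patterns
  restore the exact granularity 1/n_perm. The unflipped pattern is always
  included, so permutation p-values are valid (never below 1/n_perm).
- **Wilcoxon signed-rank** statistics on accuracy maps are computed
  vectorised over cells with the normal approximation (zero differences
  excluded, mid-ranks for ties); exact per-cell `scipy.stats.wilcoxon`
  would cost 500 permutations x thousands of cells per dataset. At n = 10
  subjects the approximation is standard practice.
- **Cluster forming** in the RSA group test uses per-timepoint permutation
  p-values, with each permutation's own forming threshold obtained by
  ranking it within the full permutation set (a parametric-t variant is the
  `statistic="t"` forming rule in `group_stats_accuracy`).
- **Sliding-window aggregation** in the pseudo-T map is the arithmetic mean
  of the per-step maps. The window specification "1 s windows starting
  0-1000 ms in 200 ms steps, 10 steps" is read as ten onsets at 0, 200, ...,
  1800 ms; both the count and the step are configurable.
- **Regularization**: covariance diagonal loading defaults to 5% of the mean
  sensor power; with zero loading a rank-deficient covariance raises rather
  than silently pseudo-inverting. The orientation eigenproblem adds a
  1e-10-scaled ridge to its B matrix as a positive-definiteness guard.
- **Degenerate inputs**: constant gestural signals yield zero movements (not
  an error); NaN reference-coil blocks are dropped from the occlusal
  transform and logged; undefined RSA correlations (zero-variance RDMs) are
  stored NaN and excluded from band means with a logged count; outlier
  movements (beyond median +- 3 MAD in amplitude or duration, a stand-in
  for manual speech-error marking) are excluded before profile fitting and
  counted.
- **Tie-breaks**: cross-correlation lag ties resolve toward the smallest
  |lag|; beamformer orientation sign is fixed by making the first nonzero
  component positive.
- **Seeding**: one root seed fans out into named per-stage substreams
  (SHA-256 of the stage name into `SeedSequence` spawn keys), so stages can
  be re-run independently yet reproducibly; identical seeds give
  bit-identical outputs, and every pipeline run records its seeds in a JSON
  manifest.

## Known limitations

- The beamformer assumes the leadfield is given; there is no head model or
  coregistration (a synthetic grid with known geometry replaces the MRI
  pipeline by design).
- Lag estimation assumes no clock drift; long sessions would need a drift
  model.
- Neural-RDM classification batches all partition pairs with a shared fold
  pattern and trims partitions to a common trial count; with the default
  equal-count partitioning at most one trial per partition is dropped.
- The rank-based coupling injection makes the behavioural-neural association
  monotone by construction; nonlinear or non-monotone codes would require a
  different generator and correlation choice.
- Group studies simulate homogeneous subjects; between-subject variance in
  effect size is not modelled, so the recovery rates reported by the tests
  are upper bounds on what heterogeneous cohorts would give.
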