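# Methods

This note documents the models, conventions, and numerical choices behind
`neomotion`, and states precisely what the synthetic-cohort results do and do
not demonstrate about real neonatal data.

## Frame-wise displacement and censoring

FD at frame *i* is the mean of the six absolute frame-to-frame displacement
terms, with rotations converted to arc length on a 30 mm sphere (a neonatal
head is roughly 60% of the adult radius commonly used for this conversion):

    FD[i] = (|Δdx| + |Δdy| + |Δdz| + 30|Δφ| + 30|Δθ| + 30|Δψ|) / 6,  FD[0] = 0.

Conventions, all deliberate:

* **Absolute values.** Written without bars the expression could go negative
  and opposing movements would cancel; the term-wise absolute value is the
  standard displacement convention and makes the Δ sign convention
  (previous-minus-current versus the reverse) irrelevant.
* **Mean, not sum.** The six terms are divided by 6. The widely used
  sum-of-terms FD is exactly 6x larger; thresholds here (0.5, 0.2 mm) are on
  the mean scale.
* **Frame 0** has FD 0 by definition and is never censored on FD grounds.
* **Mean FD after censoring** averages the original per-frame FD over
  surviving frames only; FD is not recomputed between now-adjacent survivors.
* **The scan-length cap** (default 240 s, i.e. `floor(240/TR)` frames) keeps
  the *earliest* surviving frames, preserving temporal order, and is applied
  to every censoring condition including "no censoring", so all conditions
  are compared at an equal number of frames and equal nominal SNR.
* Degree-valued rotation files (AFNI convention) and rotations-first column
  orders are converted behind explicit reader flags, never guessed.

## Nuisance cleaning

Nuisance regression and band-pass filtering are performed **simultaneously**:
one least-squares projection removes the intercept, a linear drift, the
enabled nuisance blocks (24-parameter motion expansion; white-matter mean;
CSF principal components; optional global signal), and sine/cosine regressors
at every DFT frequency outside the 0.009-0.08 Hz pass-band (edges inclusive).
Sequential regress-then-filter can reintroduce nuisance variance into the
filtered band; a single projection cannot. It also makes the question of
whether tissue regressors should themselves be band-filtered moot: the
projection depends only on the span of the design, which is unchanged by
filtering columns against other columns already in the design.

Numerical details:

* Motion expansion: the 6 parameters, their backward differences (first row
  0), and the squares of both — 24 columns in a fixed documented order.
* CSF principal components are computed by SVD of the column-centered voxel
  series, no variance scaling, each component sign-fixed so its
  largest-magnitude voxel loading is positive (deterministic across runs).
* A rank-deficient combined design triggers a warning and falls back to the
  pseudoinverse (`lstsq`) rather than failing.
* The projection needs more frames than regressors; with TR = 2 s the full
  motion + band-stop design requires roughly 115 frames, so short scans must
  either disable blocks or widen the band. This is surfaced as a validation
  error, not silently truncated.
* Cleaning runs on the **full** series; censored frames are dropped only
  afterwards, when connectivity is computed. No interpolation of censored
  frames is performed.

**tSNR** is the per-unit temporal mean over temporal SD (SD with denominator
n−1) of the *raw* (pre-regression) series, averaged over the mask; zero-SD
units are excluded from the summary and counted. tSNR is a property of the
acquired data, so it is never computed on residuals.

## Connectivity

Pearson correlation over surviving frames, then Fisher z. Correlations with
|r| ≥ 1 − 1e−12 are clamped to that bound before `atanh` so z stays finite
(z_max ≈ 13.9); clamped matrices are flagged. Zero-variance ROIs produce NaN
rows/columns rather than silent zeros. Group-average maps average the
z-values (transform first, then average). Homotopic pairs come from an
explicit partner column in the ROI table — never inferred from label parity,
which silently breaks across atlas conventions. Seed maps operate on any
"unit" axis (voxels or ROIs), with bilateral seeds averaged into one series
before correlation. Scans left with fewer than 3 surviving frames at a
condition are flagged with an all-NaN connectivity matrix and excluded from
that condition's cohort statistics.

## Cohort statistics

* **Group split**: the lowest/highest `floor(0.25 n)` scans by mean FD form
  the low/high-motion groups, re-derived *per censoring condition* (a scan
  can change groups between conditions); ties broken by scan id.
* **Two-sample tests** default to Student's pooled-variance t (Welch by
  flag); direction is reported as high > low with two-sided p.
* **FDR** is Benjamini-Hochberg step-up (via statsmodels), with monotone
  q-values; calibration is verified against a hand-coded oracle in the tests.
* **Partial correlation** of PMA and strength given mean FD residualizes both
  variables on [1, FD] and correlates the residuals — the standard
  first-order identity, verified against the closed form in the tests.
* **Bootstrap** replicates draw `floor(0.5 n)` scans *without* replacement
  (subsampling; with-replacement available by flag). Significance of the mean
  z uses a one-sample t over replicates; the partial-vs-simple increment uses
  a paired t. All replicate draws flow from one seed recorded in the result.
* All cohort-level randomness funnels through one master seed recorded in
  every output manifest, so any run is exactly reproducible.

## The synthetic cohort generator

The generator produces, per scan, an ROI-by-time series plus a 6-parameter
motion trace in which every quantity the pipeline estimates is known.

**Geometry.** Centroids are drawn uniformly in one hemisphere at neonatal
scale (|x| up to 35 mm from the midline) and mirrored across the midsagittal
plane; each ROI's homotopic partner is recorded explicitly.

**Ground-truth correlation.** A convex blend

    C = (1 − a) · exp(−d/λ) + a · (I + H),   a = 0.75,

of an exponential distance-decay kernel (length scale λ, default 40 mm) and a
pairwise homotopic block H whose entries are chosen so the homotopic
correlation hits its target exactly. The target in Fisher-z is
`atanh(h) + s·(PMA − midpoint)` with homotopic strength h (default 0.6) and
age slope s (default 0.02 z/week), so homotopic connectivity strengthens
linearly with postmenstrual age. Both blend terms are positive semidefinite
whenever every implied block weight lies in (−1, 1), so C is provably
positive-definite; requests outside that region raise an error. The decay
term makes the negative distance-connectivity trend hold by construction.

**Motion.** A random-walk jitter (step SD 0.02 mm; rotations scaled to
equivalent mm) plus sparse *surges*: with per-frame probability `burst_rate`
a Gaussian excursion of scale 1.5 mm hits a random subset of the six
parameters and settles back exponentially (decay 1.5 frames) over a
geometric number of frames. The settling matters: it spreads per-frame
displacement over a continuum of magnitudes, so the 0.5 mm and 0.2 mm
censoring thresholds remove genuinely different frame sets, as they do in
real data. Per-scan surge propensity is Gamma-distributed (shape 1, mean
0.10, truncated at 2.5x the mean): at 149 scans this reproduces the motion
statistics reported for real neonatal cohorts — cohort mean FD ≈ 0.13 mm
with SD of the same order, roughly 8% of volumes censored at 0.5 mm and
19% at 0.2 mm, and no scan losing the majority of its frames. These motion
parameters were calibrated once against those published cohort-level
statistics, not against any test outcome.

**Couplings.** Three injected effects, each with a known handle:

* *Artifact*: a shared additive component `artifact_gain · FD[t] · w`, with
  fixed per-ROI signed weights w ~ N(0, 1). Same-sign ROI pairs have
  motion-inflated correlation, opposite-sign pairs deflated — reproducing
  both observed directions of FD-FC association. Default gain 1.0/mm: at a
  1 mm surge the artifact has the amplitude of the neural signal SD.
* *tSNR loss*: white measurement noise with SD `noise_sd · (1 +
  dropout_gain · FD[t])` (defaults 0.2 and 2.0/mm: noise SD triples at a
  1 mm surge), so high-motion scans have lower tSNR. The constant signal
  offset (default 100) keeps tSNR finite and positive, mimicking raw BOLD
  intensity units.
* *Age*: PMA is uniform on 37.7-47.7 weeks and drawn **independently** of
  all motion quantities, so PMA-connectivity analyses are unconfounded by
  construction and any FD sensitivity of the simple correlation is
  attributable to the analysis, not the generator.

The artifact and noise gains are free parameters of the simulation — the
real neonatal artifact magnitude is not known quantitatively — chosen once by
the scale reasoning above and documented here.

**Seeding.** Geometry and artifact weights derive from the master seed;
cohort-level draws (PMA, sex, surge rates) use a keyed stream off the master
seed; scan *i* uses `master + 1 + i`, so any single scan is regenerable
without building the cohort.

**Recovery analyses on synthetic cohorts run without nuisance regression.**
The generator injects no drift or physiological nuisance, and the
motion-parameter expansion partially absorbs the FD-coupled artifact, which
would entangle two mitigation mechanisms in an analysis meant to isolate
censoring. Cleaning has its own spectral and orthogonality checks.

## What the synthetic results do and do not show

The generator emulates: surge-like neonatal motion with a heavy-tailed
between-scan distribution, distance-decaying covariance with exact homotopic
structure, bidirectional FD-coupled shared artifacts, FD-coupled tSNR loss,
and an age effect independent of motion. It does **not** emulate: spatial
structure within ROIs (no point-spread, smoothing, or registration error),
respiratory or cardiac waveforms, spin-history or slice-wise motion effects,
EPI distortion, or realistic BOLD autocorrelation (frames are temporally
white given the covariance). Passing tests therefore demonstrate that the
implementation is correct and that the *mechanisms* — censoring removing
FD-coupled variance, partial correlation removing a linear FD confound —
behave as designed; they do not estimate neonatal effect sizes, and the
printed association magnitudes on synthetic cohorts should not be read as
predictions for real scans.

## Problem sizes

The verification suite and `scripts/acceptance.py` use deliberately compact
cohorts chosen to keep every Monte-Carlo band tight at desk scale: 200 null
cohorts of 40 scans (10 ROIs, 120 frames) for type-I calibration; 20 cohorts
of 60 scans (200 frames) for the recovery analyses; 20 x 1000 bootstrap
replicates at n = 200 for the confound analysis; 1000 random traces for the
FD oracle; 200 p-vector draws for FDR calibration. Larger cohorts sharpen
every margin; none of the qualitative conclusions depend on these sizes.

## Known limitations

* No DVARS, no motion-parameter interpolation, no prospective correction,
  no ICA-based denoising, no spatial (cluster-extent) inference, and no
  dynamic or phase-based connectivity — censored series are treated as
  simple frame subsets.
* The joint projection assumes frames are exchangeable for least squares;
  with very aggressive censoring the effective degrees of freedom after
  cleaning can be small, and downstream correlations inherit that
  variability.
* Seed-region choices for named networks are configuration, not code; the
  pipeline takes any ROI pair or seed set.
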