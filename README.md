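# neomotion

Head-motion quality control and motion-connectivity association analysis for
neonatal resting-state fMRI.

Head motion is the dominant artifact in newborn resting-state functional
connectivity MRI: neonates move in sudden surges, motion inflates or deflates
inter-regional correlations depending on region geometry, and it lowers the
temporal signal-to-noise ratio (tSNR) of the acquired series. `neomotion`
implements the full evaluation pipeline a motion study needs — frame-wise
displacement, volume censoring ("scrubbing"), simultaneous nuisance
regression + band-pass filtering, tSNR, Fisher-z connectivity, cohort-level
motion-connectivity statistics with FDR control, and bootstrap age-association
analysis — together with a synthetic-cohort generator with known ground truth
so every stage is testable without any imaging data.

## The quantities at the core

**Frame-wise displacement.** From the six rigid-body motion estimates
(translations $d_x, d_y, d_z$ in mm; rotations $\phi, \theta, \psi$ in
radians, converted to mm on a sphere of radius $r = 30$ mm approximating the
neonatal head):

$$\mathrm{FD}_i = \tfrac{1}{6}\left(|\Delta d_x| + |\Delta d_y| + |\Delta d_z|
 + r|\Delta\phi| + r|\Delta\theta| + r|\Delta\psi|\right),\qquad \mathrm{FD}_0 = 0,$$

with $\Delta$ the frame-to-frame difference. Note the six terms are
*averaged*; FD variants that sum them are 6x larger.

**Censoring.** Frames with FD above a threshold (defaults 0.5 and 0.2 mm) are
dropped, then every condition — including "no censoring" — is capped at 4
minutes of data so conditions are compared at equal scan length.

**Connectivity.** ROI-mean BOLD series are correlated (Pearson) over
surviving frames and Fisher z-transformed, $z = \operatorname{atanh}(r)$.
Homotopic (left-right mirror pair) strength, whole-connectome edge tables
($90$ ROIs $\to 4005$ edges), and seed maps are derived from the same matrix.

**Statistics.** Across a cohort: Pearson association of mean FD with network
strength per censoring condition; per-edge FD associations and the fraction
of "contaminated" edges; low/high-motion group contrasts (lowest/highest 25%
by mean FD, two-sample t, uncorrected p < .01 and Benjamini-Hochberg FDR
q < .05); distance dependence of connectivity; one-way ANOVA of group
differences across censoring conditions; and bootstrap subsampling (50%
subsets) of the simple versus FD-partialled correlation between
postmenstrual age (PMA) and network strength.

## Worked example

Generate a 30-scan synthetic cohort (10 ROIs, 200 frames at TR = 2 s, with
motion-coupled artifact and noise) and run the three analyses:

```yaml
# demo.yaml
synthetic: {n_scans: 30, n_frames: 200, n_rois: 10, seed: 42}
clean: false
n_boot: 500
seed: 42
out_dir: demo_out
```

```text
$ neomotion qc --config demo.yaml
n=30 mean FD 0.133 +/- 0.096 mm; r(tSNR, FD) = -0.712

$ neomotion censor-eval --config demo.yaml
none: 24.44% of 45 edges FD-associated
0.5mm: 8.89% of 45 edges FD-associated
0.2mm: 8.89% of 45 edges FD-associated

$ neomotion pma --config demo.yaml
roi01: simple z 0.339 partial z 0.398 (paired p 6.8e-27)
...
```

Reading the output: the cohort moves like a real newborn cohort (mean FD
0.13 mm with a heavy tail), and scans that move more have visibly lower tSNR
(r = −0.71). Without censoring, a quarter of all edges correlate
significantly with head motion; scrubbing at 0.5 mm and 0.2 mm drives that
fraction toward the 5% false-positive floor. In the age analysis, partialling
mean FD out of the PMA-strength correlation raises the Fisher-z association
for every network — the signature of a motion confound on an age effect.
Full tables (`qc_scans.tsv`, `association.tsv`, `edgewise.tsv`,
`group_contrast.tsv`, `bootstrap.tsv`) and a reproducibility manifest are
written to `out_dir`. The same analyses are available as library functions
(`neomotion.analyze_cohort`, `neomotion.pma_association`, ...) on your own
ROI-by-time TSVs, NIfTI volumes, or 6-column motion parameter files.

## Documentation

`docs/methods.md` describes the generative model of the synthetic cohorts,
every tunable parameter with its default and rationale, the numerical
choices in the cleaning projection and the statistics, and what the
synthetic-data results do and do not say about real neonatal data.
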