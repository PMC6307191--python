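# Methods

`fcpipe` implements a cohort functional-connectivity analysis for resting-state
or naturalistic-viewing BOLD fMRI, together with a synthetic cohort generator
that produces data with known ground truth so every downstream stage can be
validated by parameter recovery. The pipeline targets three-group designs of
the LVCP / HVCP / NT form (autism with low verbal and cognitive performance,
composite IQ ≤ 79; autism with IQ ≥ 80; neurotypical controls), but all
stages are generic.

## Preprocessing model

Inputs are assumed motion-realigned and resampled to a common space; the
rigid-body realignment parameters are consumed, not estimated.

**Framewise displacement (FD).** Power-style sum of absolute frame-to-frame
parameter differences, with the three rotations converted to millimetres on a
50 mm head sphere: FD(t) = Σ|Δtrans| + 50·Σ|Δrot|. FD is a transition
quantity, so FD(0) = 0 by convention. Motion files store translations in mm
and rotations in radians; the TSV header states the units, because a silent
degree/radian confusion rescales rotational FD by 57×.

**Censoring.** FD(t) measures the transition between frames t−1 and t; an
excursion FD(t) > 0.2 mm removes the frames on either side of the motion
event, t−1 and t. Censored frames are flagged, not deleted: nuisance
regression and filtering see the complete time series, and the censor mask is
applied when ROI time series are extracted. A subject is usable when at least
200 motion-free volumes survive across the concatenated runs; unusable
subjects are excluded from all group analyses and the exclusion is logged
with its volume count.

**Nuisance regression + bandpass.** Per voxel, one ordinary-least-squares fit
removes simultaneously: an intercept, the six motion parameters, mean signals
over one-voxel-eroded white-matter and CSF masks, a facial soft-tissue mean
signal, optionally the global (whole-brain mean) signal, and a
discrete-cosine basis spanning every frequency outside 0.001–0.1 Hz. The DCT
column at index k oscillates at k/(2·N·TR) Hz, so regressing out the
out-of-band columns is an exact linear bandpass performed jointly with the
confound removal; a sequential IIR filter would partially reintroduce
regressed noise, and the joint fit guarantees residuals orthogonal to every
regressor to numerical precision (the test suite asserts |r| < 1e−10 and a
≥ 20 dB stop-band). A zero-phase Butterworth mode (`filter_mode:
butterworth`) is provided for comparison; it runs the confound regression
first and filters the residuals, without the orthogonality guarantee.
Erosion keeps voxels whose full 6-neighbourhood (face adjacency) lies inside
the mask; an eroded-to-empty tissue mask is an explicit error. All-zero
confound columns (a perfectly still synthetic subject) are dropped with a
warning rather than failing the rank check; genuinely collinear columns are
an error naming the columns. With 8.5-minute runs the 0.001 Hz lower edge
passes near-DC trends by construction; runs are filtered separately, and
per-ROI series are re-centred per run before concatenation so run offsets
cannot inflate correlations across the concatenation boundary.

## Connectivity summaries

ROI time series are voxel means over each parcel, restricted to kept frames,
centred per run, concatenated in run order. Connectivity is Pearson
correlation, Fisher-transformed (z = atanh r); the matrix diagonal is stored
as NaN and never averaged. Two deliberately different network-level
conventions are used, following common practice:

- **within-network** connectivity of network k = mean Fisher z over distinct
  ROI pairs inside k;
- **between-network** connectivity of networks k, l = Fisher z of the
  correlation between the two networks' *mean* time series (synchrony of
  network means), not a mean of pairwise values.

The parcellation follows the Gordon 333-parcel scheme's structure: parcels
carry one of twelve source networks, merged to eight analysis networks
(cingulo-opercular → salience, cinguloparietal → frontoparietal,
retrosplenial-temporal → default, the two sensorimotor subdivisions pooled);
parcels labelled `none` are excluded from network summaries but retained for
ROI-level and homotopic analyses. A reader for Gordon-style parcel tables
(id / hemisphere / network / centroid columns) is included.

**Homotopic pairing.** Each ROI's centroid is mirrored across the
mid-sagittal plane (x → −x in world coordinates) and paired with the
contralateral ROI whose centroid is nearest (ties to the lower id). The rule
is directional; a `mutual` flag records whether the partner maps back, since
mutual nearest-neighbour restriction is a plausible alternative convention.
On the generator's mirror-symmetric atlas the pairing is the exact mirror
bijection with zero distances, which the tests assert.

## Group statistics

- **Three-group ANCOVA**: OLS of the summary on two group indicators (LVCP
  reference) plus age, binary sex and motion-free volume count (continuous
  covariates centred); the group effect is the 2-df F-test on the
  indicators; pairwise contrasts are unprotected t-statistics from the same
  fit (no Tukey correction), matching the reporting style of omnibus F plus
  pairwise direction.
- **Two-group comparisons**: pooled-variance Student t (Welch via flag).
- **FDR**: Benjamini–Hochberg step-up, applied strictly within each analysis
  family — 8 networks, 28 network pairs per contrast, all ROIs for the
  network-to-ROI map, all homotopic pairs per contrast — never pooled across
  analyses. Tables carry raw p, q and a q ≤ 0.05 flag. For the
  within-network family both raw p and q matter: omnibus ANOVA p-values of
  the size this design produces (0.01–0.04) generally do not survive BH over
  eight networks, so figure-level significance in this literature is
  conventionally the raw ANOVA test; the tables emit both so either
  convention can be applied.
- **Dimensional IQ analysis**: Pearson r between composite IQ and each ROI
  pair's z across the subjects of one group (≥ 3 subjects required), plus
  scalar summaries (e.g. within-default mean vs IQ per group).
- **GSR contrast**: per stream and group, the median of all pairwise z; the
  sign agreement of per-cell group-difference t maps between streams; and
  the shift of the median group difference between streams. Group
  differences carried by a shared global component appear only in the
  non-GSR stream; network-specific differences keep their sign in both.

## The synthetic cohort generator

The generator emulates the data structure the analysis assumes — it is a
statistical twin, not a biophysical simulation.

**Signal model.** ROI series are zero-mean multivariate normal draws with a
target covariance, temporally coloured by an FFT low-pass kernel
|H(f)| = (1+(f/0.1 Hz)⁴)^(−1/2) applied identically to every channel (which
preserves cross-correlations) and rescaled to unit marginal variance. Units
are arbitrary z-scale; only correlations matter downstream. The target
correlation matrix is tanh of a Fisher-z parameter matrix: `within_z` on
same-network cells (default 0.35), `between_z` on cross-network cells,
plus `homotopic_z` (default 0.25) on mirror pairs; if assembly breaks
positive definiteness the nearest unit-diagonal PD matrix (eigenvalue
clipping) is used and the repair magnitude reported. The default
between-network baseline is 0: the overall (median) connectivity level of
the non-GSR stream is carried by a shared global-signal component
(`global_amp`, default 0.5 of signal SD, added to all in-brain voxels), so
that global-signal regression re-centres the median connection near zero, as
observed empirically; specific cross-network coupling is planted as
deviations from that baseline. WM, CSF and facial voxels carry their own
confound series, which leak into gray matter at `confound_amp` (0.15);
voxel white noise has SD 0.5. All generating series, covariances and spike
frames are stored in a per-subject truth record.

**Geometry.** An even-x grid with the voxel-to-world affine placing x = 0
exactly between the two middle slices, so hemispheres mirror exactly. ROIs
are 2×2×2-voxel blocks on a lattice in the left gray-matter core, mirrored
to the right; networks are assigned round-robin. WM/CSF/face masks are
disjoint rectangular slabs ≥ 3 voxels thick (guaranteed to survive one-voxel
erosion, making the erosion rule testable); the face slab lies outside the
brain mask.

**Motion.** Smooth sinusoidal drift (≤ 0.05 mm) plus Poisson-placed
one-frame translation excursions of 0.6 mm, each producing two
supra-threshold FD transitions. Group spike rates (0.224 / 0.124 / 0.115
events per frame for LVCP / HVCP / NT) are set so expected motion-free
volumes reproduce the observed group ordering (~630 < ~854 < ~884 of 1240).
A per-subject gamma rate multiplier (shape 3) gives motion-free-volume
counts the large between-subject spread reported for such cohorts (SDs of
hundreds of volumes); without it the motion-free-volume covariate is almost
collinear with group, which both misrepresents the data and roughly doubles
the variance of covariate-adjusted group contrasts.

**Phenotypes.** Truncated-normal age (7–17) and composite IQ per group
(LVCP 54 ± 17.5 in [25, 77]; HVCP 106.9 ± 13.6 in [85, 130]; NT 111.8 ±
13.1 in [85, 134]), sex ratios ~14:3 / 15:5 / 14:5, verbal scores tracking
composite with r ≈ 0.95. Group sizes default to 17/20/19.

**Between-subject variability and planted effects.** Coupling parameters get
per-subject Gaussian jitter (`subject_sd`, default 0.06 z). The study does
not constrain this SD; 0.06 was chosen by a power analysis so that the
default planted effects (0.15 z) are detectable at the design's group sizes
(contrast noncentrality ≈ 4–5 after measurement noise), i.e. the generator
reproduces the qualitative finding pattern at a detectable effect size. The
default planted pattern is: LVCP within-network z reduced by 0.15 in
default, salience, auditory and frontoparietal; default↔dorsal-attention
between-network z raised by 0.15 vs NT; homotopic z reduced by 0.10; HVCP
shares the NT baseline. An optional `iq_conn_slope` plants connectivity
decreasing in IQ (uniform z offset of −slope per within-group IQ SD,
LVCP by default), emulating the dimensional low-IQ/high-synchrony effect.

**What the generator does not emulate.** Scanner physics, spatial
autocorrelation beyond parcel blocks, hemodynamic nonlinearity, distance-
dependent motion artifact, age/sex effects on connectivity, and realistic
anatomy. Passing recovery tests therefore demonstrates the correctness and
calibration of the *analysis machinery* under the assumed generating model,
not robustness to every artifact of real BOLD data.

## Numerical choices

- OLS residuals via economic QR projection (residual = Y − Q(QᵀY)); rank
  checked on |diag R| with pivoted-QR naming of collinear columns.
- Fisher transform guards: zero-variance columns are an error naming the
  ROI; |r| = 1 off the diagonal is an error by default (`on_perfect="inf"`
  stores signed infinity); near-1 values inside network means are clipped at
  1 − 1e−15 before atanh.
- Seeds: one global seed fans out through a `numpy` SeedSequence tree
  (per-subject spawn keys independent of cohort ordering); identical
  (config, seed) reproduces cohorts bit-identically, which the manifest
  checksums assert.
- The design table is written with `%.17g` floats and read back with
  round-trip parsing so a resumed run reproduces statistics bit-identically.
- The in-memory pipeline cleans only voxels that are read downstream (ROI
  blocks); confound means are extracted from the raw data beforehand, so
  this is purely an optimisation. Cleaned whole volumes are written when
  `write_volumes` is set.

## Simulation scales used by the test suite

Chosen as reduced-scale twins of the study design: oracle and contract tests
run on 16-ROI atlases with 200–600 frames; the statistical-calibration null
uses 50 cohorts of 8/8/8 subjects (320 frames, equal spike rates, 36 family
tests pooled per cohort) plus 1000 scalar ANCOVA replicates and 2000 BH
replicates at m = 333; the planted-effect recovery twin uses 50 cohorts of
17/20/19 subjects, 40 ROIs (the planted networks get six ROIs each), one
600-frame run, study motion conditions. Measured joint recovery at these
settings is 45/50 replicates with unplanted within-network families flagged
at ≤ 12%. The acceptance script runs one full default-condition cohort
(56 subjects, 32 ROIs, two 620-frame runs, both GSR streams) in ~1.5 min.

## Known limitations

- Between-network synchrony of network means is sensitive to within-network
  coupling through the normalisation of the mean series, so planted
  within-network differences propagate into between-network cells; this is a
  property of the summary itself, shared with the original convention.
- The homotopic rule is directional nearest-mirror; on strongly asymmetric
  atlases non-mutual assignments occur and are only flagged.
- The 0.001 Hz band edge is nominal at 8.5-minute runs (resolution
  ~0.002 Hz); the DCT basis simply omits no in-band column.
- ANCOVA assumes homoscedastic errors; high-motion groups have noisier
  connectivity estimates, a mild violation that the calibration tests bound
  empirically (type-I error within [0.03, 0.07] under the study design).
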