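# Methods

## The measurement

Every analysis in this package starts from per-voxel pairwise inter-subject
correlation (ISC). For subjects i, j with BOLD time courses s_i(t), s_j(t)
at a voxel, the within-condition statistic is the Pearson correlation over
the run; a condition with N subjects yields N(N−1)/2 unordered pair values
per voxel. The between-condition statistic correlates subject i's time
course in condition c1 with subject j's in condition c2 over all ordered
pairs i ≠ j (N(N−1) of them; same-subject cross-condition pairs are
excluded). Pair values are averaged as raw r — the between-condition
summary is *defined* as the arithmetic mean of pairwise correlations — and
a Fisher-z averaging option exists but is off by default. Zero-variance
time courses produce invalid (NaN) entries that are excluded and counted,
never averaged in as zeros. The per-voxel mean is computed by summing pair
values in sorted order, which makes the map bit-identical under any
permutation of subject bookkeeping.

## Preprocessing

Only steps that act on already-registered data are implemented (no motion
correction, registration, or tissue regression):

* **linear detrend** — per-voxel removal of the best-fit line;
* **high-pass, 0.01 Hz default** — projection onto the orthocomplement of a
  discrete-cosine drift basis (all cosines with frequency k/(2·T·TR) below
  the cutoff, plus the mean). Chosen over an IIR filter because it is
  linear, deterministic, exactly idempotent and has no edge transients;
* **spatial smoothing** — per-volume Gaussian, sigma = FWHM/(2√(2 ln 2)) in
  mm converted to voxels (8 mm FWHM default);
* **silence regression** — the narrative's silent periods form an indicator
  sampled at volume times (volume k covers [k·TR, (k+1)·TR); any overlap
  marks it), convolved with the canonical HRF and regressed out per voxel
  by OLS; residuals are used downstream. The HRF is the community-standard
  double gamma: peak delay 6 s, undershoot delay 16 s, dispersions 1 s,
  undershoot ratio 1/6, 32 s kernel, peak-normalized; convolution is causal
  (full linear convolution truncated to T).

Ordering matters: the default pipeline is detrend → high-pass → (smooth) →
silence regression, recorded in the run log. When the data have been
filtered before the nuisance step, the silence regressor must be passed
through the same filters, otherwise the filtered transient no longer
matches the raw regressor and residual shared variance survives the
regression (on the reference cohort this inflated mean ISC from the true
0.30 to 0.40; with the filtered regressor recovery is exact to ±0.001).
Whether the original analysis regressed silences before or after filtering
is not documented; the filtered-design convention used here removes the
transient exactly in either ordering.

## Inference

The one-sample question — is mean pairwise r positive here? — is answered
by sign-flip permutation. Under the null each pairwise correlation is
symmetric around zero, so surrogates are built by flipping signs of the
pair values and recomputing the mean map. Two schemes are provided:

* `pair_independent`: each pair flips i.i.d. This treats pair values as
  exchangeable units, which they are not (every subject sits in many
  pairs). On 200 null cohorts (n=10 subjects, 10×10×10 voxels, T=200,
  99 permutations) its family-wise false-positive rate at nominal 0.05 was
  0.185 — anti-conservative, because independent pair flips are not a
  valid invariance of the dependent pair matrix.
* `subject_blocks`: one sign per subject; pair (i, j) flips by the product
  of the two subjects' signs. Negating a subject's whole time series *is*
  an exact distributional invariance under the null, and it flips all of
  that subject's pairs coherently. The same 200-cohort experiment measured
  a rate of 0.05 — exact calibration. This is the scheme the calibration
  suite validates; the naive scheme is retained because it is widely used
  and its inflation at small n is worth measuring (analysis
  `06_calibration.py` reports both).

Statistic maps are enhanced with TFCE: score(p) = Σ_h e(h,p)^E · h^H · dh
over a ladder of thresholds from dh to the image maximum, where e(h,p) is
the voxel count of the connected supra-threshold component containing p.
Defaults E=0.5, H=2, 26-connectivity, 100 steps (the standard defaults of
the tool family that popularized TFCE). Only the positive tail is enhanced
by default (ISC hypotheses are one-sided); a two-tailed option exists.
Family-wise error is controlled by comparing each voxel's observed TFCE
score to the permutation distribution of the image-wide maximum, with
p = (1 + b)/(1 + n_perm) so p is never zero; uncorrected per-voxel p is
emitted as a diagnostic. Conjunctions use the minimum statistic: a voxel
is jointly significant only if significant in every input map.

Numerical notes: the TFCE ladder is data-dependent (dh = max/n_steps), so
the discrete transform is monotone in the input only on a fixed ladder;
doubling n_steps changes outputs by <1% on smooth maps. Monte-Carlo
experiments coarsen the ladder to 25 steps — a permutation p-value is
exact for any statistic, so this affects only the statistic's resolution,
not validity. All-zero maps enhance to zero rather than erroring.

## Behavioral measures and association

The lipreading test score is the percentage of target words (50 across 10
sentences) correctly reported; scoring is an order-free multiset
intersection of case-folded, punctuation-stripped tokens, which reproduces
the published worked example ("we eat" against "On Thursday we eat
pancakes" → 2 of 5). No stemming or inflection tolerance is applied — the
scoring rule beyond the worked example is undocumented, and exact matching
reproduces it. Comprehension ratings are continuous 0–1 traces at 5 Hz
summarized by their mean.

The association analysis asks where pairwise lipread–listen ISC covaries
with behavior. Each ordered pair carries the behavioral value of its
member in the lipreading role; the per-voxel statistic is the Pearson
correlation across pairs between ISC values and that predictor (equivalent
up to a monotone transform to the simple-regression slope test). The null
is built Mantel-style by shuffling subject labels in the behavioral table
and rebuilding the pair predictor — never by permuting pairs
independently, which would destroy the dependence structure. Because the
shuffle unit is already the subject, subject-level exchangeability blocks
are respected by construction. Score and rating are tested in separate
runs by default (a joint multi-predictor mode computes the multiple
correlation instead). Presentation-order control subtracts order-group
means — groups defined by the ordinal position of the lipreading
condition — from the predictor and from the per-pair ISC values, grouping
pairs by the lipreading member's group; this equals including the groups
as nuisance covariates, and only the lipreading member's group is used
because the predictor itself is that member's value.

## The synthetic cohort

Signals are built to make every expectation analytic. For subject i,
condition c, voxel v:

x(t) = √b·κ_i·h(t) + √(f − b·κ_i²)·u_c(t) + √(1 − f)·ε(t) + a·silence(t)

with h a component common to all conditions, u_c condition-specific, ε
subject-specific noise, all unit variance; f and b are the configured
within/between shared fractions (b ≤ f), and κ_i = skill_i/100 inside the
designated skill region, 1 elsewhere. Hence E[r] = f within a condition
(outside the skill region) and E[r] = b·κ_i·κ_j between conditions, which
the recovery suite verifies to ±0.05 voxelwise at T=2000. White Gaussian
processes are the default so these closed forms hold exactly; an
HRF-smoothed mode mimics BOLD autocorrelation, which inflates the sampling
variance of r but not its expectation. The silence transient a·silence(t)
is common to all subjects and inflates ISC until regressed out — this is
the scenario the nuisance step exists for.

Defaults mirror the study design this generator emulates: 29 subjects,
three conditions, 282 volumes at TR 1.7 s. Skills are drawn from a
truncated normal on [6, 100] whose *realized* mean and SD are 50.7 and 26
(the parent parameters are solved numerically, since truncation shrinks
the SD — naively truncating N(50.7, 26²) would give SD ≈ 21.7). Ratings
follow clip(0.7·skill/100 + order-offset + N(0, 0.28²), 0, 1); the slope
and noise were chosen so the population score–rating correlation is 0.542,
matching the published r = 0.54, and the order offsets (0, 0.03, 0.06)
reproduce the qualitative pattern of better subjective comprehension when
lipreading comes after the other modalities. Order groups are assigned
round-robin.

Effect sizes for voxelwise ISC (f, b, and the planted region's values) are
free parameters — the study reports no voxelwise ISC magnitudes for intact
narratives — so recovery experiments state their generating values
alongside the recovered ones. The power experiments plant a 3×3×3 region
with f=0.6, b=0.5 and skill-scaled coupling, a deliberately strong effect
chosen so that power failures indicate implementation faults rather than
an underpowered design.

What the generator does not emulate: realistic spatial autocorrelation of
brain images, physiological noise, motion, or spatial registration error.
Passing recovery tests therefore demonstrates correctness of the
estimators and error control under the stated model, not robustness to
real-scanner artifacts.

## Problem sizes

Monte-Carlo suites run at desk scale as the package's validation design:
calibration on 10×10×10 grids with T=200 and 99 permutations per test
(200 null repeats for the sign-flip test, 100 for the Mantel null), power
on 6×6×6 grids with T=300 and 199 permutations (20 repeats), recovery at
T=1000–2000 on 27-voxel grids. TFCE spills into voxels immediately
adjacent to a true cluster by construction (a noise voxel joining a large
component at low thresholds gains extent), so specificity counts exclude a
one-voxel border around planted regions.

## Known limitations

* The silence-sampling rule (any overlap with [k·TR, (k+1)·TR) marks
  volume k) is a convention; acquisitions with other conventions shift the
  regressor by at most one volume.
* The Mantel test assumes the behavioral predictor is exchangeable across
  subjects under the null; confounds that co-vary with skill are not
  modeled.
* Between-condition ISC requires equal run lengths across conditions; no
  time-warping is provided.
* The pair_independent sign-flip mode is retained for comparability but is
  anti-conservative for small cohorts; prefer subject_blocks.
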