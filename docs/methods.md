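# Methods

This note documents the models, estimators and numerical choices behind
`dyssync`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Deformation data model

A ventricle is a short-axis stack of `S >= 4` slices (slice 0 = most
apical, highest index = most basal), each divided into 6 sectors numbered
counter-clockwise, with (1,4), (2,5), (3,6) taken as the opposing-wall
pairs. Each of the `6 S` segments carries six measurements —
circumferential and radial strain (%), strain rate (1/s) and displacement
(mm) — sampled at 30 phases over one cardiac cycle. Phase 0 is
end-diastole; sample *i* sits at `i L / 30` ms on a periodic cycle of
length `L = 60000 / HR` ms (20 ms native spacing at a heart rate of 100).
Mixed-morphology ventricles (both ventricles traced, septum excluded) use
the same uniform grid; the format accepts any `S >= 4`.

Peak polarity per measurement: circumferential strain and strain rate peak
negative (systolic shortening), radial strain/strain rate and both
displacements peak positive. These defaults are encoded on
`MeasurementKind` and drive every extremum search.

## Interpolation and time-to-peak

Curves are resampled to 1-ms spacing by piecewise-linear interpolation with
periodic wrap between sample 29 and sample 0; the interpolant agrees
exactly with the native samples. Time-to-peak (TTP) is located at the
extremum sample in the polarity direction (ties broken by earliest time)
and then refined to sub-sample precision with the vertex of the quadratic
through the three native samples surrounding the peak (periodic wrap;
refinement clamped to ± half the native spacing, exact for locally
quadratic curves). The refinement matters: a piecewise-linear interpolant
attains its extremum at a native sample knot, so an unrefined grid argmax
would quantize every TTP to the ~20–33 ms native spacing and a curve
shifted by, say, 50 ms would show a 40- or 60-ms TTP change. With
refinement, planted circular shifts move TTP by the planted amount to
within ~1 ms on smooth curves.

Flat curves (range below 1e-9 in native units) raise a degenerate-curve
error rather than returning an arbitrary peak.

## The four dyssynchrony metrics

For each measurement kind, from the segmental TTP grid:

- **SDTTP** (ms): sample standard deviation (n−1) of all segmental TTPs.
- **MOWD** (ms): wall mean = mean TTP of one sector pooled over all slices;
  the metric is the maximum |difference| over the three opposing pairs.
- **BAD** (ms): |mean TTP of the most basal slice − mean TTP of the most
  apical slice|, reported as a magnitude (a signed variant is a trivial
  modification but all reporting uses the absolute value).
- **CCD** (ms): both the segment curve and the reference (the pointwise
  mean of *all* segment curves, the segment itself included) are
  mean-subtracted; the circular cross-correlation
  `c(τ) = Σ_t x(t) r(t−τ)` is evaluated at every integer-ms shift in
  (−L/2, L/2], and the segmental CCD is |τ*| at the maximum, ties broken
  by smallest |τ| then negative before positive. The per-ventricle global
  CCD is the 80th percentile (linear interpolation between order
  statistics, rank `q (n−1)`) of the segmental values; the percentile is a
  pipeline parameter (`--percentile`).

The correlation scan is computed via the FFT correlation theorem;
candidates within a 1e-9 relative band of the maximum are re-scored with
exact dot products so the returned shift (including tie handling) is
identical to an exhaustive scan — asserted exactly against an independent
brute-force oracle in the tests. Cross-correlation is unnormalized; because
both curves are mean-subtracted and only the argmax is used, per-curve
scaling does not affect the result. All four metrics are invariant to
adding a constant to every sample and to positive rescaling of amplitudes.

Global strain (GCS/GRS, %) is the polarity extremum of the interpolated
all-segment mean curve of the strain kinds.

## Clustering

The 24 dyssynchrony metrics (GCS/GRS excluded) are z-scored — mean 0,
sample SD 1 per column — over the entire cohort, patients and controls
together; a zero-variance column is an error, not silently dropped.
K-means (squared Euclidean, k-means++ initialization, 50 restarts,
tolerance 1e-6, max 300 iterations) is fit on the z-matrix; the elbow scan
uses 10 restarts per k over k = 1..10 for speed, and the final model 50.

**Elbow estimator.** "Maximum inflection point" is implemented as the
interior k maximizing the discrete second difference of **log** inertia,
`log I(k−1) − 2 log I(k) + log I(k+1)`, ties toward smaller k. The log
scale makes the curvature scale-invariant: it detects where the *relative*
inertia gains collapse. The raw-scale second difference (available via
`scale="linear"`) is dominated by the largest separation in the data — with
one small, very distant cluster it peaks at k = 2–3 regardless of finer
structure — whereas the log version recovers the planted k whenever
within-cluster inertia is small relative to the cost of merging the two
closest clusters. If no interior k has positive curvature (linear or
geometric inertia decay), the smallest interior k is returned with a
no-elbow warning. Inertia is checked to be non-increasing in k; a
local-optimum blip triggers a harder refit.

Raw K-means labels are arbitrary, so clusters are renumbered by ascending
cluster mean of z-scored circumferential-strain CCD: cluster 1 is the most
synchronous, the highest label the most dyssynchronous. PCA (top two
components of the feature covariance) provides visualization coordinates;
component signs are fixed by requiring each loading vector to have
nonnegative sum. Rank-1 data is projected with a zero-variance second
component rather than rejected.

## Survival analysis

Controls are excluded from all survival analyses. Time origin is the CMR
study; the event is the composite of death or heart
transplantation/listing (the generator emits a single composite flag, so
any distinction between transplantation and listing is outside this
package's scope); censoring is at last follow-up. Kaplan–Meier
product-limit curves are computed per cluster with pairwise log-rank tests
(unadjusted by default; a Bonferroni flag multiplies p by the number of
pairs). Cox proportional-hazards models use Efron tie handling and Wald
95% CIs, with cluster indicator coding against a configurable reference;
the pipeline reports the worst cluster against each other cluster in turn,
adjusted either for ventricular morphology (LV reference; RV and mixed
indicators) or for EDVi rescaled to 10 mL/m² units. Fewer than 5 events
per covariate triggers a warning; if the default Newton iteration
oscillates, the fit is retried with damped steps (0.5, then 0.25) before
an error is raised; exact collinearity raises an error. Group descriptives
use medians (IQR) with the Mann–Whitney U test for continuous variables
and Fisher's exact test for binary ones; an all-tied continuous comparison
reports p = 1 with a tie flag.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
imaging physics. Each segment's curve is a raised-cosine bump occupying
70% of the cycle starting at 0.15 L, peaking at `0.5 L + δ` with the
segment's activation delay δ; strain-rate curves are the analytic time
derivative (their systolic peak leads the strain peak by 0.175 L), and
displacement curves share the strain delay with amplitudes of ~0.25 mm
(radial) and ~0.15 mm (circumferential) per % radial strain. Additive
Gaussian noise has SD 0.3% of each curve's amplitude — feature-tracking
curves are smooth post-processed outputs, and this noise level reproduces
~1 ms TTP measurement error.

The delay field decomposes as systematic wall delay (sectors 4–6 late by
`w`), a linear base-to-apex gradient (basal late by `b`), and segmental
jitter. Jitter is a permuted stratified-normal sample (each subject
realizes the phenotype's delay *distribution*, not an i.i.d. draw),
projected orthogonal to the wall-pair and base-apex contrast directions
and renormalized, so a subject's MOWD equals `w`, BAD equals `b` and SDTTP
equals the phenotype dispersion exactly up to measurement error. Delays
are clipped to [−0.30 L, 0.45 L] so every kind's peak stays inside the
cycle (this mildly shrinks the realized dispersion of the most extreme
phenotype at high heart rates).

Four default phenotypes, ordered by increasing dyssynchrony, are anchored
to the observed cluster profiles: SDTTP 43/48/77/132 ms, wall delay (=
MOWD) 44/52/78/128 ms, BAD 28/37/51/68 ms, GCS −16/−16/−13/−8%, GRS
24/26/18/11%, EDVi 101/101/111/169 mL/m², EF 55/56/50/36%, QRS
94/101/106/122 ms, mixing 0.518/0.222/0.217/0.043, with morphology
mixtures shifting from LV- to RV/mixed-dominant across phenotypes.
Within-phenotype heterogeneity is a 2% lognormal scatter on all delay
parameters and 8% on amplitudes. These choices make the four phenotypes
crisply separated in feature space (centroid separations well above 8
within-cluster SDs), which is what the recovery guarantees (elbow k = 4,
ARI ≥ 0.9) require; real cohorts overlap far more (observed IQRs are
20–40 ms wide within clusters), so passing recovery tests demonstrates
correctness of the machinery, not expected performance on clinical data.

Outcomes are exponential with hazard `λ0 · HR(phenotype)`, hazard ratios
1.0/1.4/1.6/6.4 monotone in dyssynchrony (the observed cohort's mild
survival inversion between its two low-risk clusters is deliberately not
emulated), and independent uniform administrative censoring on (0, 12 y)
anchored to the observed follow-up range (median 4.2 y, IQR 1.7–8.8). The
baseline hazard λ0 is solved (Brent root-finding on the closed-form
expected event fraction under uniform censoring) so the expected patient
event fraction is 11.5%. Controls reuse the curve parameters of the two
most synchronous phenotypes with control-LV covariates (EDVi ~82, EF ~60,
QRS ~84) and contribute no events.

Known simplifications: independent Gaussian curve noise (no spatial or
temporal covariance between segments), shared delays across all six
measurement kinds, deterministic phenotype signatures (stratified jitter,
orthogonalized contrasts), a single composite event flag, and uniform
rather than right-skewed censoring.

## Problem sizes and numerical tolerances

Simulation-based checks run at sizes chosen to balance statistical
resolution against desk-scale runtimes: the elbow selection rate uses 100
seeded default cohorts in the acceptance suite (20 in the acceptance
script's summary), CCD oracle equivalence 200 random curve pairs (exact
equality required), shift recovery all integer shifts 1–200 ms (±1 ms),
Cox CI coverage 200 replicates of the planted design (n = 512, ~11.5%
events), the null-recovery and bias checks 200 replicates at ~150–300
events, and log-rank permutation uniformity 400 permutations
(Kolmogorov–Smirnov p > 0.01). Degenerate-curve tolerance is 1e-9 in
native units; z-scoring uses the n−1 SD; CCD candidate re-scoring uses a
1e-9 relative band (FFT round-off is ~1e-13 relative, so the exact
re-scoring cannot miss the true maximum). Float round-trip of cohort CSVs
is bit-exact (`%.17g` on write, round-trip parsing on read).
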