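# dyssync

Mechanical-dyssynchrony phenotyping of single-ventricle (Fontan) cohorts
from CMR feature-tracking deformation curves.

Patients palliated to a Fontan circulation are a heterogeneous group whose
outcomes track with ventricular dilation, dysfunction and mechanical
dyssynchrony. `dyssync` implements, as a tested and reusable pipeline, an
unsupervised phenotyping analysis of segmental deformation data: it computes
24 timing-based dyssynchrony metrics per ventricle, partitions subjects with
K-means (model order chosen by the elbow of the inertia curve), and
contrasts the resulting phenotype clusters on a composite time-to-event
outcome (death or heart transplantation/listing). Because feature-tracking
cohorts of this kind are not publicly deposited, the package includes a
first-class synthetic cohort generator with planted phenotypes and hazards,
so every stage of the pipeline is testable end to end.

## The metrics

Each ventricle is a short-axis stack of `S >= 4` slices x 6 sectors, and
every segment carries six deformation measurements (circumferential and
radial strain, strain rate, displacement) sampled at 30 phases per cardiac
cycle. Curves are linearly interpolated to 1-ms resolution (periodic in the
cycle). With TTP(s) the time of segment *s*'s polarity extremum
(sub-sample refined; negative peak for circumferential strain and strain
rate, positive otherwise), the four metrics per measurement are:

- **SDTTP** — sample standard deviation of all segmental TTPs;
- **MOWD** — max over the three opposing-wall pairs (1,4), (2,5), (3,6) of
  |mean TTP difference| (sector means pooled over slices);
- **BAD** — |mean TTP(basal slice) − mean TTP(apical slice)|;
- **CCD** — per segment, |argmax over integer-ms circular shifts τ of
  Σ_t x(t)·r(t−τ)| against the all-segment mean curve r (both
  mean-subtracted); the per-ventricle summary is the 80th percentile of the
  segmental values.

4 metrics x 6 measurements = 24 features per subject, plus global
circumferential/radial strain (GCS/GRS) from the mean curve. Features are
z-scored over the whole cohort (patients + controls), clustered with
K-means (k-means++ init, 50 restarts), relabeled so cluster 1 is the most
synchronous, visualized with 2-component PCA, and contrasted with
Kaplan–Meier curves, pairwise log-rank tests, and multivariable Cox models
(Efron ties) adjusting for ventricular morphology or indexed end-diastolic
volume per 10 mL/m².

## Worked example

```bash
dyssync run-all --seed 7 --out demo_out
```

simulates the default cohort (512 patients + 42 controls), computes the
feature matrix, selects k by the elbow, and runs the survival contrasts:

```
selected k = 4
features: demo_out/features.csv
clusters: demo_out/clusters.csv
model: demo_out/cluster_model.json
comparisons: demo_out/comparisons.csv
survival: demo_out/survival.json
manifest: demo_out/manifest.json
```

The first feature rows (`features.csv`, delays in ms, strains in %):

```
            sdttp_cs  mowd_cs  bad_cs  ccd_cs   gcs   grs
subject_id
P0001           47.9     53.9    37.1    52.0 -16.0  26.1
P0002           75.2     79.7    50.5   111.0 -10.4  14.4
P0003           76.5     78.6    49.9   105.2 -11.0  15.3
```

P0001 is a mildly dyssynchronous ventricle with preserved strain
(GCS −16%); P0002/P0003 show wide time-to-peak dispersion, opposing-wall
delays near 80 ms and depressed strain — the intermediate-risk phenotype.
For this seed the run observed 63/512 composite events (12.3%), and the Cox
contrast of the most- vs least-dyssynchronous cluster gave HR 10.8
(95% CI 4.6–25.2) adjusted for morphology and HR 11.4 (4.3–30.4) adjusted
for EDVi per 10 mL/m² (the planted worst-vs-best hazard ratio is 6.4;
with only ~24 subjects in the worst cluster the per-cohort estimate is
noisy, which is why coverage is assessed over replicates — see below).

The same stages are available individually (`dyssync simulate`,
`dyssync metrics`, `dyssync cluster`, `dyssync survival`) and as library
functions (`dyssync.compute_features`, `dyssync.kmeans_fit`,
`dyssync.cox_fit`, ...).

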