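# Methods

This note records the models, conventions and parameter choices behind
`budquant`, in the order of the pipeline.

## Image model and reference algorithms

**Channels.** A slide is a pair of aligned rasters with a physical pixel
size (µm/pixel): PanCK (epithelium) and Hoechst (nuclei). All morphology
parameters are physical; nothing depends on the raster resolution except
through discretisation.

**Segmentation.** In the production setting the tumour mask comes from
trained semantic-segmentation models, merged by pixel-wise union (the
ensemble rule implemented in `ensemble_union`). Since such models cannot be
reproduced without their annotations, the shipped `ReferenceSegmenter` is a
classical stand-in: minimum-subtraction background correction → Gaussian
smoothing (default 1 µm) → global threshold (Otsu by default; a fixed
threshold is available and, combined with minimum subtraction, is exactly
invariant to additive intensity shifts) → filling of holes smaller than
100 µm² → removal of objects smaller than 50 µm². The hole-area cap is
deliberately small so that genuine moats around buds lying in concavities
of a mass are preserved. An optional morphological opening (default off)
regularises contours. On the two-level synthetic slides this segmenter is
essentially exact (Dice 1.0); on real stained tissue it is a baseline, not
a substitute for a trained model — the segmenter interface accepts any
object with a `segment()` method.

**Nucleus detection.** The contract is two prediction maps: pixel-wise
proximity to the nearest nucleus centre, and predicted nucleus radius. The
reference generator uses the scale-normalised Laplacian-of-Gaussian
response at σ = radius/2 (matching Gaussian-blob-like nuclei) and a
constant size map. Centres are the strict local maxima above a detection
floor, accepted greedily strongest-first with suppression of any weaker
maximum within `separation_factor × predicted radius` (default 1.0: nuclei
may abut but centres cannot overlap); ties in height break in raster order
for determinism. The floor is the larger of a quantile of the proximity map
(default 0.99, making detection invariant to multiplying the image by a
positive constant) and a fraction of the peak response (default 0.2). The
relative component matters when nuclei occupy much less than 1 % of the
image: a pure quantile then sits inside background noise and admits
spurious maxima.

**Clusters, buds, regions.** Clusters are connected components of the mask
under 8-connectivity (diagonal cell contacts should not split a cluster).
A nucleus belongs to the cluster containing its centre pixel; membership by
centre containment (rather than disc overlap) keeps assignment
deterministic. A cluster is a bud iff it contains 1–4 nuclei; 0-nucleus
PanCK objects are most plausibly artefacts or out-of-plane cuts and are
never buds. The core is the morphological closing of the mask (Euclidean,
via exact distance transforms) minus closed components below a minimum
area; closing radius and minimum core area are configurable (defaults
100 µm and 0.5 mm² at full scale; the synthetic test scale uses 40 µm and
0.02 mm², consistently with its smaller geometry). The core is the *full*
closed mass, so it overlaps the inner half of the invasive front; the front
is `dilate(core, 500 µm) XOR erode(core, 500 µm)`, a 1000 µm band. When the
core lies within 500 µm of the image border the outer band is clipped and
the partition carries a `truncated` flag.

**Features.** Seven per patient: bud count and density (buds/mm²) in core
and front (a bud is in a region iff its centroid pixel is), and hotspot
counts over circular fields of view — 0.785 mm² (radius 500 µm) singly and
ten-fold, and 0.238 mm² (radius ≈ 275.2 µm) ten-fold. The field shape is
circular (a microscope field); candidate centres lie on a grid of stride
radius/2 over the whole image; fields are selected greedily by descending
count and may not overlap (centre distance ≥ one diameter), mirroring the
manual practice of distinct fields. Greedy k = 1 coincides with the
exhaustive maximum over the candidate grid. Densities are reported in
physical units for resolution independence.

## Survival machinery

**Log-rank.** The two-group statistic is the standard observed-minus-
expected sum over distinct event times with hypergeometric variance,
referred to χ²(1). It is implemented in vectorised numpy (`LogrankScanner`
precomputes everything grouping-independent) because cut-off scans and the
tree evaluate it ~10⁵ times; it matches `lifelines` to machine precision,
including ties, and equals the Cox score test on untied data.

**Optimal cut-off and pre-validation.** Candidate cut-offs are midpoints of
consecutive sorted unique values ("low" includes equality); a candidate is
feasible when both groups hold ≥ 25 % of the sample (the minimum-prevalence
rule is applied to the univariate analyses as well as the tree — a single
consistent definition that prevents degenerate cut-offs). The reported
statistics use leave-one-out pre-validated labels. Measured on null
cohorts, the pre-validated log-rank rejects at ~7–10 % for a nominal 5 %
level — pre-validated tests are known to be mildly liberal, and the bias
grows with n as the per-fold cut-offs stabilise toward the full-data
optimum; the naive (un-pre-validated) optimal-cut-off "p-value" rejects at
~40–60 % and must never be read as a p-value. q-values therefore remain
approximate upper bounds on the discovery rate rather than exact
guarantees.

**Cox.** Univariate and categorical fits use the partial likelihood with
Efron tie handling (lifelines), Wald intervals, and for the staging
comparison the three overall tests on 2 df: likelihood ratio, Wald
(β′Σ⁻¹β), and the score log-rank (the k-group log-rank statistic).

**Multiple testing.** Benjamini–Hochberg step-up with the null proportion
fixed at 1 (the most conservative q-value variant), implemented directly
because the hypothesis count m may exceed the number of p-values actually
corrected; with m equal to the vector length it reproduces textbook BH
(cross-checked against statsmodels).

**Survival decision tree.** Each node's split minimises the log-rank
p-value over all features and cut-offs: numeric and ordinally encoded
features (TNM II=1 … IV=4; pT 2a…4b = 1…6; nodes N0<N1<N2; grade
G2<G2-3<G3) by cut-off scan, strictly categorical features (growth
pattern, treatment, gender) one-vs-rest. The ordinal TNM encoding lets a
single cut express the (II+III) vs IV separation while metastasis is also
offered as its own binary feature. Ties in p break by a fixed feature
precedence (clinical features in cohort-description order, then the seven
budding features) and then by smallest cut-off — the tree is fully
deterministic. Depth is capped at two and only the most populated depth-1
node is split (population ties go to the branch with the lower observed
event fraction), so the model always has three leaves when both splits are
feasible: II′ (low branch of the second split), III′ (high branch), IV (the
root branch not split further). A node is split only if it holds ≥ 8
patients. Pre-validation grows the tree N times on N−1 patients and routes
the held-out patient through that fold's decisions; feature votes per node
are recorded, and `fix_and_revalidate` forces the second node's feature
(re-optimising only its cut-off per fold) to make the final model unique.
If a fold's second split is infeasible the held-out patient is assigned by
the root decision alone (logged in the fold record).

## Synthetic data

**Slides.** Masses (clusters with 6–12 nuclei) are discs placed near the
image centre; in-core buds sit in holes punched inside masses, surrounded
by a moat of width 2 × nucleus radius — narrower than the closing diameter,
so closing absorbs them into the core while they remain separate connected
components; peritumoural buds keep a gap of more than twice the closing
radius from the closed mass (computed from the actual closing of the
planted mass union, so bridged gaps between masses are respected) and lie
within 500 µm of it. All clusters are separated by at least two nucleus
radii, so connected components recover the planted cluster set exactly.
Nuclei are isotropic Gaussian blobs (σ = radius/2, amplitude 120 over a
background of 5) with centres ≥ 2 radii apart; optional artefacts are
bright PanCK-only discs with no nuclei; optional stromal nuclei appear in
Hoechst outside the mask. Noise, when enabled, is Poisson shot noise plus
additive Gaussian. Placement is rejection sampling with explicit failure
(`PlacementError`) when the geometry cannot host the request. The default
pixel size is 0.5 µm (a typical 20× scan; the true scan resolution is not
documented, so this is a configurable default, not an asserted value). The
test suite and acceptance script run at 2 µm/pixel on 768² images (a
1.5 mm field) with nucleus radius 8 µm and closing radius 40 µm — the same
geometry scaled for speed.

What the slide generator does *not* emulate: staining variability and
bleed-through, out-of-focus planes, tissue folds, scanner optics, and
irregular (non-disc) cluster shapes. Passing image tests therefore
demonstrate the correctness of the morphology, counting and feature logic,
not segmentation robustness on real tissue.

**Cohorts.** Covariates follow the emulated MIBC cohort: TNM
II/IIIA/IIIB/IV at 25/41/4/30 %, metastasis iff stage IV, pT, nodal
status, grade, growth pattern, treatment and gender at their observed
prevalences, age ~ N(66, 12²) clipped to 29–87. The core bud count is
log-normal with a stage-dependent location (log-means 2.4/2.9/3.1/3.4,
σ = 0.8) — the budding–stage association — and the other six features are
noisier functions of it (Poisson-degraded), making the core count the most
informative budding readout. Survival is exponential with hazard
`baseline × exp(β_met·1[IV] + β_tb·1[core count > 20])`; defaults
β_met = log 5.5, β_tb = log 2.6, baseline 0.007/month, chosen so that a
100-patient cohort shows ≈ 24 months median disease-specific survival and
≈ 54 % deaths under uniform censoring on (0, 113.13] months. Censoring is
uniform and independent of covariates — the simplest mechanism satisfying
the Cox assumptions; the generator does not emulate competing risks,
covariate-dependent censoring, or non-proportional hazards.

## Numerical choices and degenerate inputs

- Dice of two empty masks is 1.0 by convention.
- A constant image segments to an empty mask (no contrast is not an error);
  negative intensities are an error.
- Log-rank with zero variance (e.g. identical groups) returns statistic 0,
  p = 1; an empty group is an error.
- Features with fewer than two distinct values, or no prevalence-feasible
  cut-off, raise `DegenerateDataError`; the univariate table flags and
  excludes such features rather than failing the run.
- Cohorts below 8 patients are rejected everywhere.
- Cut-off ties resolve to the smallest cut-off; equal-height detection
  maxima resolve in raster order; all fits are deterministic given inputs.

## Known limitations

- The reference segmenter and map generator are classical baselines; the
  published performance of the trained models they stand in for (e.g. their
  agreement with manual annotation) is not reproducible here.
- Pre-validated p-values are mildly liberal (see above); permutation
  calibration would be the rigorous alternative and is not implemented.
- The hotspot search is grid-based; a finer stride trades runtime for
  exactness of the continuous optimum.
- Euclidean morphology via distance transforms treats the image border as
  open; cores near the border yield truncated fronts (flagged, not
  corrected).
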