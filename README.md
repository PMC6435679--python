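# budquant

Automated tumour-budding quantification and survival staging for
muscle-invasive bladder cancer (MIBC).

Tumour buds — discrete clusters of up to four cancer cells at or near the
invasive margin — are a prognostic feature in several carcinomas, but manual
counting is slow and observer-dependent. `budquant` implements a fully
automated pipeline over two-channel immunofluorescence whole-slide images
(PanCK marking epithelium, Hoechst marking nuclei):

1. **Tumour mask** — pluggable segmenter interface with ensemble-by-union
   (a pixel is tumour if either of two segmenters calls it tumour); a
   classical reference segmenter is shipped.
2. **Nucleus detection** — per-pixel proximity and size prediction maps fed
   to a deterministic local-maxima algorithm with radius-based suppression.
3. **Cluster analysis** — tumour cell clusters are the connected components
   of the mask; a cluster containing between 1 and 4 nuclei is a tumour bud
   (0-nucleus clusters are treated as artefacts).
4. **Regions** — the tumour core is the main mass after morphological
   closing (small closed regions removed); the invasive front is the
   1000 µm band straddling its boundary (500 µm inside + 500 µm outside),
   from Euclidean dilation/erosion.
5. **Seven budding features per patient** — counts and densities (buds/mm²)
   in core and front, plus hotspot counts in circular fields of view: the
   single and the ten hottest non-overlapping 0.785 mm² fields, and the ten
   hottest 0.238 mm² fields.
6. **Survival analysis** — each feature is dichotomised at the log-rank
   optimal cut-off under a 25 % minimum group prevalence, with
   leave-one-out *pre-validation*: patient *i*'s low/high label comes from
   the cut-off optimised on the other N−1 patients, so no patient's outcome
   informs their own grouping. Log-rank tests, univariate Cox (Efron ties),
   and Benjamini–Hochberg q-values over the m = 7 budding hypotheses.
7. **TB stage model** — a depth-2 survival decision tree that splits each
   node by the (feature, cut-off) pair minimising the log-rank p-value
   (categorical features one-vs-rest), splits only the most populated
   depth-1 node, and is leave-one-out pre-validated. The three leaves
   (II′, III′, IV) are compared by categorical Cox regression (per-group
   hazard ratios, overall likelihood-ratio / Wald / score log-rank tests on
   2 df) and Kaplan–Meier curves with risk tables.

Synthetic generators make every stage testable offline: two-channel slides
with planted masses, in-core and peritumoural buds, artefacts and full
ground truth; and survival cohorts with MIBC-like covariate prevalences, a
stage-dependent budding burden, and proportional-hazards survival with
configurable effects and censoring.

## Worked example

```python
import budquant as bq
from budquant import cohort as C

df = bq.generate_cohort(bq.CohortSimParams(n_patients=100, seed=7))
table = bq.univariate_table(df, bq.FEATURE_NAMES, m=7)
print(table[["logrank_p", "q_logrank", "hr"]].round(4))

tree = bq.fix_and_revalidate(df, "Number of TB in core")
comp = bq.staging_cox(*C.survival_arrays(df), tree.groups_, baseline="II'", m=7)
print(comp.per_group.round(3))
```

prints (abridged)

```
                                  logrank_p  q_logrank      hr
feature
Number of TB in core                 0.0003     0.0023  2.8454
Number of TB in invasive front       0.0085     0.0119  2.2869
Density of TB in core                0.1204     0.1405  1.5960
...

root feature:   tnm_stage   cutoff: 3.5
second feature: Number of TB in core   cutoff: 17.5
second-node feature votes: {'Number of TB in core': 100}
group sizes: {"II'": 48, "III'": 25, 'IV': 27}
           hr  hr_ci_low  hr_ci_high      p      q
group
III'    3.081      1.369       6.936  0.007  0.046
IV     11.022      5.128      23.691  0.000  0.000
overall log-rank (2 df): 53.38  p = 2.56e-12
```

Reading: the pre-validated core bud count is the most prognostic budding
feature (HR 2.85, q = 0.0023). The tree's root separates metastatic
patients (ordinal TNM cut at 3.5, i.e. II+III vs IV); the second decision —
chosen unanimously across the 100 leave-one-out runs — dichotomises the
non-metastatic branch at ~18 buds in the core, and the resulting three-group
staging separates survival strongly (overall log-rank 53.4 on 2 df).

The image side is symmetric: `bq.generate_if_image` renders a slide with
known ground truth and `bq.quantify_image` recovers mask (Dice 1.0 on clean
slides), nuclei, bud flags and the seven features. A `budquant` CLI exposes
`simulate-image`, `simulate-cohort`, `quantify`, `survival`, `tree` and
`replicate` subcommands.

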