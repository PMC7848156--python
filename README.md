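# ecdc — utilization subgroups in early-childhood dental care

`ecdc` discovers latent utilization subgroups in pediatric Medicaid-style
dental claims with unsupervised learning.  It is aimed at health-services
researchers and ACO analysts who want to move beyond demographic
segmentation of early-childhood dental care (ECDC, all dental services at
ages 24–60 months) and find data-driven subpopulations to target with
prevention and cost-containment programs.

## Method

1. **Visit categorization.** Dental claim lines are collapsed to
   per-patient-day *visits*, each assigned exactly one of four mutually
   exclusive categories by priority:
   *T+OR* (treatment with operating-room use: a restorative / root-canal /
   oral-surgery CDT code D2000–D3999, D7000–D7999 together with an
   anesthesia-or-facility CDT code, or an OR CPT code plus a dental ICD
   diagnosis), *T−OR* (treatment without OR evidence), *preventive*
   (D1000–D1999), and *other*.
2. **Cost-curve vectors.** For each patient and category, the cumulative
   2017-dollar cost curve C(m) = Σ cost of visits at ages ≤ m is sampled on
   a monthly grid m = 24…60.  The four curves are concatenated into a
   148-dimensional feature vector x_i.
3. **Clustering.** Patients are clustered by k-means (Euclidean distance,
   k-means++ seeding, 10 restarts) on log1p-compressed, per-feature
   standardized vectors; k is selected at the knee of the inertia-vs-k
   curve (maximal discrete curvature of log I(k), k = 2…8).  Quality is
   scored by silhouette and Calinski-Harabasz against a uniform
   random-assignment baseline.
4. **Labeling and statistics.** The five clusters are mapped bijectively to
   *zero utilization*, *regular preventive care*, and *early/mid/late onset
   of decay* (ordered by median age at first T+OR visit).  Per-subgroup
   annual-cost summaries (median, IQR, mean, share of total cost) are
   compared with Kruskal-Wallis; clusters are validated against each
   patient's pre-24-month medical history (cost, visit counts, a
   three-level chronic-complexity stratifier) and reproduced on the urban
   stratum.

Because real Medicaid claims are restricted, the package ships a synthetic
cohort generator (`ecdc.synthetic_data`) that plants a five-subgroup
structure — mixture weights 0.5 / 3.0 / 5.8 / 67.7 / 23.0 %, log-normal
annual-cost laws from published medians and IQRs, treatment onsets near
28 / 35 / 44 months, and pre-24-month medical profiles — so the whole
pipeline is testable end to end.

## Worked example

```python
from ecdc import GeneratorConfig, generate_cohort, preprocess, analyze_cohort

claims, patients, truth = generate_cohort(GeneratorConfig(n_patients=10_000, seed=1))
claims = preprocess(claims)          # drop pharmacy, clamp negatives, 2017 USD
result = analyze_cohort(claims, patients, seed=1)

print(f"elbow-selected k = {result.k}")
print(result.subgroup_table.round(2).to_string())
```

prints (seed 1):

```
elbow-selected k = 5
                n  pct_of_population  median_annual_cost       q1        q3  mean_annual_cost  pct_of_total_annual_cost
subgroup
early_onset    47               0.47             9526.95  7782.78  12190.74          10246.38                      8.42
mid_onset     284               2.84             5206.00  4315.00   6060.19           5328.81                     26.45
late_onset    566               5.66             2992.14  2412.74   3546.02           3100.08                     30.67
preventive   6817              68.17              186.54   100.97    352.12            289.15                     34.46
zero_util    2286              22.86                0.00     0.00      0.00              0.04                      0.00
```

The three decay-onset subgroups hold 9.0% of the cohort but consume 65.5%
of total annual dental cost; the early-onset median annual cost ($9,527) is
fifty times the preventive-care median ($187).  The fitted clustering
scores silhouette 0.736 against −0.042 for random labels, and the
representative (centroid-nearest) patients of the early-, mid-, and
late-onset clusters have their first T+OR visit at 27, 35, and 44 months.
The recovered clusters agree with the generator's planted subgroups with
adjusted Rand index 0.997.

A full run with artifacts (tables, plots, recovery report) and a CLI:

```bash
ecdc run --n 10000 --seed 1 --out runs/demo
ecdc report --run runs/demo
```

## Acceptance script

`scripts/acceptance.py` regenerates the default 10,000-patient cohort from
the given seed, executes the complete pipeline (preprocess → categorize →
curves → elbow-selected k-means → label → summarize → pre-24 profile), and
writes the measured subgroup quantities — population shares, median annual
costs, representative onset ages, decay-group cost share, and the
early-onset pre-24-month complexity and medical-cost figures — as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/ecdc/claims_io.py` — claim/patient data model, CSV I/O, preprocessing
- `src/ecdc/visit_categorizer.py` — per-day visit collapse and categories
- `src/ecdc/cost_curves.py` — cumulative curves and clustering vectors
- `src/ecdc/clustering.py` — k-means, k selection, quality, labeling
- `src/ecdc/subgroup_stats.py` — PMPY, subgroup cost tables, Kruskal-Wallis
- `src/ecdc/pre24_validation.py` — complexity stratifier, pre-24 profiles,
  stratum reproduction
- `src/ecdc/synthetic_data.py` — planted-structure cohort generator
- `src/ecdc/pipeline.py`, `src/ecdc/cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions and numerical choices
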