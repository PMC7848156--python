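# Methods

This note records the modelling assumptions, parameter choices, and
numerical conventions behind `ecdc`, in the spirit of the methods
documentation of packages like statsmodels or scanpy: what the procedure
computes, which knobs matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## 1. Data model and preprocessing

A claim line is (patient, claim class, service-age in days, procedure code,
diagnosis codes, paid amount, service year).  All analysis is done on
patient *age*, never calendar dates; ages in months are
`floor(days / 30.4375)`.  Preprocessing applies, in order:

- **Pharmacy exclusion** — pharmacy lines carry no dental or medical-visit
  information used here.
- **Negative-payment clamping** — negative paid amounts (payment
  adjustments/recoupments, roughly 1% of lines in practice) are set to $0.
  Clamping, not dropping: the service still occurred.
- **Inflation adjustment** — paid amounts are multiplied by a per-year
  deflator into 2017 dollars.  The deflator table is configuration (YAML);
  the default is the identity index, appropriate for the synthetic cohort
  whose amounts are generated in constant dollars.
- **Eligibility** — continuous enrollment over months [6, 60), checked at
  month granularity on half-open spans; abutting spans are continuous.
  Month granularity is a convention; sub-month gaps are invisible at the
  resolution of age-in-months claims.

ICD codes are stored undotted and upper-case so that prefix-range matching
(ICD-9 520–529; ICD-10 K00–K14, M26–M27) is deterministic.

## 2. Visit categorization

All dental lines of one patient on one day form one visit.  Category
predicates are evaluated on the day's pooled codes, then assigned by strict
priority T+OR > T−OR > preventive > other, so every visit gets exactly one
label and adding a line can only raise a day's category.  Two conventions
the code tables leave configurable:

- The OR-associated CPT set contains the literal string `"0360"`, which is
  not a well-formed 5-digit CPT code; codes are compared verbatim (no zero
  padding), and deployments can edit the YAML table.
- Medical-class lines on a dental-visit day contribute neither codes nor
  cost to the visit: categories describe dental utilization.

Zero-cost visits are retained — a $0 visit is still utilization.

## 3. Cost curves and features

Per patient and category, the cumulative cost curve is sampled at integer
months 24…60 (37 points; visits at exactly month 60 are included).  Monthly
sampling is the natural resolution of age-in-months data and fixes the
concatenated feature length at 4 × 37 = 148.  Curves are non-decreasing,
conserve total cost, and are additive over disjoint visit sets; these are
enforced as property tests.  Annual cost is the window total divided by 3
(the 36-month window), which makes the subgroup summaries directly
comparable to per-year figures.

## 4. Clustering

`TrajectoryKMeans` is Lloyd's algorithm with k-means++ seeding, `n_init=10`
restarts, a 300-iteration cap, and a fixed seed; per-iteration inertia is
recorded and checked non-increasing.  Empty clusters are re-seeded at the
worst-fit point.

**Feature transform.** By default the dollar curves pass through `log1p`
and per-feature standardization before distances are computed
(`transform="log1p"`, `scale=True`; `"none"`/`False` restore raw dollars).
This is a deliberate deviation from clustering raw dollar curves, and it is
load-bearing.  Subgroup cost laws are heavy-tailed log-normals whose
within-group spread (e.g. early-onset IQR $7,052–$11,216/yr) is comparable
to between-group mean gaps; in raw dollars, squared-Euclidean k-means then
prefers splitting wide high-cost clusters and merging the low-cost
preventive and zero-utilization masses.  On the default synthetic cohort,
raw-dollar k-means at k=5 recovers the planted subgroups with adjusted Rand
index ≈ 0.24; log1p alone ≈ 0.54; log1p + standardization ≈ 0.99.  The log
compresses the cost scale so that *when* care happens matters as much as
how much it costs; standardization re-weights rare but informative features
(e.g. T+OR months only early-onset patients occupy).  All quality scores
and centroids are reported in this clustering space.

**Choice of k.** The knee of the inertia-vs-k curve is automated as the k
maximizing the discrete curvature of log I(k) over k = 2…8, with the curve
anchored at the analytic k=1 inertia (total dispersion) so the smallest k
has a defined curvature.  The log makes the criterion scale-free: with
clusters of very different spread, the largest *absolute* second difference
always sits at the smallest k, whereas the knee of the relative-improvement
curve sits where structure is exhausted.  Equal curvature ties break toward
smaller k; a flat (degenerate) curve returns the smallest k.  The full
curve is logged and returned so a human can apply judgment to borderline
cases.  On the default cohort the rule selects k=5 with a wide margin
(curvature ≈ 0.26–0.30 at k=5 vs ≤ 0.21 elsewhere, stable across seeds).

**Quality.** Silhouette (in [−1,1]; subsampled to 2,000 points with a
seeded RNG at cohort scale, since the full pairwise matrix is O(n²)) and
the Calinski-Harabasz ratio, reported raw and as raw/(1+raw) ∈ [0,1).  A
zero within-cluster dispersion maps to a large finite sentinel (1e12).
Published CH values on the original application are far below this
statistic's usual magnitude, implying an unstated normalization; we report
both conventions and do not target those numbers.  Both scores are
compared against uniform random assignments (averaged over replicates); on
structured data the fitted clustering dominates the baseline by a wide
margin (silhouette ≈ 0.74 vs ≈ −0.04 on the default cohort).

**Labeling.** For k=5, clusters map bijectively to subgroups by
median-based rules (robust to outlier patients): minimal-median-cost
cluster with zero median visit count → zero utilization; the unique
remaining cluster whose median patient has no T+OR visit → preventive; the
rest ordered by median age at first T+OR visit → early/mid/late onset.
Violations raise errors with per-cluster diagnostics rather than guessing.
The representative patient of a cluster is the member nearest its centroid
(ties → smallest patient id).

## 5. Statistics

- PMPY: mean per-patient cost per one-year age band ([24,36), [36,48),
  [48,60] — last band closed); Welch (unequal-variance) two-sample t-tests
  for male vs female, NaN on zero variance.
- Quantiles: linear interpolation between order statistics (numpy default),
  used for all medians/IQRs.
- Kruskal-Wallis with tie correction (the zero-utilization group is a tie
  mass at $0); all-identical data returns (H, p) = (0, 1) by convention.
- No multiple-testing adjustment is applied anywhere.

## 6. The synthetic cohort

The generator plants five subgroups with the published structure: mixture
weights 0.5 / 3.0 / 5.8 / 67.7 / 23.0 % (urban stratum: 0.4 / 2.5 / 4.5 /
35.5 / 57.1 %, with the non-urban complement computed so the cohort-wide
mixture stays at the overall weights; the urban fraction defaults to
2,250/24,223).  Per subgroup, annual dental cost follows a log-normal with
μ = ln(median) and σ = ln(q3/q1)/(2·0.6745) from the published median/IQR;
onset ages are uniform integers center ± 2 months around 28/35/44;
preventive visits recur every 6 ± 1 months; pre-24-month medical cost is
log-normal from the published profile, visit counts are shifted Poisson
matched to the published medians, chronic diagnoses are emitted with the
published complex-chronic probability (two body systems) and probability
0.25 of one non-progressive system; pre-24 dental exposure follows the
published any-visit probability and first-visit-age medians.  Sex is male
with p = 0.51, independent of subgroup.

Free choices the published statistics do not constrain, fixed once:
decay-group window cost is allocated 70% to T+OR days, 25% to T−OR, 5% to
preventive visits (totals, which the published tables do constrain, are
unaffected); the early-onset group gets one extra T+OR recurrence ≈ 6
months after onset (consistent with the recurrence of caries treated under
general anesthesia); T−OR follow-up counts are 1 + Poisson(2); ~1% of paid
amounts are emitted negated to exercise clamping.

What the generator does **not** emulate: realistic CDT/CPT code diversity
(a handful of representative codes stand in), provider and place-of-service
structure, seasonality, calendar-time cost trends (amounts are constant
2017 dollars; the inflation machinery is exercised with configurable
indices in tests), pharmacy claims, in-window medical claims (medical
history is emitted only before 24 months, the only place the analysis uses
it), enrollment churn (everyone is continuously enrolled unless a gapped
fraction is requested), and any planted sex effect on cost — so the PMPY
gender t-tests exercise machinery, not a planted signal.  A green
end-to-end test therefore establishes that the pipeline recovers a planted
structure of the published shape from raw claim lines; it does not certify
behavior under real-world coding noise or enrollment complexity.

## 7. Reproducibility

Every stochastic component (generator, k-means restarts, silhouette
subsampling, random baseline) descends from explicit integer seeds; a fixed
config yields byte-identical CSV artifacts.  The pipeline serializes its
full configuration into the run directory.

## 8. Known limitations

- The complexity stratifier reproduces only the decision skeleton
  (≥2 body systems or progressive/malignant → complex) of pediatric
  complexity algorithms; the code→system map is a small configurable YAML,
  not a clinical inventory.
- Labeling is defined only for the five-cluster solution; other k values
  require interpretation by the analyst.
- With cohort sizes where the rarest subgroup drops below a handful of
  members (n ≲ 1,000 overall, or small strata), the five-cluster solution
  and its labeling can legitimately fail; errors are raised with
  diagnostics rather than silently relabeled.
- Quantities measured on the ~0.5% early-onset cluster (≈50 patients at
  n=10,000) carry visible Monte-Carlo error: binomial SD ≈ 7 points for its
  complex-chronic percentage, ≈ 6–7% for its median costs.
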