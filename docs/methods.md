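# Methods

## Glycolytic score and stratification

The glycolytic score of a sample (or cell) is the arithmetic mean of the
normalized expression values of the 14-gene glycolytic signature over the
genes present in the matrix. Missing signature genes are reported and never
imputed; by default at least half the signature must be present
(`min_fraction = 0.5`), with a warning for any missing gene and an error
below the threshold. Gene symbols are matched case-insensitively after
whitespace trimming, with a small packaged alias table (currently
`PKM2 → PKM`, two names for the same pyruvate-kinase locus) applied to both
matrix and signature before matching.

Two stratifiers operate on score vectors:

- **Median split (High/Low).** A sample is High iff its score *strictly
  exceeds* the cohort median; ties at the median are Low. Consequence: a
  constant cohort is all Low. The threshold is stored with the assignment.
- **Tertile split (Low/Intermediate/High).** Thresholds are the 1/3 and
  2/3 quantiles computed with the linear-interpolation estimator (the
  common statistical default); bins are upper-closed (`score ≤ q⅓ → Low`,
  `q⅓ < score ≤ q⅔ → Intermediate`, `score > q⅔ → High`). With all scores
  distinct and n divisible by 3 the groups are balanced.

Both stratifiers are rank-determined for distinct scores: any strictly
monotone transformation of the scores yields identical labels (a property
test enforces this).

Subtype calls take the mean expression of the Basal-like and Classical
signatures per sample and return the argmax; exact ties go Classical with
a warning (ties are measure-zero on real data). Tumor purity percentages
are binned `<50 / 50–75 / >75` with both boundaries assigned to the middle
bin so the bins are exhaustive and disjoint. The hypoxia signature is the
symbol-normalized intersection of a tumor-upregulated gene list with a
HIF-1α target list (an empty intersection is an error); the hypoxia score
is the per-sample *median* over the intersection, with the even-count
median taken as the midpoint of the two central order statistics, and
group-level summaries computed as the median of member samples.

`log_normalize` is a convenience helper (per-column library-size scaling,
then log1p in base 2 or e), not a replacement for any cohort-specific
normalization; `ExpressionMatrix.normalization_tag` records provenance
rather than guessing what normalization produced the values.

## Heterogeneity permutation test

Per-patient centroids are the mean embedding coordinates of each patient's
cells; the heterogeneity statistic is the mean of all C(g, 2) pairwise
Euclidean distances between centroids. It is invariant to cell row order
and to rigid motions of the embedding, and is defined for any embedding
dimension k ≥ 1 (2-D UMAP being the typical input).

The null model shuffles the patient-label multiset uniformly across cells
(coordinates fixed, group sizes conserved exactly in every permutation)
and recomputes the statistic; shuffling is global, not stratified by cell
type. The empirical p is the fraction of the `n_perm` (default 1000)
shuffled statistics ≥ the observed one — ties count toward the numerator,
and p may be exactly 0 under this definition. Because a zero can be
statistically awkward downstream, the conventional (b+1)/(n_perm+1)
estimate is carried alongside as `p_conservative`. A single seeded
generator drives all shuffles sequentially, so results replay
bit-identically from (data, n_perm, seed). No per-patient subsampling is
applied before centroid computation. The test is one-sided (≥) by
construction; no two-sided variant is offered.

For ≤ 8 cells the Monte-Carlo p is validated in tests against exhaustive
enumeration of all distinct label arrangements.

## Association testing

Contingency tables cross-tabulate the glycolytic group against one
categorical variable, rows/columns in declared (categorical, else sorted)
level order; samples missing either value are excluded and counted in
`table.attrs["n_excluded"]`; a factor collapsing below two observed levels
is a degenerate-table error. Continuous (float) columns are not treated as
covariates — their binned versions are.

On each table the chi-square test is always computed (Yates continuity
correction for 2×2 only). Fisher's exact test is computed for every 2×2
table and, for larger tables, when any expected count is < 5 and the total
n ≤ 500. The r×c exact p uses full enumeration of tables with the observed
margins under the probability-ordering two-sided convention (sum the
probabilities of all tables no more probable than the observed one, with a
1e-7 relative tolerance on the comparison); enumeration is abandoned past
a feasibility bound (~2×10⁶ tables), in which case the Fisher p is absent
and chi-square is primary, with a warning. The primary p is Fisher's when
the standard small-sample rule fires (any expected count < 5, or a 2×2
with n < 40), otherwise chi-square; it is reported rounded to four decimal
places (`significant` means rounded p < 0.05) with the full-precision
value kept alongside so rounding never destroys downstream comparisons.
Results are ranked by ascending full-precision primary p.

Benjamini–Hochberg adjustment is the standard step-up procedure
(delegated to statsmodels). Note that BH is not idempotent in general:
re-adjusting an already-adjusted vector re-inflates all but the largest
values, so only the documented properties (never decreases a p value,
stays in [0, 1], monotone in rank) are guaranteed.

## Survival

The 3-year overall-survival endpoint administratively censors all
follow-up beyond the 36-month horizon *before* fitting — events after 36
months become censorings at 36 (the alternative reading, truncating only
the plot axis, is not used; this choice is the documented one). Product-
limit (Kaplan–Meier) curves are fit per group and exported tidy (group,
time, at-risk, events, estimate). Groups are compared with the unweighted
log-rank test (no Peto/Wilcoxon weighting is offered). The trend across
ordered groups (Low < Intermediate < High, codes 0/1/2) is the Wald p of
the group-code coefficient from a Cox proportional-hazards fit —
asymptotically equivalent to the score test and directly available from
the fitting library. With zero events overall, curves are returned flat at
1 and both tests are absent.

## ROI quality control

A region of interest passes iff all seven thresholds hold, each a strict
inequality exactly as worded: reads > 1000, percent of reads trimmed/
stitched/aligned > 80, sequencing saturation > 50%, minimum negative-
control counts > 5, no-template-control counts < 3000, nuclei > 100, area
> 1000 µm². The rules are applied conjunctively with no rescue path. The
failure report counts every rule a record violates, so a record failing k
rules contributes exactly k to the totals and the filter is order-
independent.

## Synthetic data

The generators emulate the statistical structure the analysis assumes —
not the biology or chemistry of real assays:

- **Embeddings.** Patient centroids i.i.d. N(0, between_sd² I_k); cells
  N(centroid, within_sd² I_k); exactly `cells_per_patient` cells per
  patient. For two patients with no within-patient noise, the expected
  intercentroid distance is `between_sd·√π` (Rayleigh mean), which the
  tests verify by simulation.
- **Single-cell expression.** Values are normal on the log scale
  (mean 2.0, sd 1.0) — the matrices stand in for log-normalized
  expression, which is what every consumer operates on, so no count layer
  is simulated. `glyco_shift` therefore reads directly in noise-sd units.
  The first ⌊n/2⌋ patients (by index, before noise) are ground-truth
  "high" and get `+glyco_shift` on every signature gene; the truth map is
  returned for recovery tests. The gene universe is the signature plus
  filler genes.
- **Cohorts.** Scores are standard normal; survival times are exponential
  with hazard `baseline · HR^(code/2)` for tertile code 0/1/2 — the
  spec-level statement pins only the high-vs-low ratio, and the geometric
  midpoint for the intermediate tertile makes the log-hazard linear in the
  code, so a Cox fit on the code estimates `HR = exp(2β̂)`. The default
  baseline hazard is 0.035/month (ln 2 / 20: a ~20-month median OS typical
  of PDAC). Follow-up is administratively censored at 36 months.
  Covariates are simulated independently of the score with documented
  marginals (KRAS mutant 70%; stages T1–T4 at 5/25/50/20%; purity uniform
  on [20, 95] then binned; Basal-like 35%) — test scaffolding with no
  generative claim.
- **ROI records.** Clean records clear every threshold with margin; each
  planted violator fails exactly one randomly chosen rule, set exactly at
  the (strict) threshold value.

What passing tests on these data do **not** show: robustness to
negative-binomial count noise, batch effects, realistic scRNA depth or
dropout, non-proportional hazards, or correlated covariates. The
generators exist to verify the *rules* of the pipeline, not to certify
performance on any real cohort.

Determinism: every generator derives its randomness from
`default_rng([stream_id, seed])` with a fixed per-generator stream id, so
one seed drives independent generator calls without shared-state coupling,
and identical (config, seed) is bit-identical everywhere.

## Problem sizes used in the self-checks

The statistical self-checks run at sizes chosen to make their expected
behavior sharp: the heterogeneity significance regime at 10 patients × 100
cells (centroid spread 5, cell noise 0.5, 1000 shuffles); null calibration
over 200 replicates of 5 × 20 cells with 199 shuffles each (under
exchangeability the rejection probability at α = 0.05 is then exactly
10/200); label recovery over 50 seeds at 6 patients × 15 cells with a
5-sd shift; hazard-ratio recovery over 100 cohorts of n = 300 with HR = 3,
accepted within ±30%.

## Known limitations

- The r×c exact test enumerates rather than implementing the network
  algorithm, so moderately large sparse tables fall back to chi-square.
- The trend test reports a Wald, not a score, p value.
- Multivariable (covariate-adjusted) Cox modeling, competing risks, GSEA,
  differential-expression engines, purity inference, and embedding
  computation are out of scope: embeddings, purity values and gene lists
  are inputs.
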