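# Methods

This note documents the models, parameter choices and numerical decisions
behind `phenomiq`, and states what the synthetic-data tests do and do not
establish.

## 1. The synthetic plate experiment

The generator emulates quantitative high-throughput cell array phenotyping:
384-position agar arrays imaged kinetically, the same physical array printed
once per (drug, dose) condition so that an array position's dose series is a
replicate series. Defaults encode the experimental design the pipeline was
built for:

| parameter | default | units | rationale |
|---|---|---|---|
| gemcitabine doses | 0, 5, 10, 20, 30 | μg/mL | the study's dose series |
| cytarabine doses | 0, 10, 25, 50, 100 | μg/mL | the study's dose series |
| reference replicates | 768 | cultures | the study's control count |
| time grid | 0–48 h every 2.5 h | h | kinetic imaging every 2–3 h |
| reference CPPs (K, r, l) | 200, 0.3, 10 | intensity, 1/h, h | a healthy untreated culture reaching plateau within the imaging window |
| intensity noise SD | 5 (2.5% of K) | intensity | replicate variability of a few percent; no measured value exists, this is a placeholder magnitude |
| no-growth fraction | 0 | — | the default world is a healthy library; blank spots are opt-in (see §6) |

Reference dose response is linear in dose per drug (L rises, K and r fall),
with per-μg/mL slopes chosen so the top gemcitabine dose roughly halves the
growth rate margin — the exact values are irrelevant downstream because
scoring subtracts the reference means. A mutant's planted effect is a CPP
`shift` applied at every dose plus a per-drug `slope` applied as
slope × dose — deliberately the same linear-in-dose form the scoring
regression assumes, so planted INT values have the closed form
slope × D_max. Noise is additive i.i.d. Gaussian on intensity, clipped at
zero (intensities are non-negative); no-growth cultures emit baseline (2
intensity units) plus noise.

What the generator does **not** emulate: spatial plate effects, edge
artifacts, heteroscedastic or autocorrelated imaging noise, non-logistic
growth (diauxie, filamentation), and dose–response nonlinearity. A green
recovery test therefore establishes that the estimators are correct and
calibrated *under the model's own assumptions*, not that those assumptions
hold for any particular instrument.

## 2. Growth-curve fitting

Least squares on G(t) = K/(1 + e^(−r(t−l))) via Levenberg–Marquardt, with a
bounded trust-region retry only if the unconstrained optimum leaves the box
K ∈ (0, 2·max y], r ∈ (0, 10 /h], l ∈ [−24 h, 2·t_max]. Initialization: K₀
from the peak intensity, L₀ from the half-max crossing by linear
interpolation, r₀ from the slope of the logit transform over the
exponential phase. Up to 5 restarts from multiplicatively perturbed starts
(deterministic per-culture seeds derived from the culture identifier by
CRC32). A fit is `converged` when the optimizer succeeded, K and r are
positive, and l lies within the observation window plus slack; otherwise
best-effort parameters are returned flagged.

Baseline handling is a parameter (`baseline="none" | "subtract_min"`),
default `"none"`: the synthetic world adds no offset to growing cultures,
and subtracting the first observations from a pure logistic would bias K by
G(0)/K (≈5% at the default parameters), destroying exact parameter
recovery. For real exports with an additive agar background,
`"subtract_min"` removes the minimum of the first two timepoints.

No-growth classification: a culture is no-growth when its peak intensity is
below 10% of the plate-median final intensity or its peak/initial fold
change is below 1.5 (both strict, so a series exactly at threshold counts
as growth). The 10% fraction is chosen so the extreme-value peak of a
pure-noise blank series (~6% of K at the default noise) stays safely below
the cutoff while any real grower clears it.

## 3. Interaction scoring

Implementation follows the dose-series contract exactly (shift K₀, residual
L_i, OLS over all doses including (0, 0), INT at D_max). Decisions where the
procedure leaves room:

- The regression **includes** the D₀ point, where L₀ = 0 by construction —
  it anchors the intercept; A is estimated, never forced to zero, because
  INT = A + B·D_max is evaluated with an explicit A.
- Sample SD (n−1) everywhere.
- The Y_i_max substitution applies to **L only** (its no-growth asymptote is
  infinity); K and r use the Y_i = 0 rule. The K window for Y_i_max
  qualification is K ≥ mean_ref(K) − 2·SD_ref(K), inclusive.
- r is computed, stored and calibrated but not used for classification; K
  and L carry the phenotype.
- Classification thresholds are inclusive (z = 2.0 is actionable).
  Simultaneous enhancer and suppressor signals across CPPs yield the class
  `conflict`, flagged for review rather than silently resolved.
- A stratum SD of exactly zero can only occur in a noiseless world; INTs
  equal to the stratum mean then get z = 0 and any other INT gets NaN with
  a logged warning (an error would make the noiseless oracle worlds
  unusable).
- Profiles with no growth at D₀ are unscorable: flagged, z = NaN, class
  `none`; the clustering stage assigns them the 0.0001 sentinel.

## 4. REMc

EM Gaussian mixtures (scikit-learn, diagonal covariance by default,
`reg_covar = 1e-6` against singular components) fit for k = 1…10 with 5
restarts each from deterministically derived seeds; the BIC optimum is
selected, ties broken toward smaller k. BIC replaces the original
cross-validated-likelihood selection as a deterministic, widely understood
surrogate; covariance structure and k grid are parameters. Recursion stops
at chosen k = 1, member count < 8, or depth 4. Cluster names encode the
lineage: round-1 clusters are `1-0-c`; the children of `1-0-16` are
`2-0.16-j`. The per-iteration EM log-likelihood of every run is recordable
(`trace_collector`), and tests assert it never decreases beyond float
roundoff at convergence (tolerance 1e-7).

Columns entering the model are exactly the interaction z-scores; shift
columns ride along for display. Within-cluster display order is
average-linkage hierarchical clustering on Euclidean distance, members
pre-sorted by name so identical profiles stay lexicographic.

## 5. Enrichment, GTA, integration

- Background for enrichment is **all genes scored in the experiment**, not
  the genome. Bonferroni across all terms annotated in the background is
  reported alongside the raw hypergeometric p.
- GO-graph propagation to ancestor terms is not performed (flat annotation
  tables; a GAF-style two-column file is the interchange format).
- GTA uses sample SD; a single-gene term has SD 0, so its GTA score equals
  |GTA value|. Both K- and L-based GTA are computed and reported separately.
  Note: recomputing a printed two-gene GTA value from one-decimal inputs
  can differ from the printed value by up to 0.05 from rounding alone.
- The association statistic is the fully standardized regression slope of
  sensitivity on expression (equal to Pearson r), with a two-sided t test
  on n−2 df — a defined statistical contract mirroring linear-model
  drug-sensitivity signatures without depending on external
  pharmacogenomics packages. Sensitivity in the synthetic world is a
  continuous AAC-like value in [0, 1] (Beta(2, 5)). Tissue strata are label
  filters; no multiple-testing correction is applied to associations (raw
  p < 0.05), matching the integration design; an FDR option can be layered
  on by the caller.
- UES/OES calls require the yeast class, the coefficient sign and p < α
  simultaneously; identical homolog rows are deduplicated; homologs of
  unknown yeast genes are skipped with a warning.

## 6. A revised default, disclosed

The no-growth fraction default was initially 0.01 and was revised to 0
while building the null-calibration analysis. With any Bernoulli no-growth
admixture, the K := 0 substitution injects rare O(K)-sized INT outliers
into both the mutant and the reference stratum; the sample SD of 768
reference INTs then has mixture kurtosis ~1/p and the mutant-vs-reference
SD ratio becomes ill-conditioned for reasons unrelated to noise
calibration. Since no source states a rate, the default world is a healthy
library, and the substitution rules are exercised by dedicated tests that
set the fraction explicitly. The sequence of this decision is recorded
here deliberately.

## 7. Known limitations

- The synthetic world's noise magnitude is a placeholder; absolute z-score
  magnitudes in simulation are not comparable to instrument data.
- Cluster names are lineage-faithful but not guaranteed identical to any
  other REMc implementation's ids.
- The integration stage models one sensitivity vector per drug dataset;
  replicate datasets (e.g. two cell-line panels) are handled by running the
  stage per dataset and intersecting downstream.
- Dose selection ("functionally discriminating" concentrations) is taken as
  given; the pipeline neither chooses nor validates dose series.
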