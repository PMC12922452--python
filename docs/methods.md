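# Methods

`phenodiag` implements a reproducible workflow for comparing species or
populations from a species-by-trait matrix of mensural (continuous
measurements) and meristic (integer count) characters. This note records
the statistical model behind each stage, the defaults and why they were
chosen, and the places where the design was genuinely open.

## Data model

The central container is the `PhenotypeMatrix`: one row per individual,
one numeric column per trait, a taxon label per row, and a per-trait kind
(mensural/meristic). Rows are sorted alphabetically by taxon on input so
that every downstream table is invariant to input row order. Missing
values are first-class: trait-wise outlier removal necessarily produces
per-trait missingness, so every stage either tolerates NaN (univariate
tests, summaries, range scans drop missing values per trait) or applies a
complete-case policy (all multivariate stages drop rows with any missing
trait and log the count — distance matrices and discriminant analysis
require complete rows).

Trait kinds are detected by an all-integer heuristic (a column whose
observed values are all integers is meristic), with an explicit user
override. Misclassification affects only plot style (box-only versus
violin+box), never the statistics, which is why a heuristic is
acceptable here.

## Allometric correction

For a user-chosen size proxy *s* (snout–vent length, stem height, ...),
each mensural trait *y* is replaced by the residuals of the ordinary
least-squares fit

    ln(y) = a + b·ln(s) + ε

so the retained variable is size-independent shape variation; *b* is the
allometric slope. Natural logarithms are used — residuals are invariant
to the log base up to a constant factor, and all downstream tests and
ordinations are scale-invariant after standardization. The scaling trait
leaves the trait set; meristic traits pass through unchanged.

The regression is pooled across all individuals by default (one common
line per trait). A `per_taxon` option fits within-taxon lines instead;
pooled is the default because a single shared allometry is the simplest
model and the common choice when taxa share an ontogenetic trajectory,
but the choice is genuinely open and is therefore exposed as a flag.
Rows missing either variable are dropped for that regression only, and
fewer than 3 complete pairs is an error. Non-positive values are
rejected by name (log-scale measurements must be strictly positive).

## Outlier removal

Outliers are flagged per taxon and per trait with Tukey fences: with
group quantiles Q_low = quantile(lower_q) and Q_high = quantile(upper_q)
(linear interpolation of order statistics, the common "type 7"
estimator; defaults 0.25/0.75) and k = 1.5,

    flag x  iff  x < Q_low − k·IQR  or  x > Q_high + k·IQR .

Fences use strict inequalities, so boundary values are retained — with a
constant group the fences collapse onto the data and nothing is flagged.
Flagging within taxon prevents genuine between-species differences from
being treated as aberrant. Flagged cells become missing for that trait
only (trait-wise removal preserves the individual's other measurements),
and every removal is logged with taxon, trait, value and fences, making
the filter fully auditable. Groups with fewer than 4 observed values for
a trait are exempt (fences from ≤3 points are meaningless) and the
exemption is logged.

By default outlier removal runs *before* allometric correction so that
extreme points cannot leverage the regressions; the order is
configurable (`allometry_first`) because the opposite reading is also
defensible (an individual extreme only through size would then not be
flagged in shape space).

## Diagnostic (non-overlapping) traits

For every trait and unordered taxon pair, observed ranges are compared
as closed intervals; a row is reported iff the ranges are strictly
disjoint, with the gap between the closer endpoints. A shared endpoint
counts as overlap — conservative, since a shared observed value defeats
a field diagnosis. The scan runs on the analysis matrix by default (flag
to scan raw values instead; raw-unit ranges are what a field key would
quote, while the analysis matrix is what the rest of the inference
uses).

## Univariate tests

Each trait passes through an assumption gate at α = 0.05: Shapiro–Wilk
on the pooled residuals of the group-means model, and Bartlett's test of
variance homogeneity across groups. Shapiro–Wilk is applied to residuals
rather than per group because per-group testing is undefined below n = 3
and there is no canonical way to combine per-group p-values; the
residual-based convention is the standard one for ANOVA diagnostics.
Groups with fewer than 3 observations route the trait to the
nonparametric branch with a logged warning, as does constant data.
Shapiro–Wilk is run on a seeded subsample above n = 5000 (the statistic
is unreliable and expensive beyond that).

Traits passing both checks get classical one-way ANOVA; a significant
omnibus test (p < 0.05) is followed by Tukey HSD (Tukey–Kramer under
unbalance, via statsmodels). Degenerate inputs are defined explicitly:
zero between-group sum of squares gives F = 0, zero within-group
variance with nonzero between gives an undefined F reported as NaN.
Traits failing the gate get Kruskal–Wallis with midrank tie correction;
a significant result is followed by Dunn's test, implemented directly:

    z_ab = (R̄_a − R̄_b) / sqrt( (N(N+1)/12 − T)(1/n_a + 1/n_b) ),
    T = Σ(t³ − t) / (12(N − 1)),

with two-sided normal p-values Bonferroni-multiplied by the number of
pairs and capped at 1. For K = 2 without ties, z² equals the
Kruskal–Wallis H exactly; the test suite asserts this identity at 1e-10
and cross-checks against a brute-force rank computation.

Pairwise verdicts are condensed into a compact letter display by
insert-and-absorb: start with one letter column holding all groups; for
each significantly different pair sharing a column, split that column in
two, dropping one member from each copy; absorb columns whose group set
is contained in another's; assign letters to columns ordered by their
alphabetically first member. The defining property — two groups share a
letter iff their comparison is non-significant — always holds for
consistent inputs and is asserted on every call; conflicting duplicate
verdicts are rejected.

## Multivariate suite

All distance-based stages use Euclidean distances on the complete-case
analysis matrix.

**PERMANOVA.** With squared distances d²ᵢⱼ,

    SS_total = Σ_{i<j} d²ᵢⱼ / N,
    SS_within = Σ_g Σ_{i<j ∈ g} d²ᵢⱼ / n_g,
    F = (SS_between/(K−1)) / (SS_within/(N−K)),  R² = SS_between/SS_total,

tested by permuting row labels with a seeded generator; the p-value is
(1 + #{F_perm ≥ F_obs}) / (1 + n_perm), which is never 0. On a single
variable the pseudo-F reduces to the classical ANOVA F (asserted at
1e-10), and the statistic is cross-checked against scikit-bio's
implementation in the tests.

**PERMDISP.** Distances are embedded by principal coordinates
(eigendecomposition of the double-centered −½d² matrix; axes with
eigenvalues at numerical zero are discarded — Euclidean input produces
no negative eigenvalues, so the embedding is exact). Each individual's
distance to its group center is computed; the default center is the
spatial (geometric) median, obtained by Weiszfeld iteration, matching
the reference default of the field's standard R implementation; the
arithmetic centroid is an option, in which case the embedded distances
equal direct distances to the group mean (asserted at 1e-8). The
one-way ANOVA F on those distances is tested by permuting them across
groups (seeded), overall and for every group pair. Singleton groups get
dispersion 0 and a note.

**Validity flag.** PERMANOVA assumes comparable dispersions; the result
is flagged `valid` iff the PERMDISP p-value exceeds α (strictly), else
`dispersion_driven` — a significant PERMANOVA with heterogeneous
dispersion may reflect spread, not centroid separation.

**PCA.** Columns with any missingness (after the complete-case row
filter, only zero-variance columns remain relevant) or zero variance
are excluded and logged; the rest are centered and scaled (SD with
n−1), then decomposed by SVD. Explained fractions are the squared
singular-value variances over their total; loadings are the unit right
singular vectors, so scores·loadingsᵀ reconstructs the standardized
matrix. The top ten |loading| traits are reported for the first two
components. Components are retained for post hoc testing until the
cumulative explained variance first reaches 90% (configurable), and
each retained component goes through the same gated univariate
procedure as a raw trait.

**DAPC.** The standardized matrix is reduced to the minimal PC prefix
reaching the variance threshold (default 0.90), and linear discriminant
analysis on those scores yields K−1 discriminant axes with per-axis
explained fractions = discriminant eigenvalue / sum of eigenvalues.
Standardization is center+scale by default, consistent with the
exploratory PCA; a no-scale option reproduces the center-only convention
of the reference implementation. With the threshold at 1.0 on full-rank
data, DAPC equals plain LDA on the standardized matrix up to axis sign
(asserted in the tests). Classification ties resolve toward the
alphabetically first class for determinism.

**Jackknife.** Each individual is predicted by a DAPC refitted without
it; the retained-PC count is reselected inside every fold by default
(honest leave-one-out — the fold must not inherit a choice made with
the held-out point), with a freeze option for speed. Folds that would
leave a group below 2 members skip that individual with a logged note.
The procedure is seed-free and deterministic.

**Classification summaries.** The confusion matrix (rows = actual,
columns = predicted, classes sorted) yields per class

    sensitivity = TP / row_sum,   specificity = TN / (N − row_sum),
    TSS = sensitivity + specificity − 1,

with overall accuracy = trace/N. TSS ranges over [−1, 1]; 0 is chance.
An empty class row gives undefined sensitivity, reported as missing.
Misclassified individuals are listed one per row (id, actual,
predicted); the row count always equals N − trace.

## Figures

All figures are single-page vector PDFs at 7.5 × 6 in. Mensural traits:
violin (kernel density, Scott's rule bandwidth) with embedded boxplot —
white dot = mean, bar = median, whiskers at 1.5×IQR; meristic traits:
boxplot only. Letters from the post hoc display sit above each group at
5% of the axis range — both choices are purely presentational.
Ordination scatters plot axis 1 vs 2 with the explained percentage in
the axis label (one decimal) and convex hulls only for user-declared
taxa (degenerate hulls are drawn as segments with a warning). A
two-group DAPC has a single axis and is drawn as per-group kernel
densities over LD1. Taxa get colors from a fixed 12-color qualitative
palette, cycled when taxa outnumber colors; all figures in a run share
one taxon→color map.

## Pipeline, provenance, seeding

`run_pipeline` (or the `phenodiag` CLI) executes read → optional
preprocessing → analysis matrix → all analysis stages. Provenance
(config snapshot, package version, seed, shapes, removal counts) is
written before the analysis stages. Stages are isolated: one stage's
failure is logged and the others proceed, because the outputs are
independent products. One global seed drives the permutation stages
through derived streams, so identical config + input reproduces every
CSV byte-for-byte; figures are deterministic in content.

## Synthetic data generator

The generator emulates the structure the workflow assumes: body size
log-normal with per-taxon mean shifts (default ln-means 3.8/4.1/4.4, ln
SD 0.30 — roughly a 30% coefficient of variation, as in a pooled sample
spanning ontogenetic stages; this spread gives the log–log regression
enough leverage that the planted slope is recovered within ±0.02 at
n = 200); mensural traits exp(a + b·ln(size) + ε) so the log–log fit
recovers (a, b); Poisson meristic counts; unbalanced default group sizes
(30/25/20). Planted diagnostic traits are realized by disjoint uniform
supports for the named pair while other taxa span both. Planted
outliers sit ~10 group SDs above the mean (above only: mensural traits
live on a strictly positive scale, so a −10σ measurement would be
unmeasurable; count-trait plants are rounded to stay integer-valued);
the generator asserts before returning that every plant falls outside
its group's default Tukey fences. A second generator produces plain
Gaussian clusters with controllable separation for the multivariate
tests (separation 0 gives exchangeable groups for null calibrations).

What the generator does *not* emulate: measurement error correlated
across traits, phylogenetic structure, non-Poisson count dispersion, or
taxon-specific allometric intercept shifts. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to every feature of real museum data.

## Numerical and calibration choices

- Permutation p-values use the add-one convention; with n_perm = 999 the
  smallest attainable p is 0.001.
- The null calibrations run 500 replicates at 3 groups × 10 individuals
  (PERMANOVA with n_perm = 199), sizes chosen to give a binomial
  standard error of about 0.01 on the rejection rate while the whole
  check completes in seconds.
- Weiszfeld iteration for the spatial median runs to 1e-10 with damping
  when the iterate coincides with a data point.
- OLS identities (residual mean 0, orthogonality to the regressor) are
  asserted at 1e-8 in the tests.

## Known limitations

- PERMDISP's principal-coordinate step assumes a Euclidean-embeddable
  distance matrix (always true here); semimetric dissimilarities are out
  of scope.
- No Welch ANOVA, permutation ANOVA, effect sizes, covariate-adjusted
  PERMANOVA, or probabilistic (tolerance-interval) diagnosability.
- The all-integer meristic heuristic misclassifies a continuous trait
  recorded at integer precision; use the override map when that matters.
- Bundled validation data cover the iris measurements and a published
  nine-species classification table; the full anole measurement files
  are distributed separately by their authors and are not included.
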