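# phenodiag

Reproducible phenotypic species diagnosis and population comparison from
a species-by-trait CSV.

Taxonomists describing species from morphometric data need several
things at once: size-independent shape variables, defensible outlier
handling, characters that diagnose taxa unambiguously in the field,
appropriately chosen univariate tests, and multivariate evidence that
the proposed groups are real and recoverable. `phenodiag` runs that
entire workflow — preprocessing, diagnosis, inference, classification,
figures — as one scripted, seeded, fully auditable pipeline, for anyone
comparing populations with mensural (continuous) and meristic (count)
characters.

## What it computes

Given a CSV whose first column holds taxon labels and whose remaining
columns are numeric traits:

- **Allometric correction** (optional): each mensural trait *y* is
  replaced by the residuals of ln *y* = *a* + *b*·ln *s* on a size proxy
  *s*, isolating shape from size.
- **Outlier removal** (optional): per taxon and per trait, values
  outside Tukey fences (Q1 − k·IQR, Q3 + k·IQR), k = 1.5 by default,
  become missing for that trait only; every removal is logged.
- **Descriptive statistics**: per taxon × trait, "Mean ± SD (Min – Max)"
  in the format used in species descriptions.
- **Diagnostic traits**: all taxon pairs × traits scanned for strictly
  disjoint observed ranges (closed intervals; a shared endpoint counts
  as overlap).
- **Univariate tests**: Shapiro–Wilk (on group-means residuals) and
  Bartlett gate each trait at α = 0.05 into one-way ANOVA + Tukey HSD
  or Kruskal–Wallis + Dunn (Bonferroni); pairwise verdicts become
  compact letter displays (groups share a letter ⇔ not significantly
  different).
- **PERMDISP + PERMANOVA**: Euclidean-distance tests of dispersion
  homogeneity and location, pseudo-F
  (SS_b/(K−1))/(SS_w/(N−K)) with seeded label permutations
  (999 by default); the PERMANOVA outcome is flagged `valid` or
  `dispersion_driven` from the PERMDISP p-value.
- **PCA**: centered+scaled SVD; components retained to 90% cumulative
  variance are each re-tested through the univariate gate.
- **DAPC**: LDA on the retained PC scores (K − 1 axes), validated by
  leave-one-out jackknife with full per-fold refitting, summarized as a
  confusion matrix with per-class sensitivity, specificity and
  TSS = sensitivity + specificity − 1.

Tables are CSV; figures are 7.5 × 6 in vector PDFs (violin+box for
mensural traits, box-only for meristic, ordination scatters with
optional convex hulls, LD1 density for two-group DAPC).

## Worked example

The bundled three-species iris data (150 individuals, 4 mensural
traits):

```python
import phenodiag as pdx
from phenodiag.datasets import iris_phenotypes

iris = iris_phenotypes()
uni = pdx.run_univariate(iris)
print(uni.anova_summary.round(4).to_string(index=False))
```

```
      trait     F  df_between  df_within   p  shapiro_p  bartlett_p  assumptions_met
sepal_width 49.16           2        147 0.0      0.323      0.3515             True
```

Sepal width is the only trait passing both assumption checks
(Shapiro–Wilk p = 0.323, Bartlett p = 0.352 > 0.05), so it is tested by
ANOVA: F = 49.16 on 2 and 147 degrees of freedom — species differ
strongly in mean sepal width, and Tukey HSD gives every species its own
letter (setosa 'a', versicolor 'b', virginica 'c'). The other three
traits fail the gate and go to Kruskal–Wallis; petal length, for
example, gives χ² = 130.41 (df = 2):

```python
print(uni.kruskal_summary[["trait", "chi2", "df", "p"]].round(4).to_string(index=False))
```

```
       trait     chi2  df   p
sepal_length  96.9374   2 0.0
petal_length 130.4110   2 0.0
 petal_width 131.1854   2 0.0
```

The multivariate side:

```python
dm, groups = pdx.euclidean_distances(iris)
disp, _ = pdx.permdisp(dm, groups, n_perm=999, seed=1)
perm = pdx.permanova(dm, groups, n_perm=999, seed=2)
pdx.assess_validity(perm, disp)
print(f"PERMANOVA F={perm.F:.2f} R2={perm.R2:.3f} p={perm.p:.3f} flag={perm.valid_flag}")
print(f"PERMDISP  F={disp.F:.2f} p={disp.p:.3f}")
```

```
PERMANOVA F=487.33 R2=0.869 p=0.001 flag=dispersion_driven
PERMDISP  F=10.75 p=0.001
```

Species identity explains 86.9% of multivariate variation (p = 0.001,
the smallest value attainable with 999 permutations), but dispersions
also differ significantly (PERMDISP p = 0.001), so the PERMANOVA is
flagged `dispersion_driven`: part of the signal may be unequal spread
rather than pure centroid separation. Leave-one-out DAPC classifies 92%
of individuals into the correct species.

The same run from the shell, with all outputs under `out/`:

```sh
phenodiag --input iris.csv --seed 1 --outdir out --hull setosa
```

which writes `out/tables/*.csv` (summary stats, non-overlap scan,
`summary_anova.csv`, `summary_kruskalwallis.csv`, PERMANOVA/PERMDISP,
PCA scores/loadings, confusion matrix, per-class metrics, misclassified
individuals), `out/figures/*.pdf`, and `out/provenance/` (config
snapshot + run record) — rerunning with the same config and seed
reproduces every CSV byte-for-byte.

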