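"""Assumption-gated univariate testing with post hoc comparisons and letters.

For each trait, normality (Shapiro–Wilk on residuals of the group-means
model) and homogeneity of variances (Bartlett) are checked at α = 0.05.
Traits passing both go to one-way ANOVA with Tukey HSD (Tukey–Kramer for
unbalanced designs) post hoc; traits failing either go to Kruskal–Wallis
with Dunn's test (Bonferroni-corrected) post hoc.  Post hoc tests run only
when the omnibus test is significant.  Pairwise verdicts are condensed
into a compact letter display: two groups share a letter exactly when
their comparison is non-significant.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_data import PhenotypeMatrix

__all__ = [
    "AssumptionReport",
    "UnivariateResults",
    "check_assumptions",
    "anova_oneway",
    "tukey_hsd",
    "kruskal_wallis",
    "dunn_test",
    "compact_letters",
    "run_univariate",
]

PAIR_COLUMNS = ["group_a", "group_b", "statistic", "p_adj", "significant"]

#: Shapiro–Wilk is unreliable (and slow) beyond this n; a seeded subsample
#: of this size is tested instead.
SHAPIRO_CAP = 5000


def _split(values, groups) -> dict[str, np.ndarray]:
    """Group label -> non-missing values, keys sorted."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups).astype(str)
    out = {}
    for label in sorted(set(g)):
        x = v[g == label]
        out[label] = x[np.isfinite(x)]
    return {k: x for k, x in out.items() if x.size > 0}


@dataclass
class AssumptionReport:
    trait: str
    shapiro_p: float
    bartlett_p: float
    parametric_ok: bool
    warning: str | None = None


def check_assumptions(values, groups, trait: str = "", alpha: float = 0.05) -> AssumptionReport:
    """Gate between parametric and nonparametric branches.

    Shapiro–Wilk runs on the pooled residuals of the group-means model
    (per-group testing is undefined below n = 3 and would need an
    unspecified p-value combination); Bartlett runs across groups.  A
    group with fewer than 3 observations routes the trait to the
    nonparametric branch with a warning.
    """
    by = _split(values, groups)
    small = [k for k, x in by.items() if x.size < 3]
    if len(by) < 2 or small:
        return AssumptionReport(
            trait, np.nan, np.nan, False,
            warning=f"groups with <3 observations: {small}" if small else "fewer than 2 groups",
        )
    resid = np.concatenate([x - x.mean() for x in by.values()])
    if resid.size > SHAPIRO_CAP:
        rng = np.random.default_rng(0)
        resid = rng.choice(resid, SHAPIRO_CAP, replace=False)
    if np.ptp(resid) == 0:
        # constant data: Shapiro undefined; not a parametric candidate
        return AssumptionReport(trait, np.nan, np.nan, False, warning="zero residual variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_p = float(stats.shapiro(resid).pvalue)
        bartlett_p = float(stats.bartlett(*by.values()).pvalue)
    return AssumptionReport(trait, shapiro_p, bartlett_p,
                            bool(shapiro_p > alpha and bartlett_p > alpha))


def anova_oneway(values, groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: (F, df_between, df_within, p).

    Degenerate inputs: zero between-group sum of squares gives F = 0
    (p = 1); zero within-group variance with nonzero between gives an
    undefined F, reported as NaN.
    """
    by = _split(values, groups)
    arrays = list(by.values())
    k = len(arrays)
    n = sum(a.size for a in arrays)
    df_b, df_w = k - 1, n - k
    grand = np.concatenate(arrays).mean()
    ss_b = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_b <= 0:
        return 0.0, df_b, df_w, 1.0
    if ss_w <= 0 or df_w <= 0:
        return np.nan, df_b, df_w, np.nan  # zero within-group variance: F undefined
    F = (ss_b / df_b) / (ss_w / df_w)
    return float(F), df_b, df_w, float(stats.f.sf(F, df_b, df_w))


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD (Tukey–Kramer under unbalance) pairwise comparisons.

    ``statistic`` is the mean difference (b − a); ``p_adj`` is the
    studentized-range adjusted p-value.
    """
    by = _split(values, groups)
    v = np.concatenate(list(by.values()))
    g = np.concatenate([np.repeat(k, x.size) for k, x in by.items()])
    res = pairwise_tukeyhsd(v, g, alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    rows = [
        {
            "group_a": str(r["group1"]),
            "group_b": str(r["group2"]),
            "statistic": float(r["meandiff"]),
            "p_adj": float(r["p-adj"]),
            "significant": bool(float(r["p-adj"]) < alpha),
        }
        for _, r in frame.iterrows()
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Kruskal–Wallis rank test with tie correction: (chi2, df, p)."""
    by = _split(values, groups)
    arrays = list(by.values())
    df = len(arrays) - 1
    if all(np.ptp(np.concatenate(arrays)) == 0 for _ in [0]):
        return 0.0, df, 1.0  # all values tied
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.kruskal(*arrays)
    return float(res.statistic), df, float(res.pvalue)


def dunn_test(values, groups, alpha: float = 0.05, correction: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based post hoc test after Kruskal–Wallis.

    Per pair (a, b):  z = (R̄_a − R̄_b) / sqrt((N(N+1)/12 − T)(1/n_a + 1/n_b))
    with midranks over the pooled sample and tie term
    T = Σ(t³ − t) / (12(N − 1)).  Two-sided p-values are Bonferroni
    multiplied by the number of pairs, capped at 1.
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    by = _split(values, groups)
    labels = list(by.keys())
    pooled = np.concatenate(list(by.values()))
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # midranks
    mean_rank, sizes = {}, {}
    pos = 0
    for k, x in by.items():
        mean_rank[k] = float(ranks[pos : pos + x.size].mean())
        sizes[k] = x.size
        pos += x.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * len(pairs))
        rows.append(
            {"group_a": a, "group_b": b, "statistic": float(z),
             "p_adj": float(p_adj), "significant": bool(p_adj < alpha)}
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


# ----------------------------------------------------------------------
# Compact letter display
# ----------------------------------------------------------------------

def _letters(i: int) -> str:
    alpha = string.ascii_lowercase
    s = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        s = alpha[r] + s
    return s


def compact_letters(pairs: pd.DataFrame, groups: list[str]) -> dict[str, str]:
    """Letter groupings: groups share a letter iff their pair is non-significant.

    Insert-and-absorb: start with one letter column holding all groups; for
    each significantly different pair sharing a column, split the column in
    two (dropping one member from each copy); absorb columns whose group
    set is a subset of another's.  Letters are assigned to columns ordered
    by their alphabetically first member.
    """
    groups = sorted(groups)
    verdict: dict[frozenset, bool] = {}
    for _, r in pairs.iterrows():
        key = frozenset((str(r["group_a"]), str(r["group_b"])))
        sig = bool(r["significant"])
        if key in verdict and verdict[key] != sig:
            raise ValueError(f"conflicting verdicts for pair {sorted(key)}")
        verdict[key] = sig

    columns: list[set[str]] = [set(groups)]
    for key, sig in verdict.items():
        if not sig:
            continue
        a, b = sorted(key)
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {b})
                new_cols.append(col - {a})
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another (and duplicates)
        new_cols = [c for c in new_cols if c]
        columns = [
            c for i, c in enumerate(new_cols)
            if not any(c < d or (c == d and j < i) for j, d in enumerate(new_cols) if j != i)
        ]
    columns.sort(key=lambda c: min(c))
    out = {g: "" for g in groups}
    for i, col in enumerate(columns):
        for g in sorted(col):
            out[g] += _letters(i)
    # defining biconditional, asserted on every run
    for a, b in itertools.combinations(groups, 2):
        share = bool(set(out[a]) & set(out[b]))
        sig = verdict.get(frozenset((a, b)), False)
        if share == sig:
            raise AssertionError(f"letter display violates biconditional for ({a},{b})")
    return out


# ----------------------------------------------------------------------
# Gated per-trait driver
# ----------------------------------------------------------------------

@dataclass
class UnivariateResults:
    anova_summary: pd.DataFrame
    kruskal_summary: pd.DataFrame
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    letters: dict[str, dict[str, str]] = field(default_factory=dict)
    assumptions: dict[str, AssumptionReport] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


ANOVA_COLS = ["trait", "F", "df_between", "df_within", "p", "shapiro_p", "bartlett_p", "assumptions_met"]
KW_COLS = ["trait", "chi2", "df", "p", "significant_pairs"]


def run_univariate(m: PhenotypeMatrix, alpha: float = 0.05) -> UnivariateResults:
    """Route every trait through the gated procedure; failures are isolated.

    Each trait lands in exactly one summary table (ANOVA or
    Kruskal–Wallis).  Post hoc comparisons and letter displays are
    produced only when the omnibus test is significant at ``alpha``.
    """
    anova_rows, kw_rows = [], []
    res = UnivariateResults(pd.DataFrame(), pd.DataFrame())
    groups = m.taxa.to_numpy()
    for trait in m.trait_names:
        try:
            values = m.traits[trait].to_numpy(dtype=float)
            rep = check_assumptions(values, groups, trait=trait, alpha=alpha)
            res.assumptions[trait] = rep
            if rep.parametric_ok:
                F, dfb, dfw, p = anova_oneway(values, groups)
                anova_rows.append(
                    dict(zip(ANOVA_COLS, (trait, F, dfb, dfw, p, rep.shapiro_p, rep.bartlett_p, True)))
                )
                if np.isfinite(p) and p < alpha:
                    table = tukey_hsd(values, groups, alpha=alpha)
                    res.posthoc[trait] = table
                    res.letters[trait] = compact_letters(table, m.taxon_levels)
            else:
                chi2, df, p = kruskal_wallis(values, groups)
                sig_pairs = ""
                if np.isfinite(p) and p < alpha:
                    table = dunn_test(values, groups, alpha=alpha)
                    res.posthoc[trait] = table
                    res.letters[trait] = compact_letters(table, m.taxon_levels)
                    sig_pairs = ";".join(
                        f"{r.group_a}-{r.group_b}" for r in table.itertuples() if r.significant
                    )
                kw_rows.append(dict(zip(KW_COLS, (trait, chi2, df, p, sig_pairs))))
        except Exception as exc:  # one trait's failure never aborts others
            res.errors[trait] = f"{type(exc).__name__}: {exc}"
    res.anova_summary = pd.DataFrame(anova_rows, columns=ANOVA_COLS)
    res.kruskal_summary = pd.DataFrame(kw_rows, columns=KW_COLS)
    return res
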