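"""Multivariate diagnosability: PERMDISP/PERMANOVA, PCA, DAPC and metrics.

The distance-based tests operate on Euclidean distances over the complete
numeric trait matrix.  PERMANOVA partitions squared inter-point distances
into between- and within-group components and tests the pseudo-F by
permuting row labels; its validity is conditioned on PERMDISP, the
permutation test for homogeneity of multivariate dispersions (distances of
individuals to their group's center in principal-coordinate space).  A
significant PERMDISP flags the PERMANOVA outcome as potentially
dispersion-driven rather than a difference of centroids.

PCA (centered + scaled, prcomp convention) provides exploratory
ordination, with each retained component — minimal prefix reaching 90%
cumulative variance — routed through the assumption-gated univariate
procedure.  DAPC stacks linear discriminant analysis on the retained PC
scores (K−1 discriminant axes) and is validated by leave-one-out
jackknife refitting, summarized as a confusion matrix with per-class
sensitivity, specificity and True Skill Statistic (TSS = sens + spec − 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core_data import PhenotypeError, PhenotypeMatrix
from . import univariate as uv

__all__ = [
    "DistanceMatrix",
    "PermTestResult",
    "OrdinationResult",
    "ConfusionMatrix",
    "ClassMetrics",
    "euclidean_distances",
    "permanova",
    "permdisp",
    "assess_validity",
    "pca",
    "pc_posthoc",
    "DAPC",
    "dapc_fit",
    "jackknife_classify",
    "confusion_matrix",
    "classification_metrics",
    "misclassified_table",
]


# ----------------------------------------------------------------------
# Distances
# ----------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray  # symmetric, zero diagonal
    n_dropped: int = 0  # incomplete rows excluded

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise PhenotypeError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise PhenotypeError("distance matrix must be symmetric")
        self.values = v


def euclidean_distances(m: PhenotypeMatrix) -> tuple[DistanceMatrix, pd.Series]:
    """Pairwise Euclidean distances on complete cases.

    Returns the distance matrix and the aligned taxon labels; the count of
    dropped incomplete rows is recorded on the matrix.
    """
    cc = m.complete_cases()
    if cc.n_individuals < 2:
        raise PhenotypeError("fewer than 2 complete rows for distance computation")
    D = squareform(pdist(cc.traits.to_numpy(dtype=float), metric="euclidean"))
    dm = DistanceMatrix(list(cc.traits.index), D, n_dropped=m.n_individuals - cc.n_individuals)
    return dm, cc.taxa


# ----------------------------------------------------------------------
# PERMANOVA
# ----------------------------------------------------------------------

@dataclass
class PermTestResult:
    F: float
    p: float
    n_perm: int
    R2: float | None = None
    df_between: int | None = None
    df_within: int | None = None
    valid_flag: str | None = None
    notes: list[str] = field(default_factory=list)


def _permanova_F(D2: np.ndarray, masks: list[np.ndarray], ss_total: float,
                 sizes: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R2 for one labelling given squared distances."""
    n = D2.shape[0]
    k = len(masks)
    ss_within = 0.0
    for mask, ng in zip(masks, sizes):
        sub = D2[np.ix_(mask, mask)]
        ss_within += sub.sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    F = (ss_between / (k - 1)) / (ss_within / (n - k)) if ss_within > 0 else np.inf
    return F, ss_between / ss_total


def permanova(d: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None) -> PermTestResult:
    """One-way PERMANOVA with whole-row label permutation.

    SS_total = Σ_{i<j} d²ᵢⱼ / N, SS_within pools the analogous within-group
    sums, pseudo-F = (SS_b/(K−1)) / (SS_w/(N−K)).  The p-value is
    (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), so p > 0 always.
    """
    g = np.asarray(groups).astype(str)
    n = d.values.shape[0]
    if g.size != n:
        raise PhenotypeError("group labels do not match distance matrix size")
    levels = np.unique(g)
    if levels.size < 2:
        raise PhenotypeError("PERMANOVA needs at least 2 groups")
    D2 = d.values**2
    ss_total = D2.sum() / (2.0 * n)

    def masks_for(labels: np.ndarray):
        return [np.flatnonzero(labels == lv) for lv in levels]

    sizes = np.array([np.sum(g == lv) for lv in levels])
    F_obs, r2 = _permanova_F(D2, masks_for(g), ss_total, sizes)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        gp = rng.permutation(g)
        F_p, _ = _permanova_F(D2, masks_for(gp), ss_total, sizes=np.array([np.sum(gp == lv) for lv in levels]))
        if F_p >= F_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermTestResult(F=float(F_obs), p=float(p), n_perm=n_perm, R2=float(r2),
                          df_between=int(levels.size - 1), df_within=int(n - levels.size))


# ----------------------------------------------------------------------
# PERMDISP
# ----------------------------------------------------------------------

def _pcoa_coords(D: np.ndarray) -> np.ndarray:
    """Principal-coordinate embedding of a distance matrix (real axes)."""
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = J @ A @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    tol = max(vals.max(), 0) * 1e-10 + 1e-12
    keep = vals > tol
    return vecs[:, keep] * np.sqrt(vals[keep])


def _geometric_median(X: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld iteration for the spatial (geometric) median."""
    c = X.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(X - c, axis=1)
        at_point = dist < 1e-12
        if at_point.any():
            # damped step to escape coincidence with a data point
            dist = np.where(at_point, 1e-12, dist)
        w = 1.0 / dist
        new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - c) < tol:
            return new
        c = new
    return c


def _anova_F(z: np.ndarray, masks: list[np.ndarray]) -> float:
    n = z.size
    k = len(masks)
    grand = z.mean()
    ss_b = sum(m.size * (z[m].mean() - grand) ** 2 for m in masks)
    ss_w = sum(((z[m] - z[m].mean()) ** 2).sum() for m in masks)
    if ss_w <= 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def _disp_perm_p(z: np.ndarray, masks: list[np.ndarray], n_perm: int,
                 rng: np.random.Generator) -> tuple[float, float]:
    """Observed F and permutation p from shuffling distance-to-center values."""
    F_obs = _anova_F(z, masks)
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if _anova_F(zp, masks) >= F_obs:
            count += 1
    return F_obs, (1 + count) / (1 + n_perm)


def permdisp(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    center: str = "spatial_median",
) -> tuple[PermTestResult, pd.DataFrame]:
    """Homogeneity of multivariate dispersions with pairwise contrasts.

    Distances are embedded by principal coordinates; each individual's
    distance to its group center (spatial median by default, arithmetic
    centroid as option) is computed, and the one-way ANOVA F on those
    distances is tested by permuting them across groups (seeded).
    """
    if center not in ("spatial_median", "centroid"):
        raise PhenotypeError(f"unknown center type {center!r}")
    g = np.asarray(groups).astype(str)
    levels = np.unique(g)
    if levels.size < 2:
        raise PhenotypeError("PERMDISP needs at least 2 groups")
    X = _pcoa_coords(d.values)
    notes = []
    z = np.empty(g.size)
    for lv in levels:
        mask = np.flatnonzero(g == lv)
        sub = X[mask]
        if mask.size == 1:
            z[mask] = 0.0
            notes.append(f"group {lv!r} has a single member; dispersion 0")
            continue
        c = sub.mean(axis=0) if center == "centroid" else _geometric_median(sub)
        z[mask] = np.linalg.norm(sub - c, axis=1)

    rng = np.random.default_rng(seed)
    masks = [np.flatnonzero(g == lv) for lv in levels]
    F_obs, p = _disp_perm_p(z, masks, n_perm, rng)
    overall = PermTestResult(F=float(F_obs), p=float(p), n_perm=n_perm,
                             df_between=int(levels.size - 1),
                             df_within=int(g.size - levels.size), notes=notes)
    rows = []
    for i in range(levels.size):
        for j in range(i + 1, levels.size):
            sel = np.concatenate([masks[i], masks[j]])
            sub_masks = [np.arange(masks[i].size),
                         np.arange(masks[i].size, sel.size)]
            F_ij, p_ij = _disp_perm_p(z[sel], sub_masks, n_perm, rng)
            rows.append({"group_a": levels[i], "group_b": levels[j],
                         "F": float(F_ij), "p": float(p_ij)})
    return overall, pd.DataFrame(rows, columns=["group_a", "group_b", "F", "p"])


def assess_validity(permanova_res: PermTestResult, permdisp_res: PermTestResult,
                    alpha: float = 0.05) -> str:
    """PERMANOVA is 'valid' iff dispersion homogeneity is not rejected."""
    flag = "valid" if permdisp_res.p > alpha else "dispersion_driven"
    permanova_res.valid_flag = flag
    return flag


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class OrdinationResult:
    scores: pd.DataFrame      # individuals x axes
    loadings: pd.DataFrame    # traits x axes
    explained: np.ndarray     # fraction per axis, descending
    axis_kind: str            # "PC" or "LD"
    groups: pd.Series | None = None
    dropped_traits: list[str] = field(default_factory=list)

    def top_contributors(self, axis: int = 0, n: int = 10) -> pd.Series:
        """Traits ranked by |loading| on the given axis (0-based)."""
        col = self.loadings.columns[axis]
        return self.loadings[col].abs().sort_values(ascending=False).head(n)

    def retained_axes(self, cum_threshold: float = 0.90) -> int:
        """Minimal axis prefix whose cumulative explained variance >= threshold."""
        cum = np.cumsum(self.explained)
        return int(np.searchsorted(cum, cum_threshold - 1e-12) + 1)


def pca(m: PhenotypeMatrix) -> OrdinationResult:
    """Centered + scaled PCA on traits with no missingness and nonzero variance."""
    usable, dropped = [], []
    for t in m.trait_names:
        col = m.traits[t]
        if col.isna().any() or np.nanstd(col.to_numpy(dtype=float), ddof=1) == 0:
            dropped.append(t)
        else:
            usable.append(t)
    if not usable:
        raise PhenotypeError("no usable traits for PCA after filtering")
    X = m.traits[usable].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise PhenotypeError("PCA needs at least 2 complete rows")
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    sdev2 = s**2 / (n - 1)
    explained = sdev2 / sdev2.sum()
    axes = [f"PC{i+1}" for i in range(s.size)]
    scores = pd.DataFrame(Xs @ Vt.T, index=m.traits.index, columns=axes)
    loadings = pd.DataFrame(Vt.T, index=usable, columns=axes)
    return OrdinationResult(scores, loadings, explained, "PC",
                            groups=m.taxa.copy(), dropped_traits=dropped)


def pc_posthoc(ord_res: OrdinationResult, groups=None, cum_threshold: float = 0.90,
               alpha: float = 0.05) -> pd.DataFrame:
    """Gated univariate tests on each retained principal component.

    Components are retained until cumulative explained variance reaches
    ``cum_threshold``; each goes through the same Shapiro/Bartlett-gated
    ANOVA-or-Kruskal–Wallis procedure as a raw trait.
    """
    if groups is None:
        groups = ord_res.groups
    g = np.asarray(groups).astype(str)
    n_keep = ord_res.retained_axes(cum_threshold)
    rows = []
    for i in range(n_keep):
        axis = ord_res.scores.columns[i]
        values = ord_res.scores[axis].to_numpy()
        rep = uv.check_assumptions(values, g, trait=axis, alpha=alpha)
        if rep.parametric_ok:
            F, dfb, dfw, p = uv.anova_oneway(values, g)
            test, stat, df = "anova", F, f"{dfb}/{dfw}"
        else:
            stat, dfk, p = uv.kruskal_wallis(values, g)
            test, df = "kruskal_wallis", str(dfk)
        sig_pairs = ""
        if np.isfinite(p) and p < alpha:
            table = (uv.tukey_hsd(values, g, alpha=alpha) if test == "anova"
                     else uv.dunn_test(values, g, alpha=alpha))
            sig_pairs = ";".join(
                f"{r.group_a}-{r.group_b}" for r in table.itertuples() if r.significant
            )
        rows.append({"axis": axis, "explained": float(ord_res.explained[i]),
                     "test": test, "statistic": float(stat), "df": df,
                     "p": float(p), "significant_pairs": sig_pairs})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# DAPC
# ----------------------------------------------------------------------

class DAPC(BaseEstimator, ClassifierMixin):
    """Discriminant analysis of principal components.

    PCA reduces the (standardized) trait matrix to the minimal number of
    components explaining at least ``var_threshold`` of total variance;
    linear discriminant analysis on those scores yields K−1 discriminant
    axes.  Classification ties resolve toward the alphabetically first
    class (classes are kept sorted).

    Parameters
    ----------
    var_threshold : float
        Cumulative variance the retained PCs must reach (default 0.90).
    scale : bool
        Divide by column SDs after centering (default True, the same
        standardization as the exploratory PCA); ``False`` reproduces the
        center-only convention of some reference implementations.
    n_pcs : int or None
        Freeze the retained-PC count instead of reselecting from
        ``var_threshold`` (used to speed up jackknifing).

    Attributes
    ----------
    classes_ : ndarray of sorted class labels
    n_pcs_ : int, retained principal components
    explained_ : ndarray, fraction of discriminant variance per LD axis
    """

    def __init__(self, var_threshold: float = 0.90, scale: bool = True,
                 n_pcs: int | None = None):
        self.var_threshold = var_threshold
        self.scale = scale
        self.n_pcs = n_pcs

    def fit(self, X, y) -> "DAPC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(str)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise PhenotypeError("X and y have incompatible shapes")
        if np.isnan(X).any():
            raise PhenotypeError("DAPC requires complete cases (no missing values)")
        labels, counts = np.unique(y, return_counts=True)
        if labels.size < 2:
            raise PhenotypeError("DAPC needs at least 2 groups")
        small = labels[counts < 2]
        if small.size:
            raise PhenotypeError(
                f"groups smaller than 2 individuals: {list(small)}; "
                "within-group covariance undefined"
            )
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if self.scale:
            if (sd == 0).any():
                raise PhenotypeError("zero-variance trait cannot be scaled; drop it first")
            self.scale_ = sd
        else:
            self.scale_ = np.ones_like(sd)
        Xs = (X - self.mean_) / self.scale_
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-9)) if s.size else 0
        var = s[:rank] ** 2
        cum = np.cumsum(var) / var.sum()
        if self.n_pcs is not None:
            n_pcs = min(int(self.n_pcs), rank)
        else:
            n_pcs = int(np.searchsorted(cum, self.var_threshold - 1e-12) + 1)
        self.components_ = Vt[:n_pcs]
        self.n_pcs_ = n_pcs
        pcs = Xs @ self.components_.T
        self.classes_ = labels  # np.unique returns sorted labels
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.lda_ = LinearDiscriminantAnalysis(
                solver="svd", n_components=labels.size - 1
            ).fit(pcs, y)
        self.explained_ = np.asarray(self.lda_.explained_variance_ratio_, dtype=float)
        return self

    def _pc_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return ((X - self.mean_) / self.scale_) @ self.components_.T

    def transform(self, X) -> np.ndarray:
        """Coordinates on the discriminant axes (LD1, LD2, ...)."""
        return self.lda_.transform(self._pc_scores(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]  # argmax -> first (alphabetical) on ties

    def predict_proba(self, X) -> np.ndarray:
        return self.lda_.predict_proba(self._pc_scores(X))

    def trait_loadings(self) -> np.ndarray:
        """Discriminant axes expressed in (standardized) trait space."""
        return self.components_.T @ self.lda_.scalings_[:, : len(self.classes_) - 1]


def dapc_fit(m: PhenotypeMatrix, var_threshold: float = 0.90,
             scale: bool = True) -> tuple[OrdinationResult, DAPC]:
    """Fit DAPC on the complete-case matrix; returns ordination + model."""
    cc = m.complete_cases()
    usable = [t for t in cc.trait_names
              if np.std(cc.traits[t].to_numpy(dtype=float), ddof=1) > 0]
    model = DAPC(var_threshold=var_threshold, scale=scale)
    X = cc.traits[usable].to_numpy(dtype=float)
    model.fit(X, cc.taxa.to_numpy())
    ld = model.transform(X)
    axes = [f"LD{i+1}" for i in range(ld.shape[1])]
    scores = pd.DataFrame(ld, index=cc.traits.index, columns=axes)
    loadings = pd.DataFrame(model.trait_loadings()[:, : ld.shape[1]],
                            index=usable, columns=axes)
    explained = model.explained_[: ld.shape[1]]
    dropped = [t for t in cc.trait_names if t not in usable]
    return OrdinationResult(scores, loadings, explained, "LD",
                            groups=cc.taxa.copy(), dropped_traits=dropped), model


def jackknife_classify(m: PhenotypeMatrix, var_threshold: float = 0.90,
                       scale: bool = True, freeze_pcs: bool = False) -> pd.DataFrame:
    """Leave-one-out cross-classification with full model refit per fold.

    Each individual is predicted by a DAPC fitted without it; by default
    the retained-PC count is reselected inside every fold (honest
    leave-one-out), with ``freeze_pcs`` fixing it at the all-data value
    for speed.  Folds that would leave a group with <2 members skip that
    individual with a warning row.
    """
    cc = m.complete_cases()
    usable = [t for t in cc.trait_names
              if np.std(cc.traits[t].to_numpy(dtype=float), ddof=1) > 0]
    X = cc.traits[usable].to_numpy(dtype=float)
    y = cc.taxa.to_numpy().astype(str)
    ids = list(cc.traits.index)
    frozen = None
    if freeze_pcs:
        frozen = DAPC(var_threshold=var_threshold, scale=scale).fit(X, y).n_pcs_
    rows = []
    for i in range(len(ids)):
        keep = np.ones(len(ids), dtype=bool)
        keep[i] = False
        y_train = y[keep]
        if np.sum(y_train == y[i]) < 2:
            rows.append({"id": ids[i], "actual": y[i], "predicted": None,
                         "note": "skipped: fold leaves group with <2 members"})
            continue
        model = DAPC(var_threshold=var_threshold, scale=scale, n_pcs=frozen)
        model.fit(X[keep], y_train)
        pred = model.predict(X[i : i + 1])[0]
        rows.append({"id": ids[i], "actual": y[i], "predicted": str(pred), "note": ""})
    return pd.DataFrame(rows, columns=["id", "actual", "predicted", "note"])


# ----------------------------------------------------------------------
# Classification summaries
# ----------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K cross-classification counts; rows = actual, columns = predicted."""

    counts: pd.DataFrame

    @property
    def classes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts.to_numpy()))


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    t = pd.Series(true_labels).astype(str)
    p = pd.Series(predicted_labels).astype(str)
    if len(t) != len(p):
        raise PhenotypeError("label vectors differ in length")
    classes = sorted(set(t))
    bad = set(p) - set(classes)
    if bad:
        raise PhenotypeError(f"predicted labels outside class set: {sorted(bad)}")
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for a, b in zip(t, p):
        counts.loc[a, b] += 1
    return ConfusionMatrix(counts)


@dataclass
class ClassMetrics:
    per_class: pd.DataFrame  # class, sensitivity, specificity, tss, n
    accuracy: float


def classification_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class sensitivity, specificity and TSS, plus overall accuracy.

    sensitivity(c) = cm[c,c] / row_sum(c);
    specificity(c) = true negatives / (N − row_sum(c));
    TSS(c) = sensitivity + specificity − 1, in [−1, 1].
    """
    M = cm.counts.to_numpy(dtype=float)
    n = M.sum()
    rows = []
    for i, c in enumerate(cm.classes):
        row_sum, col_sum = M[i].sum(), M[:, i].sum()
        tp = M[i, i]
        sens = tp / row_sum if row_sum > 0 else np.nan
        tn = n - row_sum - col_sum + tp
        spec = tn / (n - row_sum) if n > row_sum else np.nan
        rows.append({"class": c, "n": int(row_sum), "sensitivity": sens,
                     "specificity": spec, "tss": sens + spec - 1})
    return ClassMetrics(pd.DataFrame(rows), accuracy=float(np.trace(M) / n))


def misclassified_table(true_labels, predicted_labels, ids=None) -> pd.DataFrame:
    """One row per misclassified individual: id, actual, predicted."""
    t = pd.Series(true_labels).astype(str).reset_index(drop=True)
    p = pd.Series(predicted_labels).astype(str).reset_index(drop=True)
    if ids is None:
        ids = pd.RangeIndex(len(t))
    ids = pd.Series(list(ids)).reset_index(drop=True)
    bad = t != p
    out = pd.DataFrame({"id": ids[bad], "actual": t[bad], "predicted": p[bad]})
    return out.reset_index(drop=True)
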