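"""Distance-based tests, ordination, DAPC and classification summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from phenodiag.core_data import PhenotypeError, PhenotypeMatrix
from phenodiag.datasets import anole_reference_confusion
from phenodiag.multivariate import (
    DAPC,
    DistanceMatrix,
    assess_validity,
    classification_metrics,
    confusion_matrix,
    dapc_fit,
    euclidean_distances,
    jackknife_classify,
    misclassified_table,
    pc_posthoc,
    pca,
    permanova,
    permdisp,
    PermTestResult,
    OrdinationResult,
)
from phenodiag.synthetic import generate_clusters
from phenodiag.univariate import anova_oneway

from conftest import make_matrix


class TestEuclideanDistances:
    def test_three_four_five(self):
        m = make_matrix("AB", x=[0.0, 3.0], y=[0.0, 4.0])
        dm, _ = euclidean_distances(m)
        assert dm.values[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        m = make_matrix("AB", x=[1.0, 1.0], y=[2.0, 2.0])
        dm, _ = euclidean_distances(m)
        assert dm.values[0, 1] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(4, 3))
        m = make_matrix("AABB", **{f"t{i}": X[:, i] for i in range(3)})
        dm, _ = euclidean_distances(m)
        for i in range(4):
            for j in range(4):
                assert dm.values[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), abs=1e-12)

    def test_incomplete_rows_dropped_and_counted(self, rng):
        m = make_matrix("AABB", x=[1.0, np.nan, 3.0, 4.0], y=[1.0, 2.0, 3.0, 4.0])
        dm, groups = euclidean_distances(m)
        assert dm.n_dropped == 1 and len(groups) == 3


class TestPermanova:
    def test_univariate_pseudo_F_equals_anova_F(self, rng):
        x = rng.normal(size=30)
        g = np.repeat(list("abc"), 10)
        m = make_matrix(g, t=x)
        dm, groups = euclidean_distances(m)
        res = permanova(dm, groups, n_perm=49, seed=0)
        F, *_ = anova_oneway(x, g)
        assert res.F == pytest.approx(F, abs=1e-10)

    def test_null_draw_has_small_R2(self):
        m = generate_clusters(n_taxa=3, n_per_taxon=40, separation=0.0, seed=21)
        dm, groups = euclidean_distances(m)
        res = permanova(dm, groups, n_perm=99, seed=1)
        assert res.R2 < 0.05

    def test_separated_groups_significant(self):
        m = generate_clusters(n_taxa=2, n_per_taxon=25, separation=5.0, seed=2)
        dm, groups = euclidean_distances(m)
        res = permanova(dm, groups, n_perm=199, seed=3)
        assert res.p == pytest.approx(1 / 200)
        assert res.R2 > 0.5

    def test_p_strictly_positive_and_deterministic(self):
        m = generate_clusters(n_taxa=2, n_per_taxon=10, separation=1.0, seed=4)
        dm, groups = euclidean_distances(m)
        r1 = permanova(dm, groups, n_perm=99, seed=7)
        r2 = permanova(dm, groups, n_perm=99, seed=7)
        assert r1.p == r2.p > 0

    def test_matches_scikit_bio_statistic(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        m = generate_clusters(n_taxa=3, n_per_taxon=12, separation=1.5, seed=5)
        dm, groups = euclidean_distances(m)
        res = permanova(dm, groups, n_perm=9, seed=0)
        sk = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm.values, ids=[str(i) for i in dm.labels]),
            grouping=list(groups), permutations=9)
        assert res.F == pytest.approx(sk["test statistic"], abs=1e-10)


class TestPermdisp:
    def test_mirror_groups_have_equal_dispersion(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(15, 3))
        X = np.vstack([A, -A])  # mirror image: identical internal geometry
        m = make_matrix("A" * 15 + "B" * 15, **{f"t{i}": X[:, i] for i in range(3)})
        dm, groups = euclidean_distances(m)
        res, _ = permdisp(dm, groups, n_perm=99, seed=0)
        assert res.F == pytest.approx(0.0, abs=1e-18)
        assert res.p == 1.0

    def test_inflated_group_detected(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(0, 10, (50, 3))])
        m = make_matrix("A" * 50 + "B" * 50, **{f"t{i}": X[:, i] for i in range(3)})
        dm, groups = euclidean_distances(m)
        res, pairs = permdisp(dm, groups, n_perm=199, seed=9)
        assert res.p <= 0.05
        assert pairs.iloc[0]["p"] <= 0.05

    def test_centroid_mode_matches_direct_distances(self, rng):
        X = rng.normal(size=(20, 2))
        g = np.repeat(["A", "B"], 10)
        m = make_matrix(g, x=X[:, 0], y=X[:, 1])
        dm, groups = euclidean_distances(m)
        # reconstruct distances-to-centroid through the ANOVA F identity:
        # F computed from PCoA embedding must equal F from raw coordinates
        res, _ = permdisp(dm, groups, n_perm=9, seed=0, center="centroid")
        direct = np.concatenate([
            np.linalg.norm(X[:10] - X[:10].mean(0), axis=1),
            np.linalg.norm(X[10:] - X[10:].mean(0), axis=1),
        ])
        F_direct, *_ = anova_oneway(direct, g)
        assert res.F == pytest.approx(F_direct, abs=1e-8)

    def test_matches_scikit_bio_statistic_both_centers(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        m = generate_clusters(n_taxa=3, n_per_taxon=12, separation=1.0, seed=10)
        dm, groups = euclidean_distances(m)
        sk_dm = skbio_stats.DistanceMatrix(dm.values, ids=[str(i) for i in dm.labels])
        for center, sk_name in [("spatial_median", "median"), ("centroid", "centroid")]:
            res, _ = permdisp(dm, groups, n_perm=9, seed=0, center=center)
            sk = skbio_stats.permdisp(sk_dm, grouping=list(groups),
                                      permutations=9, test=sk_name)
            assert res.F == pytest.approx(sk["test statistic"], abs=1e-6), center

    def test_singleton_group_flagged(self):
        m = make_matrix("ABBB", x=[0.0, 1, 2, 3], y=[0.0, 1, 0, 1])
        dm, groups = euclidean_distances(m)
        res, _ = permdisp(dm, groups, n_perm=9, seed=0)
        assert any("single member" in n for n in res.notes)


class TestValidityFlag:
    @pytest.mark.parametrize("p_disp,expected", [
        (0.185, "valid"), (0.01, "dispersion_driven"), (0.05, "dispersion_driven")])
    def test_flag_thresholds(self, p_disp, expected):
        perm = PermTestResult(F=12.62, p=0.001, n_perm=999, R2=0.64)
        disp = PermTestResult(F=1.60, p=p_disp, n_perm=999)
        assert assess_validity(perm, disp) == expected
        assert perm.valid_flag == expected


class TestPca:
    def test_full_rank_explained_sums_to_one(self, iris):
        res = pca(iris)
        assert res.explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_scores_reconstruct_standardized_matrix(self, iris):
        res = pca(iris)
        X = iris.traits.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(
            res.scores.to_numpy() @ res.loadings.to_numpy().T, Xs, atol=1e-8)

    def test_perfect_correlation_single_axis(self):
        x = np.arange(1.0, 11.0)
        m = make_matrix("AB" * 5, a=x, b=3 * x + 1)
        res = pca(m)
        assert res.explained[0] == pytest.approx(1.0)

    def test_zero_variance_and_missing_columns_dropped(self, rng):
        m = make_matrix("AABB", good=list(rng.normal(size=4)),
                        const=[1.0] * 4, holey=[1.0, np.nan, 2.0, 3.0])
        res = pca(m)
        assert set(res.dropped_traits) == {"const", "holey"}


class TestPcPosthoc:
    def _ord(self, explained, scores, groups):
        axes = [f"PC{i+1}" for i in range(len(explained))]
        return OrdinationResult(
            pd.DataFrame(scores, columns=axes), pd.DataFrame(columns=axes),
            np.asarray(explained), "PC", groups=pd.Series(groups))

    def test_retention_rule(self, rng):
        scores = rng.normal(size=(30, 4))
        o = self._ord([0.5, 0.3, 0.15, 0.05], scores, ["A"] * 15 + ["B"] * 15)
        assert o.retained_axes(0.90) == 3
        assert len(pc_posthoc(o)) == 3

    def test_dominant_first_axis_keeps_one(self, rng):
        scores = rng.normal(size=(30, 2))
        o = self._ord([0.95, 0.05], scores, ["A"] * 15 + ["B"] * 15)
        assert o.retained_axes(0.90) == 1
        table = pc_posthoc(o)
        assert list(table["axis"]) == ["PC1"]
        assert table.iloc[0]["test"] in ("anova", "kruskal_wallis")

    def test_iris_pcs_separate_species(self, iris):
        table = pc_posthoc(pca(iris))
        assert (table["p"] < 0.05).any()


class TestDapc:
    def test_two_groups_single_axis(self):
        m = generate_clusters(n_taxa=2, n_per_taxon=15, separation=3, seed=11)
        ordn, model = dapc_fit(m)
        assert ordn.scores.shape[1] == 1
        assert model.lda_.classes_.tolist() == sorted(model.classes_.tolist())

    def test_well_separated_clusters_no_overlap_on_ld1(self):
        m = generate_clusters(n_taxa=2, n_per_taxon=20, separation=10, seed=12)
        ordn, _ = dapc_fit(m)
        a = ordn.scores.to_numpy()[:20, 0]
        b = ordn.scores.to_numpy()[20:, 0]
        assert a.max() < b.min() or b.max() < a.min()

    def test_group_geometry_invariant_to_relabeling(self):
        # renaming the groups must not change the discriminant-space
        # configuration of group means (equivariance of the fit)
        m = generate_clusters(n_taxa=3, n_per_taxon=15, separation=4, seed=13)
        ordn, _ = dapc_fit(m)
        relabel = {"taxon_a": "zz", "taxon_b": "mm", "taxon_c": "aa"}
        m2 = PhenotypeMatrix(m.taxa.map(relabel), m.traits, dict(m.trait_kind))
        ordn2, _ = dapc_fit(m2)

        def mean_gaps(o):
            means = o.scores.groupby(o.groups.to_numpy()).mean().to_numpy()
            d = np.linalg.norm(means[:, None] - means[None, :], axis=2)
            return np.sort(d[np.triu_indices(3, 1)])

        np.testing.assert_allclose(mean_gaps(ordn), mean_gaps(ordn2), atol=1e-8)

    def test_full_threshold_equals_plain_lda_up_to_sign(self):
        m = generate_clusters(n_taxa=3, n_per_taxon=15, separation=2, seed=14)
        X = m.traits.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = LinearDiscriminantAnalysis(n_components=2).fit(Xs, m.taxa).transform(Xs)
        got = DAPC(var_threshold=1.0).fit(X, m.taxa).transform(X)
        for j in range(2):
            assert (np.allclose(got[:, j], ref[:, j], atol=1e-6)
                    or np.allclose(got[:, j], -ref[:, j], atol=1e-6))

    def test_group_smaller_than_two_rejected(self):
        m = make_matrix("ABB", x=[1.0, 2, 3], y=[1.0, 2, 3])
        with pytest.raises(PhenotypeError, match="smaller than 2"):
            DAPC().fit(m.traits.to_numpy(), m.taxa.to_numpy())

    def test_explained_fractions_sum_to_one(self):
        m = generate_clusters(n_taxa=4, n_per_taxon=12, separation=3, seed=15)
        ordn, _ = dapc_fit(m)
        assert ordn.explained.sum() == pytest.approx(1.0, abs=1e-8)


class TestJackknife:
    def test_separated_clusters_perfect(self):
        m = generate_clusters(n_taxa=2, n_per_taxon=20, separation=10, seed=16)
        jack = jackknife_classify(m)
        assert (jack["actual"] == jack["predicted"]).sum() == 40

    def test_null_accuracy_near_chance(self):
        m = generate_clusters(n_taxa=4, n_per_taxon=10, separation=0.0, seed=17)
        jack = jackknife_classify(m)
        acc = (jack["actual"] == jack["predicted"]).mean()
        assert acc == pytest.approx(0.25, abs=0.15)

    def test_deterministic_across_runs(self):
        m = generate_clusters(n_taxa=3, n_per_taxon=8, separation=1.0, seed=18)
        j1 = jackknife_classify(m)
        j2 = jackknife_classify(m)
        pd.testing.assert_frame_equal(j1, j2)

    def test_frozen_pc_count_is_supported(self):
        m = generate_clusters(n_taxa=2, n_per_taxon=10, separation=5, seed=19)
        jack = jackknife_classify(m, freeze_pcs=True)
        assert (jack["actual"] == jack["predicted"]).all()

    def test_tiny_group_fold_skipped_with_note(self):
        m = make_matrix("AABBBBB", x=[1.0, 1.1, 5, 5.1, 5.2, 5.3, 5.4],
                        y=[0.0, 0.2, 3, 3.1, 3.2, 3.3, 3.4])
        jack = jackknife_classify(m)
        skipped = jack[jack["predicted"].isna()]
        assert len(skipped) == 2 and all("skipped" in n for n in skipped["note"])


class TestConfusionAndMetrics:
    def test_perfect_prediction_is_diagonal(self):
        cm = confusion_matrix(list("AABBB"), list("AABBB"))
        M = cm.counts.to_numpy()
        assert np.all(M == np.diag(np.diag(M)))

    def test_row_sums_equal_class_sizes(self, rng):
        t = rng.choice(list("ABC"), 50)
        p = rng.choice(list("ABC"), 50)
        cm = confusion_matrix(t, p)
        for c in cm.classes:
            assert cm.counts.loc[c].sum() == np.sum(t == c)

    def test_unknown_predicted_label_rejected(self):
        with pytest.raises(PhenotypeError, match="outside class set"):
            confusion_matrix(list("AB"), list("AZ"))

    def test_reference_anole_table_metrics(self):
        cm = anole_reference_confusion()
        met = classification_metrics(cm)
        assert met.accuracy == pytest.approx(cm.trace / cm.n)
        per = met.per_class.set_index("class")
        assert per.loc["car", "sensitivity"] == pytest.approx(1.0)
        assert per.loc["car", "specificity"] == pytest.approx(70 / 71)
        assert per.loc["car", "tss"] == pytest.approx(70 / 71, abs=1e-12)
        # TSS identity holds exactly for every class
        np.testing.assert_allclose(
            per["tss"], per["sensitivity"] + per["specificity"] - 1, atol=0)

    def test_sensitivity_weighted_sum_equals_trace(self):
        cm = anole_reference_confusion()
        per = classification_metrics(cm).per_class
        total = (per["n"] * per["sensitivity"]).sum()
        assert total == pytest.approx(cm.trace)
        assert cm.trace / cm.n == pytest.approx(classification_metrics(cm).accuracy)

    def test_random_predictions_have_near_zero_tss(self, rng):
        t = rng.choice(list("ABCD"), 4000)
        p = rng.choice(list("ABCD"), 4000)
        per = classification_metrics(confusion_matrix(t, p)).per_class
        assert np.all(np.abs(per["tss"]) < 0.06)

    def test_misclassified_count_identity(self, rng):
        t = rng.choice(list("ABC"), 60)
        p = rng.choice(list("ABC"), 60)
        cm = confusion_matrix(t, p)
        table = misclassified_table(t, p)
        assert len(table) == cm.n - cm.trace

    def test_perfect_classification_empty_table(self):
        assert misclassified_table(list("AB"), list("AB")).empty
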