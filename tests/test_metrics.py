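import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipocket.metrics import (
    ConfusionCounts,
    auroc,
    boxplot_summary,
    classification_metrics,
    cohens_kappa,
    confusion_from_predictions,
    f1_from_rates,
    impurity_importance,
    pca_project,
    permutation_importance,
)
from lipocket.dataset_curation import DescriptorTable
from lipocket.descriptors import DESCRIPTOR_NAMES
from lipocket.synthetic_fixtures import TableSpec, make_descriptor_table

counts_strategy = st.tuples(
    st.integers(0, 500), st.integers(0, 500),
    st.integers(0, 500), st.integers(0, 500),
).filter(lambda t: sum(t) > 0)


class TestFormulaMetrics:
    def test_reported_rates_give_reported_f1(self):
        # harmonic mean of sensitivity 0.818 and precision 0.926
        assert f1_from_rates(0.818, 0.926) == pytest.approx(0.869, abs=5e-4)

    def test_perfect_classifier_all_ones(self):
        m = classification_metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert (m.sensitivity, m.specificity, m.precision,
                m.accuracy, m.f1) == (1, 1, 1, 1, 1)

    def test_hand_arithmetic_case(self):
        m = classification_metrics(ConfusionCounts(TP=3, FN=1, FP=2, TN=4))
        assert m.sensitivity == pytest.approx(0.75)
        assert m.precision == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 / (4 / 3 + 5 / 3))

    def test_zero_denominator_flagged_not_nan(self):
        m = classification_metrics(ConfusionCounts(TP=0, FN=0, FP=5, TN=5))
        assert m.sensitivity is None
        assert m.specificity == 0.5

    @settings(max_examples=200, deadline=None)
    @given(counts_strategy)
    def test_f1_equals_algebraic_identity(self, tpfp):
        tp, tn, fp, fn = tpfp
        m = classification_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        if m.f1 is not None:
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))

    @settings(max_examples=200, deadline=None)
    @given(counts_strategy)
    def test_accuracy_prevalence_identity(self, tpfp):
        tp, tn, fp, fn = tpfp
        m = classification_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        n = tp + tn + fp + fn
        prev = (tp + fn) / n
        if m.sensitivity is not None and m.specificity is not None:
            assert m.accuracy == pytest.approx(
                prev * m.sensitivity + (1 - prev) * m.specificity)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_toy_case_by_pair_counting(self):
        # positives 0.9, 0.4 vs negatives 0.8, 0.2: wins 3 of 4 pairs
        assert auroc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(size=5000)
        y = rng.integers(2, size=5000)
        assert auroc(s, y) == pytest.approx(0.5, abs=0.03)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])

    def test_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        s = rng.integers(0, 5, size=300) / 4.0  # heavy ties
        y = rng.integers(2, size=300)
        assert auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.uniform(size=60)
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        assert auroc(s, y) == pytest.approx(auroc(np.exp(3 * s), y), abs=1e-12)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(ConfusionCounts(TP=50, TN=50, FP=0, FN=0)) == 1.0

    def test_independence_is_zero(self):
        # marginals 50:50 both ways, agreement exactly at chance
        assert cohens_kappa(
            ConfusionCounts(TP=25, TN=25, FP=25, FN=25)) == pytest.approx(0.0)

    def test_hand_marginal_arithmetic(self):
        # p_o = 0.85; p_e = 0.55*0.5 + 0.45*0.5 = 0.5 -> kappa = 0.7
        assert cohens_kappa(
            ConfusionCounts(TP=45, FN=5, FP=10, TN=40)) == pytest.approx(0.7)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        yt = rng.integers(2, size=500)
        yp = rng.integers(2, size=500)
        c = confusion_from_predictions(yt, yp)
        assert cohens_kappa(c) == pytest.approx(
            cohen_kappa_score(yt, yp), abs=1e-12)


class TestPca:
    def _table_from_matrix(self, X):
        df = pd.DataFrame(X, columns=list(DESCRIPTOR_NAMES))
        df.insert(0, "structure_id", [f"s{i}" for i in range(len(X))])
        df.insert(1, "pocket_id", 1)
        df["label"] = "PP"
        df["matched_ligand"] = None
        return DescriptorTable(df)

    def test_collinear_rows_explained_by_pc1(self):
        t = np.linspace(0, 1, 30)[:, None]
        direction = np.arange(1, 18)[None, :]
        table = self._table_from_matrix(10 + t * direction)
        _, evr, _ = pca_project(table, n_components=3)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_flat_spectrum(self):
        rng = np.random.default_rng(2)
        table = self._table_from_matrix(rng.normal(size=(4000, 17)))
        _, evr, _ = pca_project(table, n_components=17)
        assert np.all(np.abs(evr - 1 / 17) < 0.01)

    def test_small_table_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 17))
        table = self._table_from_matrix(X)
        _, evr, _ = pca_project(table, n_components=4)
        Z = (X - X.mean(0)) / X.std(0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
        np.testing.assert_allclose(evr[:4], (eig / eig.sum())[:4], atol=1e-9)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 17))
        X[:, 0] = 5.0
        table = self._table_from_matrix(X)
        with pytest.warns(UserWarning, match="constant"):
            _, _, loadings = pca_project(table, n_components=2)
        assert "pock_vol" not in loadings.index


class TestImportances:
    def test_signal_feature_ranked_first(self, trained_rf, corpus_split):
        _, test = corpus_split
        imp = permutation_importance(trained_rf, test, n_repeats=10, seed=0)
        assert imp["delta_f1_mean"].idxmax() == "hydrophobicity_score"

    def test_permutation_reproducible(self, trained_rf, corpus_split):
        _, test = corpus_split
        a = permutation_importance(trained_rf, test, n_repeats=3, seed=5)
        b = permutation_importance(trained_rf, test, n_repeats=3, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_impurity_fractions_sum_to_one(self, trained_rf):
        imp = impurity_importance(trained_rf)
        assert imp.min() >= 0
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_impurity_and_permutation_agree_on_top_feature(
            self, trained_rf, corpus_split):
        _, test = corpus_split
        perm = permutation_importance(trained_rf, test, n_repeats=5, seed=1)
        mdi = impurity_importance(trained_rf)
        assert mdi.idxmax() == perm["delta_f1_mean"].idxmax()

    def test_non_tree_model_unsupported(self, corpus_split):
        from lipocket.classifier import train_classifier

        train, _ = corpus_split
        nb = train_classifier(train, algorithm="naive_bayes", seed=0)
        with pytest.raises(TypeError):
            impurity_importance(nb)


def test_boxplot_summary_quartiles_and_outliers():
    values = list(range(1, 12)) + [100]  # 100 is beyond 1.5*IQR
    s = boxplot_summary(values)
    assert s["median"] == pytest.approx(np.median(values))
    assert s["outliers"] == [100.0]
    assert s["whisker_high"] == 11.0
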