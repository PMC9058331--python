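"""PCA, ANOVA screening, LDA, majority voting and LOSOCV."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from irhisto.classify import (
    CVConfig,
    anova_select,
    fit_lda,
    fit_pca,
    losocv,
    majority_vote,
    predict_spectra,
)
from irhisto.core import InvariantError
from irhisto.synthetic import DEFAULT_AXIS

from conftest import make_table


class TestPCA:
    def test_rank_one_data_explains_everything(self):
        rng = np.random.default_rng(0)
        direction = rng.standard_normal(50)
        X = np.outer(rng.standard_normal(30), direction)
        model = fit_pca(X, n_components_cap=5)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        model = fit_pca(rng.standard_normal((40, 25)), n_components_cap=10)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)

    def test_explained_variance_non_increasing_and_bounded(self):
        rng = np.random.default_rng(2)
        model = fit_pca(rng.standard_normal((50, 20)))
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-12

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 201))
        model = fit_pca(X, n_components_cap=50)  # rank is 19
        scores = model.transform(X)
        np.testing.assert_allclose(
            model.inverse_transform(scores), X, atol=1e-8
        )

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 12))
        a = fit_pca(X)
        b = fit_pca(X.copy())
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for row in a.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_single_record_rejected(self):
        with pytest.raises(InvariantError):
            fit_pca(np.ones((1, 10)))


def _anova_oracle_f(groups):
    """Brute-force one-way fixed-effects F from group means and SS."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    k = len(groups)
    n = all_x.size
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestAnovaSelect:
    def test_strong_component_selected_with_tiny_p(self):
        rng = np.random.default_rng(0)
        n = 200
        labels = np.array(["a"] * n + ["b"] * n)
        scores = rng.standard_normal((2 * n, 30))
        scores[:, 0] += np.where(labels == "a", 0.0, 10.0)
        sel = anova_select(scores, labels)
        assert 0 in sel.indices
        assert sel.p_values[0] < 1e-10

    def test_cap_enforced(self):
        rng = np.random.default_rng(1)
        n = 100
        labels = np.array(["a"] * n + ["b"] * n)
        scores = rng.standard_normal((2 * n, 30))
        scores += np.where(labels == "a", 0.0, 3.0)[:, None]  # all 30 differ
        sel = anova_select(scores, labels, max_keep=25)
        assert len(sel.indices) == 25

    def test_selection_ordered_by_p_value(self):
        rng = np.random.default_rng(2)
        labels = np.array(["a"] * 50 + ["b"] * 50)
        scores = rng.standard_normal((100, 10))
        scores[:, 3] += np.where(labels == "a", 0, 5.0)
        scores[:, 7] += np.where(labels == "a", 0, 1.0)
        sel = anova_select(scores, labels)
        assert sel.indices[0] == 3
        ps = sel.p_values[sel.indices]
        assert np.all(np.diff(ps) >= 0)

    def test_f_matches_brute_force_oracle(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        for _ in range(20):
            groups = [rng.standard_normal(rng.integers(3, 12))
                      for _ in range(rng.integers(2, 5))]
            f_scipy = stats.f_oneway(*groups).statistic
            assert f_scipy == pytest.approx(_anova_oracle_f(groups), abs=1e-10)

    def test_small_group_rejected(self):
        labels = np.array(["a", "a", "b"])
        with pytest.raises(InvariantError):
            anova_select(np.zeros((3, 2)), labels)


class TestLDA:
    def test_two_gaussians_near_bayes_boundary(self):
        rng = np.random.default_rng(0)
        n = 500
        X = np.vstack([
            rng.normal([-5, 0], 1.0, (n, 2)),
            rng.normal([5, 0], 1.0, (n, 2)),
        ])
        y = np.array(["neg"] * n + ["pos"] * n)
        model = fit_lda(X, y)
        X_test = np.vstack([
            rng.normal([-5, 0], 1.0, (n, 2)),
            rng.normal([5, 0], 1.0, (n, 2)),
        ])
        err = (model.predict(X_test) != y).mean()
        assert err < 0.01
        # boundary ~ x=0: the direction is dominated by the first axis
        d = model.directions[:, 0]
        assert abs(d[0]) > 10 * abs(d[1])

    def test_identical_classes_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((400, 5))
        y = np.array(["a", "b"] * 200)
        model = fit_lda(X, y)
        X_new = rng.standard_normal((2000, 5))
        y_new = np.array(["a", "b"] * 1000)
        acc = (model.predict(X_new) == y_new).mean()
        # binomial 95% interval around 0.5 at n=2000
        assert abs(acc - 0.5) < 1.96 * np.sqrt(0.25 / 2000) + 0.02

    def test_single_component_reduces_to_threshold(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(4, 1, 300)])
        y = np.array(["lo"] * 300 + ["hi"] * 300)
        model = fit_lda(x[:, None], y)
        grid = np.linspace(-3, 7, 200)[:, None]
        pred = model.predict(grid)
        flips = (pred[:-1] != pred[1:]).sum()
        assert flips == 1  # one threshold on the line

    def test_two_class_direction_parallel_to_cov_inv_mean_diff(self):
        rng = np.random.default_rng(3)
        X = np.vstack([
            rng.multivariate_normal([0, 0, 0], np.diag([1, 2, 3]), 300),
            rng.multivariate_normal([2, 1, -1], np.diag([1, 2, 3]), 300),
        ])
        y = np.array(["a"] * 300 + ["b"] * 300)
        model = fit_lda(X, y)
        expected = np.linalg.solve(
            model.pooled_cov, model.means[1] - model.means[0]
        )
        d = model.directions[:, 0]
        cos = abs(d @ expected) / (np.linalg.norm(d) * np.linalg.norm(expected))
        assert cos > 1 - 1e-8

    def test_singular_covariance_without_ridge_advises(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.arange(10)  # two dimensions have zero variance
        y = np.array(["a", "b"] * 5)
        with pytest.raises(InvariantError, match="ridge"):
            fit_lda(X, y, ridge=0.0)

    def test_agrees_with_sklearn_on_separated_data(self):
        rng = np.random.default_rng(4)
        X = np.vstack([
            rng.normal([-3, 0, 1], 1.0, (200, 3)),
            rng.normal([0, 3, -1], 1.0, (200, 3)),
            rng.normal([3, -3, 0], 1.0, (200, 3)),
        ])
        y = np.array(["a"] * 200 + ["b"] * 200 + ["c"] * 200)
        model = fit_lda(X, y)
        sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(X, y)
        agree = (model.predict(X) == sk.predict(X)).mean()
        assert agree > 0.99


class TestPredictSpectra:
    def _chain(self, seed=0):
        rng = np.random.default_rng(seed)
        nchan = len(DEFAULT_AXIS)
        base = rng.random(nchan)
        shift = np.zeros(nchan)
        shift[20:40] = 0.5
        X = np.vstack([
            base + rng.normal(0, 0.02, (100, nchan)),
            base + shift + rng.normal(0, 0.02, (100, nchan)),
        ])
        y = np.array(["normal"] * 100 + ["cancer"] * 100)
        pca = fit_pca(X, 10)
        sel = anova_select(pca.transform(X), y)
        lda = fit_lda(pca.transform(X)[:, sel.indices], y)
        return X, y, pca, sel, lda, base, shift

    def test_class_mean_classified_confidently(self):
        X, y, pca, sel, lda, base, shift = self._chain()
        pred = predict_spectra(pca, sel, lda, (base + shift)[None, :])
        assert pred.predicted[0] == "cancer"
        assert pred.posteriors[0].max() > 0.5

    def test_posteriors_normalized(self):
        X, y, pca, sel, lda, *_ = self._chain()
        pred = predict_spectra(pca, sel, lda, X)
        np.testing.assert_allclose(pred.posteriors.sum(axis=1), 1.0, atol=1e-8)

    def test_equidistant_point_splits_posteriors(self):
        # equidistant from both *fitted* class means with equal priors
        _, _, _, _, lda, _, _ = self._chain()
        midpoint = lda.means.mean(axis=0)
        post = lda.predict_posteriors(midpoint[None, :])
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-8)

    def test_axis_mismatch_rejected(self):
        X, y, pca, sel, lda, *_ = self._chain()
        with pytest.raises(InvariantError):
            predict_spectra(pca, sel, lda, X[:, :-1])


class TestMajorityVote:
    def test_fifty_one_percent_is_decisive(self):
        preds = ["A"] * 51 + ["B"] * 49
        vote = majority_vote(preds, classes=["A", "B"])
        assert vote.prediction == "A"
        assert vote.decisive

    def test_plurality_without_majority_not_decisive(self):
        preds = ["a"] * 40 + ["b"] * 30 + ["c"] * 20 + ["d"] * 10
        vote = majority_vote(preds, classes=["a", "b", "c", "d"])
        assert vote.prediction == "a"
        assert not vote.decisive
        assert vote.fractions == {"a": 0.4, "b": 0.3, "c": 0.2, "d": 0.1}

    def test_unanimous(self):
        vote = majority_vote(["x"] * 7, classes=["x", "y"])
        assert vote.prediction == "x"
        assert vote.fractions["x"] == 1.0
        assert vote.decisive

    def test_tie_broken_by_mean_posterior(self):
        preds = ["a", "b"]
        posteriors = np.array([[0.55, 0.45], [0.1, 0.9]])
        vote = majority_vote(preds, posteriors, classes=["a", "b"])
        assert vote.prediction == "b"
        assert not vote.decisive

    def test_empty_input_rejected(self):
        with pytest.raises(InvariantError):
            majority_vote([])


def _labelled_cohort_table(effect=0.4, n_samples=3, n_spectra=40, seed=0):
    """Flat 2-group spectra table with a per-group spectral shift."""
    rng = np.random.default_rng(seed)
    nchan = len(DEFAULT_AXIS)
    base = rng.random(nchan)
    shift = np.zeros(nchan)
    shift[60:90] = effect
    tables = []
    for g, (group, offset) in enumerate(
        [("epithelial_misplacement", 0.0), ("cancer", 1.0)]
    ):
        for s in range(n_samples):
            spectra = base + offset * shift
            spectra = spectra + rng.normal(0, 0.05, (n_spectra, nchan))
            tables.append(
                make_table(
                    spectra,
                    sample_id=f"{group}_{s}",
                    pathology=group,
                )
            )
    from irhisto.core import concat_tables

    return concat_tables(tables)


class TestLOSOCV:
    def test_each_sample_tested_once(self):
        table = _labelled_cohort_table(n_samples=4)
        cv = losocv(table, config=CVConfig(pca_cap=10))
        assert len(cv.sample_df) == 8
        assert sorted(cv.sample_df["sample_id"]) == sorted(set(table.meta["sample_id"]))
        tested = cv.spectrum_df.groupby("sample_id").size()
        assert (tested == 40).all()

    def test_no_leakage_in_any_fold(self):
        import hashlib

        table = _labelled_cohort_table(n_samples=3, seed=1)
        cv = losocv(table, config=CVConfig(pca_cap=10))
        all_ids = set(table.meta["sample_id"])
        for fold in cv.fold_audit:
            expected = sorted(all_ids - {fold["test_sample"]})
            expected_hash = hashlib.sha256(
                "\n".join(expected).encode()
            ).hexdigest()
            assert fold["train_hash"] == expected_hash

    def test_strong_signal_perfect_majority_vote(self):
        table = _labelled_cohort_table(effect=1.0, n_samples=4, seed=2)
        cv = losocv(table, config=CVConfig(pca_cap=10))
        assert cv.sample_accuracy == 1.0

    def test_group_with_single_sample_rejected(self):
        table = _labelled_cohort_table(n_samples=2)
        keep = table.meta["sample_id"] != "cancer_1"
        with pytest.raises(InvariantError):
            losocv(table.select(keep.to_numpy()), config=CVConfig(pca_cap=10))

    def test_single_group_subset_rejected(self):
        # ANOVA (and LDA) need >= 2 groups, so a one-group subset must raise
        table = _labelled_cohort_table(n_samples=3)
        with pytest.raises(InvariantError):
            losocv(table, groups=["cancer"], config=CVConfig(pca_cap=10))

    def test_vote_fractions_sum_to_one(self):
        table = _labelled_cohort_table(n_samples=3, seed=3)
        cv = losocv(table, config=CVConfig(pca_cap=10))
        frac_cols = [c for c in cv.sample_df.columns if c.startswith("frac_")]
        np.testing.assert_allclose(
            cv.sample_df[frac_cols].sum(axis=1), 1.0, atol=1e-12
        )

    def test_subsampling_caps_spectra_per_sample(self):
        table = _labelled_cohort_table(n_samples=3, n_spectra=50, seed=4)
        cv = losocv(
            table, config=CVConfig(pca_cap=10, subsample_per_sample=20, seed=1)
        )
        counts = cv.spectrum_df.groupby("sample_id").size()
        assert (counts == 20).all()

    def test_global_pca_flag_runs(self):
        table = _labelled_cohort_table(n_samples=3, seed=5)
        cv = losocv(table, config=CVConfig(pca_cap=10, global_pca=True))
        assert len(cv.sample_df) == 6
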