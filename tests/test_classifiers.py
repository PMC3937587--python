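"""Unit and property tests for the eight classification methods."""

import numpy as np
import pytest
from scipy.special import gammaln
from sklearn.tree import DecisionTreeClassifier

from misclassim.classifiers import (DegenerateFitError, DevianceTreeClassifier,
                                    LeastSquaresNetClassifier,
                                    LinearGaussianDiscriminant, METHOD_NAMES,
                                    MixtureDiscriminantClassifier,
                                    MultinomialLogit,
                                    NearestNeighborForestClassifier,
                                    PenalizedSplineGAM,
                                    QuadraticGaussianDiscriminant,
                                    make_classifier, node_deviance)
from conftest import make_dataset

# exact-moment training set: class means (0, 1, 2), pooled ML variance 1
X_EXACT = np.array([-1.0, 1.0, 0.0, 2.0, 1.0, 3.0])[:, None]
Y_EXACT = np.array([1, 1, 2, 2, 3, 3])


class TestLinearDiscriminant:
    def test_classification_scores_match_closed_form(self):
        """Scores c_k0 + c_k x + ln(n_k/N) at x=1 for means (0,1,2), s^2=1."""
        m = LinearGaussianDiscriminant().fit(X_EXACT, Y_EXACT)
        assert m.pooled_var_ == pytest.approx(1.0)
        scores = m.decision_scores([[1.0]])[0]
        third = np.log(1 / 3)
        assert scores == pytest.approx([third, 0.5 + third, third])
        assert m.predict([[1.0]])[0] == 2

    def test_equal_priors_give_nearest_mean_rule(self):
        m = LinearGaussianDiscriminant().fit(X_EXACT, Y_EXACT)
        grid = np.linspace(-2, 4, 101)[:, None]
        nearest = 1 + np.argmin(np.abs(grid - np.array([0.0, 1.0, 2.0])), axis=1)
        assert np.array_equal(m.predict(grid), nearest)

    def test_log_prior_gap_shifts_boundary_toward_small_groups(self):
        """With counts (100, 25, 25) the 1|2 boundary moves up by ln4/d."""
        d = 0.8
        m = LinearGaussianDiscriminant()
        m.classes_ = np.array([1, 2, 3])
        m.means_ = np.array([0.0, d, 2 * d])
        m.pooled_var_ = 1.0
        m.priors_ = np.array([100, 25, 25]) / 150
        m.coef_ = m.means_
        m.intercept_ = -m.means_**2 / 2
        boundary = d / 2 + np.log(4) / d
        eps = 1e-6
        below = m.decision_scores([[boundary - eps]])[0]
        above = m.decision_scores([[boundary + eps]])[0]
        assert below[0] > below[1] and above[1] > above[0]
        # equal priors would cross at d/2 instead
        mid = m.decision_scores([[d / 2 + eps]])[0]
        assert mid[0] > mid[1]

    def test_single_case_class_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            LinearGaussianDiscriminant().fit([[0.0], [1.0], [1.1]], [1, 2, 2])


class TestQuadraticDiscriminant:
    def test_matches_lda_under_equal_group_variances(self):
        lda = LinearGaussianDiscriminant().fit(X_EXACT, Y_EXACT)
        qda = QuadraticGaussianDiscriminant().fit(X_EXACT, Y_EXACT)
        grid = np.linspace(-3, 5, 201)[:, None]
        assert np.array_equal(lda.predict(grid), qda.predict(grid))

    def test_uses_per_group_variance(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.3, 200), rng.normal(0, 3.0, 200),
                            rng.normal(8, 1.0, 200)])
        y = np.repeat([1, 2, 3], 200)
        qda = QuadraticGaussianDiscriminant().fit(x[:, None], y)
        # a far outlier from the tight class is captured by the wide class
        assert qda.predict([[-4.0]])[0] == 2


class TestMultinomialLogit:
    def test_separable_groups_reach_zero_training_error(self):
        ds = make_dataset(n_total=201, ratio=(1, 1, 1), d=10.0, seed=1)
        m = MultinomialLogit().fit(ds.x[:, None], ds.true_label)
        assert np.mean(m.predict(ds.x[:, None]) != ds.true_label) == 0.0

    def test_rates_track_linear_discriminant(self):
        """Across 100 simulated datasets LR and LDA error rates nearly agree."""
        diffs = []
        for seed in range(100):
            ds = make_dataset(d=0.8, seed=seed)
            X = ds.x[:, None]
            lr = MultinomialLogit().fit(X, ds.observed_label)
            lda = LinearGaussianDiscriminant().fit(X, ds.observed_label)
            diffs.append(np.mean(lr.predict(X) != ds.true_label)
                         - np.mean(lda.predict(X) != ds.true_label))
        assert np.mean(np.abs(diffs)) < 0.02


class TestNodeDeviance:
    @pytest.mark.parametrize("counts,expected", [
        ((50, 0, 0), 0.0),
        ((50, 50, 0), 138.62943611198906),
        ((30, 30, 30), 197.75021196025975),
    ])
    def test_direct_formula_values(self, counts, expected):
        assert node_deviance(counts) == pytest.approx(expected, abs=1e-9)

    def test_matches_multinomial_loglikelihood_oracle(self):
        """D_m = -2 log Lhat of the node's counts, via the multinomial pmf."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            counts = rng.integers(0, 200, size=3)
            if counts.sum() == 0:
                continue
            n = counts.sum()
            p = counts / n
            logcoef = gammaln(n + 1) - gammaln(counts + 1).sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                logpmf = logcoef + np.nansum(
                    np.where(counts > 0, counts * np.log(p), 0.0))
            oracle = -2.0 * (logpmf - logcoef)
            assert node_deviance(counts) == pytest.approx(oracle, abs=1e-9)

    def test_rejects_empty_or_negative(self):
        with pytest.raises(ValueError):
            node_deviance((0, 0, 0))
        with pytest.raises(ValueError):
            node_deviance((-1, 2, 3))


class TestDevianceTree:
    def test_pure_node_is_not_split(self):
        x = np.linspace(0, 1, 50)[:, None]
        tree = DevianceTreeClassifier().fit(
            np.vstack([x, x + 10]), np.repeat([1, 2], 50))
        # one split separates the pure halves; children stay leaves
        assert tree.n_leaves_ == 2
        assert tree.total_deviance() == pytest.approx(0.0)

    def test_size_guards_respected(self, noisy_dataset):
        tree = DevianceTreeClassifier(min_split=20, min_leaf=7).fit(
            noisy_dataset.x[:, None], noisy_dataset.observed_label)
        def leaf_sizes(node):
            if node.threshold is None:
                return [int(node.counts.sum())]
            return leaf_sizes(node.left) + leaf_sizes(node.right)
        assert min(leaf_sizes(tree.tree_)) >= 7

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_entropy_tree_oracle(self, seed):
        """Greedy deviance splitting == sklearn's entropy tree (same guards)."""
        ds = make_dataset(pi=0.2, seed=seed, d=0.5)
        X, y = ds.x[:, None], ds.observed_label
        mine = DevianceTreeClassifier(min_split=20, min_leaf=7).fit(X, y)
        ref = DecisionTreeClassifier(criterion="entropy", min_samples_split=20,
                                     min_samples_leaf=7, random_state=0).fit(X, y)
        assert np.array_equal(mine.predict(X), ref.predict(X))


class TestNearestNeighborForest:
    def test_single_tree_matches_grown_bootstrap_tree(self):
        """The nearest-neighbor shortcut equals a fully grown deviance tree
        on the same bootstrap sample (the sklearn tree is the oracle)."""
        ds = make_dataset(pi=0.2, seed=3)
        X, y = ds.x[:, None], ds.observed_label
        for seed in range(10):
            f = NearestNeighborForestClassifier(n_trees=1, random_state=seed)
            f.fit(X, y)
            ins = f._inbag[0]
            ref = DecisionTreeClassifier(criterion="entropy", random_state=0)
            ref.fit(f._xs[ins][:, None], f._ys[ins])
            grid = np.linspace(ds.x.min(), ds.x.max(), 500)[:, None]
            assert np.array_equal(f.predict(grid), ref.predict(grid))

    def test_resubstitution_error_near_zero_without_noise(self):
        ds = make_dataset(d=0.2, pi=0.0, seed=4)
        f = NearestNeighborForestClassifier(n_trees=200, random_state=0)
        f.fit(ds.x[:, None], ds.observed_label)
        err = np.mean(f.predict(ds.x[:, None]) != ds.true_label)
        assert err <= 0.01

    def test_vote_counts_sum_to_tree_count(self, noisy_dataset):
        f = NearestNeighborForestClassifier(n_trees=57, random_state=1)
        f.fit(noisy_dataset.x[:, None], noisy_dataset.observed_label)
        votes = f.vote_counts(noisy_dataset.x[:, None])
        assert np.all(votes.sum(axis=1) == 57)

    def test_rejects_empty_ensemble(self):
        with pytest.raises(ValueError):
            NearestNeighborForestClassifier(n_trees=0).fit([[0.0], [1.0]], [1, 2])


class TestPenalizedSplineGAM:
    def test_huge_penalty_recovers_linear_logit_fit(self):
        """The difference-penalty nullspace is linear, so lam -> inf gives LR."""
        ds = make_dataset(d=0.8, pi=0.1, seed=5)
        X, y = ds.x[:, None], ds.observed_label
        gam = PenalizedSplineGAM(lam=1e7, max_iter=500).fit(X, y)
        lr = MultinomialLogit().fit(X, y)
        assert np.mean(gam.predict(X) == lr.predict(X)) >= 0.98

    def test_predictions_monotone_for_separated_groups(self):
        ds = make_dataset(d=3.0, seed=6)
        gam = PenalizedSplineGAM().fit(ds.x[:, None], ds.observed_label)
        order = np.argsort(ds.x)
        pred = gam.predict(ds.x[order][:, None])
        assert np.all(np.diff(pred) >= 0)

    def test_default_smoothing_weight(self):
        from misclassim.pipeline import DEFAULT_SETTINGS
        assert PenalizedSplineGAM().lam == 1.4
        assert DEFAULT_SETTINGS["gam_lambda"] == 1.4


class TestMixtureDiscriminant:
    def test_em_loglikelihood_never_decreases(self):
        for seed in range(5):
            ds = make_dataset(pi=0.2, seed=seed)
            m = MixtureDiscriminantClassifier(n_subclasses=3, random_state=seed)
            m.fit(ds.x[:, None], ds.observed_label)
            assert np.all(np.diff(m.loglik_path_) >= -1e-8)

    @pytest.mark.parametrize("seed", range(50))
    def test_one_subclass_common_variance_degenerates_to_lda(self, seed):
        ds = make_dataset(d=0.5, pi=0.1, seed=seed)
        X, y = ds.x[:, None], ds.observed_label
        mix = MixtureDiscriminantClassifier(n_subclasses=1, covariance="common",
                                            random_state=0).fit(X, y)
        lda = LinearGaussianDiscriminant().fit(X, y)
        assert np.array_equal(mix.predict(X), lda.predict(X))

    def test_recovers_subgroup_means(self):
        """A two-subgroup class at means -2/+2 is recovered within 0.1."""
        rng = np.random.default_rng(8)
        x1 = np.concatenate([rng.normal(-2, 1, 1000), rng.normal(2, 1, 1000)])
        x2 = rng.normal(10, 1, 2000)
        x = np.concatenate([x1, x2])
        y = np.repeat([1, 2], 2000)
        m = MixtureDiscriminantClassifier(n_subclasses=2, covariance="common",
                                          random_state=1).fit(x[:, None], y)
        assert np.allclose(np.sort(m.subclass_means_[0]), [-2.0, 2.0], atol=0.1)
        assert m.subclass_weights_[0] == pytest.approx([0.5, 0.5], abs=0.05)

    def test_too_few_cases_per_subclass_rejected(self):
        with pytest.raises(DegenerateFitError):
            MixtureDiscriminantClassifier(n_subclasses=5).fit(
                [[0.0], [0.1], [5.0], [5.1], [5.2]], [1, 1, 2, 2, 2])


class TestLeastSquaresNet:
    def test_penalized_loss_decreases_over_accepted_steps(self, noisy_dataset):
        m = LeastSquaresNetClassifier(random_state=0)
        m.fit(noisy_dataset.x[:, None], noisy_dataset.observed_label)
        assert np.all(np.diff(m.loss_path_) <= 1e-8)

    def test_huge_decay_collapses_to_majority_class(self):
        ds = make_dataset(ratio=(25, 100, 25), n_total=150, d=0.8, seed=9)
        m = LeastSquaresNetClassifier(decay=1e5, random_state=0)
        m.fit(ds.x[:, None], ds.observed_label)
        pred = m.predict(ds.x[:, None])
        assert np.all(pred == 2)

    def test_separable_groups_reach_zero_training_error(self):
        ds = make_dataset(n_total=150, d=10.0, seed=10)
        m = LeastSquaresNetClassifier(random_state=1)
        m.fit(ds.x[:, None], ds.observed_label)
        assert np.mean(m.predict(ds.x[:, None]) != ds.true_label) == 0.0


class TestUniformContract:
    @pytest.mark.parametrize("name", METHOD_NAMES)
    def test_fit_predict_total_on_shared_dataset(self, name, noisy_dataset):
        model = make_classifier(name, {"rf_trees": 50}, random_state=0)
        model.fit(noisy_dataset.x[:, None], noisy_dataset.observed_label)
        pred = model.predict(noisy_dataset.x[:, None])
        assert len(pred) == len(noisy_dataset)
        assert set(np.unique(pred)) <= {1, 2, 3}

    @pytest.mark.parametrize("name", [m for m in METHOD_NAMES if m != "RF"])
    def test_wider_separation_lowers_training_error(self, name):
        """d = 1.6 beats d = 0.2 on the same seeds for every method but RF."""
        errs = {}
        for d in (0.2, 1.6):
            errs[d] = []
            for seed in (0, 1, 2):
                ds = make_dataset(d=d, seed=seed)
                model = make_classifier(name, random_state=seed)
                model.fit(ds.x[:, None], ds.observed_label)
                errs[d].append(np.mean(model.predict(ds.x[:, None])
                                       != ds.true_label))
        assert np.mean(errs[1.6]) < np.mean(errs[0.2])
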