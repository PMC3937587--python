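"""Eight supervised classifiers for three ordered groups on one predictor.

Every estimator follows the scikit-learn contract (``fit(X, y)`` /
``predict(X)``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore) so the methods are interchangeable in the Monte Carlo
runner and compose with sklearn tooling.  ``X`` is an ``(n, 1)`` array of
predictor scores and ``y`` holds integer group labels.

Score ties are broken deterministically toward the lower-ordered group
(``argmax`` returns the first maximum and classes are kept sorted).

The discriminant scorers (linear and quadratic), the deviance-splitting
classification tree, the nearest-neighbor-equivalent bootstrap forest, the
Gaussian-mixture discriminant (EM) and the least-squares neural net are
implemented here from their defining formulas; multinomial logistic
regression is delegated to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DegenerateFitError",
    "LinearGaussianDiscriminant",
    "QuadraticGaussianDiscriminant",
    "MultinomialLogit",
    "DevianceTreeClassifier",
    "NearestNeighborForestClassifier",
    "PenalizedSplineGAM",
    "MixtureDiscriminantClassifier",
    "LeastSquaresNetClassifier",
    "node_deviance",
    "make_classifier",
    "METHOD_NAMES",
    "fit_lda",
    "fit_qda",
    "fit_lr",
    "fit_cart",
    "fit_rf",
    "fit_gam",
    "fit_mixda",
    "fit_nnet",
]


class DegenerateFitError(ValueError):
    """Raised when a training sample cannot support the requested model."""


def _check_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] != 1:
        raise ValueError("expected a single-column predictor matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("predictor contains non-finite values")
    return X


def _check_X_y(X, y):
    X = _check_X(X)
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateFitError("need at least two observed classes")
    return X, y, classes


class _ScoreArgmaxMixin:
    """Predict by argmax of per-class scores; first (lowest) class wins ties."""

    def predict(self, X):
        check_is_fitted(self, "classes_")
        scores = self.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]


class LinearGaussianDiscriminant(_ScoreArgmaxMixin, ClassifierMixin, BaseEstimator):
    """Linear discriminant scores for one predictor.

    Per-class classification score ``C_k(x) = c_k0 + c_k * x + ln(n_k/N)`` with
    ``c_k = mu_k / s^2`` and ``c_k0 = -mu_k^2 / (2 s^2)``, where ``s^2`` is the
    pooled (maximum-likelihood) within-group variance.  The log-prior term
    shifts boundaries toward the smaller groups.
    """

    def fit(self, X, y):
        X, y, classes = _check_X_y(X, y)
        x = X[:, 0]
        counts = np.array([(y == c).sum() for c in classes])
        if np.any(counts < 2):
            raise DegenerateFitError("every class needs at least two cases")
        means = np.array([x[y == c].mean() for c in classes])
        ss = sum(((x[y == c] - m) ** 2).sum() for c, m in zip(classes, means))
        s2 = ss / len(x)
        if s2 <= 0:
            raise DegenerateFitError("zero pooled within-group variance")
        self.classes_ = classes
        self.means_ = means
        self.pooled_var_ = s2
        self.priors_ = counts / counts.sum()
        self.coef_ = means / s2                  # c_k
        self.intercept_ = -means**2 / (2 * s2)   # c_k0
        return self

    def decision_scores(self, X):
        x = _check_X(X)[:, 0]
        return (self.intercept_ + np.log(self.priors_)
                + x[:, None] * self.coef_)


class QuadraticGaussianDiscriminant(_ScoreArgmaxMixin, ClassifierMixin, BaseEstimator):
    """Gaussian discriminant with a separate variance per group."""

    def fit(self, X, y):
        X, y, classes = _check_X_y(X, y)
        x = X[:, 0]
        means, variances, counts = [], [], []
        for c in classes:
            xc = x[y == c]
            if len(xc) < 2:
                raise DegenerateFitError("every class needs at least two cases")
            v = xc.var()
            if v <= 0:
                raise DegenerateFitError("zero within-group variance")
            means.append(xc.mean())
            variances.append(v)
            counts.append(len(xc))
        counts = np.array(counts, dtype=float)
        self.classes_ = classes
        self.means_ = np.array(means)
        self.vars_ = np.array(variances)
        self.priors_ = counts / counts.sum()
        return self

    def decision_scores(self, X):
        x = _check_X(X)[:, 0]
        return (np.log(self.priors_) - 0.5 * np.log(self.vars_)
                - (x[:, None] - self.means_) ** 2 / (2 * self.vars_))


class MultinomialLogit(ClassifierMixin, BaseEstimator):
    """Three-class maximum-likelihood logistic regression (softmax link).

    Thin wrapper around scikit-learn's unpenalized ``LogisticRegression``; the
    two-group log-odds model generalizes to the multinomial likelihood.
    """

    def __init__(self, max_iter: int = 1000):
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y, classes = _check_X_y(X, y)
        self._lr = LogisticRegression(C=np.inf, solver="lbfgs",
                                      max_iter=self.max_iter)
        self._lr.fit(X, y)
        self.classes_ = self._lr.classes_
        self.coef_ = self._lr.coef_
        self.intercept_ = self._lr.intercept_
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self._lr.predict(_check_X(X))

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        return self._lr.predict_proba(_check_X(X))


# ---------------------------------------------------------------------------
# deviance-splitting classification tree
# ---------------------------------------------------------------------------

def node_deviance(counts) -> float:
    """Node deviance ``D_m = -2 * sum_k n_mk * ln(p_mk)`` with ``0*ln 0 = 0``.

    Equals minus twice the maximized multinomial log-likelihood of the node's
    label counts; zero for a pure node.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    n = counts.sum()
    p = counts / n
    nz = counts > 0
    return float(-2.0 * np.sum(counts[nz] * np.log(p[nz])))


@dataclass
class _TreeNode:
    counts: np.ndarray
    deviance: float
    label: int                  # plurality label (lowest class on ties)
    threshold: float | None = None
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None


def _children_deviance(left_counts, right_counts):
    """Summed deviance of a candidate split, vectorized over thresholds.

    ``left_counts``/``right_counts`` have shape (n_thresholds, K).
    """
    out = np.zeros(left_counts.shape[0])
    for counts in (left_counts, right_counts):
        n = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = counts * np.log(counts / n)
        out -= 2.0 * np.nansum(np.where(counts > 0, term, 0.0), axis=1)
    return out


class DevianceTreeClassifier(ClassifierMixin, BaseEstimator):
    """Greedy binary classification tree minimizing summed node deviance.

    Splits choose the threshold minimizing the deviance of the two children;
    growth stops when no split reduces deviance or when the size guards bind
    (``min_split`` cases to attempt a split, ``min_leaf`` per child).  Among
    equal-deviance splits the lowest threshold wins.  Terminal nodes predict
    their plurality group.
    """

    def __init__(self, min_split: int = 20, min_leaf: int = 7):
        self.min_split = min_split
        self.min_leaf = min_leaf

    def fit(self, X, y):
        X, y, classes = _check_X_y(X, y)
        self.classes_ = classes
        x = X[:, 0]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        # one-hot rows in sorted order, cumulated for O(1) range counts
        onehot = (y[order][:, None] == classes[None, :]).astype(np.int64)
        cum = np.vstack([np.zeros(len(classes), dtype=np.int64), np.cumsum(onehot, axis=0)])
        self.tree_ = self._grow(xs, cum, 0, len(xs))
        self.n_leaves_ = self._count_leaves(self.tree_)
        return self

    def _grow(self, xs, cum, lo, hi) -> _TreeNode:
        counts = cum[hi] - cum[lo]
        dev = node_deviance(counts)
        node = _TreeNode(counts, dev, int(self.classes_[np.argmax(counts)]))
        n = hi - lo
        if n < self.min_split or dev <= 0:
            return node
        # candidate split positions: between distinct adjacent x, honoring min_leaf
        pos = np.arange(lo + self.min_leaf, hi - self.min_leaf + 1)
        if len(pos) == 0:
            return node
        pos = pos[xs[pos - 1] < xs[pos]]  # cannot split between equal x
        if len(pos) == 0:
            return node
        child_dev = _children_deviance(cum[pos] - cum[lo], cum[hi] - cum[pos])
        best = np.argmin(child_dev)
        if child_dev[best] >= dev - 1e-9:  # no deviance decrease
            return node
        split = pos[best]
        node.threshold = 0.5 * (xs[split - 1] + xs[split])
        node.left = self._grow(xs, cum, lo, split)
        node.right = self._grow(xs, cum, split, hi)
        return node

    def _count_leaves(self, node) -> int:
        if node.threshold is None:
            return 1
        return self._count_leaves(node.left) + self._count_leaves(node.right)

    def total_deviance(self) -> float:
        """Summed deviance over terminal nodes of the fitted tree."""
        check_is_fitted(self, "tree_")
        def rec(node):
            if node.threshold is None:
                return node.deviance
            return rec(node.left) + rec(node.right)
        return rec(self.tree_)

    def predict(self, X):
        check_is_fitted(self, "tree_")
        x = _check_X(X)[:, 0]
        out = np.empty(len(x), dtype=self.classes_.dtype)
        for i, xi in enumerate(x):
            node = self.tree_
            while node.threshold is not None:
                node = node.left if xi <= node.threshold else node.right
            out[i] = node.label
        return out


# ---------------------------------------------------------------------------
# bootstrap forest
# ---------------------------------------------------------------------------

class NearestNeighborForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest of fully grown deviance trees on case bootstrap samples.

    With a single continuous predictor the predictor-subsampling step is
    vacuous, and a fully grown (pure-leaf) deviance tree is *exactly* the
    1-nearest-neighbor rule with midpoint thresholds over its bootstrap
    sample: purity forces a cut at the midpoint between every adjacent pair of
    opposite-label points, and further cuts never change the prediction.  The
    ensemble therefore computes each tree's prediction by nearest-bootstrap-
    neighbor lookup, which is exact and orders of magnitude faster than
    growing the trees explicitly.  Prediction is by majority vote across
    trees, ties toward the lower-ordered group.
    """

    def __init__(self, n_trees: int = 1000, random_state=None):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        X, y, classes = _check_X_y(X, y)
        x = X[:, 0]
        order = np.argsort(x, kind="stable")
        self.classes_ = classes
        self._xs = x[order]
        self._ys = y[order]
        self._rng = np.random.default_rng(self.random_state)
        n = len(x)
        # per-tree in-bag membership over sorted cases (bootstrap w/ replacement)
        self._inbag = [np.flatnonzero(np.bincount(
            self._rng.integers(0, n, n), minlength=n) > 0)
            for _ in range(self.n_trees)]
        return self

    def vote_counts(self, X):
        """Number of trees voting for each class, shape (n, n_classes)."""
        check_is_fitted(self, "classes_")
        q = _check_X(X)[:, 0]
        class_index = np.searchsorted(self.classes_, self._ys)
        votes = np.zeros((len(q), len(self.classes_)), dtype=np.int32)
        for ins in self._inbag:
            ux = self._xs[ins]
            pos = np.clip(np.searchsorted(ux, q), 1, len(ux) - 1)
            left_closer = (q - ux[pos - 1]) <= (ux[pos] - q)
            nn = np.where(q <= ux[0], 0,
                          np.where(q >= ux[-1], len(ux) - 1,
                                   np.where(left_closer, pos - 1, pos)))
            lab = class_index[ins[nn]]
            votes[np.arange(len(q)), lab] += 1
        return votes

    def predict(self, X):
        votes = self.vote_counts(X)
        return self.classes_[np.argmax(votes, axis=1)]


# ---------------------------------------------------------------------------
# penalized-spline additive model
# ---------------------------------------------------------------------------

class PenalizedSplineGAM(ClassifierMixin, BaseEstimator):
    """Multinomial additive model with a penalized cubic spline of x.

    The class logits are cubic B-spline expansions on equally spaced knots,
    fitted by penalized maximum likelihood with a second-order difference
    penalty of weight ``lam`` on each class's coefficients (default 1.4).  The
    penalty nullspace is exactly the constant-plus-linear family, so very
    large ``lam`` recovers the plain multinomial-logit fit.
    """

    def __init__(self, lam: float = 1.4, n_basis: int = 10, ridge: float = 1e-8,
                 max_iter: int = 1000):
        self.lam = lam
        self.n_basis = n_basis
        self.ridge = ridge
        self.max_iter = max_iter

    def _design(self, x):
        lo, hi = self.x_range_
        xc = np.clip(x, lo, hi)
        return self._spl.design_matrix(xc, self._knots, 3,
                                       extrapolate=False).toarray()

    def fit(self, X, y):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        X, y, classes = _check_X_y(X, y)
        x = X[:, 0]
        self.classes_ = classes
        self.x_range_ = (float(x.min()), float(x.max()))
        n_interior = max(self.n_basis - 4, 0)
        lo, hi = self.x_range_
        span = (hi - lo) or 1.0
        inner = np.linspace(lo, hi, n_interior + 2)
        self._knots = np.concatenate([[lo - span * 1e-6] * 3, inner,
                                      [hi + span * 1e-6] * 3])
        self._spl = BSpline
        B = self._design(x)
        nb, K = B.shape[1], len(classes)
        D2 = np.diff(np.eye(nb), n=2, axis=0)
        P = D2.T @ D2
        Y = (y[:, None] == classes[None, :]).astype(float)

        # whiten the penalty: optimize theta with beta = U diag(w) theta so the
        # quadratic term has O(1) curvature at any lam (keeps quasi-Newton
        # descent well conditioned even in the lam -> inf linear limit)
        s, U = np.linalg.eigh(P)
        s = np.maximum(s, 0.0)
        w = 1.0 / np.sqrt(1.0 + self.lam * s + self.ridge)
        A = U * w
        Bt = B @ A
        quad = (self.lam * s + self.ridge) * w**2  # diagonal penalty on theta

        def objective(theta_flat):
            theta = theta_flat.reshape(K, nb)
            eta = Bt @ theta.T
            eta -= eta.max(axis=1, keepdims=True)
            expeta = np.exp(eta)
            Z = expeta.sum(axis=1, keepdims=True)
            pi = expeta / Z
            nll = -np.sum(Y * (eta - np.log(Z)))
            pen = 0.5 * np.sum(quad * theta**2)
            grad = (pi - Y).T @ Bt + quad * theta
            return nll + pen, grad.ravel()

        res = optimize.minimize(objective, np.zeros(K * nb), jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": self.max_iter,
                                         "ftol": 1e-12, "gtol": 1e-8})
        self.coef_ = (A @ res.x.reshape(K, nb).T).T
        self.n_iter_ = res.nit
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        B = self._design(_check_X(X)[:, 0])
        eta = B @ self.coef_.T
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# mixture discriminant analysis
# ---------------------------------------------------------------------------

class MixtureDiscriminantClassifier(_ScoreArgmaxMixin, ClassifierMixin, BaseEstimator):
    """Per-class Gaussian mixtures fitted by EM; classify by posterior density.

    Each observed class is modeled as a mixture of ``n_subclasses`` normal
    subgroups.  ``covariance="common"`` shares one variance across all
    subgroups of all classes (with one subclass per class this degenerates to
    the linear discriminant); ``covariance="per_group"`` gives each class its
    own shared subgroup variance.  EM runs until the total log-likelihood
    changes by less than ``tol`` or ``max_iter`` is hit (``converged_`` flags
    which); the best iterate is kept either way.
    """

    def __init__(self, n_subclasses: int = 3, covariance: str = "common",
                 max_iter: int = 500, tol: float = 1e-6, random_state=None):
        self.n_subclasses = n_subclasses
        self.covariance = covariance
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_subclasses < 1:
            raise ValueError("n_subclasses must be >= 1")
        if self.covariance not in ("common", "per_group"):
            raise ValueError("covariance must be 'common' or 'per_group'")
        X, y, classes = _check_X_y(X, y)
        x = X[:, 0]
        rng = np.random.default_rng(self.random_state)
        R = self.n_subclasses
        xs_by_class = [x[y == c] for c in classes]
        if any(len(xc) < R for xc in xs_by_class):
            raise DegenerateFitError("each class needs at least n_subclasses cases")

        var_floor = max(1e-8 * x.var(), 1e-12)
        # k-means-style init: R distinct points per class as subgroup centers
        means = [np.sort(rng.choice(xc, size=R, replace=False)) for xc in xs_by_class]
        weights = [np.full(R, 1.0 / R) for _ in classes]
        if self.covariance == "common":
            variances = [np.full(R, max(x.var(), var_floor))] * len(classes)
        else:
            variances = [np.full(R, max(xc.var(), var_floor)) for xc in xs_by_class]

        loglik_path = []
        prev = -np.inf
        self.converged_ = False
        for _ in range(self.max_iter):
            total_ll = 0.0
            resps, stats = [], []
            for k, xc in enumerate(xs_by_class):
                dens = weights[k] * norm.pdf(xc[:, None], means[k],
                                             np.sqrt(variances[k]))
                tot = dens.sum(axis=1)
                tot = np.maximum(tot, 1e-300)
                total_ll += float(np.log(tot).sum())
                resps.append(dens / tot[:, None])
            loglik_path.append(total_ll)
            if total_ll - prev < self.tol and np.isfinite(prev):
                self.converged_ = True
                break
            prev = total_ll
            # M-step
            new_means, new_weights, sq = [], [], []
            for k, xc in enumerate(xs_by_class):
                r = resps[k]
                nk = r.sum(axis=0)
                nk = np.maximum(nk, 1e-12)
                mu = (r * xc[:, None]).sum(axis=0) / nk
                new_means.append(mu)
                new_weights.append(nk / len(xc))
                sq.append(float((r * (xc[:, None] - mu) ** 2).sum()))
            means, weights = new_means, new_weights
            if self.covariance == "common":
                v = max(sum(sq) / len(x), var_floor)
                variances = [np.full(R, v)] * len(classes)
            else:
                variances = [np.full(R, max(s / len(xc), var_floor))
                             for s, xc in zip(sq, xs_by_class)]

        self.classes_ = classes
        self.subclass_means_ = [np.asarray(m) for m in means]
        self.subclass_weights_ = [np.asarray(w) for w in weights]
        self.subclass_vars_ = [np.asarray(v) for v in variances]
        self.priors_ = np.array([len(xc) for xc in xs_by_class], dtype=float)
        self.priors_ /= self.priors_.sum()
        self.loglik_path_ = np.array(loglik_path)
        return self

    def decision_scores(self, X):
        x = _check_X(X)[:, 0]
        scores = np.empty((len(x), len(self.classes_)))
        for k in range(len(self.classes_)):
            dens = (self.subclass_weights_[k]
                    * norm.pdf(x[:, None], self.subclass_means_[k],
                               np.sqrt(self.subclass_vars_[k]))).sum(axis=1)
            scores[:, k] = np.log(self.priors_[k]) + np.log(np.maximum(dens, 1e-300))
        return scores


# ---------------------------------------------------------------------------
# least-squares neural network
# ---------------------------------------------------------------------------

class LeastSquaresNetClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer feed-forward network minimizing squared error.

    Logistic hidden and output units; the training criterion is the summed
    squared difference between the one-hot group indicators and the network
    outputs, plus a weight-decay penalty ``decay * sum(w^2)`` shrinking large
    weights.  Gradients are back-propagated and the penalized loss is driven
    down by quasi-Newton descent from a small random start; a non-finite fit
    restarts from a fresh draw (bounded restarts).
    """

    def __init__(self, hidden: int = 5, decay: float = 0.1, max_iter: int = 500,
                 n_restarts: int = 3, random_state=None):
        self.hidden = hidden
        self.decay = decay
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _sigmoid(z):
        return 0.5 * (np.tanh(0.5 * z) + 1.0)

    def _unpack(self, w, K):
        H = self.hidden
        w1 = w[:H]                       # input -> hidden weights
        b1 = w[H:2 * H]                  # hidden biases
        w2 = w[2 * H:2 * H + H * K].reshape(H, K)
        b2 = w[2 * H + H * K:]
        return w1, b1, w2, b2

    def _forward(self, x, w, K):
        w1, b1, w2, b2 = self._unpack(w, K)
        hidden = self._sigmoid(x[:, None] * w1 + b1)
        out = self._sigmoid(hidden @ w2 + b2)
        return hidden, out

    def fit(self, X, y):
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        X, y, classes = _check_X_y(X, y)
        x = X[:, 0]
        K = len(classes)
        Y = (y[:, None] == classes[None, :]).astype(float)
        rng = np.random.default_rng(self.random_state)
        n_weights = 2 * self.hidden + self.hidden * K + K

        def objective(w, path=None):
            w1, b1, w2, b2 = self._unpack(w, K)
            hidden = self._sigmoid(x[:, None] * w1 + b1)
            out = self._sigmoid(hidden @ w2 + b2)
            resid = out - Y
            loss = float(np.sum(resid**2)) + self.decay * float(np.sum(w**2))
            d_out = 2.0 * resid * out * (1.0 - out)
            g_w2 = hidden.T @ d_out
            g_b2 = d_out.sum(axis=0)
            d_hidden = (d_out @ w2.T) * hidden * (1.0 - hidden)
            g_w1 = d_hidden.T @ x
            g_b1 = d_hidden.sum(axis=0)
            grad = np.concatenate([g_w1, g_b1, g_w2.ravel(), g_b2])
            grad += 2.0 * self.decay * w
            return loss, grad

        best = None
        for _ in range(self.n_restarts):
            w0 = rng.uniform(-0.5, 0.5, size=n_weights)
            path = [objective(w0)[0]]
            res = optimize.minimize(
                objective, w0, jac=True, method="L-BFGS-B",
                callback=lambda wk: path.append(objective(wk)[0]),
                options={"maxiter": self.max_iter})
            if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
                best = (res.fun, res.x, path)
                break  # finite fit: keep it (restarts only on divergence)
        if best is None:
            raise DegenerateFitError("network training diverged on every restart")
        self.classes_ = classes
        self.loss_, self.weights_, self.loss_path_ = best
        self.loss_path_ = np.array(self.loss_path_)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        x = _check_X(X)[:, 0]
        _, out = self._forward(x, self.weights_, len(self.classes_))
        s = out.sum(axis=1, keepdims=True)
        return out / np.maximum(s, 1e-300)

    def predict(self, X):
        check_is_fitted(self, "weights_")
        x = _check_X(X)[:, 0]
        _, out = self._forward(x, self.weights_, len(self.classes_))
        return self.classes_[np.argmax(out, axis=1)]


# ---------------------------------------------------------------------------
# registry and thin functional wrappers
# ---------------------------------------------------------------------------

METHOD_NAMES = ("LDA", "QDA", "LR", "CART", "RF", "GAM", "MIXDA", "NNET")


def make_classifier(name: str, settings: dict | None = None, random_state=None):
    """Instantiate one of the eight study methods by its short name."""
    s = dict(settings or {})
    name = name.upper()
    if name == "LDA":
        return LinearGaussianDiscriminant()
    if name == "QDA":
        return QuadraticGaussianDiscriminant()
    if name == "LR":
        return MultinomialLogit()
    if name == "CART":
        return DevianceTreeClassifier(min_split=s.get("cart_min_split", 20),
                                      min_leaf=s.get("cart_min_leaf", 7))
    if name == "RF":
        return NearestNeighborForestClassifier(n_trees=s.get("rf_trees", 1000),
                                               random_state=random_state)
    if name == "GAM":
        return PenalizedSplineGAM(lam=s.get("gam_lambda", 1.4),
                                  n_basis=s.get("gam_basis", 10))
    if name == "MIXDA":
        return MixtureDiscriminantClassifier(
            n_subclasses=s.get("mixda_subclasses", 3),
            covariance=s.get("mixda_covariance", "common"),
            random_state=random_state)
    if name == "NNET":
        return LeastSquaresNetClassifier(hidden=s.get("nnet_hidden", 5),
                                         decay=s.get("nnet_decay", 0.1),
                                         max_iter=s.get("nnet_max_iter", 500),
                                         random_state=random_state)
    raise ValueError(f"unknown method {name!r}")


def _fit(est, ds):
    return est.fit(ds.x[:, None],
                   ds.true_label if ds.observed_label is None else ds.observed_label)


def fit_lda(ds):
    return _fit(LinearGaussianDiscriminant(), ds)


def fit_qda(ds):
    return _fit(QuadraticGaussianDiscriminant(), ds)


def fit_lr(ds):
    return _fit(MultinomialLogit(), ds)


def fit_cart(ds, min_split: int = 20, min_leaf: int = 7):
    return _fit(DevianceTreeClassifier(min_split=min_split, min_leaf=min_leaf), ds)


def fit_rf(ds, n_trees: int = 1000, rng=None):
    return _fit(NearestNeighborForestClassifier(n_trees=n_trees, random_state=rng), ds)


def fit_gam(ds, lam: float = 1.4):
    return _fit(PenalizedSplineGAM(lam=lam), ds)


def fit_mixda(ds, subclasses: int = 3, rng=None, covariance: str = "common"):
    return _fit(MixtureDiscriminantClassifier(n_subclasses=subclasses,
                                              covariance=covariance,
                                              random_state=rng), ds)


def fit_nnet(ds, hidden: int = 5, decay: float = 0.1, rng=None):
    return _fit(LeastSquaresNetClassifier(hidden=hidden, decay=decay,
                                          random_state=rng), ds)
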