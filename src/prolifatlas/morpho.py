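"""Landmark geometric morphometrics and multivariate shape–proliferation tests.

Estimator classes follow scikit-learn conventions (``fit``, fitted
attributes with a trailing underscore, ``get_params``/``set_params``) so
they compose with sklearn model selection; thin module-level functions wrap
them for scripting.

* :class:`GeneralizedProcrustes` — generalized Procrustes analysis (GPA):
  removes translation, size (unit centroid size) and rotation from landmark
  configurations by iterative alignment to an evolving mean shape.
* :class:`ShapePCA` — centred-SVD principal components with a deterministic
  sign convention.
* :class:`TwoBlockPLS` — singular-value decomposition of the cross-block
  covariance between a proliferation block and a shape block, with a
  permutation test on the leading cross-covariance (latent correlation
  reported as the effect size).
* :class:`SVMGenotypeTest` — linear SVM on standardized PC scores
  (hinge loss, C=1) with a label-permutation test on the training F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import f1_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------


class GeneralizedProcrustes(BaseEstimator):
    """Generalized Procrustes superimposition of landmark configurations.

    fit(X) with X of shape (n_specimens, n_landmarks, 3). Each
    configuration is centred, scaled to unit centroid size, and rotated to
    the current mean by orthogonal Procrustes; the mean is re-estimated
    until it moves less than ``tol``.

    Attributes
    ----------
    coords_ : (n, k, 3) aligned Procrustes shape coordinates
    mean_shape_ : (k, 3) consensus shape (unit centroid size)
    centroid_sizes_ : (n,) original centroid sizes
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[-1] != 3 or X.shape[0] < 2:
            raise ValueError("X must be (n_specimens>=2, n_landmarks, 3)")
        centred = X - X.mean(axis=1, keepdims=True)
        sizes = np.sqrt((centred**2).sum(axis=(1, 2)))
        if np.any(sizes <= 0):
            raise ValueError("degenerate (all-coincident) configuration")
        shapes = centred / sizes[:, None, None]
        mean = shapes[0].copy()
        for _ in range(self.max_iter):
            aligned = np.stack([_procrustes_rotate(s, mean) for s in shapes])
            new_mean = aligned.mean(0)
            new_mean = new_mean / np.sqrt((new_mean**2).sum())
            delta = np.sqrt(((new_mean - mean) ** 2).sum())
            mean = new_mean
            shapes = aligned
            if delta < self.tol:
                break
        self.coords_ = shapes
        self.mean_shape_ = mean
        self.centroid_sizes_ = sizes
        self.n_iter_ = _ + 1
        return self

    def transform(self, X=None):
        """Flattened Procrustes coordinates, (n, 3k)."""
        if X is not None and X is not getattr(self, "_fit_X", None):
            # align new configurations to the fitted mean
            X = np.asarray(X, dtype=float)
            centred = X - X.mean(axis=1, keepdims=True)
            sizes = np.sqrt((centred**2).sum(axis=(1, 2)))
            shapes = centred / sizes[:, None, None]
            aligned = np.stack([_procrustes_rotate(s, self.mean_shape_) for s in shapes])
            return aligned.reshape(len(aligned), -1)
        return self.coords_.reshape(len(self.coords_), -1)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()


def _procrustes_rotate(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate one centred unit-size configuration onto a target (no reflection)."""
    U, _, Vt = np.linalg.svd(shape.T @ target)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return shape @ (U @ D @ Vt)


def gpa(configurations) -> GeneralizedProcrustes:
    """Functional wrapper: run GPA on an (n, k, 3) landmark array."""
    return GeneralizedProcrustes().fit(np.asarray(configurations, dtype=float))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class ShapePCA(BaseEstimator):
    """Centred-SVD PCA with a reproducible sign convention.

    Each component is flipped so its largest-magnitude loading is positive,
    removing the sign ambiguity of the SVD. Works for both Procrustes shape
    coordinates and flattened proliferation matrices.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a 2D (specimens × features) matrix, n>=2")
        self.mean_ = X.mean(0)
        Xc = X - self.mean_
        if np.allclose(Xc, 0):
            raise ValueError("zero-variance matrix")
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        flip = np.sign(Vt[np.arange(len(Vt)), np.argmax(np.abs(Vt), axis=1)])
        flip[flip == 0] = 1.0
        Vt = Vt * flip[:, None]
        U = U * flip[None, :]
        k = self.n_components or len(S)
        var = S**2 / (len(X) - 1)
        self.components_ = Vt[:k]
        self.singular_values_ = S[:k]
        self.explained_variance_ = var[:k]
        self.explained_variance_ratio_ = var[:k] / var.sum()
        self.scores_ = (U * S)[:, :k]
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_


def pca(X, n_components: int | None = None) -> ShapePCA:
    return ShapePCA(n_components=n_components).fit(X)


# ---------------------------------------------------------------------------
# two-block PLS
# ---------------------------------------------------------------------------


@dataclass
class PLSResult:
    r: float
    z: float
    p_value: float
    n_perm: int
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    singular_values: np.ndarray
    perm_stats: np.ndarray


class TwoBlockPLS(BaseEstimator):
    """Two-block partial least squares between proliferation and shape blocks.

    fit(X, Y) column-centres both blocks and takes the SVD of the
    cross-block covariance X'Y/(n−1); the first left/right singular vectors
    give maximally covarying latent axes.  ``r_`` is the Pearson
    correlation of the first latent score pair.  The permutation test
    shuffles specimen rows of X (block 1, proliferation) with Y fixed,
    one-tailed; ``z_`` standardizes the observed statistic against the
    permuted distribution.

    ``perm_stat`` selects the permutation statistic: ``"covariance"`` (the
    first singular value, default) or ``"correlation"`` (the latent r).
    With many more features than specimens the latent correlation of *any*
    two blocks saturates near 1, so the singular value is the statistic
    that actually discriminates signal from chance in the voxel-block
    regime; r remains the reported effect size.
    """

    def __init__(self, n_perm: int = 999, seed: int | None = 0,
                 exhaustive: bool = False, perm_stat: str = "covariance"):
        self.n_perm = n_perm
        self.seed = seed
        self.exhaustive = exhaustive
        self.perm_stat = perm_stat

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("blocks must have the same specimen rows")
        n = X.shape[0]
        if n < 3:
            raise ValueError("need at least 3 specimens")
        if self.n_perm < 1 and not self.exhaustive:
            raise ValueError("n_perm must be >= 1")
        if self.perm_stat not in ("covariance", "correlation"):
            raise ValueError("perm_stat must be 'covariance' or 'correlation'")
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        u, v, s = _first_singular_pair(Xc, Yc)
        self.x_weights_ = u
        self.y_weights_ = v
        self.singular_values_ = s
        xs, ys = Xc @ u, Yc @ v
        self.x_scores_, self.y_scores_ = xs, ys
        self.r_ = _safe_corr(xs, ys)

        def stat(Xp):
            up, vp, sp = _first_singular_pair(Xp, Yc)
            if self.perm_stat == "covariance":
                return float(sp[0])
            return _safe_corr(Xp @ up, Yc @ vp)

        obs = stat(Xc)
        if self.exhaustive:
            from itertools import permutations

            perms = [np.asarray(p) for p in permutations(range(n))]
        else:
            rng = np.random.default_rng(self.seed)
            perms = [rng.permutation(n) for _ in range(self.n_perm)]
        perm_stats = np.array([stat(Xc[p]) for p in perms])
        self.perm_stats_ = perm_stats
        self.observed_stat_ = obs
        if self.exhaustive:
            # the identity permutation is part of the exhaustive set
            self.p_value_ = float((perm_stats >= obs - 1e-12).sum() / len(perm_stats))
        else:
            self.p_value_ = float(
                ((perm_stats >= obs - 1e-12).sum() + 1) / (len(perm_stats) + 1))
        sd = perm_stats.std(ddof=1)
        self.z_ = float((obs - perm_stats.mean()) / sd) if sd > 0 else np.inf
        self.n_perm_ = len(perm_stats)
        return self

    def result(self) -> PLSResult:
        return PLSResult(self.r_, self.z_, self.p_value_, self.n_perm_,
                         self.x_scores_, self.y_scores_, self.x_weights_,
                         self.y_weights_, self.singular_values_, self.perm_stats_)


def _first_singular_pair(Xc, Yc):
    C = Xc.T @ Yc / (len(Xc) - 1)
    U, S, Vt = np.linalg.svd(C, full_matrices=False)
    return U[:, 0], Vt[0], S


def _safe_corr(a, b) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def two_block_pls(block1, block2, n_perm: int = 999, seed: int | None = 0,
                  exhaustive: bool = False, perm_stat: str = "covariance") -> PLSResult:
    """Two-block PLS of proliferation (block 1) against shape (block 2)."""
    return TwoBlockPLS(n_perm=n_perm, seed=seed, exhaustive=exhaustive,
                       perm_stat=perm_stat).fit(block1, block2).result()


# ---------------------------------------------------------------------------
# stage residualization and splitting
# ---------------------------------------------------------------------------


def residualize_on_stage(block, somites) -> np.ndarray:
    """Residuals of each column after OLS regression on tail-somite count."""
    block = np.asarray(block, dtype=float)
    somites = np.asarray(somites, dtype=float)
    if block.shape[0] != len(somites):
        raise ValueError("row mismatch")
    if block.shape[0] < 3:
        raise ValueError("need at least 3 specimens")
    if np.ptp(somites) == 0:
        raise ValueError("somite counts are constant; stage is not identifiable")
    design = np.column_stack([np.ones_like(somites), somites])
    beta, *_ = np.linalg.lstsq(design, block, rcond=None)
    return block - design @ beta


def split_by_somites(cohort, boundary: int = 14):
    """Partition specimens into younger (≤ boundary somites) and older (>)."""
    younger = [s for s in cohort if s.somites <= boundary]
    older = [s for s in cohort if s.somites > boundary]
    if not younger or not older:
        warnings.warn("one side of the somite split is empty", RuntimeWarning)
    return younger, older


# ---------------------------------------------------------------------------
# SVM genotype separation
# ---------------------------------------------------------------------------


@dataclass
class SVMResult:
    coefficients: np.ndarray
    intercept: float
    accuracy: float
    f1: float
    p_value: float
    n_perm: int
    perm_f1: np.ndarray


class SVMGenotypeTest(BaseEstimator):
    """Linear SVM separating genotypes on standardized PC scores, with a
    label-permutation test on the training F1.

    Scores are z-scored, then a linear max-margin classifier (hinge loss,
    C=1, 10,000 iterations) is fit; accuracy and F1 are evaluated on the
    training task, matching the small-n design where no held-out data
    exists.  The permutation test refits under shuffled labels and reports
    p = (#{F1_perm ≥ F1_obs}+1)/(n_perm+1); with 1000 permutations the
    smallest attainable p is 1/1001.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 10000, n_perm: int = 1000,
                 seed: int | None = 0, positive_label="WT"):
        self.C = C
        self.max_iter = max_iter
        self.n_perm = n_perm
        self.seed = seed
        self.positive_label = positive_label

    def _fit_svm(self, Z, y):
        clf = LinearSVC(C=self.C, loss="hinge", max_iter=self.max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Z, y)
        return clf

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need two classes")
        if np.min(counts) < 2:
            raise ValueError("need at least 2 specimens per class")
        pos = self.positive_label if self.positive_label in classes else classes[0]
        y_bin = (y == pos).astype(int)
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        clf = self._fit_svm(Z, y_bin)
        pred = clf.predict(Z)
        self.estimator_ = clf
        self.coef_ = clf.coef_.ravel()
        self.intercept_ = float(clf.intercept_[0])
        self.accuracy_ = float((pred == y_bin).mean())
        self.f1_ = float(f1_score(y_bin, pred, pos_label=1))

        rng = np.random.default_rng(self.seed)
        perm_f1 = np.empty(self.n_perm)
        for i in range(self.n_perm):
            yp = rng.permutation(y_bin)
            clf_p = self._fit_svm(Z, yp)
            perm_f1[i] = f1_score(yp, clf_p.predict(Z), pos_label=1, zero_division=0)
        self.perm_f1_ = perm_f1
        self.p_value_ = float(((perm_f1 >= self.f1_ - 1e-12).sum() + 1) / (self.n_perm + 1))
        return self

    def result(self) -> SVMResult:
        return SVMResult(self.coef_, self.intercept_, self.accuracy_, self.f1_,
                         self.p_value_, self.n_perm, self.perm_f1_)


def svm_genotype(pc_scores, labels, C: float = 1.0, max_iter: int = 10000,
                 n_perm: int = 1000, seed: int | None = 0) -> SVMResult:
    """Separate wild type from carriers on the first PC scores (see
    :class:`SVMGenotypeTest`)."""
    return SVMGenotypeTest(C=C, max_iter=max_iter, n_perm=n_perm, seed=seed).fit(
        pc_scores, labels
    ).result()
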