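"""Sparse PLS discriminant analysis for two-group omics tables.

The classifier regresses the 0/1 group code on autoscaled protein
abundances with latent PLS components, imposing sparsity through a
soft-threshold on the cross-covariance vector: at each component the
surrogate direction keeps only variables whose |X'y| exceeds a fraction
``eta`` of the maximum, the active set accumulates those variables, and a
plain PLS regression is refit on the active set (surrogate-direction /
active-set-refit construction).  ``eta`` in [0, 1) controls sparsity
(0 = ordinary PLS1, near 1 = single best variable); ``n_components`` (K)
is the number of latent directions.

Class prediction thresholds the fitted linear score at 0.5 on the 0/1
code, so the per-variable regression coefficients beta both classify and
carry the sign information used downstream for direction-consistency
checks.  Both hyperparameters are chosen by stratified internal
cross-validation on misclassification error (:func:`tune_splsda`), 4-fold
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .exceptions import (
    ConfigError,
    DegenerateResponseError,
    FoldError,
    IntegrityError,
    RankError,
)
from .io import ProteinQuantTable, SampleDesign


def spls_direction(X: np.ndarray, y: np.ndarray, eta: float) -> np.ndarray:
    """Soft-thresholded direction vector for one sparse PLS component.

    With Z = X'y, coordinate j of the unnormalized direction is
    ``sign(Z_j) * (|Z_j| - eta * max_i |Z_i|)_+``; the result is scaled to
    unit length.  For any eta < 1 at least the argmax coordinate survives.
    ``X`` is expected centered (and typically scaled); ``y`` centered.
    """
    if not 0.0 <= eta < 1.0:
        raise ConfigError(f"eta must lie in [0, 1), got {eta}")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateResponseError("response is constant; no direction exists")
    Z = np.asarray(X, dtype=float).T @ y
    zmax = np.max(np.abs(Z))
    if zmax == 0:
        return np.zeros_like(Z)
    w = np.sign(Z) * np.clip(np.abs(Z) - eta * zmax, 0.0, None)
    norm = np.linalg.norm(w)
    return w / norm


def _pls1(X: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Plain univariate-response PLS regression with ``k`` components.

    Returns (beta, scores); beta is on the scale of the columns of ``X``
    (assumed centered), scores is the n x k_eff latent-score matrix.
    Deflation can exhaust the signal early, in which case fewer components
    are used.
    """
    n, p = X.shape
    Xd = X.copy()
    yd = y.astype(float).copy()
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    T = np.zeros((n, k))
    k_eff = 0
    for j in range(k):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn < 1e-12:
            break
        w /= wn
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            break
        pj = Xd.T @ t / tt
        qj = yd @ t / tt
        Xd -= np.outer(t, pj)
        yd -= qj * t
        W[:, j], P[:, j], q[j], T[:, j] = w, pj, qj, t
        k_eff += 1
    if k_eff == 0:
        return np.zeros(p), np.zeros((n, 0))
    W, P, q, T = W[:, :k_eff], P[:, :k_eff], q[:k_eff], T[:, :k_eff]
    beta = W @ np.linalg.solve(P.T @ W, q)
    return beta, T


class SPLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Sparse PLS-DA classifier for a two-group response.

    Parameters
    ----------
    eta : float
        Sparsity penalty in [0, 1).  Fraction of the maximum
        cross-covariance below which variable weights are zeroed.
    n_components : int
        Number of latent components K (must not exceed n_samples - 1 or
        n_features).
    scale : bool
        Autoscale columns of X to unit variance (n-1 denominator) before
        fitting.  The response is centered only.

    Attributes
    ----------
    coef_ : ndarray (n_features,)
        Regression coefficients beta on the original variable scale;
        exactly zero outside the active set.
    selected_ : ndarray of bool (n_features,)
        Active-set membership (beta != 0 or entering any direction).
    directions_ : ndarray (n_components_, n_features)
        Soft-thresholded surrogate directions, one per component.
    scores_ : ndarray (n_samples, n_components_)
        Latent scores of the training samples from the final active-set
        refit.
    x_mean_, x_scale_ : ndarray (n_features,)
        Centering/scaling applied to X.
    intercept_ : float
        Intercept of the linear score on the original scale.
    """

    def __init__(self, eta: float = 0.5, n_components: int = 1, scale: bool = True) -> None:
        self.eta = eta
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y) -> "SPLSDAClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise IntegrityError("X must be 2-D with one row per response entry")
        if not np.isfinite(X).all():
            raise IntegrityError("X contains missing or non-finite values")
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise DegenerateResponseError(
                f"response must contain both group codes 0 and 1, got {classes}"
            )
        n, p = X.shape
        k_max = min(n - 1, p)
        if not 1 <= self.n_components <= k_max:
            raise RankError(
                f"n_components={self.n_components} exceeds the data's limit "
                f"min(n_samples - 1, n_features) = {k_max}"
            )

        self.x_mean_ = X.mean(axis=0)
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0  # constant columns carry no signal; leave them unscaled
            self.x_scale_ = sd
        else:
            self.x_scale_ = np.ones(p)
        Xs = (X - self.x_mean_) / self.x_scale_
        self.y_mean_ = y.mean()
        yc = y - self.y_mean_

        active = np.zeros(p, dtype=bool)
        beta_s = np.zeros(p)
        directions = []
        scores = np.zeros((n, 0))
        for k in range(1, self.n_components + 1):
            r = yc - Xs @ beta_s
            if np.ptp(r) == 0:  # response fully explained; further components are noise
                break
            w = spls_direction(Xs, r, self.eta)
            directions.append(w)
            active |= w != 0
            active |= beta_s != 0
            if not active.any():
                break
            idx = np.flatnonzero(active)
            beta_a, scores = _pls1(Xs[:, idx], yc, min(k, idx.size))
            beta_s = np.zeros(p)
            beta_s[idx] = beta_a

        self.n_components_ = len(directions)
        self.directions_ = np.array(directions) if directions else np.zeros((0, p))
        self.coef_ = beta_s / self.x_scale_
        self.intercept_ = float(self.y_mean_ - self.x_mean_ @ self.coef_)
        self.selected_ = beta_s != 0
        self.scores_ = scores
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = p
        return self

    def decision_function(self, X) -> np.ndarray:
        """Fitted linear score: the predicted value of the 0/1 group code."""
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Predicted group code: linear score thresholded at 0.5."""
        return (self.decision_function(X) >= 0.5).astype(float)



@dataclass
class SplsdaConfig:
    """Hyperparameter grid and fold settings for internal tuning.

    Defaults follow the common practice for small two-group designs: eta on
    0.1..0.9 in steps of 0.1, K on 1..5, stratified 4-fold CV.
    """

    eta_grid: tuple = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
    k_grid: tuple = (1, 2, 3, 4, 5)
    n_folds: int = 4
    fold_seed: int = 0
    scale_x: bool = True

    def __post_init__(self) -> None:
        if any(not 0.0 <= e < 1.0 for e in self.eta_grid):
            raise ConfigError("every eta grid point must lie in [0, 1)")
        if any(k < 1 for k in self.k_grid):
            raise ConfigError("every K grid point must be >= 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")


class SPLSDACV(BaseEstimator, ClassifierMixin):
    """sPLS-DA with internal cross-validated selection of (eta, K).

    ``fit`` evaluates mean misclassification over stratified folds for every
    grid point, picks the minimizer -- ties broken toward larger eta then
    smaller K (sparser, simpler model) -- and refits on the full data.

    Attributes
    ----------
    eta_, k_ : chosen hyperparameters.
    cv_error_grid_ : DataFrame (index eta, columns K) of CV error rates.
    estimator_ : the final :class:`SPLSDAClassifier` fit on all samples.
    """

    def __init__(self, config: SplsdaConfig | None = None) -> None:
        self.config = config

    def fit(self, X, y) -> "SPLSDACV":
        cfg = self.config or SplsdaConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        counts = [int((y == c).sum()) for c in (0.0, 1.0)]
        if min(counts) < cfg.n_folds:
            raise FoldError(
                f"stratified {cfg.n_folds}-fold CV needs >= {cfg.n_folds} samples per class, "
                f"got sizes {counts}"
            )
        skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.fold_seed)
        folds = list(skf.split(X, y))

        grid = pd.DataFrame(np.nan, index=list(cfg.eta_grid), columns=list(cfg.k_grid))
        for eta in cfg.eta_grid:
            for k in cfg.k_grid:
                errs = []
                for train, test in folds:
                    k_cap = min(k, len(train) - 1, X.shape[1])
                    clf = SPLSDAClassifier(eta=eta, n_components=k_cap, scale=cfg.scale_x)
                    clf.fit(X[train], y[train])
                    errs.append(np.mean(clf.predict(X[test]) != y[test]))
                grid.loc[eta, k] = float(np.mean(errs))

        best = grid.to_numpy().min()
        # ties: larger eta first, then smaller K
        best_eta, best_k = None, None
        for eta in sorted(cfg.eta_grid, reverse=True):
            for k in sorted(cfg.k_grid):
                if grid.loc[eta, k] == best:
                    best_eta, best_k = float(eta), int(k)
                    break
            if best_eta is not None:
                break

        self.eta_, self.k_ = best_eta, best_k
        self.cv_error_grid_ = grid
        self.estimator_ = SPLSDAClassifier(
            eta=best_eta, n_components=min(best_k, n - 1, X.shape[1]), scale=cfg.scale_x
        ).fit(X, y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        return self.estimator_.predict(X)

    def decision_function(self, X) -> np.ndarray:
        return self.estimator_.decision_function(X)


def design_matrix(P: ProteinQuantTable, d: SampleDesign) -> tuple[pd.DataFrame, np.ndarray]:
    """Samples-by-proteins predictor matrix and 0/1 response from the tables.

    Proteins with any missing abundance among the design's samples are
    excluded (the model requires complete predictors); sample rows follow
    the design order.
    """
    missing = [s for s in d.samples if s not in P.abundances.columns]
    if missing:
        raise IntegrityError(f"design samples absent from protein table: {missing}")
    Xdf = P.abundances[d.samples].T
    complete = Xdf.notna().all(axis=0)
    Xdf = Xdf.loc[:, complete]
    if Xdf.shape[1] == 0:
        raise IntegrityError("no protein has complete abundances across the design samples")
    return Xdf, d.y()


def fit_splsda(
    P: ProteinQuantTable, d: SampleDesign, eta: float, K: int, scale_x: bool = True
) -> tuple[SPLSDAClassifier, pd.Index]:
    """Fit sPLS-DA on a rolled-up protein table at fixed (eta, K).

    Returns the fitted classifier and the index of proteins actually fitted
    (those with complete abundances), aligned with ``coef_``.
    """
    Xdf, y = design_matrix(P, d)
    clf = SPLSDAClassifier(eta=eta, n_components=K, scale=scale_x).fit(Xdf.to_numpy(), y)
    return clf, Xdf.columns


def tune_splsda(
    P: ProteinQuantTable, d: SampleDesign, cfg: SplsdaConfig | None = None
) -> tuple[float, int, pd.DataFrame]:
    """Select (eta, K) by stratified internal CV; returns the full error grid too."""
    Xdf, y = design_matrix(P, d)
    cv = SPLSDACV(cfg).fit(Xdf.to_numpy(), y)
    return cv.eta_, cv.k_, cv.cv_error_grid_


def scores_plot_data(
    fit: SPLSDAClassifier, P: ProteinQuantTable, d: SampleDesign
) -> pd.DataFrame:
    """Per-sample coordinates on latent components 1-2 with group names.

    With a single fitted component the second coordinate is zero-filled and
    the ``single_component`` column flags it.
    """
    scores = fit.scores_
    n = scores.shape[0]
    if n != len(d.samples):
        raise IntegrityError("fit and design disagree on sample count")
    c1 = scores[:, 0] if scores.shape[1] >= 1 else np.zeros(n)
    single = scores.shape[1] < 2
    c2 = np.zeros(n) if single else scores[:, 1]
    names = d.group_names
    return pd.DataFrame(
        {
            "sample": d.samples,
            "component_1": c1,
            "component_2": c2,
            "group": d.groups.to_numpy(),
            "group_name": [names[g] for g in d.groups],
            "single_component": single,
        }
    )
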