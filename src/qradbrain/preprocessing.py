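"""Tabular preprocessing: scaling, stratified split, imbalance resampling,
correlation pruning and the two-stage primary selection before the QUBO.

All fitting happens on training rows only (no information leakage); the
resampler is applied to the training split after the split, never to test
rows.  The primary selection is a sparsity-inducing linear max-margin model
(L1-penalized hinge loss, proximal subgradient descent) followed by a
mutual-information ranking that keeps the top-m candidates handed to the
QUBO selector.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

from .qubo import estimate_mi

__all__ = [
    "standardize",
    "stratified_split",
    "SmoteUnderSampler",
    "resample_balance",
    "spearman_prune",
    "SpearmanPruner",
    "linear_margin_select",
    "L1MarginSelector",
    "mi_rank",
    "MutualInfoRanker",
]


# ---------------------------------------------------------------------------
# scaling and splitting

def standardize(values: np.ndarray, fit_idx) -> tuple[np.ndarray, np.ndarray,
                                                      np.ndarray, np.ndarray]:
    """Column-wise z-scoring with parameters fitted on ``fit_idx`` rows.

    Columns constant on the fit rows are dropped (with a warning).  Returns
    ``(transformed, kept_column_indices, means, stds)``.
    """
    values = np.asarray(values, dtype=float)
    fit_idx = np.asarray(fit_idx)
    if fit_idx.size == 0:
        raise ValueError("fit index set is empty")
    scaler = StandardScaler()
    scaler.fit(values[fit_idx])
    keep = np.flatnonzero(scaler.var_ > 0)
    if keep.size < values.shape[1]:
        dropped = np.flatnonzero(scaler.var_ == 0)
        warnings.warn(f"dropping {dropped.size} zero-variance column(s): "
                      f"{dropped.tolist()}")
    out = (values[:, keep] - scaler.mean_[keep]) / scaler.scale_[keep]
    return out, keep, scaler.mean_[keep], scaler.scale_[keep]


def stratified_split(labels, fraction: float = 0.7, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test split.

    Per-class train counts are ``round(fraction * class size)`` (ties to
    even per IEEE rounding of the float product).  Returns sorted
    ``(train_idx, test_idx)``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        n_train = int(np.floor(fraction * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        train.append(rng.permutation(idx)[:n_train])
    train_idx = np.sort(np.concatenate(train))
    test_idx = np.setdiff1d(np.arange(labels.size), train_idx)
    return train_idx, test_idx


# ---------------------------------------------------------------------------
# resampling

class SmoteUnderSampler(BaseEstimator):
    """Combined SMOTE oversampling and random undersampling.

    Minority rows are synthesised by convex interpolation between a minority
    sample and one of its ``k_neighbors`` nearest minority neighbours
    (uniform t in [0, 1]); the majority class is then subsampled without
    replacement.  Meet-in-the-middle sizing: the minority grows to at most
    twice its size (capped by the ratio target), the majority shrinks to
    ``minority / target_ratio``.

    ``fit_resample(X, y)`` follows the imblearn convention and leaves any
    rows not passed in untouched by construction.
    """

    def __init__(self, k_neighbors: int = 5, target_ratio: float = 1.0,
                 random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.target_ratio = target_ratio
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must be in (0, 1]")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("exactly two classes are required")
        mi_cls = classes[np.argmin(counts)]
        ma_cls = classes[np.argmax(counts)]
        Xmin, Xmaj = X[y == mi_cls], X[y == ma_cls]
        n_min, n_maj = len(Xmin), len(Xmaj)
        if n_min <= self.k_neighbors:
            raise ValueError("minority count must exceed k_neighbors")

        n_min_target = min(2 * n_min,
                           int(np.ceil(self.target_ratio * n_maj)))
        n_min_target = max(n_min_target, n_min)
        n_maj_target = min(n_maj,
                           int(round(n_min_target / self.target_ratio)))

        rng = np.random.default_rng(self.random_state)
        n_new = n_min_target - n_min
        if n_new > 0:
            nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(Xmin)
            _, neigh = nn.kneighbors(Xmin)
            base = rng.integers(0, n_min, size=n_new)
            pick = rng.integers(1, self.k_neighbors + 1, size=n_new)
            partner = neigh[base, pick]
            t = rng.random(n_new)[:, None]
            synth = Xmin[base] + t * (Xmin[partner] - Xmin[base])
            Xmin = np.vstack([Xmin, synth])
        keep = rng.choice(n_maj, size=n_maj_target, replace=False)
        Xmaj = Xmaj[keep]
        Xr = np.vstack([Xmin, Xmaj])
        yr = np.concatenate([np.full(len(Xmin), mi_cls),
                             np.full(len(Xmaj), ma_cls)])
        return Xr, yr


def resample_balance(X, y, k_neighbors: int = 5, target_ratio: float = 1.0,
                     seed: int = 0):
    """Functional form of :class:`SmoteUnderSampler`."""
    return SmoteUnderSampler(k_neighbors=k_neighbors,
                             target_ratio=target_ratio,
                             random_state=seed).fit_resample(X, y)


# ---------------------------------------------------------------------------
# correlation pruning

def spearman_prune(X, threshold: float = 0.8, priority=None) -> np.ndarray:
    """Greedy removal of columns with |Spearman rho| above ``threshold``.

    Columns are scanned in decreasing ``priority`` (higher kept first;
    column order when no priority is given — the pipeline passes marginal
    MI with the label so the informative member of a redundant pair
    survives).  Ties in ranks use average ranks.  Returns the kept column
    indices in original order; no surviving pair exceeds the threshold.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 columns")
    rho = np.asarray(spearmanr(X).statistic)
    if rho.ndim == 0:  # scipy collapses the p == 2 case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    if priority is None:
        order = np.arange(p)
    else:
        priority = np.asarray(priority, dtype=float)
        order = np.argsort(-priority, kind="stable")
    kept: list[int] = []
    for j in order:
        if all(abs(rho[j, k]) <= threshold for k in kept):
            kept.append(int(j))
    return np.array(sorted(kept))


class SpearmanPruner(SelectorMixin, BaseEstimator):
    """Selector form of :func:`spearman_prune`; when fitted with ``y`` the
    priority is the marginal MI of each column with the label."""

    def __init__(self, threshold: float = 0.8, bins: int = 4):
        self.threshold = threshold
        self.bins = bins

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_features=2, reset=True)
        priority = None
        if y is not None:
            y = np.asarray(y).ravel()
            priority = [estimate_mi(X[:, j], y, bins=self.bins)
                        for j in range(X.shape[1])]
        kept = spearman_prune(X, threshold=self.threshold, priority=priority)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[kept] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


# ---------------------------------------------------------------------------
# linear max-margin selection

class L1MarginSelector(SelectorMixin, BaseEstimator):
    """Sparsity-inducing linear max-margin feature selector.

    Minimises ``mean(hinge(1 - y (Xw + b))) + penalty * ||w||_1`` by
    proximal subgradient descent (hinge subgradient step with learning rate
    ``lr0 / sqrt(t)``, then soft-thresholding of ``w``).  Columns with
    ``|w| > tol`` are selected.  Expects standardized inputs.
    """

    def __init__(self, penalty: float = 0.01, max_iter: int = 2000,
                 lr0: float = 0.5, tol: float = 1e-5):
        self.penalty = penalty
        self.max_iter = max_iter
        self.lr0 = lr0
        self.tol = tol

    def fit(self, X, y):
        X = validate_data(self, X, reset=True)
        y = np.asarray(y, dtype=float).ravel()
        if len(np.unique(y)) != 2:
            raise ValueError("both classes must be present")
        n, p = X.shape
        w = np.zeros(p)
        b = 0.0
        best = np.inf
        stall = 0
        converged = False
        for t in range(1, self.max_iter + 1):
            margin = y * (X @ w + b)
            viol = margin < 1.0
            gw = -(y[viol, None] * X[viol]).sum(axis=0) / n
            gb = -float(y[viol].sum()) / n
            lr = self.lr0 / np.sqrt(t)
            w -= lr * gw
            b -= lr * gb
            w = np.sign(w) * np.maximum(np.abs(w) - lr * self.penalty, 0.0)
            loss = float(np.maximum(1.0 - margin, 0.0).mean()
                         + self.penalty * np.abs(w).sum())
            # subgradient iterates oscillate; stop when the best objective
            # has not improved appreciably for a while
            if loss < best - 1e-6:
                best = loss
                stall = 0
            else:
                stall += 1
                if stall >= 100:
                    converged = True
                    break
        if not converged:
            warnings.warn("L1 margin selector did not fully converge; "
                          "using the current solution")
        self.coef_ = w
        self.intercept_ = b
        self.support_ = np.abs(w) > self.tol
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


def linear_margin_select(X, y, penalty_strength: float = 0.01) -> np.ndarray:
    """Column indices kept by the L1-hinge max-margin selector."""
    sel = L1MarginSelector(penalty=penalty_strength).fit(X, y)
    return np.flatnonzero(sel.support_)


# ---------------------------------------------------------------------------
# mutual-information ranking

def mi_rank(X, y, top_m: int = 17, bins: int = 4) -> np.ndarray:
    """Column indices of the ``top_m`` features by plug-in MI with the
    label (descending; ties broken by column order)."""
    X = np.asarray(X, dtype=float)
    if top_m > X.shape[1]:
        raise ValueError("top_m must not exceed the number of columns")
    y = np.asarray(y).ravel()
    scores = np.array([estimate_mi(X[:, j], y, bins=bins)
                       for j in range(X.shape[1])])
    order = np.argsort(-scores, kind="stable")
    return order[:top_m]


class MutualInfoRanker(SelectorMixin, BaseEstimator):
    """Selector keeping the ``top_m`` columns by marginal MI with the label."""

    def __init__(self, top_m: int = 17, bins: int = 4):
        self.top_m = top_m
        self.bins = bins

    def fit(self, X, y):
        X = validate_data(self, X, reset=True)
        kept = mi_rank(X, np.asarray(y).ravel(),
                       top_m=min(self.top_m, X.shape[1]), bins=self.bins)
        self.ranking_ = kept
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[kept] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
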