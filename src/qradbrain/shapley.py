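"""Sample-wise Shapley attribution of a classifier score.

Features are players in a cooperative game whose value for a coalition S is
the model score with the features in S taken from the explained sample and
the remaining features replaced by background rows (averaged over the
background — the interventional masking convention).  The exact Shapley
value weights every coalition by ``|S|! (M-1-|S|)! / M!``; Kernel SHAP
recovers the same attribution as the solution of a weighted least-squares
problem with the Shapley kernel

    w(s) = (M - 1) / (C(M, s) * s * (M - s)),   0 < s < M,

with the empty and full coalitions imposed exactly (their kernel weight is
infinite) through the constraint base + sum(phi) = f(x).  Attributions
target the real-valued score, not the thresholded label.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np
import pandas as pd

__all__ = [
    "ShapleyAttribution",
    "shapley_kernel_weight",
    "kernel_shap",
    "exact_shapley",
    "shap_summary",
    "KernelShapExplainer",
]

_EXACT_MAX_M = 15


@dataclass
class ShapleyAttribution:
    phi: np.ndarray
    base_value: float
    fx: float
    residual: float = 0.0

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)


def shapley_kernel_weight(M: int, s: int) -> float:
    """Shapley kernel weight for a coalition of size ``s`` out of ``M``."""
    if not 0 < s < M:
        raise ValueError("kernel weight defined for 0 < s < M; the boundary "
                         "coalitions are hard constraints")
    return (M - 1) / (comb(M, s) * s * (M - s))


def _coalition_values(model, x, background, Z):
    """Background-averaged masked scores for each coalition row of Z."""
    x = np.asarray(x, dtype=float).ravel()
    background = np.asarray(background, dtype=float)
    n_bg, M = background.shape
    n_co = len(Z)
    # (n_co * n_bg, M) masked inputs, single model call
    masked = np.where(Z[:, None, :].astype(bool), x, background[None, :, :])
    vals = np.asarray(model(masked.reshape(-1, M)), dtype=float)
    return vals.reshape(n_co, n_bg).mean(axis=1)


def exact_shapley(model, x, background) -> ShapleyAttribution:
    """Exact Shapley attribution by full coalition enumeration (M <= 15)."""
    x = np.asarray(x, dtype=float).ravel()
    M = x.size
    if M > _EXACT_MAX_M:
        raise ValueError(f"M={M} too large for enumeration (max {_EXACT_MAX_M})")
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background must be non-empty")

    ints = np.arange(2**M, dtype=np.int64)
    Z = ((ints[:, None] >> np.arange(M)) & 1).astype(np.int8)
    v = _coalition_values(model, x, background, Z)
    sizes = Z.sum(axis=1)
    # permutation weights by coalition size (coalition excludes the player)
    w_by_size = np.array(
        [factorial(s) * factorial(M - 1 - s) / factorial(M) for s in range(M)]
    )
    phi = np.zeros(M)
    for i in range(M):
        off = Z[:, i] == 0
        with_i = ints[off] | (1 << i)
        phi[i] = np.sum(w_by_size[sizes[off]] * (v[with_i] - v[off]))
    base, fx = float(v[0]), float(v[-1])
    return ShapleyAttribution(phi=phi, base_value=base, fx=fx,
                              residual=abs(base + phi.sum() - fx))


def kernel_shap(model, x, background, n_coalitions: int = 2048,
                seed: int = 0) -> ShapleyAttribution:
    """Kernel SHAP estimate of the Shapley attribution.

    All ``2**M - 2`` interior coalitions are enumerated when the budget
    allows (the estimate is then exact up to numerics); otherwise coalition
    sizes are sampled from the normalised kernel distribution and members
    uniformly within a size.  The efficiency constraint
    ``base + sum(phi) = f(x)`` is imposed by eliminating the last feature
    from the regression; a ridge fallback (lambda = 1e-8) handles singular
    designs.  ``residual`` reports the weighted RMS regression residual.
    """
    x = np.asarray(x, dtype=float).ravel()
    M = x.size
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background must be non-empty")
    rng = np.random.default_rng(seed)

    n_interior = 2**M - 2
    if n_coalitions >= n_interior:
        ints = np.arange(1, 2**M - 1, dtype=np.int64)
        Z = ((ints[:, None] >> np.arange(M)) & 1).astype(float)
        w = np.array([shapley_kernel_weight(M, int(s)) for s in Z.sum(axis=1)])
    else:
        size_w = np.array([shapley_kernel_weight(M, s) * comb(M, s)
                           for s in range(1, M)])
        size_p = size_w / size_w.sum()
        sizes = rng.choice(np.arange(1, M), size=n_coalitions, p=size_p)
        Z = np.zeros((n_coalitions, M))
        for r, s in enumerate(sizes):
            Z[r, rng.choice(M, size=s, replace=False)] = 1.0
        w = np.ones(n_coalitions)  # importance handled by the sampling law

    base = float(np.asarray(model(background), dtype=float).mean())
    fx = float(np.asarray(model(x.reshape(1, -1)), dtype=float)[0])
    v = _coalition_values(model, x, background, Z.astype(np.int8))

    # eliminate phi_M using the efficiency constraint
    zM = Z[:, -1]
    A = Z[:, :-1] - zM[:, None]
    b = v - base - zM * (fx - base)
    Aw = A * w[:, None]
    G = Aw.T @ A
    rhs = Aw.T @ b
    try:
        phi_head = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        phi_head = np.linalg.solve(G + 1e-8 * np.eye(M - 1), rhs)
    phi = np.append(phi_head, (fx - base) - phi_head.sum())
    resid = A @ phi_head - b
    rms = float(np.sqrt(np.sum(w * resid**2) / np.sum(w)))
    return ShapleyAttribution(phi=phi, base_value=base, fx=fx, residual=rms)


class KernelShapExplainer:
    """Convenience explainer binding a model to a seeded background set."""

    def __init__(self, model, background, n_coalitions: int = 2048,
                 max_background: int = 50, seed: int = 0):
        background = np.asarray(background, dtype=float)
        if len(background) > max_background:
            rng = np.random.default_rng(seed)
            background = background[
                rng.choice(len(background), size=max_background, replace=False)
            ]
        self.model = model
        self.background = background
        self.n_coalitions = n_coalitions
        self.seed = seed

    def explain(self, X) -> list[ShapleyAttribution]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return [
            kernel_shap(self.model, row, self.background,
                        n_coalitions=self.n_coalitions, seed=self.seed)
            for row in X
        ]


def shap_summary(attributions, X, labels, predictions,
                 feature_names=None) -> dict[str, pd.DataFrame]:
    """Summary tables of per-sample attributions.

    Returns ``importance`` (per-feature mean |phi|, ranked), ``by_class``
    (mean phi and mean feature value per predicted class) and
    ``by_correctness`` (the same split into true/false predictions).
    """
    if len(attributions) == 0:
        raise ValueError("need at least one attribution")
    phi = np.vstack([a.phi for a in attributions])
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    M = phi.shape[1]
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(M)
    ]

    importance = (
        pd.DataFrame({"feature": names, "mean_abs_phi": np.abs(phi).mean(axis=0)})
        .sort_values("mean_abs_phi", ascending=False, kind="stable")
        .reset_index(drop=True)
    )

    def _group_table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
        rows = []
        for gname, sel in groups.items():
            if not sel.any():
                continue
            for j, fname in enumerate(names):
                rows.append({
                    "group": gname, "feature": fname,
                    "mean_phi": phi[sel, j].mean(),
                    "mean_feature_value": X[sel, j].mean(),
                    "n": int(sel.sum()),
                })
        return pd.DataFrame(rows)

    by_class = _group_table({
        "pred_-1": predictions == -1, "pred_+1": predictions == 1})
    correct = predictions == labels
    by_correct = _group_table({"true": correct, "false": ~correct})
    return {"importance": importance, "by_class": by_class,
            "by_correctness": by_correct}
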