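"""Mutual-information feature selection as a QUBO solved by annealing.

Selecting the feature subset S that maximises I(S; Y) is NP-hard.  Under a
conditional-independence approximation the objective separates into marginal
mutual-information terms I(X_i; Y) and pairwise conditional terms
I(X_i; Y | X_j), which fit a quadratic unconstrained binary optimisation

    min_x  -sum_i Q_ii x_i  -  sum_{i<j} (Q_ij + Q_ji) x_i x_j
           + alpha * (sum_i x_i - k)^2,        x in {0, 1}^p

with ``Q_ii = I(X_i; Y)`` on the diagonal and ``Q_ij = I(X_i; Y | X_j)``
off it (all in bits).  The cardinality penalty with a sufficiently large
amplitude ``alpha`` pins the optimum at exactly ``k`` selected features.
The QUBO maps to an Ising Hamiltonian through ``x = (1 - s) / 2`` and is
solved either exactly by enumeration (small ``p``) or by a best-of-reads
simulated-annealing sampler standing in for a quantum annealer; the sampler
interface is pluggable so a hardware backend can be substituted.

MI and CMI are plug-in estimates from joint histograms with equal-frequency
binning of continuous variables (base-2 logarithms, negatives clipped at 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "estimate_mi",
    "estimate_cmi",
    "build_q_matrix",
    "QuboProblem",
    "QuboSolution",
    "qubo_energy",
    "to_ising",
    "solve_exhaustive",
    "solve_anneal",
    "select_features",
    "QuboFeatureSelector",
]

_EXHAUSTIVE_MAX_P = 22


# ---------------------------------------------------------------------------
# entropy estimation

def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Integer codes for ``x``: identity for low-cardinality discrete input,
    equal-frequency bins otherwise."""
    x = np.asarray(x).ravel()
    vals = np.unique(x)
    if vals.size <= bins:
        return np.searchsorted(vals, x)
    edges = np.quantile(x, np.linspace(0.0, 1.0, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a (flattened) count table; 0 log 0 = 0."""
    counts = counts[counts > 0].astype(float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_codes(*codes: np.ndarray) -> np.ndarray:
    """Single integer code per sample for the cartesian product of codes."""
    out = np.zeros_like(codes[0])
    for c in codes:
        out = out * (c.max() + 1) + c
    return out


def _h(*codes: np.ndarray) -> float:
    return _entropy_from_counts(np.bincount(_joint_codes(*codes)))


def estimate_mi(x, y, bins: int = 4) -> float:
    """Plug-in mutual information I(X; Y) in bits, clipped at 0.

    ``I(X; Y) = H(Y) - H(Y | X) = H(X) + H(Y) - H(X, Y)`` evaluated on the
    joint histogram; continuous ``x`` is discretized into ``bins``
    equal-frequency bins.
    """
    x, y = np.asarray(x).ravel(), np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    cx, cy = _discretize(x, bins), _discretize(y, bins)
    mi = _h(cx) + _h(cy) - _h(cx, cy)
    return max(mi, 0.0)


def estimate_cmi(x, y, z, bins: int = 4) -> float:
    """Plug-in conditional mutual information I(X; Y | Z) in bits.

    ``I(X; Y | Z) = H(X, Z) + H(Y, Z) - H(Z) - H(X, Y, Z)`` over the 3-way
    histogram; clipped at 0.
    """
    x, y, z = (np.asarray(a).ravel() for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z must have equal length")
    cx, cy, cz = (_discretize(a, bins) for a in (x, y, z))
    cmi = _h(cx, cz) + _h(cy, cz) - _h(cz) - _h(cx, cy, cz)
    return max(cmi, 0.0)


def build_q_matrix(X, y, bins: int = 4) -> np.ndarray:
    """Q matrix of the selection QUBO: marginal MI on the diagonal,
    ``Q_ij = I(X_i; Y | X_j)`` (row = candidate, column = conditioned) off it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be an n x p matrix with p >= 1")
    y = np.asarray(y).ravel()
    p = X.shape[1]
    codes = [_discretize(X[:, j], bins) for j in range(p)]
    cy = _discretize(y, bins)
    hy = _h(cy)
    hsingle = [_h(c) for c in codes]
    Q = np.zeros((p, p))
    for i in range(p):
        Q[i, i] = max(hsingle[i] + hy - _h(codes[i], cy), 0.0)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            # I(Xi; Y | Xj) = H(Xi,Xj) + H(Y,Xj) - H(Xj) - H(Xi,Y,Xj)
            cmi = (
                _h(codes[i], codes[j])
                + _h(cy, codes[j])
                - hsingle[j]
                - _h(codes[i], cy, codes[j])
            )
            Q[i, j] = max(cmi, 0.0)
    return Q


# ---------------------------------------------------------------------------
# QUBO problem

@dataclass
class QuboProblem:
    """Cardinality-penalized feature-selection QUBO (energies in bits)."""

    Q: np.ndarray
    k: int
    alpha: float

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        p = self.Q.shape[0]
        if self.Q.ndim != 2 or self.Q.shape[1] != p or p < 1:
            raise ValueError("Q must be a square p x p matrix, p >= 1")
        if not 1 <= self.k <= p:
            raise ValueError("k must satisfy 1 <= k <= p")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if np.diag(self.Q).min() < -1e-9:
            raise ValueError("diagonal MI terms must be >= 0 (clip estimates)")

    @property
    def p(self) -> int:
        return self.Q.shape[0]

    def coefficients(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Linear / upper-triangular-quadratic / constant coefficients of the
        minimization objective including the penalty (using x_i^2 = x_i)."""
        p, a, k = self.p, self.alpha, self.k
        lin = -np.diag(self.Q) + a * (1.0 - 2.0 * k)
        quad = np.triu(-(self.Q + self.Q.T) + 2.0 * a, k=1)
        return lin, quad, a * k * k


@dataclass
class QuboSolution:
    x: np.ndarray
    energy: float
    reads: int
    solver: str
    read_energies: np.ndarray | None = field(default=None, repr=False)

    @property
    def cardinality(self) -> int:
        return int(self.x.sum())

    @property
    def indices(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.x)]


def qubo_energy(problem: QuboProblem, x) -> float:
    """Objective value of a binary configuration, penalty included."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != problem.p:
        raise ValueError("configuration length must equal p")
    lin, quad, const = problem.coefficients()
    return float(lin @ x + x @ quad @ x + const)


def _batch_energy(problem: QuboProblem, X: np.ndarray) -> np.ndarray:
    lin, quad, const = problem.coefficients()
    X = X.astype(float)
    return X @ lin + ((X @ quad) * X).sum(axis=1) + const


def to_ising(problem: QuboProblem) -> tuple[np.ndarray, np.ndarray, float]:
    """Map the QUBO to an Ising Hamiltonian via ``x_i = (1 - s_i) / 2``.

    Returns ``(h, J, offset)`` with ``J`` strictly upper triangular such that
    for every configuration ``E_qubo(x) = sum h_i s_i + sum_{i<j} J_ij s_i s_j
    + offset``.
    """
    lin, quad, const = problem.coefficients()
    sym = quad + quad.T
    h = -lin / 2.0 - sym.sum(axis=1) / 4.0
    J = quad / 4.0
    offset = const + lin.sum() / 2.0 + quad.sum() / 4.0
    return h, J, offset


# ---------------------------------------------------------------------------
# solvers

def _lex_smallest(X: np.ndarray) -> np.ndarray:
    order = np.lexsort(X.T[::-1])
    return X[order[0]]


def solve_exhaustive(problem: QuboProblem, hard_constraint: bool = False) -> QuboSolution:
    """Global minimum by enumeration.

    With ``hard_constraint=True`` only the C(p, k) configurations of
    cardinality ``k`` are enumerated (the penalty then only adds the constant
    0); otherwise all ``2**p`` states.  Ties resolve to the lexicographically
    smallest configuration.
    """
    p = problem.p
    if p > _EXHAUSTIVE_MAX_P:
        raise ValueError(
            f"p={p} too large for enumeration (max {_EXHAUSTIVE_MAX_P}); "
            "use solve_anneal"
        )
    if hard_constraint:
        combos = np.array(list(itertools.combinations(range(p), problem.k)))
        states = np.zeros((len(combos), p), dtype=np.int8)
        states[np.arange(len(combos))[:, None], combos] = 1
        chunks = [states]
        total = len(states)
    else:
        total = 2**p
        chunks = (
            ((np.arange(lo, min(lo + 2**18, total), dtype=np.int64)[:, None]
              >> np.arange(p)) & 1).astype(np.int8)
            for lo in range(0, total, 2**18)
        )
    best = np.inf
    best_ties: np.ndarray | None = None
    for states in chunks:
        energies = _batch_energy(problem, states)
        lo = energies.min()
        if lo < best:
            best = lo
            best_ties = states[energies == lo]
        elif lo == best:
            best_ties = np.vstack([best_ties, states[energies == lo]])
    x = _lex_smallest(best_ties)
    return QuboSolution(x=x.astype(np.int8), energy=float(best), reads=total,
                        solver="exhaustive")


def solve_anneal(
    problem: QuboProblem,
    reads: int = 5000,
    sweeps: int = 100,
    schedule: tuple[float, float] | None = None,
    seed: int = 0,
) -> QuboSolution:
    """Best-of-reads single-spin-flip Metropolis simulated annealing.

    Each read starts from a random configuration and performs ``sweeps``
    sweeps of ``p`` proposed single-bit flips under a geometric temperature
    schedule from hot to cold (defaults scale with the coefficient
    magnitudes).  Every read owns an independent random stream derived from
    ``(seed, read index)``, so the first ``r`` reads are identical whatever
    the total read count (best-of-reads is monotone in ``reads``); all reads
    are executed in lockstep (vectorized).
    """
    if reads < 1:
        raise ValueError("reads must be >= 1")
    p = problem.p
    lin, quad, const = problem.coefficients()
    B = quad + quad.T  # symmetric couplings

    if schedule is None:
        scale = max(np.abs(lin).max(), np.abs(B).max() if p > 1 else 0.0, 1e-12)
        t_hot, t_cold = 2.0 * scale, 1e-3 * scale
    else:
        t_hot, t_cold = schedule
    n_steps = max(sweeps, 1)
    temps = t_hot * (t_cold / t_hot) ** (np.arange(n_steps) / max(n_steps - 1, 1))

    # per-read streams: initial state, then (sweeps * p) flip indices and
    # uniform variates each
    X = np.empty((reads, p), dtype=np.int8)
    flips = np.empty((reads, n_steps * p), dtype=np.int32)
    unif = np.empty((reads, n_steps * p))
    for r in range(reads):
        rng = np.random.default_rng([seed, r])
        X[r] = rng.integers(0, 2, size=p)
        flips[r] = rng.integers(0, p, size=n_steps * p)
        unif[r] = rng.random(n_steps * p)

    E = _batch_energy(problem, X)
    best_X, best_E = X.copy(), E.copy()
    rows = np.arange(reads)
    t = 0
    for T in temps:
        for _ in range(p):
            idx = flips[:, t]
            delta = (1 - 2 * X[rows, idx]) * (lin[idx] + (B[idx] * X).sum(axis=1))
            accept = (delta <= 0) | (unif[:, t] < np.exp(-np.clip(delta, 0, 700) / T))
            X[rows[accept], idx[accept]] ^= 1
            E[accept] += delta[accept]
            improved = E < best_E
            if improved.any():
                best_E[improved] = E[improved]
                best_X[improved] = X[improved]
            t += 1
    winner = int(np.argmin(best_E))
    return QuboSolution(
        x=best_X[winner].copy(),
        energy=float(best_E[winner]),
        reads=reads,
        solver="annealing",
        read_energies=best_E,
    )


def _auto_alpha(Q: np.ndarray) -> float:
    """Penalty amplitude strictly exceeding the objective's total range, so
    any cardinality violation costs more than the best attainable gain."""
    sym = Q + Q.T
    rng = float(np.diag(Q).sum() + np.abs(np.triu(sym, k=1)).sum())
    return rng + 1e-9


def select_features(
    X,
    y,
    k: int = 10,
    bins: int = 4,
    alpha: float | str = "auto",
    reads: int = 5000,
    seed: int = 0,
) -> list[int]:
    """Select ``k`` features by solving the MI/CMI QUBO.

    ``alpha="auto"`` sets the penalty above the objective range, which
    guarantees the optimum has cardinality exactly ``k``.  The exact
    enumerator is used for ``p <= 22``, the annealer otherwise.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p < k:
        raise ValueError("number of columns must be >= k")
    Q = build_q_matrix(X, y, bins=bins)
    a = _auto_alpha(Q) if alpha == "auto" else float(alpha)
    problem = QuboProblem(Q, k=k, alpha=a)
    if p <= _EXHAUSTIVE_MAX_P:
        sol = solve_exhaustive(problem)
    else:
        sol = solve_anneal(problem, reads=reads, seed=seed)
    if alpha == "auto" and sol.cardinality != k and sol.solver == "exhaustive":
        raise RuntimeError(
            "auto penalty failed to enforce cardinality; this indicates an "
            "internal invariant breach"
        )
    return sol.indices


class QuboFeatureSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector wrapping :func:`select_features`.

    Parameters
    ----------
    k : number of features to keep.
    bins : equal-frequency bins for the MI/CMI plug-in estimators.
    alpha : penalty amplitude, or ``"auto"`` for the range upper bound.
    reads : annealer reads when ``p`` exceeds the enumeration limit.
    random_state : seed for the annealer.

    Attributes
    ----------
    support_ : boolean mask of selected columns.
    q_matrix_ : the estimated MI/CMI Q matrix.
    solution_ : the :class:`QuboSolution` of the solve.
    """

    def __init__(self, k: int = 10, bins: int = 4, alpha="auto",
                 reads: int = 5000, random_state: int = 0):
        self.k = k
        self.bins = bins
        self.alpha = alpha
        self.reads = reads
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_features=self.k, reset=True)
        y = np.asarray(y).ravel()
        self.q_matrix_ = build_q_matrix(X, y, bins=self.bins)
        a = _auto_alpha(self.q_matrix_) if self.alpha == "auto" else float(self.alpha)
        problem = QuboProblem(self.q_matrix_, k=self.k, alpha=a)
        if problem.p <= _EXHAUSTIVE_MAX_P:
            self.solution_ = solve_exhaustive(problem)
        else:
            self.solution_ = solve_anneal(problem, reads=self.reads,
                                          seed=self.random_state)
        self.support_ = self.solution_.x.astype(bool)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
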