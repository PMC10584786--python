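"""2-qubit variational quantum classifier on a dense statevector simulator.

The classifier ingests the 10 selected radiomic features, reduces them to 3
principal components, rescales them to [0, 1], pads them with a fixed
constant (so the per-sample normalisation factor required by the Born rule
remains recoverable) and L2-normalises the resulting 4-vector.  That
non-negative amplitude vector is written into the state of 2 qubits by a
reversed cascade of controlled Y rotations (Mottonen-style state
preparation), each controlled rotation decomposed into CNOT and RY gates.
A 6-layer entangling ansatz of arbitrary single-qubit rotations
``Rot(phi, theta, omega) = RZ(omega) RY(theta) RZ(phi)`` followed by CNOTs
is applied, and the expectation of Pauli Z on the first qubit plus a
trainable classical bias is the decision score: negative scores predict the
metastasis-like class (-1), otherwise glioma-like (+1).

Training minimises the squared error between the score and the +/-1 label
with Adam; gradients of the rotation angles use the exact parameter-shift
rule.  The simulator is a generic dense n-qubit statevector (qubit 0 is the
most significant bit of the basis index), vectorized over samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "AmplitudeEncoder",
    "reduce_and_pad",
    "encoding_angles",
    "prepare_state",
    "circuit_expectation",
    "CircuitParams",
    "VariationalQuantumClassifier",
    "train_qnn",
    "predict",
]


# ---------------------------------------------------------------------------
# statevector simulator (batched over samples; qubit 0 = most significant)

def _apply_single(states: np.ndarray, U: np.ndarray, qubit: int, n_qubits: int):
    """Apply a 2x2 unitary to one qubit of a batch of statevectors."""
    m = states.shape[0]
    left = 2**qubit
    right = 2 ** (n_qubits - qubit - 1)
    s = states.reshape(m, left, 2, right)
    out = np.einsum("ab,mlbr->mlar", U, s)
    return out.reshape(m, -1)


def _apply_cnot(states: np.ndarray, control: int, target: int, n_qubits: int):
    """CNOT by permuting basis amplitudes where the control bit is 1."""
    dim = 2**n_qubits
    idx = np.arange(dim)
    cbit = (idx >> (n_qubits - control - 1)) & 1
    flipped = idx ^ (1 << (n_qubits - target - 1))
    perm = np.where(cbit == 1, flipped, idx)
    return states[:, perm]


def _ry(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]])


def _rz(phi: float) -> np.ndarray:
    return np.array([[np.exp(-0.5j * phi), 0.0], [0.0, np.exp(0.5j * phi)]])


def _rot(phi: float, theta: float, omega: float) -> np.ndarray:
    return _rz(omega) @ _ry(theta) @ _rz(phi)


def _x() -> np.ndarray:
    return np.array([[0.0, 1.0], [1.0, 0.0]])


def _apply_cry(states, theta, control, target, n_qubits, control_value=1):
    """Controlled RY via the standard half-angle 2-CNOT decomposition.

    ``RY(t/2) . CNOT . RY(-t/2) . CNOT`` on the target implements a rotation
    by ``t`` exactly when the control is 1; conjugating the control with X
    flips the polarity to control-on-0.
    """
    if control_value == 0:
        states = _apply_single(states, _x(), control, n_qubits)
    states = _apply_single(states, _ry(theta / 2.0), target, n_qubits)
    states = _apply_cnot(states, control, target, n_qubits)
    states = _apply_single(states, _ry(-theta / 2.0), target, n_qubits)
    states = _apply_cnot(states, control, target, n_qubits)
    if control_value == 0:
        states = _apply_single(states, _x(), control, n_qubits)
    return states


# ---------------------------------------------------------------------------
# amplitude encoding

def encoding_angles(alpha) -> np.ndarray:
    """Y-rotation angles (beta_1^2, beta_1^1, beta_2^1) encoding a
    non-negative unit 4-vector; 0/0 branches are defined as 0."""
    a = np.asarray(alpha, dtype=float).ravel()
    if a.shape != (4,):
        raise ValueError("amplitude vector must have 4 entries")
    if np.any(a < -1e-12):
        raise ValueError("amplitudes must be non-negative")
    if abs(np.linalg.norm(a) - 1.0) > 1e-8:
        raise ValueError("amplitude vector must have unit norm")

    def _beta(num, den):
        if den <= 0.0:
            return 0.0
        return 2.0 * np.arcsin(min(num / den, 1.0))

    lo = np.hypot(a[0], a[1])  # |q1=0| block
    hi = np.hypot(a[2], a[3])  # |q1=1| block
    b12 = 2.0 * np.arcsin(min(hi, 1.0))
    b11 = _beta(a[1], lo)
    b21 = _beta(a[3], hi)
    return np.array([b12, b11, b21])


def prepare_state(alpha) -> np.ndarray:
    """Statevector preparing the non-negative unit amplitude vector.

    ``RY(beta_1^2)`` on qubit 1, then on qubit 2 a Y rotation by
    ``beta_1^1`` controlled on qubit 1 being 0 and by ``beta_2^1``
    controlled on qubit 1 being 1 (each decomposed into CNOT + RY).
    Basis order is ``|q1 q2> = 00, 01, 10, 11``.
    """
    b12, b11, b21 = encoding_angles(alpha)
    states = np.zeros((1, 4), dtype=complex)
    states[0, 0] = 1.0
    states = _apply_single(states, _ry(b12), 0, 2)
    states = _apply_cry(states, b11, control=0, target=1, n_qubits=2,
                        control_value=0)
    states = _apply_cry(states, b21, control=0, target=1, n_qubits=2,
                        control_value=1)
    return states[0]


def _prepare_batch(alphas: np.ndarray) -> np.ndarray:
    """Vectorized state preparation from rows of non-negative unit 4-vectors.

    The gate cascade maps the encoding angles back to the amplitudes exactly
    (round-trip property), so the prepared batch equals the input promoted to
    complex; the single-sample :func:`prepare_state` keeps the explicit gate
    path and the tests pin their equivalence.
    """
    return alphas.astype(complex)


# ---------------------------------------------------------------------------
# variational circuit

@dataclass
class CircuitParams:
    """Rotation angles of the layered ansatz plus the classical bias."""

    angles: np.ndarray  # (layers, 2, 3): (phi, theta, omega) per qubit
    bias: float = 0.0

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 3 or self.angles.shape[1:] != (2, 3):
            raise ValueError("angles must have shape (layers, 2, 3)")
        if not np.all(np.isfinite(self.angles)) or not np.isfinite(self.bias):
            raise ValueError("parameters must be finite")

    @property
    def n_layers(self) -> int:
        return self.angles.shape[0]

    def to_dict(self) -> dict:
        return {"angles": self.angles.tolist(), "bias": float(self.bias)}

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        return cls(np.asarray(d["angles"]), float(d["bias"]))


def _run_ansatz(states: np.ndarray, angles: np.ndarray) -> np.ndarray:
    for layer in angles:
        states = _apply_single(states, _rot(*layer[0]), 0, 2)
        states = _apply_single(states, _rot(*layer[1]), 1, 2)
        states = _apply_cnot(states, 0, 1, 2)
    return states


def _expectations(states: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """<Z x I> on qubit 1 after the ansatz, for a batch of states."""
    out = _run_ansatz(states, angles)
    prob = np.abs(out) ** 2
    return prob[:, 0] + prob[:, 1] - prob[:, 2] - prob[:, 3]


def circuit_expectation(state, params: CircuitParams | np.ndarray) -> float:
    """Pauli-Z expectation on the first qubit after the layered ansatz."""
    angles = params.angles if isinstance(params, CircuitParams) else np.asarray(params)
    state = np.asarray(state, dtype=complex).reshape(1, -1)
    if abs(np.linalg.norm(state) - 1.0) > 1e-8:
        raise ValueError("state must have unit norm")
    return float(_expectations(state, angles)[0])


# ---------------------------------------------------------------------------
# dimensionality reduction + padding

class AmplitudeEncoder(TransformerMixin, BaseEstimator):
    """Map 10 standardized features to non-negative unit 4-vectors.

    Fit: center on the fit rows, project onto the top ``n_components=3``
    principal directions (component sign fixed so the largest-|loading|
    coordinate is positive), record per-component min/max.  Transform:
    project, min-max scale to [0, 1] with the fitted ranges (clipped),
    append the padding constant, normalise each row to unit norm.
    """

    def __init__(self, n_components: int = 3, pad_constant: float = 0.3):
        self.n_components = n_components
        self.pad_constant = pad_constant

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=self.n_components + 1,
                          reset=True)
        if self.pad_constant <= 0:
            raise ValueError("pad_constant must be positive")
        self.pca_ = PCA(n_components=self.n_components, svd_solver="full")
        Z = self.pca_.fit_transform(X)
        if (self.pca_.n_components_ < self.n_components
                or self.pca_.explained_variance_.min() < 1e-10):
            raise ValueError("fit rows have rank below n_components")
        # deterministic sign: largest-|loading| entry of each component > 0
        flip = np.sign(
            self.pca_.components_[
                np.arange(self.n_components),
                np.argmax(np.abs(self.pca_.components_), axis=1),
            ]
        )
        flip[flip == 0] = 1.0
        self.pca_.components_ *= flip[:, None]
        Z *= flip
        self.min_ = Z.min(axis=0)
        self.range_ = Z.max(axis=0) - self.min_
        if np.any(self.range_ <= 0):
            raise ValueError("degenerate component range on fit rows")
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        Z = self.pca_.transform(X)
        Z = np.clip((Z - self.min_) / self.range_, 0.0, 1.0)
        out = np.column_stack([Z, np.full(len(Z), self.pad_constant)])
        return out / np.linalg.norm(out, axis=1, keepdims=True)


def reduce_and_pad(X10, fit_idx=None, n_components: int = 3,
                   pad_constant: float = 0.3):
    """Functional form of :class:`AmplitudeEncoder`: returns the encoded
    amplitude rows together with the fitted transform."""
    X10 = np.asarray(X10, dtype=float)
    fit_idx = np.arange(len(X10)) if fit_idx is None else np.asarray(fit_idx)
    enc = AmplitudeEncoder(n_components=n_components, pad_constant=pad_constant)
    enc.fit(X10[fit_idx])
    return enc.transform(X10), enc


# ---------------------------------------------------------------------------
# training

class VariationalQuantumClassifier(ClassifierMixin, BaseEstimator):
    """Amplitude-encoded 2-qubit variational classifier.

    Parameters
    ----------
    n_layers : ansatz depth (Rot pair + CNOT per layer).
    lr : Adam learning rate.
    epochs : training epochs (full-batch unless ``batch_size`` set).
    batch_size : minibatch size, or None for full batch.
    pad_constant : padding constant appended before normalisation.
    init_scale : std of the seeded Gaussian angle initialisation.
    random_state : seed for initialisation and batching.

    Attributes
    ----------
    params_ : fitted :class:`CircuitParams` (angles + classical bias).
    encoder_ : the fitted :class:`AmplitudeEncoder`.
    history_ : per-epoch ``loss`` (MSE) and ``accuracy`` DataFrame.
    classes_ : ``[-1, 1]``.
    """

    def __init__(self, n_layers: int = 6, lr: float = 0.01, epochs: int = 100,
                 batch_size: int | None = None, pad_constant: float = 0.3,
                 init_scale: float = 0.01, random_state: int = 0):
        self.n_layers = n_layers
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.pad_constant = pad_constant
        self.init_scale = init_scale
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _scores_from_states(self, states, angles, bias):
        return _expectations(states, angles) + bias

    def _grads(self, states, y, angles, bias):
        """MSE gradient via the parameter-shift rule (exact for Rot gates)."""
        resid = self._scores_from_states(states, angles, bias) - y
        n = len(y)
        g = np.zeros_like(angles)
        flat = angles.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + np.pi / 2.0
            up = _expectations(states, angles)
            flat[i] = orig - np.pi / 2.0
            dn = _expectations(states, angles)
            flat[i] = orig
            dexp = (up - dn) / 2.0
            gflat[i] = 2.0 * np.mean(resid * dexp)
        gbias = 2.0 * float(np.mean(resid))
        return g, gbias, float(np.mean(resid**2))

    def fit(self, X, y):
        X = validate_data(self, X, reset=True)
        y = np.asarray(y, dtype=float).ravel()
        if set(np.unique(y)) - {-1.0, 1.0}:
            raise ValueError("labels must be in {-1, +1}")
        if min((y == -1).sum(), (y == 1).sum()) < 2:
            raise ValueError("need at least 2 samples per class")
        self.classes_ = np.array([-1, 1])
        rng = np.random.default_rng(self.random_state)

        self.encoder_ = AmplitudeEncoder(pad_constant=self.pad_constant)
        self.encoder_.fit(X)
        states = _prepare_batch(self.encoder_.transform(X))

        angles = rng.normal(0.0, self.init_scale, size=(self.n_layers, 2, 3))
        bias = 0.0
        m = np.zeros(angles.size + 1)
        v = np.zeros(angles.size + 1)
        b1, b2, eps = 0.9, 0.999, 1e-8
        history = []
        t = 0
        n = len(y)
        bs = self.batch_size or n
        for epoch in range(self.epochs):
            order = rng.permutation(n) if bs < n else np.arange(n)
            for lo in range(0, n, bs):
                sel = order[lo:lo + bs]
                g, gbias, _ = self._grads(states[sel], y[sel], angles, bias)
                grad = np.append(g.ravel(), gbias)
                if not np.all(np.isfinite(grad)):
                    raise FloatingPointError(
                        f"non-finite gradient at epoch {epoch}")
                t += 1
                m = b1 * m + (1 - b1) * grad
                v = b2 * v + (1 - b2) * grad**2
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                step = self.lr * mhat / (np.sqrt(vhat) + eps)
                angles -= step[:-1].reshape(angles.shape)
                bias -= step[-1]
            scores = self._scores_from_states(states, angles, bias)
            loss = float(np.mean((scores - y) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            pred = np.where(scores < 0, -1.0, 1.0)
            history.append(
                {"epoch": epoch, "loss": loss,
                 "accuracy": float(np.mean(pred == y))})
        self.params_ = CircuitParams(angles, bias)
        self.history_ = pd.DataFrame(
            history, columns=["epoch", "loss", "accuracy"])
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        states = _prepare_batch(self.encoder_.transform(X))
        return self._scores_from_states(states, self.params_.angles,
                                        self.params_.bias)

    def predict(self, X):
        # tie rule: a score of exactly 0 predicts +1 (glioma-like)
        return np.where(self.decision_function(X) < 0, -1, 1)


def train_qnn(table, lr: float = 0.01, epochs: int = 100,
              batch_size: int | None = None, seed: int = 0,
              n_layers: int = 6) -> tuple[VariationalQuantumClassifier, pd.DataFrame]:
    """Train the classifier on a :class:`~qradbrain.tables.FeatureTable`."""
    clf = VariationalQuantumClassifier(
        n_layers=n_layers, lr=lr, epochs=epochs, batch_size=batch_size,
        random_state=seed,
    )
    clf.fit(table.values, table.labels)
    return clf, clf.history_


def predict(x10, clf: VariationalQuantumClassifier):
    """Score and label for one 10-feature vector using a fitted classifier."""
    x10 = np.asarray(x10, dtype=float).reshape(1, -1)
    score = float(clf.decision_function(x10)[0])
    return score, (-1 if score < 0 else 1)
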