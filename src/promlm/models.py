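"""Classifiers: a small 1D convolutional network and a kNN baseline.

The network maps a feature vector of length D through

    input (1 x D)
    -> 1D convolution, 64 filters, kernel 3, stride 1, no padding (linear)
    -> ReLU
    -> max pooling, size 2, stride 2
    -> dropout 0.3 (training only)
    -> flatten
    -> fully connected layer to 2 units
    -> softmax

trained with mini-batch adadelta under a per-filter max-norm weight
constraint.  Everything is plain NumPy, seeded and single-threaded, so a
fixed seed reproduces parameters bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.neighbors import KNeighborsClassifier

from .data_io import FeatureTable


def relu(x):
    """f(x) = max(0, x), elementwise."""
    return np.maximum(x, 0)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax; rejects non-finite input."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input must be finite")
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class CnnConfig:
    """Tuned architecture and optimizer settings."""

    input_dim: int
    n_filters: int = 64
    kernel: int = 3
    pool: int = 2
    pool_stride: int = 2
    dropout: float = 0.3
    weight_max_norm: float = 4.0
    batch_size: int = 100
    epochs: int = 100
    lr: float = 1.0          # adadelta step scale
    rho: float = 0.95
    eps: float = 1e-6
    output_units: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel > self.input_dim:
            raise ValueError(
                f"kernel ({self.kernel}) exceeds input_dim ({self.input_dim})")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.output_units != 2:
            raise ValueError("binary task: output_units must be 2")

    @property
    def conv_len(self) -> int:
        return self.input_dim - self.kernel + 1

    @property
    def pool_len(self) -> int:
        return (self.conv_len - self.pool) // self.pool_stride + 1

    @property
    def flat_len(self) -> int:
        return self.pool_len * self.n_filters


class Conv1DNet:
    """The convolutional classifier; ``build_cnn`` is the public constructor."""

    #: parameters are kept in float32: the model is memory-bandwidth bound and
    #: single precision halves traffic at no cost to a 2-class decision
    DTYPE = np.float32

    def __init__(self, config: CnnConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        lim_w = np.sqrt(6.0 / (c.kernel + c.n_filters))
        self.W = rng.uniform(-lim_w, lim_w,
                             size=(c.n_filters, c.kernel)).astype(self.DTYPE)
        self.b = np.zeros(c.n_filters, dtype=self.DTYPE)
        lim_d = np.sqrt(6.0 / (c.flat_len + c.output_units))
        self.Wd = rng.uniform(-lim_d, lim_d,
                              size=(c.flat_len, c.output_units)).astype(self.DTYPE)
        self.bd = np.zeros(c.output_units, dtype=self.DTYPE)
        self.history: list[float] = []
        self._rng = rng

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size + self.Wd.size + self.bd.size

    # -- forward -------------------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool = False):
        c = self.config
        B = X.shape[0]
        X = np.ascontiguousarray(X, dtype=self.DTYPE)
        # im2col once, then one GEMM: (B*L, K) @ (K, F)
        cols = np.ascontiguousarray(
            sliding_window_view(X, c.kernel, axis=1)).reshape(-1, c.kernel)
        A = cols @ self.W.T + self.b                            # (B*L, F)
        R = relu(A)
        used = c.pool_len * c.pool_stride
        Rw = R.reshape(B, c.conv_len, c.n_filters)[:, :used, :] \
              .reshape(B, c.pool_len, c.pool, c.n_filters)
        if c.pool == 2:  # fast path: a single comparison replaces argmax
            r0, r1 = Rw[:, :, 0, :], Rw[:, :, 1, :]
            arg = r1 > r0
            P = np.where(arg, r1, r0)
        else:
            arg = Rw.argmax(axis=2)
            P = np.take_along_axis(Rw, arg[:, :, None, :], axis=2)[:, :, 0, :]
        if train and c.dropout > 0:
            mask = ((self._rng.random(P.shape) >= c.dropout) / (1.0 - c.dropout)
                    ).astype(self.DTYPE)
            P = P * mask
        else:
            mask = None
        flat = P.reshape(B, c.flat_len)
        logits = flat @ self.Wd + self.bd
        probs = softmax(logits, axis=1)
        cache = (cols, A, arg, mask, flat)
        return probs, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode probabilities (dropout is the identity map)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected (n, {self.config.input_dim}) input, got {X.shape}")
        probs, _ = self._forward(X, train=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class calls: argmax, ties to the positive class (index 1)."""
        probs = self.predict_proba(X)
        return np.where(probs[:, 1] >= probs[:, 0], 1, 0)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    # -- training ------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv1DNet":
        c = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        n = X.shape[0]
        Y = np.zeros((n, c.output_units))
        Y[np.arange(n), y] = 1.0

        params = [self.W, self.b, self.Wd, self.bd]
        Eg = [np.zeros_like(p) for p in params]
        Ex = [np.zeros_like(p) for p in params]

        for _ in range(c.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, c.batch_size):
                idx = order[start:start + c.batch_size]
                grads, loss = self._grads(X[idx], Y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        "NaN/inf training loss; check feature standardization "
                        "and learning-rate settings")
                epoch_loss += loss * len(idx)
                for p, g, eg, ex in zip(params, grads, Eg, Ex):
                    eg *= c.rho
                    eg += (1 - c.rho) * g * g
                    step = -c.lr * np.sqrt(ex + c.eps) / np.sqrt(eg + c.eps) * g
                    ex *= c.rho
                    ex += (1 - c.rho) * step * step
                    p += step
                self._apply_max_norm()
            self.history.append(epoch_loss / n)
        return self

    def _grads(self, Xb, Yb):
        c = self.config
        B = Xb.shape[0]
        probs, (cols, A, arg, mask, flat) = self._forward(Xb, train=True)
        loss = float(-np.sum(Yb * np.log(np.maximum(probs.astype(np.float64),
                                                    1e-300))) / B)

        glog = ((probs - Yb) / B).astype(self.DTYPE)             # (B, 2)
        dWd = flat.T @ glog
        dbd = glog.sum(axis=0)
        dflat = glog @ self.Wd.T                                 # (B, flat)
        dP = dflat.reshape(B, c.pool_len, c.n_filters)
        if mask is not None:
            dP = dP * mask
        # unpool: route gradient to the argmax slot of each pooling window
        used = c.pool_len * c.pool_stride
        dRw = np.zeros((B, c.pool_len, c.pool, c.n_filters), dtype=self.DTYPE)
        if c.pool == 2:
            dRw[:, :, 1, :] = dP * arg
            dRw[:, :, 0, :] = dP * ~arg
        else:
            np.put_along_axis(dRw, arg[:, :, None, :], dP[:, :, None, :], axis=2)
        dR = np.zeros((B, c.conv_len, c.n_filters), dtype=self.DTYPE)
        dR[:, :used, :] = dRw.reshape(B, used, c.n_filters)
        dA = dR.reshape(-1, c.n_filters)
        dA *= A > 0
        dW = dA.T @ cols                                         # (F, K) GEMM
        db = dA.sum(axis=0)
        return (dW, db, dWd, dbd), loss

    def _apply_max_norm(self) -> None:
        """Rescale any weight vector whose norm exceeds the constraint."""
        m = self.config.weight_max_norm
        if m <= 0:
            return
        norms = np.linalg.norm(self.W, axis=1, keepdims=True)
        np.divide(self.W, norms / m, out=self.W, where=norms > m)
        dnorms = np.linalg.norm(self.Wd, axis=0, keepdims=True)
        np.divide(self.Wd, dnorms / m, out=self.Wd, where=dnorms > m)


def build_cnn(config: CnnConfig) -> Conv1DNet:
    """Instantiate the untrained network for the given input width."""
    return Conv1DNet(config)


def train_cnn(model: Conv1DNet, table: FeatureTable) -> Conv1DNet:
    """Train on a feature table (features should be standardized)."""
    return model.fit(table.matrix, table.labels)


# ---------------------------------------------------------------------------
# kNN baseline
# ---------------------------------------------------------------------------

class KnnModel:
    """Euclidean kNN majority vote; ties go to the positive class."""

    def __init__(self, k: int = 10) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._clf = KNeighborsClassifier(n_neighbors=k)

    def fit(self, X, y):
        if self.k > len(y):
            raise ValueError(f"k={self.k} exceeds training size {len(y)}")
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=np.int64)
        self._clf.fit(self.X_, self.y_)
        return self

    def predict_proba(self, X):
        proba = self._clf.predict_proba(X)
        if proba.shape[1] == 1:  # degenerate single-class fit guard
            cls = int(self._clf.classes_[0])
            out = np.zeros((proba.shape[0], 2))
            out[:, cls] = 1.0
            return out
        return proba

    def predict(self, X):
        proba = self.predict_proba(X)
        return np.where(proba[:, 1] >= proba[:, 0], 1, 0)

    def decision_scores(self, X):
        return self.predict_proba(X)[:, 1]


def knn_baseline(table: FeatureTable, k: int = 10, cv=None, seed: int = 0):
    """Evaluate the kNN baseline under the shared CV harness.

    Returns the per-fold metrics DataFrame and the summary row, as produced
    by :func:`promlm.evaluation.cross_validate`.
    """
    from .evaluation import cross_validate, make_folds

    plan = cv if cv is not None else make_folds(table.labels, seed=seed)
    return cross_validate(lambda: KnnModel(k=k), table.matrix, table.labels, plan)
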