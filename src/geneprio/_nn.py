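"""Minimal 1D convolutional network in numpy.

Sized for short tabular feature vectors (length 14 here), where a full deep
learning framework would be overkill: same-padded conv blocks with ReLU and
L1 weight regularization, same-padded max pooling of stride 2, dense ReLU
layers with inverted dropout, a 2-way softmax head, cross-entropy loss and
Adam. Everything is seeded through one numpy Generator, so training is
bit-for-bit reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CNNClassifier"]


class _Conv1DSame:
    """k-wide same-padded 1D convolution + ReLU, with optional L1 penalty."""

    def __init__(self, cin: int, cout: int, k: int, l1: float, rng: np.random.Generator):
        self.k, self.cin, self.cout, self.l1 = k, cin, cout, l1
        scale = np.sqrt(2.0 / (k * cin))
        self.W = rng.normal(0.0, scale, size=(k * cin, cout))
        self.b = np.zeros(cout)
        self.params = {"W": self.W, "b": self.b}
        self.grads: dict[str, np.ndarray] = {}

    def _patches(self, x: np.ndarray) -> np.ndarray:
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # (B, L, Cin, K) -> (B, L, K, Cin) -> (B, L, K*Cin)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], x.shape[1], self.k * self.cin
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._p = self._patches(x)
        self._in_len = x.shape[1]
        z = self._p @ self.params["W"] + self.params["b"]
        self._mask = z > 0
        return z * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * self._mask
        B, L, _ = dz.shape
        P = self.k * self.cin
        self.grads["W"] = (
            self._p.reshape(-1, P).T @ dz.reshape(-1, self.cout)
            + self.l1 * np.sign(self.params["W"])
        )
        self.grads["b"] = dz.sum(axis=(0, 1))
        dp = (dz @ self.params["W"].T).reshape(B, L, self.k, self.cin)
        pad = self.k // 2
        dxp = np.zeros((B, L + 2 * pad, self.cin))
        for o in range(self.k):
            dxp[:, o:o + L, :] += dp[:, :, o, :]
        return dxp[:, pad:pad + L, :]

    def penalty(self) -> float:
        return self.l1 * np.abs(self.params["W"]).sum()


class _MaxPool1DSame:
    """Max pool, window 2 stride 2; odd lengths are right-padded ("same")."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        self._in_len = L
        if L % 2:
            x = np.concatenate([x, np.full((B, 1, C), -np.inf)], axis=1)
        pairs = x.reshape(B, -1, 2, C)
        self._arg = pairs.argmax(axis=2)  # (B, Lout, C)
        return pairs.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, Lout, C = dout.shape
        dpairs = np.zeros((B, Lout, 2, C))
        np.put_along_axis(dpairs, self._arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = dpairs.reshape(B, Lout * 2, C)
        return dx[:, : self._in_len, :]

    def penalty(self) -> float:
        return 0.0


class _Flatten:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def penalty(self) -> float:
        return 0.0


class _Dense:
    def __init__(self, cin: int, cout: int, relu: bool, rng: np.random.Generator):
        scale = np.sqrt((2.0 if relu else 1.0) / cin)
        self.W = rng.normal(0.0, scale, size=(cin, cout))
        self.b = np.zeros(cout)
        self.relu = relu
        self.params = {"W": self.W, "b": self.b}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.relu:
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * self._mask if self.relu else dout
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T

    def penalty(self) -> float:
        return 0.0


class _Dropout:
    """Inverted dropout; identity at inference."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask

    def penalty(self) -> float:
        return 0.0


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNClassifier:
    """1D convnet for binary classification of fixed-length feature vectors.

    Architecture: four conv blocks (filters 32/64/128/256, kernel 3, stride
    1, same padding, ReLU, L1(0.001) on kernels), each followed by max
    pooling (size 2, stride 2, same padding); then dense 1024-ReLU and
    512-ReLU layers, each followed by dropout, and a 2-way softmax output.
    For input length 14 the spatial length shrinks 14 -> 7 -> 4 -> 2 -> 1,
    so the flattened width is 256.

    Training: cross-entropy + L1 penalty, Adam (default rate 1e-3), batches
    of 32, up to ``max_epochs`` with early stopping on a stratified
    validation split (patience in epochs); the best-validation weights are
    restored. Fully deterministic given ``seed``.
    """

    def __init__(
        self,
        n_features: int = 14,
        filters: tuple[int, ...] = (32, 64, 128, 256),
        kernel: int = 3,
        dense: tuple[int, ...] = (1024, 512),
        dropout: float = 0.5,
        l1: float = 1e-3,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 10,
        val_frac: float = 0.1,
        seed: int = 0,
    ):
        self.n_features = n_features
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_frac = val_frac
        self.learning_rate = learning_rate
        self.rng = np.random.default_rng(seed)

        self.layers: list = []
        cin, length = 1, n_features
        for f in filters:
            self.layers.append(_Conv1DSame(cin, f, kernel, l1, self.rng))
            self.layers.append(_MaxPool1DSame())
            cin = f
            length = (length + 1) // 2
        self.flat_width = cin * length
        self.layers.append(_Flatten())
        width = self.flat_width
        for d in dense:
            self.layers.append(_Dense(width, d, relu=True, rng=self.rng))
            self.layers.append(_Dropout(dropout, self.rng))
            width = d
        self.layers.append(_Dense(width, 2, relu=False, rng=self.rng))

        self._adam_m: list[dict[str, np.ndarray]] = [
            {k: np.zeros_like(v) for k, v in lyr.params.items()} for lyr in self.layers
        ]
        self._adam_v: list[dict[str, np.ndarray]] = [
            {k: np.zeros_like(v) for k, v in lyr.params.items()} for lyr in self.layers
        ]
        self._adam_t = 0

    # ------------------------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        out = X[:, :, None]  # (B, L, 1)
        for lyr in self.layers:
            out = lyr.forward(out, train)
        return out  # logits (B, 2)

    def _loss(self, logits: np.ndarray, y: np.ndarray,
              penalized: bool = True) -> float:
        p = _softmax(logits)
        ce = -np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None)).mean()
        if penalized:
            ce += sum(lyr.penalty() for lyr in self.layers)
        return float(ce)

    def _step(self, X: np.ndarray, y: np.ndarray) -> None:
        logits = self._forward(X, train=True)
        p = _softmax(logits)
        dlogits = p.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        grad = dlogits
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for lyr, m, v in zip(self.layers, self._adam_m, self._adam_v):
            for k in lyr.params:
                g = lyr.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**t)
                vhat = v[k] / (1 - b2**t)
                lyr.params[k] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def _snapshot(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in lyr.params.items()} for lyr in self.layers]

    def _restore(self, snap: list[dict[str, np.ndarray]]) -> None:
        for lyr, st in zip(self.layers, snap):
            for k in st:
                lyr.params[k][...] = st[k]

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        n = len(y)
        # stratified validation split for early stopping
        val_idx: np.ndarray = np.array([], dtype=int)
        if self.val_frac > 0 and n >= 20:
            parts = []
            for lab in np.unique(y):
                idx = np.flatnonzero(y == lab)
                k = max(1, int(round(self.val_frac * len(idx))))
                parts.append(self.rng.permutation(idx)[:k])
            val_idx = np.concatenate(parts)
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]

        best_loss, best_snap, since_best = np.inf, self._snapshot(), 0
        for _ in range(self.max_epochs):
            order = self.rng.permutation(len(ytr))
            for lo in range(0, len(ytr), self.batch_size):
                sel = order[lo:lo + self.batch_size]
                self._step(Xtr[sel], ytr[sel])
            monitor_X, monitor_y = (Xval, yval) if len(val_idx) else (Xtr, ytr)
            # monitor the data term only: the L1 penalty falls monotonically as
            # weights shrink and would mask rising validation error
            loss = self._loss(self._forward(monitor_X, train=False), monitor_y,
                              penalized=False)
            if loss < best_loss - 1e-6:
                best_loss, best_snap, since_best = loss, self._snapshot(), 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        self._restore(best_snap)
        return self

    def decision_logits(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float), train=False)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.decision_logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)
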