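"""Feedforward network with parallel synapses between hidden and output layers.

A two-layer fully connected classifier: linear synapses from inputs to a
Softplus hidden layer (with batch normalization of the hidden layer's
pre-activations), and either M sigmoidal parallel synapses per hidden→output
connection or single nonnegative linear synapses (the parameter-matched
comparison). Both variants keep the hidden→output map coordinatewise
monotone, mirroring the excitatory constraint of the single-neuron models.

Implemented in plain numpy with manual backpropagation and an Adam
optimizer; optionally consumes MNIST IDX files, but all tests run on the
synthetic generators below.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "Network",
    "count_parameters",
    "train_network",
    "synthetic_blobs",
    "synthetic_stripes",
    "load_mnist_idx",
]

_BN_EPS = 1e-5


@dataclass(frozen=True)
class NetworkSpec:
    d_in: int = 784
    d_hidden: int = 20
    d_out: int = 10
    synapse_mode: str = "parallel"  # or "linear_nonneg"
    n_synapses: int = 3  # M; ignored in linear mode

    def __post_init__(self) -> None:
        if min(self.d_in, self.d_hidden, self.d_out) < 1:
            raise ValueError("layer sizes must be positive")
        if self.synapse_mode not in ("parallel", "linear_nonneg"):
            raise ValueError(f"unknown synapse_mode {self.synapse_mode!r}")
        if self.synapse_mode == "parallel" and self.n_synapses < 1:
            raise ValueError("n_synapses must be positive")


def count_parameters(spec: NetworkSpec) -> int:
    """Closed-form count of learnable values, biases included.

    parallel:     (D_in+1)·D_hidden + (3M·D_hidden + 1)·D_out
    linear_nonneg:(D_in+1)·D_hidden + (D_hidden + 1)·D_out
    """
    base = (spec.d_in + 1) * spec.d_hidden
    if spec.synapse_mode == "parallel":
        return base + (3 * spec.n_synapses * spec.d_hidden + 1) * spec.d_out
    return base + (spec.d_hidden + 1) * spec.d_out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class Network:
    """Two-layer network; ``params`` holds exactly the learnable arrays."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        H, K = spec.d_hidden, spec.d_out
        self.params: dict[str, np.ndarray] = {
            "W1": rng.normal(0.0, 1.0 / np.sqrt(spec.d_in), size=(spec.d_in, H)),
            "b1": np.zeros(H),
            "b2": np.zeros(K),
        }
        if spec.synapse_mode == "parallel":
            M = spec.n_synapses
            self.params["amp_root"] = rng.uniform(0.1, 0.5, size=(H, K, M))
            self.params["slope"] = rng.uniform(1.0, 4.0, size=(H, K, M))
            self.params["thr"] = rng.uniform(0.1, 2.2, size=(H, K, M))
        else:
            self.params["W2"] = rng.uniform(0.0, 1.0 / np.sqrt(H), size=(H, K))
        # batch-norm running statistics (not learnable, not counted)
        self.run_mean = np.zeros(H)
        self.run_var = np.ones(H)

    # -- forward -----------------------------------------------------------
    def _hidden(self, X: np.ndarray, train: bool):
        u = X @ self.params["W1"] + self.params["b1"]
        if train:
            mean, var = u.mean(axis=0), u.var(axis=0)
            self.run_mean = 0.9 * self.run_mean + 0.1 * mean
            self.run_var = 0.9 * self.run_var + 0.1 * var
        else:
            mean, var = self.run_mean, self.run_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        u_hat = (u - mean) * inv_std
        h = _softplus(u_hat)
        return u_hat, inv_std, h

    def _output(self, h: np.ndarray):
        """Scores plus the synapse intermediates needed for backprop."""
        if self.spec.synapse_mode == "parallel":
            amp, slope, thr = (
                self.params["amp_root"],
                self.params["slope"],
                self.params["thr"],
            )
            sig = _sigmoid(slope[None] * (h[:, :, None, None] - thr[None]))
            scores = (amp[None] ** 2 * sig).sum(axis=(1, 3)) + self.params["b2"]
            return scores, sig
        scores = h @ self.params["W2"] + self.params["b2"]
        return scores, None

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Class scores for a batch of input rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            raise ValueError("batch must be nonempty")
        if X.shape[1] != self.spec.d_in:
            raise ValueError(
                f"expected {self.spec.d_in} input features, got {X.shape[1]}"
            )
        _, _, h = self._hidden(X, train)
        scores, _ = self._output(h)
        return scores

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._hidden(X, train=False)[2]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(X), axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def n_learnable_values(self) -> int:
        """Enumeration cross-check for :func:`count_parameters`."""
        return int(sum(p.size for p in self.params.values()))

    # -- backward ----------------------------------------------------------
    def _grads(self, X: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
        B = X.shape[0]
        u_hat, inv_std, h = self._hidden(X, train=True)
        scores, sig = self._output(h)

        shifted = scores - scores.max(axis=1, keepdims=True)
        expo = np.exp(shifted)
        probs = expo / expo.sum(axis=1, keepdims=True)
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-300)))
        dscores = probs.copy()
        dscores[np.arange(B), y] -= 1.0
        dscores /= B

        grads: dict[str, np.ndarray] = {"b2": dscores.sum(axis=0)}
        if self.spec.synapse_mode == "parallel":
            amp, slope, thr = (
                self.params["amp_root"],
                self.params["slope"],
                self.params["thr"],
            )
            ds = dscores[:, None, :, None]  # (B,1,K,1)
            core = (amp[None] ** 2) * sig * (1.0 - sig)  # dr/d(pre-sigmoid)
            grads["amp_root"] = (ds * 2.0 * amp[None] * sig).sum(axis=0)
            grads["slope"] = (
                ds * core * (h[:, :, None, None] - thr[None])
            ).sum(axis=0)
            grads["thr"] = (-ds * core * slope[None]).sum(axis=0)
            dh = (ds * core * slope[None]).sum(axis=(2, 3))
        else:
            grads["W2"] = h.T @ dscores
            dh = dscores @ self.params["W2"].T

        du_hat = dh * _sigmoid(u_hat)  # softplus' = sigmoid
        # batch-norm backward (no affine parameters)
        du = (inv_std / B) * (
            B * du_hat
            - du_hat.sum(axis=0)
            - u_hat * (du_hat * u_hat).sum(axis=0)
        )
        grads["W1"] = X.T @ du
        grads["b1"] = du.sum(axis=0)
        return loss, grads

    def _project(self) -> None:
        if self.spec.synapse_mode == "parallel":
            np.maximum(self.params["slope"], 0.0, out=self.params["slope"])
        else:
            np.maximum(self.params["W2"], 0.0, out=self.params["W2"])


def train_network(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 50,
    batch_size: int = 128,
    lr: float = 1e-3,
    seed: int = 0,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> dict:
    """Minimize softmax cross-entropy with Adam; enforce monotonicity.

    Slopes (parallel mode) or hidden→output weights (linear mode) are
    projected to be nonnegative after every optimizer step. Returns a
    history dict with per-epoch mean loss, train accuracy and — when test
    data is supplied — test accuracy. Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.min() < 0 or y.max() >= net.spec.d_out:
        raise ValueError("labels must lie in 0..d_out-1")
    if epochs < 1:
        raise ValueError("epochs must be positive")
    rng = np.random.default_rng(seed)
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(p) for k, p in net.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: dict[str, list] = {"loss": [], "train_acc": []}
    if X_test is not None:
        history["test_acc"] = []
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            batch = order[start : start + batch_size]
            loss, grads = net._grads(X[batch], y[batch])
            losses.append(loss)
            step += 1
            for key, g in grads.items():
                m[key] = beta1 * m[key] + (1 - beta1) * g
                v[key] = beta2 * v[key] + (1 - beta2) * g * g
                m_hat = m[key] / (1 - beta1**step)
                v_hat = v[key] / (1 - beta2**step)
                net.params[key] -= lr * m_hat / (np.sqrt(v_hat) + eps)
            net._project()
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(net.accuracy(X, y))
        if X_test is not None:
            history["test_acc"].append(net.accuracy(X_test, y_test))
    return history


# -- synthetic fixtures ----------------------------------------------------

def synthetic_blobs(
    n: int, d_in: int = 4, n_classes: int = 2, separation: float = 4.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian clusters, one per class, linearly separable for large separation.

    Class k's center sits at `separation` along axis k (mod d_in), so centers
    are at least separation·√2 apart for n_classes ≤ d_in.
    """
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_classes, d_in))
    for k in range(n_classes):
        centers[k, k % d_in] = separation * (1 + k // d_in)
    y = rng.integers(0, n_classes, size=n)
    X = centers[y] + rng.normal(size=(n, d_in))
    return X, y


def synthetic_stripes(
    n: int, side: int = 8, n_classes: int = 2, noise: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Digit-like striped bitmaps: class k has stripes of period k+2.

    Class 0 stripes run horizontally, odd classes vertically, with
    increasing spatial frequency; pixels carry additive Gaussian noise.
    Flattened to rows of length side².
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, size=n)
    rows = np.arange(side)
    X = np.empty((n, side * side))
    for k in range(n_classes):
        period = 2 + k // 2
        stripe = (rows // period) % 2
        if k % 2 == 0:
            img = np.tile(stripe[:, None], (1, side)).astype(float)
        else:
            img = np.tile(stripe[None, :], (side, 1)).astype(float)
        mask = y == k
        X[mask] = img.ravel()[None, :]
    X += noise * rng.normal(size=X.shape)
    return X, y


# -- optional MNIST IDX reading -------------------------------------------

def _read_idx(path: str) -> np.ndarray:
    with open(path, "rb") as fh:
        zero, dtype_code, ndim = struct.unpack(">HBB", fh.read(4))
        if zero != 0:
            raise ValueError(f"{path}: not an IDX file")
        shape = struct.unpack(">" + "I" * ndim, fh.read(4 * ndim))
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    return data.reshape(shape)


def load_mnist_idx(directory: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Load the four standard MNIST IDX files from a directory.

    Returns (X_train, y_train, X_test, y_test) with images flattened to
    float rows in [0, 1]. Raises FileNotFoundError if the files are absent.
    """
    names = {
        "X_train": "train-images-idx3-ubyte",
        "y_train": "train-labels-idx1-ubyte",
        "X_test": "t10k-images-idx3-ubyte",
        "y_test": "t10k-labels-idx1-ubyte",
    }
    arrays = {}
    for key, name in names.items():
        path = os.path.join(directory, name)
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        arrays[key] = _read_idx(path)
    X_train = arrays["X_train"].reshape(len(arrays["X_train"]), -1) / 255.0
    X_test = arrays["X_test"].reshape(len(arrays["X_test"]), -1) / 255.0
    return X_train, arrays["y_train"].astype(int), X_test, arrays["y_test"].astype(int)
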