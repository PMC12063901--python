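"""Sign-constrained (nonnegative-weight) perceptron baseline.

The comparison model: linear synapses of nonnegative efficacy and a
step-function soma. Trained with the classical margin-perceptron rule plus a
projection to the nonnegative orthant after every update. Its asymptotic
classification capacity P*/N is 1, which is the quantitative benchmark the
parallel-synapse models are measured against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from parsyn.tasks import PatternSet

__all__ = [
    "SignConstrainedPerceptron",
    "train_perceptron",
    "perceptron_capacity_reference",
]


@dataclass(frozen=True)
class SignConstrainedPerceptron:
    weights: np.ndarray
    bias_threshold: float
    margin: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("weights must be a vector")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "bias_threshold", float(self.bias_threshold))

    def decision(self, inputs: np.ndarray) -> np.ndarray:
        inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
        return inputs @ self.weights - self.bias_threshold

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return np.where(self.decision(inputs) > 0, 1.0, -1.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "perceptron",
                "weights": self.weights.tolist(),
                "bias_threshold": self.bias_threshold,
                "margin": self.margin,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SignConstrainedPerceptron":
        doc = json.loads(text)
        return cls(np.asarray(doc["weights"]), doc["bias_threshold"], doc["margin"])


def train_perceptron(
    ps: PatternSet,
    max_epochs: int = 10000,
    margin: float = 0.0,
    eta: float = 0.01,
    seed: int = 0,
) -> tuple[SignConstrainedPerceptron, bool]:
    """Margin-perceptron training with nonnegative-orthant projection.

    Sweeps the patterns in a seed-shuffled order each epoch; on every pattern
    violating y·(w·x − θ) > margin it applies w ← max(w + η·y·x, 0) and
    θ ← θ − η·y. Success means all patterns strictly correctly classified at
    the end of some sweep.
    """
    if max_epochs < 1:
        raise ValueError("max_epochs must be positive")
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    rng = np.random.default_rng(seed)
    X, y = ps.inputs, ps.labels
    P, N = X.shape
    w = np.zeros(N)
    theta = 0.0
    success = False
    chunk = 128  # vectorized fast path; update order is still strictly sequential
    for _ in range(max_epochs):
        order = rng.permutation(P)
        updated = False
        for start in range(0, P, chunk):
            idx = order[start : start + chunk]
            # a chunk with no violator under the current weights triggers no
            # update, so skipping it wholesale preserves the exact sequential
            # sweep trajectory
            if np.all(y[idx] * (X[idx] @ w - theta) > margin):
                continue
            for mu in idx:
                if y[mu] * (X[mu] @ w - theta) <= margin:
                    w += eta * y[mu] * X[mu]
                    np.maximum(w, 0.0, out=w)
                    theta -= eta * y[mu]
                    updated = True
        if np.all(y * (X @ w - theta) > 0):
            success = True
            break
        if not updated:
            break  # margin met everywhere yet not strictly correct: stuck
    return SignConstrainedPerceptron(w, theta, margin), success


def perceptron_capacity_reference(n_axons: int) -> tuple[float, bool]:
    """Asymptotic capacity P*/N of the sign-constrained perceptron.

    Returns (1.0, finite_n_caveat); the caveat flags very small N where the
    asymptotic statement is a poor guide.
    """
    if n_axons < 1:
        raise ValueError("n_axons must be positive")
    return 1.0, n_axons < 50
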