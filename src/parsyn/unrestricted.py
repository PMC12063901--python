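"""Neuron with unlimited parallel synapses: monotone staircase transmission.

Each axon carries an arbitrary nondecreasing staircase transmission function
with at most one step per distinct input value (the first value pinned to 0).
For fixed per-pattern importance weights w_μ the optimal staircase for one
axon minimizes

    −Σ_α w_α y_α I_α + λ Σ_α I_α²     over 0 = I_1 ≤ I_2 ≤ … ≤ I_P,

which is solved exactly by an envelope construction: build the greatest
convex minorant of the cumulative weighted-label walk Σ_{k≤α} y_k w_k and
read the staircase values off the segment slopes (divided by 2λ), keeping
only nonnegative slopes. Classification then proceeds iteratively: solve all
axons, threshold the summed currents, and increment the weights of
misclassified patterns by one until all are correct or the iteration budget
is exhausted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from parsyn.tasks import PatternSet

__all__ = [
    "StaircaseAxon",
    "StaircaseModel",
    "ImportanceState",
    "envelope_solve",
    "axon_transmission",
    "train_unrestricted",
    "effective_synapse_count",
    "best_threshold",
]


@dataclass(frozen=True)
class StaircaseAxon:
    """One axon's staircase: sorted breakpoints with nondecreasing values.

    ``sorted_inputs[α]`` are the axon's training inputs in increasing order,
    ``order`` maps data order μ to sorted order α (``sorted_inputs =
    inputs[order]``) and ``values[α]`` is the transmission at the α-th sorted
    input. ``values`` is nonnegative, nondecreasing, starts at 0, and tied
    inputs share a single value.
    """

    sorted_inputs: np.ndarray
    order: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        si = np.asarray(self.sorted_inputs, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        order = np.asarray(self.order, dtype=int)
        if si.shape != vals.shape or si.shape != order.shape or si.ndim != 1:
            raise ValueError("sorted_inputs, order, values must be 1-D of equal length")
        if np.any(np.diff(si) < 0):
            raise ValueError("sorted_inputs must be nondecreasing")
        if np.any(np.diff(vals) < -1e-12):
            raise ValueError("values must be nondecreasing")
        if vals.size and abs(vals[0]) > 1e-12:
            raise ValueError("values[0] must be 0")
        object.__setattr__(self, "sorted_inputs", si)
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "values", vals)

    def values_in_data_order(self) -> np.ndarray:
        out = np.empty_like(self.values)
        out[self.order] = self.values
        return out


@dataclass(frozen=True)
class StaircaseModel:
    """N staircase axons plus a somatic threshold."""

    axons: list
    soma_threshold: float

    @property
    def n_axons(self) -> int:
        return len(self.axons)

    def somatic_input(self, inputs: np.ndarray) -> np.ndarray:
        inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
        if inputs.shape[1] != self.n_axons:
            raise ValueError("input width does not match number of axons")
        z = np.zeros(inputs.shape[0])
        for i, axon in enumerate(self.axons):
            z += axon_transmission(axon, inputs[:, i])
        return z

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        z = self.somatic_input(inputs)
        return np.where(z - self.soma_threshold > 0, 1.0, -1.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "unrestricted",
                "soma_threshold": self.soma_threshold,
                "axons": [
                    {
                        "sorted_inputs": ax.sorted_inputs.tolist(),
                        "order": ax.order.tolist(),
                        "values": ax.values.tolist(),
                    }
                    for ax in self.axons
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StaircaseModel":
        doc = json.loads(text)
        axons = [
            StaircaseAxon(
                np.asarray(ax["sorted_inputs"]),
                np.asarray(ax["order"]),
                np.asarray(ax["values"]),
            )
            for ax in doc["axons"]
        ]
        return cls(axons, float(doc["soma_threshold"]))


@dataclass
class ImportanceState:
    """Per-pattern integer weights driving the iterative envelope algorithm."""

    weights: np.ndarray
    iteration: int = 0


def envelope_solve(
    labels: np.ndarray,
    weights: np.ndarray,
    lam: float,
    tie_groups: np.ndarray | None = None,
) -> np.ndarray:
    """Optimal staircase values for one axon at fixed importance weights.

    `labels` and `weights` are given in sorted-input order. Returns the
    unique minimizer of −Σ w y I + λ Σ I² over nondecreasing sequences with
    I_1 = 0, computed by a single left-to-right convex-minorant stack pass
    over the cumulative walk of y·w. `tie_groups`, if given, assigns a
    nondecreasing group id to each position; tied inputs are pooled and
    share one value.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    labels = np.asarray(labels, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if labels.shape != weights.shape or labels.ndim != 1:
        raise ValueError("labels and weights must be 1-D of equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    n = labels.size
    if n == 0:
        return np.zeros(0)

    if tie_groups is None:
        gid = np.arange(n)
        counts = np.ones(n)
        walk_steps = labels * weights
    else:
        gid = np.asarray(tie_groups, dtype=int)
        if gid.shape != labels.shape or np.any(np.diff(gid) < 0):
            raise ValueError("tie_groups must be nondecreasing per position")
        gid = np.unique(gid, return_inverse=True)[1]  # compact 0..G-1
        counts = np.bincount(gid).astype(float)
        walk_steps = np.bincount(gid, weights=labels * weights)
    n_groups = counts.size

    # Greatest-convex-minorant stack pass over groups 2..G of the cumulative
    # walk; the first group is pinned at 0 and contributes no step. Each
    # block stores (total count, total walk distance); the block's value is
    # distance/(2λ·count), the slope of the corresponding envelope segment.
    blk_count: list[float] = []
    blk_dist: list[float] = []
    blk_span: list[int] = []  # number of groups merged into the block
    for g in range(1, n_groups):
        c, d, s = counts[g], walk_steps[g], 1
        # merge while the new block's mean slope does not exceed the previous
        # one's (envelope slopes must strictly increase left to right)
        while blk_count and blk_dist[-1] / blk_count[-1] >= d / c:
            c += blk_count.pop()
            d += blk_dist.pop()
            s += blk_span.pop()
        blk_count.append(c)
        blk_dist.append(d)
        blk_span.append(s)

    group_values = np.zeros(n_groups)
    pos = 1
    for c, d, s in zip(blk_count, blk_dist, blk_span):
        group_values[pos : pos + s] = max(d / (2.0 * lam * c), 0.0)
        pos += s
    return group_values[gid]


def axon_transmission(axon: StaircaseAxon, x) -> np.ndarray | float:
    """Right-continuous staircase lookup: value at the largest breakpoint ≤ x.

    Returns 0 below the smallest breakpoint and the top value above the
    largest, so evaluation at training inputs reproduces the fitted values
    exactly.
    """
    x = np.asarray(x, dtype=float)
    idx = np.searchsorted(axon.sorted_inputs, x, side="right") - 1
    vals = np.concatenate(([0.0], axon.values))
    out = vals[idx + 1]
    return float(out) if out.ndim == 0 else out


def best_threshold(z: np.ndarray, labels: np.ndarray) -> float:
    """Somatic threshold minimizing misclassifications of sign(z − θ).

    Scans the P+1 cut points of the sorted somatic sums (cuts only between
    distinct values); ties in error count break toward the smaller θ.
    Predictions use the convention sign(0) = −1.
    """
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels, dtype=float)
    order = np.argsort(z, kind="stable")
    zs, ys = z[order], labels[order]
    n = z.size
    pos_cum = np.concatenate(([0], np.cumsum(ys == 1)))
    neg_total = int((ys == -1).sum())
    # errors(k): first k predicted −1, rest +1
    ks = np.arange(n + 1)
    errors = pos_cum + (neg_total - (ks - pos_cum))
    valid = np.ones(n + 1, dtype=bool)
    valid[1:n] = zs[:-1] < zs[1:]
    errors = np.where(valid, errors, n + 1)
    k = int(np.argmin(errors))  # argmin takes the first minimum: smaller θ
    if k == 0:
        return float(zs[0] - 1.0)
    if k == n:
        return float(zs[-1])  # z − θ ≤ 0 everywhere; sign(0) = −1
    return float(0.5 * (zs[k - 1] + zs[k]))


def _tie_groups(sorted_inputs: np.ndarray) -> np.ndarray:
    """Group id per sorted position; equal inputs share a group."""
    if sorted_inputs.size == 0:
        return np.zeros(0, dtype=int)
    return np.concatenate(([0], np.cumsum(np.diff(sorted_inputs) > 0)))


def train_unrestricted(
    ps: PatternSet,
    lam: float = 0.5,
    max_iter: int = 1000,
) -> tuple[StaircaseModel, bool, int, ImportanceState]:
    """Fit staircase axons by iterative envelope solves with reweighting.

    Per iteration: solve :func:`envelope_solve` for every axon with the
    shared importance weights, set the somatic threshold by the 1-D scan of
    :func:`best_threshold`, and increment the weight of every misclassified
    pattern by exactly 1. Stops when all P patterns are correct or after
    `max_iter` reweighting rounds. Deterministic (no randomness).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be positive")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    P, N = ps.n_patterns, ps.n_axons
    orders = [np.argsort(ps.inputs[:, i], kind="stable") for i in range(N)]
    sorted_inputs = [ps.inputs[orders[i], i] for i in range(N)]
    groups = [_tie_groups(si) for si in sorted_inputs]

    weights = np.ones(P)
    model = None
    iterations = 0
    success = False
    for iteration in range(1, max_iter + 1):
        iterations = iteration
        z = np.zeros(P)
        axons = []
        for i in range(N):
            vals = envelope_solve(
                ps.labels[orders[i]], weights[orders[i]], lam, groups[i]
            )
            axons.append(StaircaseAxon(sorted_inputs[i], orders[i], vals))
            z[orders[i]] += vals
        theta = best_threshold(z, ps.labels)
        model = StaircaseModel(axons, theta)
        # correctness under the declared tie-break sign(0) = −1
        wrong = np.where(z - theta > 0, 1.0, -1.0) != ps.labels
        if not wrong.any():
            success = True
            break
        weights[wrong] += 1.0

    state = ImportanceState(weights=weights, iteration=iterations)
    return model, success, iterations, state


def effective_synapse_count(axon: StaircaseAxon, ratio: float = 1e-3) -> int:
    """Number of staircase steps larger than `ratio` × the axon's biggest step.

    A step is one increment ΔI between consecutive sorted values; flat axons
    have no steps and count 0.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    steps = np.diff(axon.values)
    if steps.size == 0:
        return 0
    max_step = steps.max()
    if max_step <= 0:
        return 0
    return int((steps > ratio * max_step).sum())
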