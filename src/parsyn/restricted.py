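"""Neuron with a fixed number M of sigmoidal parallel synapses per axon.

Each synapse transmits ``a² · σ(s·(x − t))`` of its axon's input x, with
learnable amplitude root a, nonnegative slope s and threshold t. The somatic
current is the sum over all N axons and M synapses; the prediction is
``sign(z − θ)``. Training minimizes a hinge loss with margin ε by full-batch
gradient descent over the violating set, with a periodic "resurrection" sweep
that revives synapses whose amplitude has collapsed (and with it their
gradient).

Internally training uses the hyperbolic-tangent parameterization
``a² · tanh(s·(x − t))``, which is centered around zero and therefore easier
on the somatic threshold; :func:`to_sigmoid_form` maps a trained tanh-form
neuron to the equivalent sigmoid-form one for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from parsyn.tasks import PatternSet

__all__ = [
    "RestrictedNeuron",
    "TrainConfig",
    "synapse_response",
    "somatic_input",
    "predict",
    "hinge_loss",
    "violating_set",
    "gradient_step",
    "resurrect_synapses",
    "train_restricted",
    "to_sigmoid_form",
    "initialize_neuron",
]


@dataclass(frozen=True)
class RestrictedNeuron:
    """Parameter triplets for N axons × M synapses plus a somatic threshold.

    ``amp_root[i, j]`` is the square root of synapse (i, j)'s amplitude;
    the effective amplitude is its square, so amplitudes are nonnegative by
    construction. ``param_form`` selects the transmission nonlinearity:
    ``"sigmoid"`` gives ``a²·σ(s(x−t))``, ``"tanh"`` gives ``a²·tanh(s(x−t))``.
    """

    amp_root: np.ndarray
    slope: np.ndarray
    threshold: np.ndarray
    soma_threshold: float
    param_form: str = "sigmoid"

    def __post_init__(self) -> None:
        amp = np.asarray(self.amp_root, dtype=float)
        slope = np.asarray(self.slope, dtype=float)
        thr = np.asarray(self.threshold, dtype=float)
        if amp.ndim != 2 or slope.shape != amp.shape or thr.shape != amp.shape:
            raise ValueError("amp_root, slope, threshold must share shape (N, M)")
        if np.any(slope < 0):
            raise ValueError("slopes must be nonnegative")
        if self.param_form not in ("sigmoid", "tanh"):
            raise ValueError(f"unknown param_form {self.param_form!r}")
        object.__setattr__(self, "amp_root", amp)
        object.__setattr__(self, "slope", slope)
        object.__setattr__(self, "threshold", thr)
        object.__setattr__(self, "soma_threshold", float(self.soma_threshold))

    @property
    def n_axons(self) -> int:
        return self.amp_root.shape[0]

    @property
    def n_synapses(self) -> int:
        """Parallel synapses per axon (M)."""
        return self.amp_root.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "restricted",
                "n_axons": self.n_axons,
                "n_synapses": self.n_synapses,
                "param_form": self.param_form,
                "amp_root": self.amp_root.ravel().tolist(),
                "slope": self.slope.ravel().tolist(),
                "threshold": self.threshold.ravel().tolist(),
                "soma_threshold": self.soma_threshold,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RestrictedNeuron":
        doc = json.loads(text)
        shape = (doc["n_axons"], doc["n_synapses"])
        return cls(
            amp_root=np.asarray(doc["amp_root"]).reshape(shape),
            slope=np.asarray(doc["slope"]).reshape(shape),
            threshold=np.asarray(doc["threshold"]).reshape(shape),
            soma_threshold=doc["soma_threshold"],
            param_form=doc["param_form"],
        )


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the hinge-loss gradient training loop.

    The four learning rates are deliberately unequal: threshold gradients
    scale with the (large) slopes and need a small rate, while slopes
    themselves receive tiny gradients once the nonlinearity saturates and
    need a large one. `decay_tau` applies a 1/(1 + epoch/τ) schedule to all
    rates; memorization at high load is a subgradient problem and does not
    converge exactly under constant steps.
    """

    margin: float = 0.1
    eta_amp: float = 1e-3
    eta_slope: float = 3e-2
    eta_threshold: float = 1e-4
    eta_soma: float = 1e-3
    max_epochs: int = 100000
    resurrection_period: int = 100
    amp_floor: float = 0.01
    decay_tau: float | None = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        for eta in (self.eta_amp, self.eta_slope, self.eta_threshold, self.eta_soma):
            if eta <= 0:
                raise ValueError("learning rates must be positive")
        if self.max_epochs < 1 or self.resurrection_period < 1:
            raise ValueError("epoch counts must be positive")
        if self.amp_floor <= 0:
            raise ValueError("amp_floor must be positive")
        if self.decay_tau is not None and self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive or None")


def synapse_response(a: float, s: float, t: float, x) -> np.ndarray | float:
    """Single sigmoid-form synapse: ``a² · σ(s·(x − t))``, in [0, a²]."""
    if s < 0:
        raise ValueError("slope must be nonnegative")
    x = np.asarray(x, dtype=float)
    out = (a * a) / (1.0 + np.exp(-s * (x - t)))
    return float(out) if out.ndim == 0 else out


def _responses(neuron: RestrictedNeuron, inputs: np.ndarray) -> np.ndarray:
    """Per-synapse responses, shape (P, N, M)."""
    u = neuron.slope[None] * (inputs[:, :, None] - neuron.threshold[None])
    amp = neuron.amp_root[None] ** 2
    if neuron.param_form == "sigmoid":
        return amp / (1.0 + np.exp(-u))
    return amp * np.tanh(u)


def somatic_input(neuron: RestrictedNeuron, ps: PatternSet) -> np.ndarray:
    """Total current into the soma, z_μ = Σ_i Σ_j h_ij(x_iμ), length P."""
    if ps.n_axons != neuron.n_axons:
        raise ValueError(
            f"pattern set has {ps.n_axons} axons, neuron expects {neuron.n_axons}"
        )
    return _responses(neuron, ps.inputs).sum(axis=(1, 2))


def predict(neuron: RestrictedNeuron, ps: PatternSet) -> np.ndarray:
    """Predicted labels sign(z − θ); the tie z = θ maps to −1."""
    z = somatic_input(neuron, ps)
    return np.where(z - neuron.soma_threshold > 0, 1.0, -1.0)


def hinge_loss(z: np.ndarray, labels: np.ndarray, theta: float, margin: float) -> float:
    """Summed hinge loss Σ_μ max(0, ε − (z_μ − θ)·y_μ)."""
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if z.shape != labels.shape:
        raise ValueError("z and labels must have equal length")
    return float(np.maximum(0.0, margin - (z - theta) * labels).sum())


def violating_set(
    z: np.ndarray, labels: np.ndarray, theta: float, margin: float
) -> np.ndarray:
    """Indices Ω = {μ : ε − (z_μ − θ)·y_μ > 0} (strict inequality)."""
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if z.shape != labels.shape:
        raise ValueError("z and labels must have equal length")
    return np.flatnonzero(margin - (z - theta) * labels > 0)


def gradient_step(
    neuron: RestrictedNeuron,
    ps: PatternSet,
    cfg: TrainConfig,
    z: np.ndarray | None = None,
) -> RestrictedNeuron:
    """One full-batch gradient-descent step of the hinge loss over Ω.

    All four parameter groups are updated simultaneously from gradients
    evaluated at the pre-update parameters; slopes are clipped at zero
    afterwards. An empty violating set returns the neuron unchanged.
    A precomputed somatic input `z` (for the current parameters) may be
    passed to avoid a second forward pass.
    """
    if z is None:
        z = somatic_input(neuron, ps)
    omega = violating_set(z, ps.labels, neuron.soma_threshold, cfg.margin)
    if omega.size == 0:
        return neuron

    x = ps.inputs[omega][:, :, None]  # (|Ω|, N, 1)
    y = ps.labels[omega][:, None, None]
    a, s, t = neuron.amp_root, neuron.slope, neuron.threshold
    u = s[None] * (x - t[None])
    if neuron.param_form == "sigmoid":
        sig = 1.0 / (1.0 + np.exp(-u))
        dz_da = 2.0 * a[None] * sig
        core = (a[None] ** 2) * sig * (1.0 - sig)  # dh/du
    else:
        tau = np.tanh(u)
        dz_da = 2.0 * a[None] * tau
        core = (a[None] ** 2) * (1.0 - tau * tau)
    dz_ds = core * (x - t[None])
    dz_dt = -core * s[None]

    # descent on L: param += η · Σ_Ω y · ∂z/∂param ; θ −= η · Σ_Ω y
    new_a = a + cfg.eta_amp * (y * dz_da).sum(axis=0)
    new_s = s + cfg.eta_slope * (y * dz_ds).sum(axis=0)
    new_t = t + cfg.eta_threshold * (y * dz_dt).sum(axis=0)
    new_theta = neuron.soma_threshold - cfg.eta_soma * float(ps.labels[omega].sum())
    return RestrictedNeuron(
        amp_root=new_a,
        slope=np.maximum(new_s, 0.0),
        threshold=new_t,
        soma_threshold=new_theta,
        param_form=neuron.param_form,
    )


def _edge_biased_thresholds(
    rng: np.random.Generator, size: int, input_range: tuple[float, float]
) -> np.ndarray:
    """Thresholds concentrated near both edges of the input range: Beta(½, ½)."""
    lo, hi = input_range
    return lo + (hi - lo) * rng.beta(0.5, 0.5, size=size)


def resurrect_synapses(
    neuron: RestrictedNeuron,
    amp_floor: float,
    input_range: tuple[float, float],
    seed: int | np.random.Generator = 0,
) -> RestrictedNeuron:
    """Revive synapses whose amplitude (a²) fell below `amp_floor`.

    Their amplitude is raised to exactly `amp_floor` and their threshold is
    resampled from an edge-biased distribution over `input_range`; all other
    synapses are untouched. Near-zero amplitudes stall every gradient of the
    synapse, so without this sweep such synapses stay dead forever.
    """
    if amp_floor <= 0:
        raise ValueError("amp_floor must be positive")
    lo, hi = input_range
    if not hi > lo:
        raise ValueError("input_range must be a nonempty interval")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dead = neuron.amp_root**2 < amp_floor
    if not dead.any():
        return neuron
    amp_root = neuron.amp_root.copy()
    threshold = neuron.threshold.copy()
    amp_root[dead] = np.sqrt(amp_floor)
    threshold[dead] = _edge_biased_thresholds(rng, int(dead.sum()), input_range)
    return replace(neuron, amp_root=amp_root, threshold=threshold)


def initialize_neuron(
    n_axons: int,
    n_synapses: int,
    input_range: tuple[float, float],
    rng: np.random.Generator,
    param_form: str = "tanh",
) -> RestrictedNeuron:
    """Random starting point: nonzero amplitudes, spread slopes and thresholds.

    θ starts at the mean somatic input of a centered synapse bank (Σa²/2 in
    sigmoid form, 0 in tanh form) so the initial prediction is not stuck on
    one class.
    """
    lo, hi = input_range
    amp_root = rng.uniform(0.1, 0.5, size=(n_axons, n_synapses))
    slope = rng.uniform(5.0, 50.0, size=(n_axons, n_synapses))
    threshold = rng.uniform(lo, hi, size=(n_axons, n_synapses))
    theta = 0.0 if param_form == "tanh" else float((amp_root**2).sum()) / 2.0
    return RestrictedNeuron(amp_root, slope, threshold, theta, param_form)


def train_restricted(
    ps: PatternSet,
    n_synapses: int,
    cfg: TrainConfig | None = None,
    param_form: str = "tanh",
) -> tuple[RestrictedNeuron, bool, int]:
    """Train an M-synapse neuron on a pattern set by hinge-loss gradient descent.

    Runs :func:`gradient_step` epochs until every pattern is strictly
    correctly classified ((z − θ)·y > 0 for all μ) or `max_epochs` is
    reached; every `resurrection_period` epochs, dead synapses are revived.
    Returns ``(neuron, success, epochs_used)``. The trajectory is a
    deterministic function of (ps, n_synapses, cfg).
    """
    if n_synapses < 1:
        raise ValueError("n_synapses must be positive")
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    input_range = ps.input_range()
    neuron = initialize_neuron(ps.n_axons, n_synapses, input_range, rng, param_form)

    epochs_used = 0
    for epoch in range(1, cfg.max_epochs + 1):
        z = somatic_input(neuron, ps)
        gaps = (z - neuron.soma_threshold) * ps.labels
        if np.all(gaps > 0):
            return neuron, True, epochs_used
        if np.all(gaps >= cfg.margin):
            break  # Ω empty: loss is zero, no further updates possible
        if cfg.decay_tau is not None:
            d = 1.0 / (1.0 + epoch / cfg.decay_tau)
            step_cfg = replace(
                cfg,
                eta_amp=cfg.eta_amp * d,
                eta_slope=cfg.eta_slope * d,
                eta_threshold=cfg.eta_threshold * d,
                eta_soma=cfg.eta_soma * d,
            )
        else:
            step_cfg = cfg
        neuron = gradient_step(neuron, ps, step_cfg, z=z)
        epochs_used = epoch
        if epoch % cfg.resurrection_period == 0:
            neuron = resurrect_synapses(neuron, cfg.amp_floor, input_range, rng)

    z = somatic_input(neuron, ps)
    success = bool(np.all((z - neuron.soma_threshold) * ps.labels > 0))
    return neuron, success, epochs_used


def to_sigmoid_form(neuron: RestrictedNeuron) -> RestrictedNeuron:
    """Map a tanh-form neuron to the prediction-equivalent sigmoid form.

    Uses a²·tanh(s(x−t)) = 2a²·σ(2s(x−t)) − a², so amplitudes double
    (a² → 2a²), slopes double, thresholds are unchanged, and the somatic
    threshold absorbs the constant: θ_sigmoid = θ_tanh + Σ_ij a²_ij, which
    keeps z − θ identical on every input.
    """
    if neuron.param_form != "tanh":
        raise ValueError("to_sigmoid_form expects a tanh-form neuron")
    amp_sq = neuron.amp_root**2
    return RestrictedNeuron(
        amp_root=np.sqrt(2.0) * neuron.amp_root,
        slope=2.0 * neuron.slope,
        threshold=neuron.threshold.copy(),
        soma_threshold=neuron.soma_threshold + float(amp_sq.sum()),
        param_form="sigmoid",
    )
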