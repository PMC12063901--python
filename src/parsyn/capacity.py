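"""Classification-capacity estimation protocol.

For a given model family and axon count N, the success rate of training
(classifying *all* P patterns correctly) is estimated on a grid of loads
P/N with several independent random tasks per load. A decreasing logistic
pinned to the range [0, 1] is least-squares fitted to rate vs load; the
capacity P*/N is the load at which the fitted success rate crosses 50%.
Confidence intervals come from refitting on random half-samples of the
trials at every load and taking the standard deviation of the refitted
crossings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from parsyn.perceptron import train_perceptron
from parsyn.restricted import TrainConfig, train_restricted
from parsyn.tasks import generate_patterns, task_seed
from parsyn.unrestricted import train_unrestricted

__all__ = [
    "SuccessGrid",
    "CapacityEstimate",
    "CapacityFitError",
    "run_success_grid",
    "fit_capacity",
    "bootstrap_capacity",
    "auto_load_grid",
]

_MODEL_TAGS = ("restricted", "unrestricted", "perceptron")


class CapacityFitError(RuntimeError):
    """Raised when the success grid does not bracket the 50% crossing."""


@dataclass(frozen=True)
class SuccessGrid:
    """Boolean training outcomes for each load on a P/N grid."""

    load_values: np.ndarray
    trials: list  # list (per load) of lists of bools
    trial_seeds: list  # parallel structure of per-trial task seeds
    model_tag: str
    n_axons: int
    n_synapses: int | None = None  # M, restricted model only

    def __post_init__(self) -> None:
        loads = np.asarray(self.load_values, dtype=float)
        if loads.ndim != 1 or np.any(np.diff(loads) <= 0):
            raise ValueError("load_values must be strictly increasing")
        if len(self.trials) != loads.size or any(len(t) < 1 for t in self.trials):
            raise ValueError("every load needs at least one trial")
        object.__setattr__(self, "load_values", loads)

    def success_rates(self) -> np.ndarray:
        return np.array([np.mean(t) for t in self.trials])

    def to_json(self) -> str:
        return json.dumps(
            {
                "load_values": self.load_values.tolist(),
                "trials": [[bool(b) for b in t] for t in self.trials],
                "trial_seeds": self.trial_seeds,
                "model_tag": self.model_tag,
                "n_axons": self.n_axons,
                "n_synapses": self.n_synapses,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SuccessGrid":
        doc = json.loads(text)
        return cls(
            np.asarray(doc["load_values"]),
            doc["trials"],
            doc["trial_seeds"],
            doc["model_tag"],
            doc["n_axons"],
            doc.get("n_synapses"),
        )


@dataclass(frozen=True)
class CapacityEstimate:
    """Fitted 50% crossing P*/N with resampling spread."""

    load_star: float
    ci_std: float
    n_resamples: int
    fit_params: tuple  # (location c, scale b) of the logistic
    resample_values: np.ndarray | None = None


def _run_one_trial(
    model_tag: str,
    n_axons: int,
    n_patterns: int,
    seed: int,
    distribution: str,
    n_synapses: int | None,
    train_config: TrainConfig | None,
    lam: float,
    max_iter: int,
    perceptron_epochs: int,
) -> bool:
    ps = generate_patterns(n_axons, n_patterns, distribution, seed)
    if model_tag == "restricted":
        cfg = train_config or TrainConfig()
        # per-trial seed also drives initialization / resurrection draws
        cfg = replace(cfg, seed=seed)
        _, success, _ = train_restricted(ps, n_synapses or 1, cfg)
    elif model_tag == "unrestricted":
        _, success, _, _ = train_unrestricted(ps, lam=lam, max_iter=max_iter)
    elif model_tag == "perceptron":
        _, success = train_perceptron(ps, max_epochs=perceptron_epochs, seed=seed)
    else:
        raise ValueError(f"unknown model_tag {model_tag!r}")
    return bool(success)


def run_success_grid(
    model_tag: str,
    n_axons: int,
    loads,
    trials_per_load: int = 5,
    seed: int = 0,
    n_synapses: int | None = None,
    train_config: TrainConfig | None = None,
    distribution: str = "uniform01",
    lam: float = 0.5,
    max_iter: int = 1000,
    perceptron_epochs: int = 10000,
) -> SuccessGrid:
    """Train `trials_per_load` independent tasks at every load P/N.

    Each trial's task seed is derived from (seed, global trial index), so any
    single trial can be replayed in isolation. All randomness flows from
    `seed`.
    """
    if model_tag not in _MODEL_TAGS:
        raise ValueError(f"unknown model_tag {model_tag!r}")
    loads = np.asarray(loads, dtype=float)
    if np.any(loads <= 0):
        raise ValueError("loads must be positive")
    if trials_per_load < 1:
        raise ValueError("trials_per_load must be positive")
    trials: list[list[bool]] = []
    trial_seeds: list[list[int]] = []
    counter = 0
    for load in loads:
        n_patterns = max(1, int(round(load * n_axons)))
        outcomes, seeds_here = [], []
        for _ in range(trials_per_load):
            ts = task_seed(seed, counter)
            counter += 1
            outcomes.append(
                _run_one_trial(
                    model_tag,
                    n_axons,
                    n_patterns,
                    ts,
                    distribution,
                    n_synapses,
                    train_config,
                    lam,
                    max_iter,
                    perceptron_epochs,
                )
            )
            seeds_here.append(ts)
        trials.append(outcomes)
        trial_seeds.append(seeds_here)
    return SuccessGrid(loads, trials, trial_seeds, model_tag, n_axons, n_synapses)


def _fit_logistic(loads: np.ndarray, rates: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of rate = 1/(1 + exp((load − c)/b)), b > 0."""
    if not (np.any(rates > 0.5) and np.any(rates < 0.5)):
        raise CapacityFitError(
            "success rates do not bracket 0.5: "
            f"rates={rates.tolist()} at loads={loads.tolist()}"
        )
    c0 = float(loads[np.argmin(np.abs(rates - 0.5))])
    b0 = max(float(loads[-1] - loads[0]) / 4.0, 1e-3)

    def resid(params):
        c, b = params
        return 1.0 / (1.0 + np.exp(np.clip((loads - c) / b, -500, 500))) - rates

    sol = least_squares(
        resid,
        x0=[c0, b0],
        bounds=([loads[0] - (loads[-1] - loads[0]), 1e-9], [2 * loads[-1], np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    c, b = sol.x
    return float(c), float(b)


def fit_capacity(grid: SuccessGrid) -> CapacityEstimate:
    """Fit the decreasing logistic and return its 50% crossing as P*/N."""
    c, b = _fit_logistic(grid.load_values, grid.success_rates())
    return CapacityEstimate(load_star=c, ci_std=0.0, n_resamples=0, fit_params=(c, b))


def bootstrap_capacity(
    grid: SuccessGrid, n_resamples: int = 100, seed: int = 0
) -> CapacityEstimate:
    """Half-sample resampling CI for the capacity estimate.

    For each of `n_resamples` rounds, half of the trials at every load are
    drawn without replacement, the logistic is refitted and its crossing
    recorded. Returns the mean crossing and the standard deviation across
    rounds as `ci_std`. Rounds whose half-sample fails to bracket 0.5 are
    redrawn (up to a cap) so that exactly `n_resamples` values are recorded.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be positive")
    if any(len(t) < 2 for t in grid.trials):
        raise ValueError("every load needs at least 2 trials for resampling")
    rng = np.random.default_rng(seed)
    loads = grid.load_values
    values = []
    attempts = 0
    max_attempts = 100 * n_resamples
    while len(values) < n_resamples:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityFitError(
                "could not obtain enough bracketing half-samples; "
                "add trials or widen the load grid"
            )
        rates = np.empty(loads.size)
        for k, outcomes in enumerate(grid.trials):
            half = max(1, len(outcomes) // 2)
            pick = rng.choice(len(outcomes), size=half, replace=False)
            rates[k] = np.mean([outcomes[p] for p in pick])
        try:
            c, _ = _fit_logistic(loads, rates)
        except CapacityFitError:
            continue
        values.append(c)
    values = np.asarray(values)
    full = fit_capacity(grid)
    return CapacityEstimate(
        load_star=float(values.mean()),
        ci_std=float(values.std()),
        n_resamples=n_resamples,
        fit_params=full.fit_params,
        resample_values=values,
    )


def auto_load_grid(
    model_tag: str,
    n_axons: int,
    seed: int = 0,
    pilot_trials: int = 3,
    n_points: int = 5,
    start_load: float = 1.0,
    max_doublings: int = 12,
    **trial_kwargs,
) -> np.ndarray:
    """Bracket the 50% crossing by doubling/halving P, then lay a grid.

    Runs small pilot batches at geometrically spaced loads until one load
    succeeds in more than half the pilots and a larger one succeeds in at
    most half, then returns `n_points` geometrically spaced loads spanning
    the bracket with margin.
    """
    lo = hi = None
    load = start_load
    for k in range(max_doublings):
        grid = run_success_grid(
            model_tag, n_axons, [load], pilot_trials, task_seed(seed, 10_000 + k),
            **trial_kwargs,
        )
        rate = grid.success_rates()[0]
        if rate > 0.5:
            lo = load
            load *= 2.0
            if hi is not None:
                break
        else:
            hi = load
            load /= 2.0
            if lo is not None:
                break
        if lo is not None and hi is not None:
            break
    if lo is None or hi is None:
        raise CapacityFitError("pilot bracketing failed; adjust start_load")
    lo, hi = min(lo, hi), max(lo, hi)
    return np.geomspace(0.75 * lo, 1.25 * hi, n_points)
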