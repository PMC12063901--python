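"""Post-training diagnostics of learned synapse populations.

Reconstructs the descriptive views used to characterize trained neurons:
per-axon aggregate transmission functions, amplitude and threshold
histograms with per-bin mean amplitudes, and input-dependent effective
synaptic weights (aggregate response divided by the input value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from parsyn.restricted import RestrictedNeuron, _responses
from parsyn.unrestricted import StaircaseModel, axon_transmission

__all__ = [
    "AggregateFunction",
    "aggregate_function",
    "amplitude_threshold_profile",
    "effective_weight_profile",
    "default_grid",
]


@dataclass(frozen=True)
class AggregateFunction:
    """One axon's summed transmission evaluated on a grid."""

    axon_index: int
    eval_grid: np.ndarray
    values: np.ndarray
    normalized: bool
    degenerate: bool = False  # all-flat axon: normalization skipped


def default_grid(input_range: tuple[float, float], n_points: int = 201) -> np.ndarray:
    lo, hi = input_range
    return np.linspace(lo, hi, n_points)


def _axon_aggregate(model, axon: int, grid: np.ndarray) -> np.ndarray:
    if isinstance(model, RestrictedNeuron):
        fake_inputs = np.zeros((grid.size, model.n_axons))
        fake_inputs[:, axon] = grid
        return _responses(model, fake_inputs)[:, axon, :].sum(axis=1)
    if isinstance(model, StaircaseModel):
        return np.asarray(axon_transmission(model.axons[axon], grid))
    raise TypeError(f"unsupported model type {type(model).__name__}")


def aggregate_function(
    model, axon: int, grid, normalize: bool = False
) -> AggregateFunction:
    """Per-axon aggregate transmission (sum of parallel synapses) on a grid."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    n_axons = model.n_axons
    if not 0 <= axon < n_axons:
        raise ValueError(f"axon {axon} out of range for {n_axons} axons")
    values = _axon_aggregate(model, axon, grid)
    degenerate = False
    if normalize:
        peak = np.abs(values).max() if values.size else 0.0
        if peak > 0:
            values = values / peak
        else:
            degenerate = True
            normalize = False
    return AggregateFunction(axon, grid, values, normalize, degenerate)


def _synapse_population(model) -> tuple[np.ndarray, np.ndarray]:
    """(amplitudes, thresholds) of all synapses in the model.

    For the restricted neuron these are (a², t) of every (axon, synapse)
    pair. For the staircase model every positive step is one synapse: its
    amplitude is the step increment and its threshold the breakpoint where
    the step occurs.
    """
    if isinstance(model, RestrictedNeuron):
        return (model.amp_root**2).ravel(), model.threshold.ravel()
    if isinstance(model, StaircaseModel):
        amps, thrs = [], []
        for ax in model.axons:
            steps = np.diff(ax.values)
            where = steps > 0
            amps.append(steps[where])
            thrs.append(ax.sorted_inputs[1:][where])
        return np.concatenate(amps) if amps else np.zeros(0), (
            np.concatenate(thrs) if thrs else np.zeros(0)
        )
    raise TypeError(f"unsupported model type {type(model).__name__}")


def amplitude_threshold_profile(
    model,
    n_bins: int = 20,
    input_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bin synapse thresholds and profile amplitudes against them.

    Returns ``(bin_edges, mean_amplitude, threshold_counts, amplitude_hist)``
    with equal-width bins over `input_range`. ``mean_amplitude[k]`` is the
    mean amplitude of synapses whose threshold falls in bin k (NaN for empty
    bins). Thresholds outside the range are clipped into the edge bins so
    counts always total the synapse population.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    lo, hi = input_range
    if not hi > lo:
        raise ValueError("input_range must be a nonempty interval")
    amplitudes, thresholds = _synapse_population(model)
    edges = np.linspace(lo, hi, n_bins + 1)
    clipped = np.clip(thresholds, lo, hi)
    idx = np.clip(np.searchsorted(edges, clipped, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=amplitudes, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_amp = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    amp_hist, _ = np.histogram(
        amplitudes, bins=n_bins, range=(0.0, max(float(amplitudes.max(initial=0.0)), 1e-12))
    )
    return edges, mean_amp, counts, amp_hist


def effective_weight_profile(model, axon: int, grid) -> np.ndarray:
    """Effective synaptic weight aggregate(x)/x on a grid of positive inputs."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid entries must be positive (ratio undefined at 0)")
    agg = aggregate_function(model, axon, grid)
    return agg.values / grid
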