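"""Random binary-classification tasks used to measure capacity.

A task is a matrix of P input patterns over N axons together with ±1 labels.
Inputs are i.i.d. uniform on [0, 1] (the default benchmark) or standard
Gaussian; labels are i.i.d. equiprobable ±1, independent of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_DISTRIBUTIONS = ("uniform01", "gaussian")


@dataclass(frozen=True)
class PatternSet:
    """A P×N matrix of axonal inputs with one ±1 label per pattern.

    Attributes
    ----------
    inputs : ndarray of shape (P, N)
        Row μ holds the activities of the N axons for pattern μ.
    labels : ndarray of shape (P,)
        Entries in {+1, -1}.
    distribution_tag : str
        ``"uniform01"`` or ``"gaussian"``; records the generating law.
    seed : int
        Seed used to generate the set (0 for sets read from disk).
    """

    inputs: np.ndarray
    labels: np.ndarray
    distribution_tag: str = "uniform01"
    seed: int = 0

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        labels = np.asarray(self.labels, dtype=float)
        if inputs.ndim != 2:
            raise ValueError("inputs must be a 2-D array of shape (P, N)")
        if labels.shape != (inputs.shape[0],):
            raise ValueError(
                f"labels length {labels.shape} does not match "
                f"{inputs.shape[0]} patterns"
            )
        if not np.all(np.isin(labels, (-1.0, 1.0))):
            raise ValueError("labels must contain only +1 and -1")
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "labels", labels)

    @property
    def n_patterns(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_axons(self) -> int:
        return self.inputs.shape[1]

    def input_range(self) -> tuple[float, float]:
        """Natural input range: [0, 1] for uniform inputs, data hull otherwise."""
        if self.distribution_tag == "uniform01":
            return (0.0, 1.0)
        return (float(self.inputs.min()), float(self.inputs.max()))


def generate_patterns(
    n_axons: int,
    n_patterns: int,
    distribution: str = "uniform01",
    seed: int = 0,
) -> PatternSet:
    """Draw a random task of `n_patterns` patterns over `n_axons` axons.

    Entries are i.i.d. from the named distribution and labels are i.i.d.
    equiprobable ±1. Identical arguments yield bit-identical output.
    """
    if n_axons < 1 or n_patterns < 1:
        raise ValueError("n_axons and n_patterns must be positive")
    if distribution not in _DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {distribution!r}")
    if seed < 0:
        raise ValueError("seed must be nonnegative")
    rng = np.random.default_rng(seed)
    if distribution == "uniform01":
        inputs = rng.random((n_patterns, n_axons))
    else:
        inputs = rng.standard_normal((n_patterns, n_axons))
    labels = rng.choice([-1.0, 1.0], size=n_patterns)
    return PatternSet(inputs, labels, distribution_tag=distribution, seed=seed)


def task_seed(base_seed: int, task_index: int) -> int:
    """Derive the seed of the `task_index`-th task in a batch.

    Batch runs spawn many tasks from one base seed; each task must be
    replayable in isolation, so the per-task seed is a pure function of
    (base_seed, task_index).
    """
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(task_index,))
    return int(ss.generate_state(1, dtype=np.uint64)[0] >> 1)


class PatternFormatError(ValueError):
    """Raised when a pattern file violates the delimited-text contract."""


def write_patterns(ps: PatternSet, path) -> None:
    """Write a pattern set as CSV: N input columns plus a trailing label column."""
    with open(path, "w") as fh:
        cols = [f"x{i + 1}" for i in range(ps.n_axons)] + ["label"]
        fh.write("# " + ",".join(cols) + "\n")
        fh.write(f"# distribution={ps.distribution_tag} seed={ps.seed}\n")
        for row, label in zip(ps.inputs, ps.labels):
            vals = ",".join(repr(float(v)) for v in row)
            fh.write(f"{vals},{int(label):+d}\n")


def read_patterns(path) -> PatternSet:
    """Read a CSV pattern file written by :func:`write_patterns` (or by hand).

    Rows are N comma-separated input values followed by a ±1 label; lines
    starting with ``#`` are comments. Raises :class:`PatternFormatError`
    on ragged rows or labels outside {+1, -1}.
    """
    distribution_tag = "uniform01"
    seed = 0
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "distribution=" in line:
                    for tok in line.lstrip("# ").split():
                        key, _, val = tok.partition("=")
                        if key == "distribution":
                            distribution_tag = val
                        elif key == "seed":
                            seed = int(val)
                continue
            try:
                values = [float(tok) for tok in line.split(",")]
            except ValueError as exc:
                raise PatternFormatError(f"line {lineno}: non-numeric field") from exc
            rows.append(values)
    if not rows:
        raise PatternFormatError("file contains no data rows")
    width = len(rows[0])
    if width < 2:
        raise PatternFormatError("rows must have at least one input column and a label")
    for lineno, row in enumerate(rows, start=1):
        if len(row) != width:
            raise PatternFormatError(f"row {lineno}: expected {width} fields, got {len(row)}")
    data = np.asarray(rows, dtype=float)
    inputs, labels = data[:, :-1], data[:, -1]
    if not np.all(np.isin(labels, (-1.0, 1.0))):
        raise PatternFormatError("label column must contain only +1 and -1")
    if distribution_tag not in _DISTRIBUTIONS:
        distribution_tag = "uniform01"
    return PatternSet(inputs, labels, distribution_tag=distribution_tag, seed=seed)
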