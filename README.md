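# parsyn

Single-neuron classifiers with nonlinear **parallel synapses** and the
machinery to measure their classification capacity on random patterns.

A presynaptic axon may contact the postsynaptic neuron through several
synapses, each with its own monotone sigmoidal transmission function; the
somatic current is the plain sum over all axons and synapses and the binary
decision is a threshold on that sum. The package implements:

- **`parsyn.tasks`** — random binary classification tasks (P patterns × N
  axons, uniform-[0,1] or Gaussian inputs, ±1 labels) with CSV round-trip.
- **`parsyn.restricted`** — the neuron with a fixed number M of sigmoidal
  synapses per axon: forward evaluation, hinge-loss full-batch gradient
  training (with a slope-nonnegativity constraint and a periodic
  "resurrection" of collapsed synapses), and the exact tanh ↔ sigmoid
  parameter-form mapping.
- **`parsyn.unrestricted`** — the limiting neuron whose per-axon aggregate
  transmission is an arbitrary nondecreasing staircase. Each axon is fit by
  an exact envelope solver (greatest convex minorant of the cumulative
  weighted-label walk — equivalently a weighted nonnegative isotonic
  regression) inside an iterative importance-reweighting loop.
- **`parsyn.perceptron`** — sign-constrained (nonnegative-weight) perceptron
  baseline, asymptotic capacity P*/N = 1.
- **`parsyn.capacity`** — success-rate grids over P/N, decreasing-logistic
  fits of the 50% crossing P*/N, and half-sample resampling confidence
  intervals.
- **`parsyn.analysis`** — post-training diagnostics: aggregate transmission
  functions, amplitude/threshold histograms, effective synaptic weights.
- **`parsyn.mlp`** — a two-layer feedforward network with parallel synapses
  between hidden and output layers, a parameter-matched nonnegative-linear
  comparison net, closed-form parameter counts, and a pure-numpy Adam
  training loop. Optionally reads MNIST IDX files; fully testable on the
  built-in synthetic image generators.

## CLI

```sh
parsyn generate -n 100 -p 200 --seed 1 -o task.csv
parsyn train-restricted --patterns task.csv -m 2 -o neuron.json
parsyn train-unrestricted --patterns task.csv -o staircase.json
parsyn train-perceptron --patterns task.csv -o perceptron.json
parsyn capacity --model perceptron -n 200 --loads 0.6,0.8,1.0,1.2 --trials 10
parsyn analyze --model-file neuron.json --out-prefix report
parsyn mlp --synthetic --d-hidden 10 -m 3 --epochs 20
```

Training commands exit 0 on successful classification of all patterns and
1 otherwise.

## Notes on scale

Full capacity curves (N up to 1000) are supported by the same APIs but are
cluster-scale computations: a single restricted-neuron training run near
capacity takes on the order of 10⁵ full-batch epochs. Use
`parsyn capacity --max-epochs ...` and expect hours per (N, M) point.
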