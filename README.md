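# flamingo-ecg

A bounded continuous optimizer — the flamingo search algorithm (FSA) — and a
small ECG heartbeat-classification pipeline that the optimizer can both
*train* (searching the network's weight space directly, in place of a
gradient optimizer) and *tune* (searching a hyperparameter space). The
package is aimed at people studying swarm-intelligence metaheuristics on
biomedical signal tasks: everything is seeded, desk-scale, and reproducible
without any external download.

## The optimizer

FSA is a population metaheuristic mimicking flamingo foraging and migration.
A flock of candidate solutions `y_l ∈ R^k` evolves inside box bounds; each
iteration a random subset *forages* and the rest *emigrate*:

- **foraging** (bill-scanning + claw-locomotive), per coordinate `k`:

  `y_lk ← ( y_lk + λ1·y_sk + M2·|M1·y_dk + λ1 + y_lk| ) / R`

  with `λ1 ~ U[-1,1]`, `M1, M2 ~ N(0,1)` drawn per flamingo-coordinate,
  and the diffusion factor `R ~ χ²(q)` drawn once per flamingo;
- **emigration**, toward the best position found so far `y_d`:

  `y_lk ← y_lk + σ·(y_dk − y_lk)`, `σ ~ N(0, q)` per coordinate.

`y_s` is the current iteration's best flamingo and `y_d` ("abundance of
food") the elitist best ever evaluated, so the best-so-far fitness trace is
monotone. Positions are clipped (or reflected) back into bounds after every
move. Benchmarks shipped: 2-D Rosenbrock `f(x) = 100(x1²−x2)² + (1−x1)²`,
sphere, Rastrigin.

## The ECG pipeline

- `synthetic` — seeded generator of labeled beats (Gaussian-bump PQRST
  morphologies for the five AAMI classes N, S, V, F, Q, plus jitter and
  noise), so the whole pipeline is testable offline;
- `data` — WFDB record reading (MIT-BIH-style `.hea`/`.dat`/`.atr`,
  formats 16 and 212), AAMI EC57 symbol mapping, R-peak-centered beat
  segmentation, train-only standard scaling, stratified
  training-percentage splits;
- `cnn` — a small 1-D CNN (valid conv → ReLU → max-pool blocks, dense,
  softmax) in plain numpy with an Adam baseline trainer, plus the two FSA
  couplings (`weight_fsa`, `hyper_fsa`) and a random-search tuner baseline;
- `metrics`/`sweep` — confusion matrix, accuracy `(TP+TN)/(TP+TN+FP+FN)`,
  sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)` (macro one-vs-rest or
  binary collapse), and training-percentage / epoch sweep harnesses.

## Worked example

```python
import flamingo_ecg as fe

# 1. optimize the Rosenbrock valley
res = fe.run_fsa(fe.make_objective("rosenbrock"),
                 fe.FSAConfig(seed=3, population_size=30, max_iterations=500))
print(res.best_fitness, res.best_position)
# 0.00903877442746936 [1.09462318 1.19727672]

# 2. generate beats, split, scale, train, score
ds = fe.generate_dataset(fe.SyntheticConfig(n_per_class=30, window_length=64,
                                            noise_sd=0.05, seed=0))
train, test = fe.split_by_training_percentage(ds, 80, seed=0)
scaler = fe.fit_scaler(train)
train, test = fe.apply_scaler(train, scaler), fe.apply_scaler(test, scaler)
arch = fe.CNNArchitecture(fe.CNNHyperparams(epochs=15), ds.window_length, 5)
model = fe.train_with_adam(arch, train, seed=0)
cm = fe.confusion_matrix(test.labels, model.predict(test.beats), ds.class_names)
print(fe.compute_metrics(cm).as_percent())
# {'accuracy': 93.33, 'sensitivity': 93.33, 'specificity': 98.33}
```

The first line prints the best Rosenbrock fitness found (0 is the optimum)
and its position near `(1, 1)`; the metrics dict is the held-out test
performance in percent, macro-averaged one-vs-rest over the five beat
classes — 30 test beats total, so each misclassified beat costs about 3.3
accuracy points. Difficulty scales with `noise_sd` and the jitters.

The same pipeline runs from the shell:

```bash
flamingo-ecg generate --seed 1 --out-dir data
flamingo-ecg train --data data/beats.csv --seed 1 --out-dir model
flamingo-ecg sweep --data data/beats.csv --seed 1 --out-dir sweep
```

Every command writes a `manifest.json` (config hash, seed, version) and
bit-reproduces its outputs from `(config, seed)`.

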