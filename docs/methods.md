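# Methods

## The flamingo search algorithm

FSA maintains a flock of `P` candidate positions inside box bounds. Each
iteration the flock is randomly repartitioned: a fraction
`foraging_fraction` performs the foraging move and the remainder the
emigration move. Both moves re-evaluate the objective and update two
bookkeeping positions: `y_s`, the best member of the current population,
and `y_d`, the best position ever evaluated ("food"). `y_d` is elitist —
never replaced by a worse solution — which makes the best-so-far trace
monotone and is what `run_fsa` returns.

**Foraging** updates coordinate `k` of flamingo `l` as

```
y_lk ← ( y_lk + λ1·y_sk + M2·|M1·y_dk + λ1 + y_lk| ) / R
```

with fresh draws per flamingo-coordinate `λ1 ~ U[-1,1]` and
`M1, M2 ~ N(0,1)`, and one diffusion factor `R ~ χ²(q)` per flamingo per
iteration scaling the whole move. The intermediate "maximum distance"
`A1 = M1·y_d + λ1 + y` and "scanning range" `A2 = M2·|A1|` appear only
through the shared `M2·|·|` term; they are not independent state.

**Emigration** contracts toward the best-known position:

```
y_lk ← y_lk + σ·(y_dk − y_lk),   σ ~ N(0, q) per coordinate.
```

After either move, positions are mapped back into bounds — clipped by
default, or reflected (folded with period `2·(hi−lo)`) under
`bound_policy="reflect"`. The division by `R` can throw positions far
outside the box, so the policy is consequential and both are tested.

### Interpretation choices

The update rules above admit several readings; the ones taken here, chosen
once and frozen:

- **Divide by R.** The position update is typeset ambiguously as `(…)R`;
  we divide, matching the original formulation of the algorithm, and
  expose `divide_by_r=False` as a multiply variant for sensitivity
  analysis.
- **M1/M2 distribution.** Described both as uniform and as standard
  normal in different sentences; standard normal is the default
  (`m_distribution="uniform"` switches to `U(0,1)` draws).
- **σ's distribution.** "A Gaussian with q degrees of freedom" is not a
  distribution; we read the notation `V(0, q)` as `N(0, q)` — mean 0,
  variance q — sharing `q` with the chi-square diffusion factor.
- **Emigration target.** The emigration move is described as heading to
  the "best fitness solution for the population", which can mean the
  current iteration's best `y_s` or the best-ever `y_d`. We use `y_d`.
  The alternative was measured (20 seeds × 500 iterations, population 30)
  and gives no reliable local refinement: the per-iteration best itself
  scatters every round, and Rosenbrock reaches 1e-2 in only about half
  the runs under every `(q, foraging_fraction)` combination tried.
  Targeting `y_d` concentrates contractive emigration draws around the
  elitist incumbent and raises that to 19–20 of 20 runs while leaving the
  foraging rule untouched. Foraging keeps `y_s` as written.
- **Optimization sense.** The optimizer minimizes by default (the
  shipped Rosenbrock benchmark's interesting extremum is its minimum at
  `(1,1)`); `sense="max"` flips the comparisons.
- **λ2** is declared alongside λ1 in the source description but appears
  in no equation; it is not implemented.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `population_size` | 30 | flock size; each member costs one evaluation per iteration |
| `max_iterations` | 500 | only stopping rule (total evaluations = P·(iters+1)) |
| `foraging_fraction` | 0.4 | share of the flock foraging each iteration, membership resampled |
| `chi_square_dof` (q) | 4 | dof of R ~ χ²(q) and variance of σ |
| `bound_policy` | clip | clip or reflect out-of-bounds positions |
| `seed` | 0 | single RNG seed; identical seeds give bit-identical runs |

`q = 4` and `foraging_fraction = 0.4` were fixed by a benchmark design
study (60 seeds per setting, population 30, 500 iterations): small `q`
makes `1/R` heavy-tailed and destabilizes foraging; large `q` widens σ and
weakens emigration's contraction; fractions near 0.5 under-supply
emigration steps. At the chosen defaults the Rosenbrock-within-1e-2 and
sphere-within-1e-3 rates were 59/60 and 60/60. `R` is floored at 1e-12 to
keep the division finite.

## Synthetic beats

Each beat is a sum of Gaussian bumps `a·exp(−((t−c)/w)²/2)` on the unit
window, one bump per wave (P, Q, R, S, T where present). Class morphologies
differ the way the AAMI superclasses grossly differ on a single lead:
N has a full PQRST complex with a dominant upright R; S an early narrow R
and no P wave; V a wide, inverted, high-amplitude complex with a discordant
T; F is the mean of the N and V shapes; Q a low-amplitude broad shape.
Per-beat amplitude jitter (`1 + 0.10·z`), timing jitter (`0.02·z` window
fractions) and additive sample noise (`N(0, noise_sd)`, default 0.05 mV)
provide within-class variation. Defaults: 100 beats per class, 186-sample
windows (≈0.5 s at 360 Hz).

What the generator does *not* emulate: rhythm context (RR intervals,
preceding beats), baseline wander, electrode artifacts, class imbalance, or
inter-patient morphology shifts. Passing tests therefore demonstrate that
the pipeline's machinery is correct and that the optimizer couplings work
on a separable task — not that the classifier would reach any particular
accuracy on real ambulatory recordings. At zero noise the five classes are
separable (leave-one-out 1-NN scores 100% on the shipped configuration),
and raising `noise_sd` degrades that monotonically, which is the property
the pipeline tests lean on.

The generator can also emit a miniature WFDB record (header + 16-bit
signal + MIT-format annotations) by concatenating beats with flat gaps, so
the WFDB reader and segmenter are exercised without any download. Real
MIT-BIH records (format 212) are supported by the same reader but never
required.

## Beat acquisition and preprocessing

Annotation symbols map to AAMI EC57 superclasses as
N←{N,L,R,e,j}, S←{A,a,J,S}, V←{V,E}, F←{F}, Q←{/,f,Q}; any other symbol is
a non-beat annotation and is skipped. Windows are cut verbatim around each
annotated R peak (default 90 before, 95 after, 186 samples at 360 Hz);
beats whose window crosses a record boundary are dropped. Lead 0 (MLII in
most MIT-BIH records) is the default.

Standardization is per sample position (column-wise), population
convention (ddof = 0), fitted on the training split only and applied to
both splits; zero-variance columns fall back to `std = 1` with a warning so
constant positions become zeros. No further filtering or denoising is
applied.

Training-percentage splits are beat-wise, random, stratified by class with
per-class rounding: a class with `n_c` members contributes
`round(pct/100 · n_c)` training beats, so the total can differ from
`round(pct/100 · n)` by at most half the class count in unbalanced data.
Classes with fewer than two members degrade to unstratified assignment
with a warning.

## Classifier and the two optimizer couplings

The network is `B` conv blocks (1-D valid convolution, stride 1, ReLU,
non-overlapping max-pool dropping the remainder: `L → (L−k+1)//p`), a
flatten, one ReLU dense layer with inverted dropout during gradient
training, and a softmax output over 5 (or 2) classes. Loss is mean
cross-entropy. Weights are He-initialized, biases zero. The forward and
backward passes and the Adam update (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, bias
correction) are implemented directly in numpy; gradients are verified
against central finite differences in the test suite.

- **weight_fsa** flattens all parameters into one vector (order fixed by
  the architecture manifest; flatten/unflatten is exact) and runs FSA over
  the box `[−3, 3]^d` minimizing training cross-entropy. This is only
  honest for tiny networks, so architectures above 5 000 weights are
  refused with guidance rather than silently attempted.
- **hyper_fsa** runs FSA over a bounded hyperparameter space (filter
  count, kernel size, dense width, dropout, log₁₀ learning rate by
  default; integers are snapped on decode, all coordinates clipped, so
  decode never fails). The objective is the validation error of an
  Adam-trained candidate at a reduced epoch budget, with the inner seed
  fixed so the outer search is deterministic, and a cache keyed by the
  decoded setting avoids retraining duplicates. The winner is retrained at
  full epochs. A uniform random-search tuner with the same evaluation
  budget serves as the comparison baseline. A total-epoch ceiling
  (default 20 000) refuses runaway budgets with an estimate.

## Evaluation

Accuracy, sensitivity and specificity are binary notions; the five-class
task reports them macro one-vs-rest (per-class TP/TN/FP/FN, metrics
averaged over classes where the denominator is nonzero, with a warning
when a class is dropped) or after collapsing to normal-vs-abnormal. At
K = 2 macro and binary accuracy coincide identically; macro sensitivity
equals `(sens + spec)/2` of the positive class — the balanced accuracy —
so it matches the binary sensitivity only when sensitivity equals
specificity (as in the symmetric worked example TP=TN=9, FP=FN=1 →
0.9/0.9/0.9). Percentages are formatted to 2–3 decimals; fractions are
stored.

The sweep harness runs split → scale → train → score for each grid cell
(training percentage or epoch count × seed), records failures per cell
without aborting the sweep, and emits a long-format table plus a median
pivot.

## Problem sizes and numerical choices

The shipped studies are desk-scale by design: optimizer checks use
population 30 × 500 iterations; the weight-mode study uses a 93-weight net
on 60 noise-free two-class beats (32-sample windows), 10 seeds; the tuner
study uses 200 beats (40 per class, 64-sample windows, noise 0.1 mV), an
inner budget of 6 epochs, and 10 flamingos × 5 iterations against 50
random samples over 5 paired seeds; the training-percentage trend uses 150
noise-free beats over 5 seeds. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; reruns are bit-identical.

## Known limitations

- FSA has no step-size annealing; its local refinement comes entirely
  from contractive emigration draws around the incumbent, so very tight
  tolerances (≪1e-6 in position) need generous budgets.
- The weight-space coupling does not scale: population search in more
  than a few thousand dimensions is hopeless against gradients, which is
  why the ceiling exists and why the gradient baseline is also the inner
  trainer for hyperparameter tuning.
- Splits are beat-wise; inter-patient (record-wise) generalization, the
  harder clinical question, is out of scope for the synthetic task
  (`stratify=False` plus caller-side grouping covers the mechanics).
- The WFDB layer reads formats 16 and 212 with beat annotations only —
  enough for MIT-BIH-style records, not a general WFDB implementation.
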