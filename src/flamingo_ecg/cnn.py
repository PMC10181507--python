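"""Small 1-D convolutional beat classifier and its two flamingo-search couplings.

The network is conv blocks (valid convolution, stride 1 -> ReLU ->
non-overlapping max pool) x B, flatten, one ReLU dense layer (with inverted
dropout during gradient training), and a softmax output over the beat
classes. Three training modes are exposed:

* ``adam_baseline`` — minibatch gradient descent with Adam (the
  conventional route, also the inner trainer of the hyperparameter tuner);
* ``weight_fsa``    — the flamingo search explores the flattened
  weight vector directly, minimizing training cross-entropy;
* ``hyper_fsa``     — the flamingo search explores a bounded hyperparameter
  space, minimizing validation error of Adam-trained candidates.

Everything is plain numpy; the architectures this package targets are tiny
(hundreds to a few thousand weights), which is also the regime where
population search over raw weights is honest at all.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np

from .data import BeatDataset
from .fsa import FSAConfig, ObjectiveSpec, OptimizationResult, run_fsa

__all__ = [
    "CNNHyperparams",
    "CNNArchitecture",
    "ArchitectureError",
    "TrainedModel",
    "SearchSpace",
    "HyperDimension",
    "default_search_space",
    "flatten_weights",
    "unflatten_weights",
    "softmax",
    "cross_entropy",
    "forward",
    "weight_objective",
    "train_with_adam",
    "train_weights_with_fsa",
    "hyper_objective",
    "tune_hyperparams_with_fsa",
    "random_search_tune",
]

MAX_FSA_WEIGHTS = 5000
DEFAULT_WEIGHT_BOUND = 3.0


class ArchitectureError(ValueError):
    """The layer stack is inconsistent with the input window length."""


@dataclass(frozen=True)
class CNNHyperparams:
    n_conv_blocks: int = 1
    filters_per_block: tuple = (8,)
    kernel_size: int = 7
    pool_size: int = 2
    dense_units: int = 16
    dropout_rate: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30

    def __post_init__(self):
        if self.n_conv_blocks < 1:
            raise ValueError("need at least one conv block")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        object.__setattr__(self, "filters_per_block", tuple(self.filters_per_block))

    def block_filters(self) -> tuple:
        f = self.filters_per_block
        if len(f) < self.n_conv_blocks:  # repeat last entry for missing blocks
            f = f + (f[-1],) * (self.n_conv_blocks - len(f))
        return f[: self.n_conv_blocks]


class CNNArchitecture:
    """Shape arithmetic and parameter manifest for one hyperparameter setting.

    Valid (no) padding, stride 1, non-overlapping max pooling that drops the
    remainder: a block maps length L to (L - kernel + 1) // pool.
    """

    def __init__(self, hyper: CNNHyperparams, window_length: int, n_classes: int = 5):
        self.hyper = hyper
        self.window_length = int(window_length)
        self.n_classes = int(n_classes)
        length, channels = self.window_length, 1
        self.block_shapes = []
        manifest = []
        for b, n_filters in enumerate(hyper.block_filters()):
            conv_len = length - hyper.kernel_size + 1
            if conv_len < 1:
                raise ArchitectureError(
                    f"conv block {b}: kernel {hyper.kernel_size} exceeds length {length}"
                )
            pooled = conv_len // hyper.pool_size
            if pooled < 1:
                raise ArchitectureError(
                    f"conv block {b}: pool {hyper.pool_size} collapses length {conv_len}"
                )
            manifest.append((f"conv{b}_W", (n_filters, channels, hyper.kernel_size)))
            manifest.append((f"conv{b}_b", (n_filters,)))
            self.block_shapes.append((conv_len, pooled, n_filters))
            length, channels = pooled, n_filters
        self.flat_features = length * channels
        manifest.append(("dense_W", (self.flat_features, hyper.dense_units)))
        manifest.append(("dense_b", (hyper.dense_units,)))
        manifest.append(("out_W", (hyper.dense_units, self.n_classes)))
        manifest.append(("out_b", (self.n_classes,)))
        self.manifest = manifest

    @property
    def n_weights(self) -> int:
        return int(sum(np.prod(shape) for _, shape in self.manifest))

    def init_params(self, rng: np.random.Generator) -> dict:
        """He-initialized weights, zero biases."""
        params = {}
        for name, shape in self.manifest:
            if name.endswith("_b"):
                params[name] = np.zeros(shape)
            else:
                fan_in = int(np.prod(shape[:-1])) if name.startswith("conv") else shape[0]
                params[name] = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        return params

    def to_dict(self) -> dict:
        h = self.hyper
        return {
            "window_length": self.window_length,
            "n_classes": self.n_classes,
            "hyper": {
                "n_conv_blocks": h.n_conv_blocks,
                "filters_per_block": list(h.filters_per_block),
                "kernel_size": h.kernel_size,
                "pool_size": h.pool_size,
                "dense_units": h.dense_units,
                "dropout_rate": h.dropout_rate,
                "learning_rate": h.learning_rate,
                "batch_size": h.batch_size,
                "epochs": h.epochs,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CNNArchitecture":
        h = d["hyper"]
        hyper = CNNHyperparams(
            n_conv_blocks=h["n_conv_blocks"],
            filters_per_block=tuple(h["filters_per_block"]),
            kernel_size=h["kernel_size"],
            pool_size=h["pool_size"],
            dense_units=h["dense_units"],
            dropout_rate=h["dropout_rate"],
            learning_rate=h["learning_rate"],
            batch_size=h["batch_size"],
            epochs=h["epochs"],
        )
        return cls(hyper, d["window_length"], d["n_classes"])


def flatten_weights(params: dict, manifest) -> np.ndarray:
    return np.concatenate([params[name].ravel() for name, _ in manifest])


def unflatten_weights(w: np.ndarray, manifest) -> dict:
    w = np.asarray(w, dtype=float)
    expected = int(sum(np.prod(shape) for _, shape in manifest))
    if w.size != expected:
        raise ValueError(f"weight vector has {w.size} entries, manifest needs {expected}")
    params, offset = {}, 0
    for name, shape in manifest:
        size = int(np.prod(shape))
        params[name] = w[offset : offset + size].reshape(shape).copy()
        offset += size
    return params


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y_idx: np.ndarray) -> float:
    z = logits - logits.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-log_probs[np.arange(y_idx.size), y_idx].mean())


def _sliding(x: np.ndarray, k: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=2)


def forward(
    arch: CNNArchitecture,
    params: dict,
    X: np.ndarray,
    train: bool = False,
    dropout_rng: np.random.Generator | None = None,
):
    """Run the network; returns (logits, cache) — cache feeds backward()."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != arch.window_length:
        raise ValueError(
            f"input window length {X.shape[1]} != architecture {arch.window_length}"
        )
    a = X[:, None, :]
    h = arch.hyper
    blocks = []
    for b in range(h.n_conv_blocks):
        W, bias = params[f"conv{b}_W"], params[f"conv{b}_b"]
        windows = _sliding(a, h.kernel_size)
        z = np.einsum("nclk,ock->nol", windows, W, optimize=True) + bias[None, :, None]
        relu = np.maximum(z, 0.0)
        n, c, conv_len = relu.shape
        pooled_len = conv_len // h.pool_size
        tiles = relu[:, :, : pooled_len * h.pool_size].reshape(n, c, pooled_len, h.pool_size)
        argmax = tiles.argmax(axis=3)
        pooled = np.take_along_axis(tiles, argmax[..., None], axis=3)[..., 0]
        blocks.append({"input": a, "windows": windows, "z": z, "argmax": argmax,
                       "conv_len": conv_len, "pooled_len": pooled_len})
        a = pooled
    flat = a.reshape(a.shape[0], -1)
    zd = flat @ params["dense_W"] + params["dense_b"]
    hidden = np.maximum(zd, 0.0)
    mask = None
    if train and h.dropout_rate > 0.0:
        if dropout_rng is None:
            raise ValueError("dropout during training requires dropout_rng")
        keep = 1.0 - h.dropout_rate
        mask = (dropout_rng.random(hidden.shape) < keep) / keep
        hidden = hidden * mask
    logits = hidden @ params["out_W"] + params["out_b"]
    cache = {"blocks": blocks, "flat": flat, "zd": zd, "hidden": hidden,
             "mask": mask, "pre_pool_shape": a.shape}
    return logits, cache


def _backward(arch, params, cache, probs, y_idx):
    h = arch.hyper
    n = y_idx.size
    grads = {}
    dlogits = probs.copy()
    dlogits[np.arange(n), y_idx] -= 1.0
    dlogits /= n
    grads["out_W"] = cache["hidden"].T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    dhidden = dlogits @ params["out_W"].T
    if cache["mask"] is not None:
        dhidden = dhidden * cache["mask"]
    dzd = dhidden * (cache["zd"] > 0.0)
    grads["dense_W"] = cache["flat"].T @ dzd
    grads["dense_b"] = dzd.sum(axis=0)
    da = (dzd @ params["dense_W"].T).reshape(cache["pre_pool_shape"])
    for b in range(h.n_conv_blocks - 1, -1, -1):
        blk = cache["blocks"][b]
        nb, c = da.shape[0], da.shape[1]
        # un-pool: route gradient to the argmax slot of each tile
        dtiles = np.zeros((nb, c, blk["pooled_len"], h.pool_size))
        np.put_along_axis(dtiles, blk["argmax"][..., None], da[..., None], axis=3)
        dz = np.zeros((nb, c, blk["conv_len"]))
        dz[:, :, : blk["pooled_len"] * h.pool_size] = dtiles.reshape(
            nb, c, blk["pooled_len"] * h.pool_size
        )
        dz *= blk["z"] > 0.0
        W = params[f"conv{b}_W"]
        grads[f"conv{b}_W"] = np.einsum("nol,nclk->ock", dz, blk["windows"], optimize=True)
        grads[f"conv{b}_b"] = dz.sum(axis=(0, 2))
        if b > 0:
            din = np.zeros_like(blk["input"])
            for dk in range(h.kernel_size):
                din[:, :, dk : dk + blk["conv_len"]] += np.einsum(
                    "nol,oc->ncl", dz, W[:, :, dk], optimize=True
                )
            da = din
    return grads


@dataclass
class TrainedModel:
    """A fitted classifier: architecture, weights, training history, mode."""

    arch: CNNArchitecture
    params: dict
    history: np.ndarray
    mode: str
    class_names: tuple

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = forward(self.arch, self.params, X, train=False)
        return softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels for beat windows."""
        idx = self.predict_proba(X).argmax(axis=1)
        return np.asarray([self.class_names[i] for i in idx], dtype=object)

    def accuracy(self, data: BeatDataset) -> float:
        return float(np.mean(self.predict(data.beats) == data.labels))

    def save(self, prefix: str) -> None:
        """Checkpoint as architecture JSON + flat weight array (.json/.npy)."""
        with open(prefix + ".json", "w") as fh:
            json.dump(
                {"arch": self.arch.to_dict(), "mode": self.mode,
                 "class_names": list(self.class_names)},
                fh, indent=2, sort_keys=True,
            )
        np.save(prefix + ".npy", flatten_weights(self.params, self.arch.manifest))

    @classmethod
    def load(cls, prefix: str) -> "TrainedModel":
        with open(prefix + ".json") as fh:
            meta = json.load(fh)
        arch = CNNArchitecture.from_dict(meta["arch"])
        w = np.load(prefix + ".npy")
        return cls(arch, unflatten_weights(w, arch.manifest), np.empty(0),
                   meta["mode"], tuple(meta["class_names"]))


def weight_objective(w: np.ndarray, arch: CNNArchitecture, train: BeatDataset) -> float:
    """Training cross-entropy of the network with flattened weights ``w``."""
    params = unflatten_weights(w, arch.manifest)
    logits, _ = forward(arch, params, train.beats, train=False)
    return cross_entropy(logits, train.label_indices())


def train_with_adam(
    arch: CNNArchitecture,
    train: BeatDataset,
    seed: int = 0,
    epochs: int | None = None,
    class_names: tuple | None = None,
) -> TrainedModel:
    """Minibatch Adam with cross-entropy loss; the conventional baseline.

    Uses the architecture's hyperparameters (learning_rate, batch_size,
    dropout_rate, epochs unless overridden). History is mean loss per epoch.
    """
    h = arch.hyper
    epochs = h.epochs if epochs is None else int(epochs)
    rng = np.random.default_rng(seed)
    params = arch.init_params(rng)
    y = train.label_indices()
    n = train.n_beats
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(val) for k, val in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = np.empty(epochs)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, h.batch_size):
            batch = order[start : start + h.batch_size]
            logits, cache = forward(
                arch, params, train.beats[batch], train=True, dropout_rng=rng
            )
            probs = softmax(logits)
            losses.append(cross_entropy(logits, y[batch]))
            grads = _backward(arch, params, cache, probs, y[batch])
            step += 1
            lr_t = h.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
        history[epoch] = float(np.mean(losses))
    names = class_names if class_names is not None else train.class_names
    return TrainedModel(arch, params, history, "adam_baseline", tuple(names))


def train_weights_with_fsa(
    arch: CNNArchitecture,
    train: BeatDataset,
    fsa_config: FSAConfig,
    weight_bound: float = DEFAULT_WEIGHT_BOUND,
    max_weights: int = MAX_FSA_WEIGHTS,
) -> TrainedModel:
    """Flamingo search over the flattened weight vector (Adam replacement).

    Sensible only for tiny networks; refuses above ``max_weights`` weights.
    The per-iteration loss history inherits the optimizer's elitist
    monotonicity.
    """
    k = arch.n_weights
    if k > max_weights:
        raise ValueError(
            f"architecture has {k} weights, above the {max_weights} ceiling for "
            "population search over raw weights; shrink the network "
            "(fewer/narrower blocks, smaller dense layer) or use adam/hyper modes"
        )
    objective = ObjectiveSpec(
        evaluate=lambda w: weight_objective(w, arch, train),
        lower_bounds=np.full(k, -weight_bound),
        upper_bounds=np.full(k, weight_bound),
        sense="min",
    )
    result = run_fsa(objective, fsa_config)
    params = unflatten_weights(result.best_position, arch.manifest)
    return TrainedModel(arch, params, result.history, "weight_fsa", train.class_names)


@dataclass(frozen=True)
class HyperDimension:
    """One tunable axis: continuous, integer (snapped), or log10-scaled."""

    name: str
    low: float
    high: float
    kind: str = "continuous"

    def __post_init__(self):
        if self.kind not in ("continuous", "integer", "log"):
            raise ValueError("kind must be continuous|integer|log")
        if not self.low < self.high:
            raise ValueError("low must be < high")


class SearchSpace:
    """Bounded encoding of CNNHyperparams as an FSA position vector.

    Log dimensions live in log10 space; integer dimensions are rounded on
    decode; every coordinate is clipped into its bounds, so decode never
    fails on an out-of-grid position. The special name ``filters`` sets
    ``filters_per_block`` uniformly across blocks.
    """

    def __init__(self, dimensions, base: CNNHyperparams | None = None):
        self.dimensions = list(dimensions)
        self.base = base if base is not None else CNNHyperparams()

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.array(
            [np.log10(d.low) if d.kind == "log" else d.low for d in self.dimensions]
        )

    @property
    def upper_bounds(self) -> np.ndarray:
        return np.array(
            [np.log10(d.high) if d.kind == "log" else d.high for d in self.dimensions]
        )

    def encode(self, hyper: CNNHyperparams) -> np.ndarray:
        vec = np.empty(len(self.dimensions))
        for i, d in enumerate(self.dimensions):
            if d.name == "filters":
                value = hyper.filters_per_block[0]
            else:
                value = getattr(hyper, d.name)
            vec[i] = np.log10(value) if d.kind == "log" else float(value)
        return vec

    def decode(self, position: np.ndarray) -> CNNHyperparams:
        position = np.clip(np.asarray(position, dtype=float),
                           self.lower_bounds, self.upper_bounds)
        updates = {}
        for value, d in zip(position, self.dimensions):
            if d.kind == "log":
                value = 10.0**value
            if d.kind == "integer":
                value = int(round(value))
                value = int(np.clip(value, d.low, d.high))
            if d.name == "filters":
                updates["filters_per_block"] = (value,) * self.base.n_conv_blocks
            else:
                updates[d.name] = value
        return replace(self.base, **updates)


def default_search_space(base: CNNHyperparams | None = None) -> SearchSpace:
    """The shipped tuning space: width, kernel, dense size, dropout, log-lr."""
    if base is None:
        base = CNNHyperparams(n_conv_blocks=1, filters_per_block=(8,), dense_units=16)
    return SearchSpace(
        [
            HyperDimension("filters", 2, 16, "integer"),
            HyperDimension("kernel_size", 3, 9, "integer"),
            HyperDimension("dense_units", 4, 32, "integer"),
            HyperDimension("dropout_rate", 0.0, 0.5, "continuous"),
            HyperDimension("learning_rate", 1e-4, 3e-2, "log"),
        ],
        base=base,
    )


def hyper_objective(
    position: np.ndarray,
    space: SearchSpace,
    train: BeatDataset,
    val: BeatDataset,
    budget_epochs: int,
    inner_seed: int = 0,
    n_classes: int | None = None,
    cache: dict | None = None,
) -> float:
    """Validation error rate of an Adam-trained candidate (FSA minimizes it).

    The inner training seed is fixed so the outer search sees a
    deterministic objective; a cache keyed by the decoded hyperparameters
    avoids retraining duplicates.
    """
    hyper = space.decode(position)
    key = (hyper.n_conv_blocks, hyper.filters_per_block, hyper.kernel_size,
           hyper.pool_size, hyper.dense_units, round(hyper.dropout_rate, 12),
           round(float(np.log10(hyper.learning_rate)), 12))
    if cache is not None and key in cache:
        return cache[key]
    k = len(train.class_names) if n_classes is None else n_classes
    arch = CNNArchitecture(hyper, train.window_length, k)
    model = train_with_adam(arch, train, seed=inner_seed, epochs=budget_epochs)
    error = 1.0 - model.accuracy(val)
    if cache is not None:
        cache[key] = error
    return error


def _check_tuning_budget(n_evals: int, budget_epochs: int, max_total_epochs: int):
    total = n_evals * budget_epochs
    if total > max_total_epochs:
        raise ValueError(
            f"tuning budget of {n_evals} trainings x {budget_epochs} epochs = "
            f"{total} epochs exceeds the {max_total_epochs} ceiling; lower the "
            "population, iterations or budget_epochs"
        )


def tune_hyperparams_with_fsa(
    space: SearchSpace,
    train: BeatDataset,
    val: BeatDataset,
    fsa_config: FSAConfig,
    budget_epochs: int = 6,
    final_epochs: int | None = None,
    inner_seed: int = 0,
    max_total_epochs: int = 20000,
):
    """Flamingo search over the hyperparameter space; winner retrained fully.

    Returns ``(best_hyperparams, final_model, search_result)``.
    """
    n_evals = fsa_config.population_size * (fsa_config.max_iterations + 1)
    _check_tuning_budget(n_evals, budget_epochs, max_total_epochs)
    cache: dict = {}
    objective = ObjectiveSpec(
        evaluate=lambda p: hyper_objective(
            p, space, train, val, budget_epochs, inner_seed=inner_seed, cache=cache
        ),
        lower_bounds=space.lower_bounds,
        upper_bounds=space.upper_bounds,
        sense="min",
    )
    result = run_fsa(objective, fsa_config)
    best = space.decode(result.best_position)
    arch = CNNArchitecture(best, train.window_length, len(train.class_names))
    model = train_with_adam(
        arch, train, seed=inner_seed,
        epochs=best.epochs if final_epochs is None else final_epochs,
    )
    model.mode = "hyper_fsa"
    return best, model, result


def random_search_tune(
    space: SearchSpace,
    train: BeatDataset,
    val: BeatDataset,
    n_samples: int,
    budget_epochs: int = 6,
    seed: int = 0,
    inner_seed: int = 0,
    max_total_epochs: int = 20000,
):
    """Uniform random search baseline at the same evaluation budget.

    Returns ``(best_hyperparams, best_validation_error)``.
    """
    _check_tuning_budget(n_samples, budget_epochs, max_total_epochs)
    rng = np.random.default_rng(seed)
    cache: dict = {}
    best_err, best_hyper = np.inf, None
    lo, hi = space.lower_bounds, space.upper_bounds
    for _ in range(n_samples):
        position = rng.uniform(lo, hi)
        err = hyper_objective(
            position, space, train, val, budget_epochs,
            inner_seed=inner_seed, cache=cache,
        )
        if err < best_err:
            best_err, best_hyper = err, space.decode(position)
    return best_hyper, float(best_err)
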