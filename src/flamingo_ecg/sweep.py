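"""Training-percentage and epoch sweep harnesses.

Each cell of a sweep runs the full pipeline — stratified split, scaler
fitted on the training split only, model training, test-set scoring — and
the results are collected in a long-format table
(method, metric, pct_or_epochs, seed, value) with medians computable by a
groupby. A failed cell is recorded (NaN value, error string) and the sweep
continues.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cnn import CNNArchitecture, CNNHyperparams, train_weights_with_fsa, train_with_adam
from .data import BeatDataset, apply_scaler, fit_scaler, split_by_training_percentage
from .fsa import FSAConfig
from .metrics import compute_metrics, confusion_matrix

__all__ = ["run_pipeline_cell", "sweep_training_percentage", "sweep_epochs", "median_table"]

DEFAULT_PCTS = (40, 50, 60, 70, 80)


def run_pipeline_cell(
    data: BeatDataset,
    pct: float,
    seed: int,
    hyper: CNNHyperparams,
    method: str = "adam",
    n_classes: int | None = None,
    epochs: int | None = None,
    fsa_config: FSAConfig | None = None,
) -> dict:
    """One split-train-evaluate run; returns the three metrics as fractions."""
    train, test = split_by_training_percentage(data, pct, seed=seed)
    scaler = fit_scaler(train)
    train_s, test_s = apply_scaler(train, scaler), apply_scaler(test, scaler)
    k = len(data.class_names) if n_classes is None else n_classes
    arch = CNNArchitecture(hyper, data.window_length, k)
    if method == "adam":
        model = train_with_adam(arch, train_s, seed=seed, epochs=epochs)
    elif method == "weight_fsa":
        cfg = fsa_config if fsa_config is not None else FSAConfig(seed=seed)
        if cfg.seed != seed:
            cfg = FSAConfig(**{**cfg.__dict__, "seed": seed})
        model = train_weights_with_fsa(arch, train_s, cfg)
    else:
        raise ValueError(f"unknown method {method!r}")
    predicted = model.predict(test_s.beats)
    cm = confusion_matrix(test_s.labels, predicted, data.class_names)
    report = compute_metrics(cm, mode="macro")
    return {
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
    }


def _sweep(data, axis_name, axis_values, seeds, hyper, method, cell_kwargs) -> pd.DataFrame:
    rows = []
    for value in axis_values:
        for seed in seeds:
            kwargs = dict(cell_kwargs)
            if axis_name == "pct":
                kwargs["pct"] = value
            else:
                kwargs["epochs"] = int(value)
            try:
                metrics = run_pipeline_cell(
                    data, seed=seed, hyper=hyper, method=method, **kwargs
                )
                error = ""
            except Exception as exc:  # record and continue
                metrics = {"accuracy": np.nan, "sensitivity": np.nan,
                           "specificity": np.nan}
                error = f"{type(exc).__name__}: {exc}"
            for metric, val in metrics.items():
                rows.append({"method": method, "metric": metric, axis_name: value,
                             "seed": seed, "value": val, "error": error})
    return pd.DataFrame(rows)


def sweep_training_percentage(
    data: BeatDataset,
    pcts=DEFAULT_PCTS,
    seeds=(0, 1, 2, 3, 4),
    hyper: CNNHyperparams | None = None,
    method: str = "adam",
    epochs: int | None = None,
) -> pd.DataFrame:
    """Grid of training percentages x seeds; long-format results table."""
    hyper = hyper if hyper is not None else CNNHyperparams()
    return _sweep(data, "pct", list(pcts), list(seeds), hyper, method,
                  {"epochs": epochs})


def sweep_epochs(
    data: BeatDataset,
    epoch_grid=(20, 40, 60, 80, 100),
    seeds=(0, 1, 2, 3, 4),
    hyper: CNNHyperparams | None = None,
    method: str = "adam",
    pct: float = 80,
) -> pd.DataFrame:
    """Grid of training epochs x seeds at a fixed training percentage."""
    hyper = hyper if hyper is not None else CNNHyperparams()
    return _sweep(data, "epochs", list(epoch_grid), list(seeds), hyper, method,
                  {"pct": pct})


def median_table(results: pd.DataFrame, axis_name: str) -> pd.DataFrame:
    """Median over seeds, shaped metric x axis value (the table layout)."""
    return results.pivot_table(index="metric", columns=axis_name, values="value",
                               aggfunc="median")
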