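"""ECG beat acquisition and preprocessing.

WFDB record reading, AAMI EC57 five-class labeling (N, S, V, F, Q), R-peak
centered beat segmentation, column-wise standard scaling fitted on the
training split only, and stratified training-percentage splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import wfdb_io

__all__ = [
    "AAMI_CLASSES",
    "AAMI_SYMBOL_MAP",
    "ECGRecord",
    "BeatDataset",
    "ScalerParams",
    "EmptyDatasetError",
    "read_wfdb_record",
    "map_symbol_to_aami",
    "segment_beats",
    "fit_scaler",
    "apply_scaler",
    "split_by_training_percentage",
]

AAMI_CLASSES = ("N", "S", "V", "F", "Q")

# AAMI EC57 grouping of MIT-BIH beat annotation symbols into superclasses.
AAMI_SYMBOL_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}


class EmptyDatasetError(ValueError):
    """Raised when an operation would produce a dataset with no beats."""


@dataclass
class ECGRecord:
    """A single selected lead with annotated R-peak positions."""

    signal: np.ndarray
    sampling_rate: float
    r_peak_indices: np.ndarray
    beat_symbols: list
    record_id: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float).ravel()
        self.r_peak_indices = np.asarray(self.r_peak_indices, dtype=int)
        if self.r_peak_indices.size and not (np.diff(self.r_peak_indices) > 0).all():
            raise ValueError("r_peak_indices must be strictly increasing")
        if len(self.beat_symbols) != self.r_peak_indices.size:
            raise ValueError("one annotation symbol per R-peak index required")


@dataclass
class BeatDataset:
    """Fixed-length labeled beat windows.

    ``beats`` is (n_beats, window_length); ``labels`` holds one AAMI class
    per row.
    """

    beats: np.ndarray
    labels: np.ndarray
    class_names: tuple = AAMI_CLASSES

    def __post_init__(self):
        self.beats = np.asarray(self.beats, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.beats.ndim != 2:
            raise ValueError("beats must be a 2-D array")
        if self.beats.shape[0] != self.labels.size:
            raise ValueError("one label per beat required")
        unknown = set(self.labels) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels outside class_names: {sorted(unknown)}")

    @property
    def n_beats(self) -> int:
        return self.beats.shape[0]

    @property
    def window_length(self) -> int:
        return self.beats.shape[1]

    def label_indices(self) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lookup[l] for l in self.labels], dtype=int)

    def subset(self, idx) -> "BeatDataset":
        return BeatDataset(self.beats[idx], self.labels[idx], self.class_names)

    def to_csv(self, path) -> None:
        """One row per beat, sample columns then a final `label` column."""
        df = pd.DataFrame(self.beats)
        df.columns = [f"s{i}" for i in range(self.window_length)]
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, class_names=AAMI_CLASSES) -> "BeatDataset":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=object)
        return cls(df.to_numpy(dtype=float), labels, class_names)

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            beats=self.beats,
            labels=self.labels.astype(str),
            class_names=np.asarray(self.class_names, dtype=str),
        )

    @classmethod
    def from_npz(cls, path) -> "BeatDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                z["beats"],
                z["labels"].astype(object),
                tuple(z["class_names"].tolist()),
            )


@dataclass
class ScalerParams:
    """Per-sample-position mean and standard deviation (population, ddof=0)."""

    mean: np.ndarray
    std: np.ndarray


def read_wfdb_record(path: str, lead_index: int = 0) -> ECGRecord:
    """Read one lead plus beat annotations from a WFDB record.

    ``path`` is the record path without extension (or the .hea file).
    """
    header = wfdb_io.read_header(path)
    if not 0 <= lead_index < header.n_signals:
        raise IndexError(
            f"lead_index {lead_index} out of range for {header.n_signals} signal(s)"
        )
    physical = wfdb_io.read_signal(path, header)
    samples, symbols = wfdb_io.read_annotations(path)
    return ECGRecord(
        signal=physical[:, lead_index],
        sampling_rate=header.sampling_rate,
        r_peak_indices=samples,
        beat_symbols=list(symbols),
        record_id=header.record_name,
    )


def map_symbol_to_aami(symbol: str):
    """Map a beat annotation symbol to its AAMI class, or None for non-beat codes."""
    return AAMI_SYMBOL_MAP.get(symbol)


def segment_beats(
    record: ECGRecord, pre_samples: int = 90, post_samples: int = 95
) -> BeatDataset:
    """Cut one window per annotated beat, centered on the R peak.

    Window row for a beat at index i is ``signal[i - pre : i + post + 1]``.
    Beats whose window crosses a signal boundary, and annotations that are
    not beat symbols, are dropped.
    """
    window_length = pre_samples + post_samples + 1
    n = record.signal.size
    if window_length > n:
        raise EmptyDatasetError(
            f"window of {window_length} samples exceeds signal length {n}"
        )
    rows, labels = [], []
    for idx, sym in zip(record.r_peak_indices, record.beat_symbols):
        label = map_symbol_to_aami(sym)
        if label is None:
            continue
        start, stop = idx - pre_samples, idx + post_samples + 1
        if start < 0 or stop > n:
            continue
        rows.append(record.signal[start:stop])
        labels.append(label)
    if not rows:
        raise EmptyDatasetError("no complete beat windows in record")
    return BeatDataset(np.vstack(rows), np.asarray(labels, dtype=object))


def fit_scaler(train: BeatDataset) -> ScalerParams:
    """Column-wise mean/std on the training split (population convention).

    Zero-variance columns fall back to std = 1 with a warning so constant
    positions pass through as zeros.
    """
    mean = train.beats.mean(axis=0)
    std = train.beats.std(axis=0, ddof=0)
    zero = std == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance sample position(s); using std=1",
            stacklevel=2,
        )
        std = np.where(zero, 1.0, std)
    return ScalerParams(mean=mean, std=std)


def apply_scaler(data: BeatDataset, params: ScalerParams) -> BeatDataset:
    scaled = (data.beats - params.mean) / params.std
    return BeatDataset(scaled, data.labels.copy(), data.class_names)


def split_by_training_percentage(
    data: BeatDataset, pct: float, seed: int = 0, stratify: bool = True
):
    """Random split with round(pct% of n) training beats, stratified by class.

    Returns ``(train, test)``; membership is disjoint and exhaustive and
    identical for identical seeds. Classes with fewer than 2 members degrade
    to unstratified assignment with a warning.
    """
    if not 0 < pct < 100:
        raise ValueError("pct must be strictly between 0 and 100")
    rng = np.random.default_rng(seed)
    n = data.n_beats
    train_idx: list = []
    if stratify:
        leftovers = []
        for cls in data.class_names:
            members = np.flatnonzero(data.labels == cls)
            if members.size == 0:
                continue
            if members.size < 2:
                warnings.warn(
                    f"class {cls!r} has <2 members; unstratified for this class",
                    stacklevel=2,
                )
                leftovers.extend(members.tolist())
                continue
            members = rng.permutation(members)
            k = int(round(pct / 100.0 * members.size))
            train_idx.extend(members[:k].tolist())
        if leftovers:
            leftovers = rng.permutation(np.asarray(leftovers, dtype=int))
            k = int(round(pct / 100.0 * len(leftovers)))
            train_idx.extend(leftovers[:k].tolist())
    else:
        perm = rng.permutation(n)
        k = int(round(pct / 100.0 * n))
        train_idx = perm[:k].tolist()
    train_mask = np.zeros(n, dtype=bool)
    train_mask[np.asarray(train_idx, dtype=int)] = True
    return data.subset(train_mask), data.subset(~train_mask)
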