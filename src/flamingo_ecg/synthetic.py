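"""Seeded generator of labeled synthetic ECG beats.

Each beat is a sum of Gaussian bumps (P, Q, R, S, T waves) on a fixed
window, with per-beat amplitude and timing jitter plus additive Gaussian
sample noise. The five default morphologies mimic the gross AAMI class
differences a beat classifier exploits:

* **N** — full PQRST complex, dominant upright R;
* **S** — supraventricular ectopic: early narrow R, absent P wave;
* **V** — ventricular ectopic: wide, high-amplitude inverted complex;
* **F** — fusion: the average of the N and V shapes;
* **Q** — unknown/paced: low-amplitude broad shape.

This is a class-separability testbed, not a physiological simulator: there
is no rhythm context, baseline wander, or electrode artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AAMI_CLASSES, BeatDataset, EmptyDatasetError
from . import wfdb_io

__all__ = [
    "BeatMorphology",
    "SyntheticConfig",
    "default_morphologies",
    "generate_beat",
    "generate_dataset",
    "write_wfdb_fixture",
]


@dataclass(frozen=True)
class BeatMorphology:
    """Gaussian-bump mixture: (amplitude mV, center fraction, width fraction)."""

    components: tuple
    label: str

    def __post_init__(self):
        for amp, center, width in self.components:
            if not 0.0 < center < 1.0:
                raise ValueError("component centers must lie in (0, 1)")
            if width <= 0:
                raise ValueError("component widths must be positive")


# (amplitude mV, center as fraction of window, width as fraction of window)
_N_COMPONENTS = (
    (0.15, 0.28, 0.040),   # P
    (-0.10, 0.44, 0.012),  # Q
    (1.00, 0.48, 0.018),   # R
    (-0.25, 0.53, 0.015),  # S
    (0.35, 0.72, 0.060),   # T
)
_V_COMPONENTS = (
    (-1.30, 0.50, 0.060),  # wide inverted QRS
    (0.60, 0.76, 0.080),   # discordant tall T
)


def default_morphologies() -> dict:
    """The five shipped class morphologies keyed by AAMI label."""
    s_components = (
        (-0.08, 0.36, 0.012),
        (0.85, 0.40, 0.012),   # early, narrow R; no P wave
        (-0.20, 0.45, 0.012),
        (0.28, 0.64, 0.050),
    )
    f_components = tuple(
        (0.5 * amp, center, width) for amp, center, width in _N_COMPONENTS
    ) + tuple((0.5 * amp, center, width) for amp, center, width in _V_COMPONENTS)
    q_components = (
        (0.25, 0.47, 0.100),
        (-0.12, 0.68, 0.070),
    )
    return {
        "N": BeatMorphology(_N_COMPONENTS, "N"),
        "S": BeatMorphology(s_components, "S"),
        "V": BeatMorphology(_V_COMPONENTS, "V"),
        "F": BeatMorphology(f_components, "F"),
        "Q": BeatMorphology(q_components, "Q"),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation conditions.

    ``n_per_class`` is either one count for every class or a mapping
    label -> count. Jitters are fractional: amplitudes are scaled by
    ``1 + amplitude_jitter * z`` and centers shifted by
    ``timing_jitter * z`` window fractions, z ~ N(0, 1) per beat.
    """

    n_per_class: int | dict = 100
    window_length: int = 186
    noise_sd: float = 0.05
    amplitude_jitter: float = 0.10
    timing_jitter: float = 0.02
    seed: int = 0

    def counts(self) -> dict:
        if isinstance(self.n_per_class, dict):
            out = {c: int(self.n_per_class.get(c, 0)) for c in AAMI_CLASSES}
        else:
            out = {c: int(self.n_per_class) for c in AAMI_CLASSES}
        if any(v < 0 for v in out.values()):
            raise ValueError("class counts must be nonnegative")
        return out

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")


def generate_beat(
    morph: BeatMorphology, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """One jittered, noisy realization of a morphology on the window grid."""
    t = np.linspace(0.0, 1.0, config.window_length)
    beat = np.zeros(config.window_length)
    for amp, center, width in morph.components:
        a = amp * (1.0 + config.amplitude_jitter * rng.standard_normal())
        c = center + config.timing_jitter * rng.standard_normal()
        beat += a * np.exp(-0.5 * ((t - c) / width) ** 2)
    if config.noise_sd > 0:
        beat += rng.normal(0.0, config.noise_sd, size=config.window_length)
    return beat


def generate_dataset(config: SyntheticConfig) -> BeatDataset:
    """Shuffled labeled dataset using the five default morphologies."""
    counts = config.counts()
    total = sum(counts.values())
    if total == 0:
        raise EmptyDatasetError("all class counts are zero")
    rng = np.random.default_rng(config.seed)
    morphs = default_morphologies()
    rows, labels = [], []
    for cls in AAMI_CLASSES:
        for _ in range(counts[cls]):
            rows.append(generate_beat(morphs[cls], config, rng))
            labels.append(cls)
    beats = np.vstack(rows)
    labels = np.asarray(labels, dtype=object)
    order = rng.permutation(total)
    return BeatDataset(beats[order], labels[order])


# representative raw MIT-BIH annotation symbol per AAMI class, used when
# emitting WFDB fixtures so the reader exercises the symbol->class mapping
_FIXTURE_SYMBOLS = {"N": "N", "S": "A", "V": "V", "F": "F", "Q": "/"}


def write_wfdb_fixture(
    path: str,
    config: SyntheticConfig | None = None,
    sampling_rate: float = 360.0,
    gap_samples: int = 40,
) -> dict:
    """Write a small WFDB record (.hea/.dat/.atr) of concatenated beats.

    Beats are laid end to end with flat gaps; each annotation sits at the
    window center of its beat. Returns {'r_peaks': ..., 'symbols': ...,
    'labels': ...} ground truth for round-trip tests.
    """
    if config is None:
        config = SyntheticConfig(n_per_class=3, noise_sd=0.0, seed=7)
    counts = config.counts()
    rng = np.random.default_rng(config.seed)
    morphs = default_morphologies()
    pieces = [np.zeros(gap_samples)]
    r_peaks, symbols, labels = [], [], []
    offset = gap_samples
    for cls in AAMI_CLASSES:
        for _ in range(counts[cls]):
            beat = generate_beat(morphs[cls], config, rng)
            pieces.append(beat)
            pieces.append(np.zeros(gap_samples))
            r_peaks.append(offset + config.window_length // 2)
            symbols.append(_FIXTURE_SYMBOLS[cls])
            labels.append(cls)
            offset += config.window_length + gap_samples
    signal = np.concatenate(pieces)
    wfdb_io.write_record(path, signal[:, None], sampling_rate, descriptions=["MLII"])
    wfdb_io.write_annotations(path, r_peaks, symbols)
    return {
        "r_peaks": np.asarray(r_peaks, dtype=int),
        "symbols": symbols,
        "labels": labels,
        "signal": signal,
    }
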