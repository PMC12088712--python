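"""Model-input preparation: random 2 s windows, uniform-noise augmentation,
and baseline/follow-up concatenation into a 24-lead stack.

Each training step sees a freshly drawn contiguous 2 s segment (12 x 1000
samples at 500 Hz) from the 15 s record; in dual mode the baseline and
follow-up windows are drawn with independent offsets and stacked baseline
first, giving a (24, 1000) matrix.  Augmentation adds i.i.d. per-sample
Uniform(-limit, +limit) mV noise (default limit 0.1 mV) and is disabled at
evaluation time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import EcgRecord


@dataclass(frozen=True)
class WindowSpec:
    window_seconds: float = 2.0
    fs: float = 500.0

    @property
    def window_samples(self) -> int:
        n = self.window_seconds * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window_seconds * fs must be an integer sample count")
        return int(round(n))


@dataclass(frozen=True)
class AugmentSpec:
    noise_limit: float = 0.1   # mV
    enabled: bool = True

    def __post_init__(self):
        if self.noise_limit < 0:
            raise ValueError("noise_limit must be >= 0")


def extract_window(record: EcgRecord, spec: WindowSpec = WindowSpec(),
                   rng: np.random.Generator | None = None,
                   offset: int | None = None) -> np.ndarray:
    """Contiguous (12, window_samples) slice at a uniform random offset.

    All leads share the offset; no resampling or filtering is applied.  An
    explicit ``offset`` overrides the random draw (used for deterministic
    evaluation windows).
    """
    w = spec.window_samples
    t = record.n_samples
    if t < w:
        raise ValueError(
            f"record {record.patient_id or '<unnamed>'} has {t} samples, "
            f"shorter than the {w}-sample window")
    if offset is None:
        rng = np.random.default_rng() if rng is None else rng
        offset = int(rng.integers(0, t - w + 1))
    if not 0 <= offset <= t - w:
        raise ValueError(f"offset {offset} outside [0, {t - w}]")
    return record.signal[:, offset:offset + w]


def add_uniform_noise(window: np.ndarray, spec: AugmentSpec = AugmentSpec(),
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Add i.i.d. Uniform(-limit, +limit) mV per sample per lead."""
    if not spec.enabled or spec.noise_limit == 0:
        return window
    rng = np.random.default_rng() if rng is None else rng
    return window + rng.uniform(-spec.noise_limit, spec.noise_limit, size=window.shape)


def concat_dual(baseline_window: np.ndarray, follow_up_window: np.ndarray) -> np.ndarray:
    """Stack two (12, W) windows into (24, W): baseline rows 0-11, follow-up 12-23."""
    b = np.asarray(baseline_window)
    f = np.asarray(follow_up_window)
    if b.shape != f.shape or b.ndim != 2 or b.shape[0] != 12:
        raise ValueError(f"expected two matching (12, W) windows, got {b.shape} and {f.shape}")
    return np.concatenate([b, f], axis=0)
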