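"""Raw 30 Hz tri-axial acceleration → 1-min epoch activity counts.

The pipeline mirrors the processing applied to GENEActiv-class wrist
recordings: the Euclidean norm of the change in the acceleration vector
between consecutive samples is (1) converted to mm/s², (2) smoothed with a
centred rolling Gaussian window spanning 30 samples (1 s at 30 Hz), (3)
gated by a high-pass noise-floor threshold (20 mg = 196 mm/s²; sub-threshold
samples are zeroed), and (4) summed within whole 1-min epochs.  Because the
first difference removes the static gravity component, the output is
invariant to device orientation and to any constant acceleration offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .actigraphy_io import EpochSeries, RawAccelSeries

#: standard gravity, m/s² — converts acceleration in g to SI
STANDARD_GRAVITY = 9.80665

#: default noise-floor threshold: 20 mg expressed in mm/s²
DEFAULT_THRESHOLD_MMPS2 = 20 * STANDARD_GRAVITY  # 196.133


def mg_to_mmps2(value_mg: float) -> float:
    """Convert an acceleration in milli-g to mm/s² (20 mg → 196.133 mm/s²)."""
    return value_mg * STANDARD_GRAVITY


@dataclass
class PreprocessParams:
    smooth_window: int = 30              # samples (1 s at 30 Hz)
    highpass_threshold: float = DEFAULT_THRESHOLD_MMPS2  # mm/s²
    epoch_min: int = 1

    def __post_init__(self) -> None:
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.highpass_threshold < 0:
            raise ValueError("highpass_threshold must be >= 0")
        if self.epoch_min < 1:
            raise ValueError("epoch_min must be >= 1")


def gaussian_kernel(window: int) -> np.ndarray:
    """Gaussian kernel on a ``window``-sample support, σ = window/6,
    renormalized to unit sum (so a constant signal passes unchanged)."""
    sigma = window / 6.0
    x = np.arange(window) - (window - 1) / 2.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    # centred convolution with reflection padding to avoid onset transients
    if window <= 1 or len(x) == 0:
        return x.copy()
    k = gaussian_kernel(window)
    left = window // 2
    right = window - 1 - left
    pad = min(max(left, right), len(x) - 1)
    xp = np.pad(x, pad, mode="reflect")
    out = np.convolve(xp, k, mode="same")
    return out[pad:pad + len(x)]


def accel_to_epochs(raw: RawAccelSeries,
                    params: PreprocessParams | None = None) -> EpochSeries:
    """Run the full difference → smooth → threshold → epoch-sum pipeline.

    The trailing partial epoch is dropped; the epoch grid starts at the raw
    start time floored to the minute.
    """
    params = params or PreprocessParams()
    if raw.n_samples < 2:
        raise ValueError("need at least 2 raw samples")
    samples_per_epoch = raw.rate_hz * 60 * params.epoch_min
    if abs(samples_per_epoch - round(samples_per_epoch)) > 1e-9:
        raise ValueError("sampling rate does not yield a whole number of "
                         "samples per epoch")
    spe = int(round(samples_per_epoch))

    diff = np.diff(raw.samples, axis=0)
    mag = np.linalg.norm(diff, axis=1) * STANDARD_GRAVITY * 1000.0  # g → mm/s²
    sm = _smooth(mag, params.smooth_window)
    sm = np.where(sm >= params.highpass_threshold, sm, 0.0)

    n_epochs = len(sm) // spe
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    counts = sm[:n_epochs * spe].reshape(n_epochs, spe).sum(axis=1)
    start = pd.Timestamp(raw.start_time).floor("min")
    return EpochSeries(start_time=start, counts=counts,
                       epoch_min=params.epoch_min)
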