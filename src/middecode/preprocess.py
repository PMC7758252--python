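"""Epoch preprocessing: 30 Hz low-pass, linear-interpolation downsampling to
125 Hz, and per-channel z-scoring.

The filter is a 4th-order Butterworth applied forward-backward (zero phase)
by default.  Downsampling places samples on the grid ``t0 + k * 1000/rate``
and linearly interpolates between the two bracketing raw samples, which is an
exact copy whenever grid points coincide with raw samples.  The 125-point
grid over a 1000 ms epoch runs -200..792 ms at 8 ms spacing.  z-scoring
standardizes each channel of each (pseudo-)epoch over time.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError, ValidationError
from .synth import EpochSet

__all__ = [
    "PreprocConfig",
    "lowpass_filter",
    "resample_epochs",
    "zscore_epochs",
    "preprocess_epochs",
]


@dataclass
class PreprocConfig:
    lowpass_hz: float = 30.0
    target_rate_hz: float = 125.0
    filter_order: int = 4
    zero_phase: bool = True
    zscore_axis: str = "channels"  # per pseudo-epoch: across channels ("channels")
    #                                or per channel over time ("time")

    def __post_init__(self) -> None:
        if self.lowpass_hz <= 0 or self.target_rate_hz <= 0:
            raise ConfigurationError("cutoff and target rate must be positive")
        if self.lowpass_hz >= self.target_rate_hz / 2.0:
            raise ConfigurationError(
                "lowpass_hz must be below the target Nyquist frequency"
            )
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")
        if self.zscore_axis not in ("channels", "time"):
            raise ConfigurationError(f"unsupported zscore_axis {self.zscore_axis!r}")


def lowpass_filter(epochs: EpochSet, cfg: PreprocConfig | None = None) -> EpochSet:
    """Low-pass the time axis of every epoch (zero-phase by default)."""
    cfg = cfg or PreprocConfig()
    nyq = epochs.rate_hz / 2.0
    if cfg.lowpass_hz >= nyq:
        raise ConfigurationError(
            f"cutoff {cfg.lowpass_hz} Hz >= Nyquist {nyq} Hz"
        )
    sos = signal.butter(cfg.filter_order, cfg.lowpass_hz, btype="low",
                        fs=epochs.rate_hz, output="sos")
    if cfg.zero_phase:
        filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    else:
        filtered = signal.sosfilt(sos, epochs.data, axis=-1)
    return dataclasses.replace(epochs, data=np.ascontiguousarray(filtered))


def resample_epochs(epochs: EpochSet, cfg: PreprocConfig | None = None) -> EpochSet:
    """Downsample by linear interpolation onto the target-rate grid."""
    cfg = cfg or PreprocConfig()
    if cfg.target_rate_hz > epochs.rate_hz:
        raise ConfigurationError("target rate exceeds raw sampling rate")
    t_raw = epochs.times_ms
    dt_raw = 1000.0 / epochs.rate_hz
    duration_ms = epochs.data.shape[-1] * dt_raw
    n_out = int(round(duration_ms * cfg.target_rate_hz / 1000.0))
    step = 1000.0 / cfg.target_rate_hz
    t_new = t_raw[0] + step * np.arange(n_out)
    if n_out and t_new[-1] > t_raw[-1] + 1e-9:
        raise ValidationError("target grid extends beyond the raw time span")
    pos = (t_new - t_raw[0]) / dt_raw
    i0 = np.floor(pos + 1e-9).astype(int)
    i0 = np.clip(i0, 0, t_raw.size - 1)
    i1 = np.clip(i0 + 1, 0, t_raw.size - 1)
    frac = pos - i0
    frac[np.abs(frac) < 1e-9] = 0.0  # exact copy on coincident grid points
    out = epochs.data[..., i0] * (1.0 - frac) + epochs.data[..., i1] * frac
    # preserve bit-exactness where frac == 0
    exact = frac == 0.0
    out[..., exact] = epochs.data[..., i0[exact]]
    return dataclasses.replace(
        epochs, data=out, times_ms=t_new, rate_hz=cfg.target_rate_hz
    )


def zscore_epochs(data, axis: str = "channels"):
    """Standardize each (pseudo-)epoch to equalize electrode scales.

    ``axis="channels"`` (default): at every timepoint, subtract the mean and
    divide by the standard deviation *across channels*.  This is a purely
    per-timepoint operation, so no post-stimulus signal can bleed into the
    baseline samples.  ``axis="time"``: standardize each channel over time
    instead; note that this mixes the evoked response into every sample's
    normalization (the channel mean and SD span the whole epoch), which
    introduces acausal baseline structure when signals are strong.

    Accepts an array shaped ``(..., n_channels, n_times)`` or an
    :class:`EpochSet`.  Degenerate (zero-variance) slices are replaced by
    zeros and a warning is issued.
    """
    if isinstance(data, EpochSet):
        return dataclasses.replace(data, data=zscore_epochs(data.data, axis))
    if axis not in ("channels", "time"):
        raise ConfigurationError(f"unsupported zscore axis {axis!r}")
    x = np.asarray(data, dtype=float)
    ax = -2 if axis == "channels" else -1
    mean = x.mean(axis=ax, keepdims=True)
    sd = x.std(axis=ax, keepdims=True)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} flat slice(s) z-scored to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = np.where(flat, 1.0, sd)
    out = (x - mean) / safe_sd
    out = np.where(np.broadcast_to(flat, out.shape), 0.0, out)
    return out


def preprocess_epochs(epochs: EpochSet, cfg: PreprocConfig | None = None) -> EpochSet:
    """Filter then downsample (z-scoring happens after bootstrap averaging)."""
    cfg = cfg or PreprocConfig()
    return resample_epochs(lowpass_filter(epochs, cfg), cfg)
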