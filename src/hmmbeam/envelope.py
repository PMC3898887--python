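"""Band-pass filtering, Hilbert envelopes and z-statistical time courses.

The raw z time course is the beamformed estimate divided by its standard
deviation.  For envelope ("power") time courses three variants are provided:

* ``stationary`` -- envelope of the raw z time course, appropriate when the
  std is constant over time;
* ``mc`` -- Monte-Carlo: sample time courses from N(mean(t), std(t)^2),
  envelope each, and divide the envelope of the mean by the per-sample std
  over draws;
* ``prop`` -- approximate the envelope std as proportional to the raw std
  (proportionality constant 1; per-voxel constants cancel in downstream
  correlation and GLM statistics).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .datasets import SensorDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ZPowerTimecourse",
    "bandpass",
    "hilbert_envelope",
    "z_timecourse",
    "envelope_z",
    "smooth_downsample",
    "edge_samples",
]

#: filter order of the zero-phase Butterworth band-pass
BANDPASS_ORDER = 4
#: relative floor applied to Monte-Carlo envelope stds to avoid division
#: blow-up; scaled by the median envelope of the mean time course
MC_STD_FLOOR = 1e-8


@dataclass
class ZPowerTimecourse:
    values: np.ndarray          # (V, T) or (T,), nonnegative
    method: str                 # 'stationary' | 'mc' | 'prop'
    n_mc: int | None = None
    fs_out: float | None = None


def bandpass(
    data: SensorDataset | np.ndarray,
    lo_hz: float,
    hi_hz: float,
    fs: float | None = None,
) -> SensorDataset | np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward application gives zero group delay; DC is removed by
    the band-pass itself.
    """
    if isinstance(data, SensorDataset):
        out = bandpass(data.data, lo_hz, hi_hz, fs=data.fs)
        return data.copy_with(out)
    if fs is None:
        raise ValueError("fs required when passing a bare array")
    if not 0 < lo_hz < hi_hz < fs / 2:
        raise ValueError(
            f"band [{lo_hz}, {hi_hz}] Hz must satisfy 0 < lo < hi < fs/2 "
            f"(= {fs / 2})"
        )
    sos = butter(BANDPASS_ORDER, [lo_hz, hi_hz], btype="band", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(data, float), axis=-1)


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude via the analytic signal, along the last axis."""
    return np.abs(hilbert(np.asarray(x, float), axis=-1))


def edge_samples(fs: float, lo_hz: float) -> int:
    """Number of samples at each end contaminated by envelope edge effects."""
    return int(np.ceil(fs / lo_hz))


def z_timecourse(mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """Elementwise ``mean / std``; every std must be strictly positive."""
    mean = np.asarray(mean, float)
    std = np.asarray(std, float)
    if np.any(std <= 0):
        raise ValueError("std must be strictly positive everywhere")
    return mean / std


def envelope_z(
    mean: np.ndarray,
    std: np.ndarray,
    method: str = "prop",
    n_mc: int = 100,
    seed: int | None = None,
) -> ZPowerTimecourse:
    """Variance-corrected envelope ("z-statistical power") time course.

    ``stationary`` envelopes the raw z time course.  ``mc`` draws ``n_mc``
    time courses independently per sample from N(mean, std^2), envelopes
    each, and uses the per-sample std over draws as the denominator of the
    envelope of the mean.  ``prop`` uses the raw std itself as denominator.
    Note the ordering: the stationary variant divides before enveloping,
    the mc/prop variants envelope before dividing; the two orders agree only
    when the std is constant in time.
    """
    mean = np.atleast_2d(np.asarray(mean, float))
    std = np.broadcast_to(np.asarray(std, float), mean.shape)
    if np.any(std <= 0):
        raise ValueError("std must be strictly positive everywhere")
    if method == "stationary":
        vals = hilbert_envelope(mean / std)
    elif method == "prop":
        vals = hilbert_envelope(mean) / std
    elif method == "mc":
        if n_mc < 2:
            raise ValueError("method='mc' requires n_mc >= 2")
        if seed is None:
            raise ValueError("method='mc' requires a seed")
        rng = np.random.default_rng(seed)
        vals = np.empty_like(mean)
        for v in range(mean.shape[0]):
            draws = mean[v] + std[v] * rng.standard_normal((n_mc, mean.shape[1]))
            env = hilbert_envelope(draws)
            S = env.std(axis=0, ddof=1)
            env_mean = hilbert_envelope(mean[v])
            floor = MC_STD_FLOOR * max(float(np.median(env_mean)), 1e-300)
            n_floored = int(np.count_nonzero(S < floor))
            if n_floored:
                logger.warning(
                    "MC envelope std floored at %.3g for %d samples", floor,
                    n_floored,
                )
                S = np.maximum(S, floor)
            vals[v] = env_mean / S
    else:
        raise ValueError(f"unknown method {method!r}")
    return ZPowerTimecourse(
        values=np.squeeze(vals) if vals.shape[0] == 1 else vals,
        method=method,
        n_mc=n_mc if method == "mc" else None,
    )


def smooth_downsample(
    x: np.ndarray, fs: float, width_s: float, fs_out: float
) -> np.ndarray:
    """Centred moving average of ``width_s`` seconds, then sample-picking.

    Edges are handled by shrinking the averaging window to the available
    samples.  Downsampling picks samples at the output rate (nearest-index
    decimation); ``fs_out == fs`` applies smoothing only.
    """
    x = np.asarray(x, float)
    T = x.shape[-1]
    w = int(round(width_s * fs))
    if w < 1:
        raise ValueError("width_s * fs must be at least 1 sample")
    if fs_out > fs:
        raise ValueError("fs_out cannot exceed fs")
    kernel = np.ones(w)
    counts = np.convolve(np.ones(T), kernel, mode="same")
    flat = x.reshape(-1, T)
    sm = np.empty_like(flat)
    for i in range(flat.shape[0]):
        sm[i] = np.convolve(flat[i], kernel, mode="same") / counts
    sm = sm.reshape(x.shape)
    step = fs / fs_out
    idx = np.round(np.arange(0, T, step)).astype(int)
    idx = idx[idx < T]
    return sm[..., idx]
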