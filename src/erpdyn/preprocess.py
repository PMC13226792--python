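"""Epoch-level preprocessing: referencing, filtering, baseline, rejection, averaging.

All operations are pure: they return new containers and never mutate input.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional, Tuple

import numpy as np
from scipy import signal

from .containers import ERP, EpochSet, TopoSequence
from .errors import EmptyResultError, InvalidArgumentError


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the common average: channel mean removed per sample/trial."""
    if epochs.n_channels < 2:
        raise InvalidArgumentError("common average reference needs >= 2 channels")
    data = epochs.data - epochs.data.mean(axis=0, keepdims=True)
    return epochs.with_data(data)


def bandpass(epochs: EpochSet, lo_hz: float, hi_hz: float, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass (forward-backward, effective order 2x).

    ``hi_hz`` is clipped to 0.99 x Nyquist with a warning when necessary.
    """
    nyq = epochs.fs / 2.0
    if hi_hz >= nyq:
        warnings.warn(
            f"high cutoff {hi_hz} Hz >= Nyquist {nyq} Hz; clipping to 0.99*Nyquist",
            stacklevel=2,
        )
        hi_hz = 0.99 * nyq
    if not 0 < lo_hz < hi_hz:
        raise InvalidArgumentError(f"invalid band ({lo_hz}, {hi_hz}) at fs={epochs.fs}")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=epochs.fs, output="sos")
    # a low lo_hz corner has a long impulse response; extend the default
    # reflect-padding toward ~3 time constants of the high-pass edge
    padlen = int(min(epochs.n_samples - 1, round(3.0 * epochs.fs / lo_hz)))
    data = signal.sosfiltfilt(sos, epochs.data, axis=1, padlen=padlen)
    return epochs.with_data(data)


def downsample(epochs: EpochSet, factor: int) -> EpochSet:
    """Decimate by an integer factor with zero-phase anti-alias filtering."""
    if factor < 1 or int(factor) != factor:
        raise InvalidArgumentError("factor must be a positive integer")
    if factor == 1:
        return epochs.with_data(epochs.data.copy())
    data = signal.decimate(epochs.data, int(factor), axis=1, zero_phase=True)
    return replace(epochs, data=data, fs=epochs.fs / factor)


def baseline_correct(
    epochs: EpochSet, baseline_window_ms: Tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract, per channel/trial, the mean over the half-open baseline window."""
    a, b = baseline_window_ms
    times = epochs.times_ms
    mask = (times >= a) & (times < b)
    if a < times[0] - 1e-9 or b > times[-1] + 1000.0 / epochs.fs + 1e-9 or not mask.any():
        raise InvalidArgumentError(
            f"baseline window [{a}, {b}) outside epoch [{times[0]}, {times[-1]}]"
        )
    base = epochs.data[:, mask, :].mean(axis=1, keepdims=True)
    return epochs.with_data(epochs.data - base)


def reject_amplitude(
    epochs: EpochSet, threshold_uv: float = 500.0
) -> Tuple[EpochSet, np.ndarray]:
    """Drop trials whose absolute amplitude strictly exceeds the threshold.

    Boundary values (exactly +-threshold) are retained.  Returns the filtered
    EpochSet and the indices of rejected trials.
    """
    if threshold_uv <= 0:
        raise InvalidArgumentError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(0, 1))
    rejected = np.flatnonzero(peak > threshold_uv)
    if rejected.size == epochs.n_trials:
        raise EmptyResultError("all trials rejected by amplitude criterion")
    keep = np.setdiff1d(np.arange(epochs.n_trials), rejected)
    return epochs.with_data(epochs.data[:, :, keep]), rejected


def condition_average(epochs: EpochSet) -> ERP:
    """Arithmetic mean over trials."""
    if epochs.n_trials < 1:
        raise EmptyResultError("cannot average zero trials")
    return ERP(
        subject_id=epochs.subject_id,
        group=epochs.group,
        condition=epochs.condition,
        data=epochs.data.mean(axis=2),
        channel_names=epochs.channel_names,
        fs=epochs.fs,
        t0_offset_ms=epochs.t0_offset_ms,
        n_trials_used=epochs.n_trials,
    )


def window_means(
    erp: ERP, start_ms: float = 0.0, end_ms: float = 600.0, width_ms: float = 100.0
) -> TopoSequence:
    """Average the ERP into consecutive half-open [a, b) windows of width_ms."""
    span = end_ms - start_ms
    n_win = span / width_ms
    if abs(n_win - round(n_win)) > 1e-9:
        raise InvalidArgumentError(
            f"width {width_ms} does not divide span [{start_ms}, {end_ms})"
        )
    n_win = int(round(n_win))
    times = erp.times_ms
    if start_ms < times[0] - 1e-9 or end_ms > times[-1] + 1000.0 / erp.fs + 1e-9:
        raise InvalidArgumentError("ERP does not cover the requested span")
    topos = np.empty((erp.n_channels, n_win))
    for w in range(n_win):
        a = start_ms + w * width_ms
        mask = (times >= a - 1e-9) & (times < a + width_ms - 1e-9)
        if not mask.any():
            raise InvalidArgumentError(f"no samples in window [{a}, {a + width_ms})")
        topos[:, w] = erp.data[:, mask].mean(axis=1)
    edges = start_ms + np.arange(n_win + 1) * width_ms
    return TopoSequence(
        topos=topos,
        window_edges=edges,
        channel_names=erp.channel_names,
        group=erp.group,
        condition=erp.condition,
        subject_id=erp.subject_id,
    )


def preprocess_epochs(
    epochs: EpochSet,
    *,
    filter_band: Optional[Tuple[float, float]] = None,
    baseline_window_ms: Tuple[float, float] = (-200.0, 0.0),
    reject_uv: Optional[float] = 500.0,
) -> Tuple[EpochSet, np.ndarray]:
    """Standard chain: common average reference -> (optional filter) -> baseline
    -> amplitude rejection.  Filtering defaults off for band-limited synthetic
    data; pass e.g. (0.1, 100.0) for real recordings."""
    out = common_average_reference(epochs)
    if filter_band is not None:
        out = bandpass(out, *filter_band)
    out = baseline_correct(out, baseline_window_ms)
    if reject_uv is not None:
        out, rejected = reject_amplitude(out, reject_uv)
    else:
        rejected = np.array([], dtype=int)
    return out, rejected
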