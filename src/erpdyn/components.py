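"""Conventional ERP component measures: N200/P300 amplitude, latency, and
inter-trial topographic similarity."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .containers import ERP, EpochSet, center_channels
from .errors import InvalidArgumentError


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    condition: str
    window_ms: Tuple[float, float]
    polarity: str  # "negative" | "positive"

    def __post_init__(self) -> None:
        a, b = self.window_ms
        if not (0.0 <= a < b <= 600.0):
            raise InvalidArgumentError("component window must lie within 0-600 ms")
        if self.polarity not in ("negative", "positive"):
            raise InvalidArgumentError("polarity must be 'negative' or 'positive'")


#: Fronto-central negativity to standards, 150-250 ms.
N200 = ComponentSpec("N200", "standard", (150.0, 250.0), "negative")
#: Centro-parietal positivity to targets, 250-450 ms.
P300 = ComponentSpec("P300", "target", (250.0, 450.0), "positive")


def _window_mask(times: np.ndarray, window: Tuple[float, float], fs: float) -> np.ndarray:
    a, b = window
    if a < times[0] - 1e-9 or b > times[-1] + 1000.0 / fs + 1e-9:
        raise InvalidArgumentError(f"window [{a}, {b}) outside data range")
    mask = (times >= a - 1e-9) & (times < b - 1e-9)
    if not mask.any():
        raise InvalidArgumentError(f"no samples in window [{a}, {b})")
    return mask


def component_amplitude(erp: ERP, spec: ComponentSpec) -> np.ndarray:
    """Per-channel mean amplitude (uV) over the component's half-open window."""
    mask = _window_mask(erp.times_ms, spec.window_ms, erp.fs)
    return erp.data[:, mask].mean(axis=1)


def component_latency(erp: ERP, spec: ComponentSpec) -> np.ndarray:
    """Per-channel peak latency (ms): the in-window extremum matching the
    component's polarity; ties resolve to the earliest sample."""
    mask = _window_mask(erp.times_ms, spec.window_ms, erp.fs)
    seg = erp.data[:, mask]
    times = erp.times_ms[mask]
    idx = np.argmin(seg, axis=1) if spec.polarity == "negative" else np.argmax(seg, axis=1)
    return times[idx]


def intertrial_topographic_similarity(
    epochs: EpochSet, spec: ComponentSpec, method: str = "loo"
) -> float:
    """Inter-trial consistency of the component-window topography.

    Each trial is collapsed to one channel-mean-centered topography over the
    component window.  ``method='loo'`` (default) correlates every trial with
    the mean of all other trials and averages; ``method='pairwise'`` averages
    all pairwise trial correlations.  Zero-variance trial topographies are
    skipped with a warning.
    """
    if epochs.n_trials < 2:
        raise InvalidArgumentError("similarity needs >= 2 trials")
    if method not in ("loo", "pairwise"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    mask = _window_mask(epochs.times_ms, spec.window_ms, epochs.fs)
    topos = epochs.data[:, mask, :].mean(axis=1)           # channels x trials
    topos = center_channels(topos)
    norms = np.linalg.norm(topos, axis=0)
    good = norms > 1e-12
    if not np.all(good):
        warnings.warn("zero-variance trial topographies skipped", stacklevel=2)
    topos = topos[:, good]
    n = topos.shape[1]
    if n < 2:
        raise InvalidArgumentError("fewer than 2 usable trials")

    if method == "pairwise":
        unit = topos / np.linalg.norm(topos, axis=0, keepdims=True)
        g = unit.T @ unit
        iu = np.triu_indices(n, k=1)
        return float(g[iu].mean())

    total = topos.sum(axis=1, keepdims=True)
    rs = []
    for i in range(n):
        rest = (total[:, 0] - topos[:, i]) / (n - 1)
        rest = rest - rest.mean()
        denom = np.linalg.norm(topos[:, i]) * np.linalg.norm(rest)
        if denom < 1e-12:
            warnings.warn("zero-variance leave-one-out mean skipped", stacklevel=2)
            continue
        rs.append(float(topos[:, i] @ rest / denom))
    if not rs:
        raise InvalidArgumentError("no valid trial correlations")
    return float(np.mean(rs))
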