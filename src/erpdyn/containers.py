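"""Core data containers: epoched EEG, averaged ERPs and windowed topography sequences.

All voltage data are in microvolts.  Epoch arrays are laid out
``channels x samples x trials``; averaged ERPs are ``channels x samples``.
Time is expressed in milliseconds relative to stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

GROUPS = ("TD", "ADHD-I", "ADHD-C")
CONDITIONS = ("standard", "target")

#: 19-channel international 10-20 montage (mastoids excluded).
TEN_TWENTY_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)


def _check_channel_names(names: Sequence[str], n_channels: int) -> tuple:
    names = tuple(str(c) for c in names)
    if len(names) != n_channels:
        raise InvalidArgumentError(
            f"channel_names has {len(names)} entries for {n_channels} channels"
        )
    if len(set(names)) != len(names):
        raise InvalidArgumentError("channel_names must be unique")
    return names


@dataclass
class EpochSet:
    """One subject/condition's epoched EEG: channels x samples x trials (uV)."""

    subject_id: str
    group: str
    condition: str
    data: np.ndarray
    channel_names: tuple
    fs: float
    t0_offset_ms: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError(
                f"epoch data must be channels x samples x trials, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("epoch data must be finite")
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        self.channel_names = _check_channel_names(self.channel_names, self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0_offset_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def with_data(self, data: np.ndarray) -> "EpochSet":
        return replace(self, data=data)


@dataclass
class ERP:
    """Condition-averaged waveform: channels x samples (uV)."""

    subject_id: str
    group: str
    condition: str
    data: np.ndarray
    channel_names: tuple
    fs: float
    t0_offset_ms: float
    n_trials_used: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError(
                f"ERP data must be channels x samples, got shape {self.data.shape}"
            )
        if self.n_trials_used < 1:
            raise InvalidArgumentError("n_trials_used must be >= 1")
        self.channel_names = _check_channel_names(self.channel_names, self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_offset_ms + np.arange(self.n_samples) * 1000.0 / self.fs


@dataclass
class TopoSequence:
    """Window-averaged scalp topographies: channels x n_windows (uV).

    ``window_edges`` are the half-open [a, b) window boundaries in ms,
    e.g. [0, 100, ..., 600] for the six canonical 100-ms windows T1..T6.
    """

    topos: np.ndarray
    window_edges: np.ndarray
    channel_names: tuple
    group: str = ""
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.topos = np.asarray(self.topos, dtype=float)
        self.window_edges = np.asarray(self.window_edges, dtype=float)
        if self.topos.ndim != 2:
            raise InvalidArgumentError("topos must be channels x windows")
        if len(self.window_edges) != self.topos.shape[1] + 1:
            raise InvalidArgumentError("window_edges must have n_windows + 1 entries")
        if not np.all(np.diff(self.window_edges) > 0):
            raise InvalidArgumentError("window_edges must be strictly increasing")
        self.channel_names = _check_channel_names(self.channel_names, self.topos.shape[0])

    @property
    def n_channels(self) -> int:
        return self.topos.shape[0]

    @property
    def n_windows(self) -> int:
        return self.topos.shape[1]

    @property
    def window_labels(self) -> tuple:
        return tuple(f"T{i + 1}" for i in range(self.n_windows))


def center_channels(x: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean from each topography (channel axis 0)."""
    x = np.asarray(x, dtype=float)
    return x - x.mean(axis=0, keepdims=True)


def same_montage(a, b) -> bool:
    return tuple(a.channel_names) == tuple(b.channel_names)
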