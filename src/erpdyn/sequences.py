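"""Microstate-inspired discrete state sequences and transition statistics.

Each time point of a subject's 0-600 ms response is labeled with the state
template of highest polarity-invariant spatial correlation, provided that
correlation clears the two-sided critical r at the chosen alpha
(df = n_channels - 2); otherwise it is labeled "Other".  Transition matrices
count consecutive label pairs at full sample resolution, self-pairs
included, with "Other" as a first-class state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy import stats as sps

from .containers import ERP
from .errors import InvalidArgumentError, UndefinedValueError
from .states import ProjectionTimecourse, StateBasis, _centered_window


@dataclass
class StateSeq:
    """Per-timepoint state labels: ints 0..K-1 for PC1..PCK, K for Other."""

    labels: np.ndarray
    K: int
    subject_id: str
    group: str
    condition: str
    fs: float
    alpha: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if np.any((self.labels < 0) | (self.labels > self.K)):
            raise InvalidArgumentError("labels out of range")

    @property
    def state_names(self) -> tuple:
        return tuple(f"PC{k + 1}" for k in range(self.K)) + ("Other",)

    @property
    def T(self) -> int:
        return len(self.labels)


@dataclass
class TransitionMatrix:
    counts: np.ndarray          # (K+1) x (K+1) pair counts
    P: np.ndarray               # row-stochastic where a row has outgoing pairs
    state_names: tuple
    n_transitions: int


def critical_r(alpha: float, df: int) -> float:
    """Two-sided critical Pearson |r| at significance alpha with df = n - 2."""
    if not 0 < alpha < 1 or df < 1:
        raise InvalidArgumentError("need 0 < alpha < 1 and df >= 1")
    t_crit = sps.t.isf(alpha / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def assign_states(
    erp: ERP, basis: StateBasis, alpha: float = 0.05
) -> StateSeq:
    """Label each 0-600 ms sample by its best polarity-invariant template match.

    label(t) = argmax_k |r(topo_t, template_k)| if that |r| exceeds the
    critical value, else Other; ties break toward the lowest-index PC.
    Zero-variance topographies are labeled Other with a warning.
    """
    if tuple(erp.channel_names) != tuple(basis.channel_names):
        raise InvalidArgumentError("montage mismatch")
    n_ch = len(basis.channel_names)
    if n_ch < 4:
        raise InvalidArgumentError("need >= 4 channels")
    centered = _centered_window(erp)            # channels x T
    K = basis.K
    r_crit = critical_r(alpha, n_ch - 2)

    norms = np.linalg.norm(centered, axis=0)
    good = norms > 1e-12
    if not np.all(good):
        warnings.warn("zero-variance topographies labeled Other", stacklevel=2)
    # templates are zero-mean unit-norm, topographies centered: Pearson r is
    # the normalised dot product
    labels = np.full(centered.shape[1], K, dtype=int)
    if good.any():
        rmat = np.abs(basis.templates @ centered[:, good]) / norms[good]
        best = np.argmax(rmat, axis=0)
        passed = rmat[best, np.arange(rmat.shape[1])] > r_crit
        sub = np.where(passed, best, K)
        labels[good] = sub
    return StateSeq(labels=labels, K=K, subject_id=erp.subject_id, group=erp.group,
                    condition=erp.condition, fs=erp.fs, alpha=alpha)


def transition_matrix(seq: StateSeq) -> TransitionMatrix:
    """Counts of consecutive label pairs (self-pairs included) and their
    row-normalised probabilities."""
    if seq.T < 2:
        raise InvalidArgumentError("need at least 2 time points")
    n = seq.K + 1
    counts = np.zeros((n, n))
    np.add.at(counts, (seq.labels[:-1], seq.labels[1:]), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(row_sums > 0, counts / np.maximum(row_sums, 1e-300), 0.0)
    return TransitionMatrix(counts=counts, P=P, state_names=seq.state_names,
                            n_transitions=seq.T - 1)


def _state_index(tm: TransitionMatrix, state: Union[int, str]) -> int:
    if isinstance(state, str):
        try:
            return tm.state_names.index(state)
        except ValueError:
            raise InvalidArgumentError(f"unknown state {state!r}") from None
    if not 0 <= state < len(tm.state_names):
        raise InvalidArgumentError(f"state index {state} out of range")
    return int(state)


def state_stability(tm: TransitionMatrix) -> np.ndarray:
    """Self-transition probability per state; NaN for states with no outgoing
    transitions (never visited before the final sample)."""
    out = np.diag(tm.P).astype(float).copy()
    unvisited = tm.counts.sum(axis=1) == 0
    if unvisited.any():
        warnings.warn("states with no outgoing transitions have NaN stability",
                      stacklevel=2)
        out[unvisited] = np.nan
    return out


def transition_probability(
    tm: TransitionMatrix, from_state: Union[int, str], to_state: Union[int, str]
) -> float:
    i = _state_index(tm, from_state)
    j = _state_index(tm, to_state)
    if tm.counts[i].sum() == 0:
        raise UndefinedValueError(
            f"state {tm.state_names[i]} has no outgoing transitions"
        )
    return float(tm.P[i, j])


def other_proportion(seq: StateSeq) -> float:
    """Fraction of samples labeled Other."""
    if seq.T < 1:
        raise InvalidArgumentError("empty sequence")
    return float(np.mean(seq.labels == seq.K))
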