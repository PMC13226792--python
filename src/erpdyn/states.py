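"""Data-driven dominant topographic states and time-resolved projections.

The state basis is extracted by PCA on the channel-mean-centered,
group-averaged responses of all groups and both conditions concatenated
along time (0-600 ms).  Per-subject ERPs are then projected sample-by-sample
onto the retained templates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .containers import ERP, TopoSequence, center_channels
from .errors import InvalidArgumentError
from .stats import fdr_bh

PROJECTION_WINDOW_MS = (0.0, 600.0)


@dataclass
class StateBasis:
    """K dominant topographic states (channel-mean-centered, unit norm)."""

    templates: np.ndarray       # K x n_channels, orthonormal rows
    explained_var: np.ndarray   # K fractions, non-increasing
    channel_names: tuple
    provenance: str = ""

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        self.explained_var = np.asarray(self.explained_var, dtype=float)

    @property
    def K(self) -> int:
        return self.templates.shape[0]

    @property
    def state_names(self) -> tuple:
        return tuple(f"PC{k + 1}" for k in range(self.K))


@dataclass
class ProjectionTimecourse:
    coeffs: np.ndarray          # K x T
    subject_id: str
    group: str
    condition: str
    fs: float
    t_start_ms: float = 0.0

    @property
    def K(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[1]


def _centered_window(erp: ERP, window_ms=PROJECTION_WINDOW_MS) -> np.ndarray:
    """Channel-mean-centered ERP samples restricted to the half-open window."""
    times = erp.times_ms
    a, b = window_ms
    mask = (times >= a - 1e-9) & (times < b - 1e-9)
    if not mask.any():
        raise InvalidArgumentError(f"ERP has no samples in [{a}, {b}) ms")
    return center_channels(erp.data[:, mask])


def extract_states(
    inputs: Sequence[Union[ERP, TopoSequence]], K: int = 4
) -> StateBasis:
    """PCA over the temporal concatenation of channel-centered responses.

    ``inputs`` are typically the six group-averaged ERPs (3 groups x 2
    conditions), restricted to 0-600 ms; TopoSequences are accepted for
    window-resolution variants.  Deterministic sign convention: the
    largest-magnitude loading element of each template is positive.
    """
    if not inputs:
        raise InvalidArgumentError("no inputs")
    ref_names = tuple(inputs[0].channel_names)
    cols: List[np.ndarray] = []
    for item in inputs:
        if tuple(item.channel_names) != ref_names:
            raise InvalidArgumentError("montage mismatch across inputs")
        if isinstance(item, TopoSequence):
            cols.append(center_channels(item.topos))
        else:
            cols.append(_centered_window(item))
    x = np.concatenate(cols, axis=1).T          # timepoints x channels
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * max(s[0], 1e-300)))
    if rank < K:
        raise InvalidArgumentError(
            f"concatenated responses have rank {rank} < K={K}; "
            "reduce K or provide richer input"
        )
    var = s**2 / np.sum(s**2)
    templates = vt[:K].copy()
    for k in range(K):
        if templates[k, np.argmax(np.abs(templates[k]))] < 0:
            templates[k] = -templates[k]
    return StateBasis(
        templates=templates,
        explained_var=var[:K],
        channel_names=ref_names,
        provenance=f"PCA of {len(inputs)} concatenated responses, {x.shape[0]} timepoints",
    )


def project_timecourse(erp: ERP, basis: StateBasis) -> ProjectionTimecourse:
    """Sample-wise projection coefficients onto each state template."""
    if tuple(erp.channel_names) != tuple(basis.channel_names):
        raise InvalidArgumentError("montage mismatch between ERP and basis")
    centered = _centered_window(erp)
    return ProjectionTimecourse(
        coeffs=basis.templates @ centered,
        subject_id=erp.subject_id,
        group=erp.group,
        condition=erp.condition,
        fs=erp.fs,
        t_start_ms=PROJECTION_WINDOW_MS[0],
    )


def projection_difference(
    target_tc: ProjectionTimecourse, standard_tc: ProjectionTimecourse
) -> np.ndarray:
    """Element-wise target minus standard projection coefficients (K x T)."""
    if target_tc.coeffs.shape != standard_tc.coeffs.shape:
        raise InvalidArgumentError("projection shape mismatch")
    return target_tc.coeffs - standard_tc.coeffs


def template_group_correlation(
    basis: StateBasis, group_seq: TopoSequence, fdr_q: float = 0.05
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Polarity-ignored spatial correlations |r| between each template and each
    window topography, with FDR-corrected significance over the K x W grid.

    The p-value is the standard two-sided t test on r (df = n_channels - 2),
    which is exactly the tail probability of |r| under the null, i.e. the
    polarity-invariant (folded-null) test.
    """
    if tuple(group_seq.channel_names) != tuple(basis.channel_names):
        raise InvalidArgumentError("montage mismatch")
    n_ch = len(basis.channel_names)
    K, W = basis.K, group_seq.n_windows
    absr = np.full((K, W), np.nan)
    p = np.full((K, W), np.nan)
    centered = center_channels(group_seq.topos)
    for w in range(W):
        topo = centered[:, w]
        if np.std(topo) < 1e-12:
            continue
        for k in range(K):
            r, pp = sps.pearsonr(basis.templates[k], topo)
            absr[k, w] = abs(r)
            p[k, w] = pp
    significant = np.zeros((K, W), dtype=bool)
    defined = np.isfinite(p)
    if defined.any():
        rej, _ = fdr_bh(p[defined], q=fdr_q)
        significant[defined] = rej
    return absr, p, significant


def subject_variance_explained(erp: ERP, basis: StateBasis) -> np.ndarray:
    """Fraction of the centered 0-600 ms signal energy captured by each state.

    fraction_k = sum_t coeffs[k, t]^2 / sum_t ||centered topo(t)||^2; the
    fractions sum to <= 1, with equality iff the ERP lies in the template span.
    """
    centered = _centered_window(erp)
    total = float(np.sum(centered**2))
    if total < 1e-300:
        raise InvalidArgumentError("zero-energy ERP; variance fractions undefined")
    coeffs = basis.templates @ centered
    return np.sum(coeffs**2, axis=1) / total
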