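"""Time-resolved topographic correlation analysis across the six windows."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .containers import TopoSequence, same_montage
from .errors import InvalidArgumentError
from .stats import fdr_bh


@dataclass
class CorrMatrix:
    """Window-by-window Pearson correlation grid with FDR significance.

    Cells with a zero-variance topography are undefined and stored as NaN
    in both ``r`` and ``p``; they never count as significant.
    """

    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    row_axis: str
    col_axis: str
    fdr_q: float = 0.05

    @property
    def n_rows(self) -> int:
        return self.r.shape[0]


def group_mean_toposequence(seqs: Sequence[TopoSequence]) -> TopoSequence:
    """Element-wise mean of subject toposequences sharing a montage."""
    if len(seqs) < 1:
        raise InvalidArgumentError("need >= 1 toposequence")
    ref = seqs[0]
    for s in seqs[1:]:
        if not same_montage(ref, s) or s.topos.shape != ref.topos.shape:
            raise InvalidArgumentError("montage/shape mismatch across subjects")
        if not np.allclose(s.window_edges, ref.window_edges):
            raise InvalidArgumentError("window edges differ across subjects")
    mean = np.mean([s.topos for s in seqs], axis=0)
    return TopoSequence(
        topos=mean,
        window_edges=ref.window_edges,
        channel_names=ref.channel_names,
        group=ref.group,
        condition=ref.condition,
        subject_id="group-mean",
    )


def cross_corr_matrix(
    seq_a: TopoSequence, seq_b: TopoSequence, fdr_q: float = 0.05
) -> CorrMatrix:
    """Pearson correlation across channels between every window pair of two
    toposequences; p-values from the two-sided t test (df = n_channels - 2),
    Benjamini-Hochberg FDR over all defined cells."""
    if not same_montage(seq_a, seq_b):
        raise InvalidArgumentError("montage mismatch")
    if seq_a.n_channels < 3:
        raise InvalidArgumentError("need >= 3 channels for correlation inference")
    na, nb = seq_a.n_windows, seq_b.n_windows
    r = np.full((na, nb), np.nan)
    p = np.full((na, nb), np.nan)
    for i in range(na):
        a = seq_a.topos[:, i]
        if np.std(a) < 1e-12:
            continue
        for j in range(nb):
            b = seq_b.topos[:, j]
            if np.std(b) < 1e-12:
                continue
            rr, pp = sps.pearsonr(a, b)
            r[i, j] = rr
            p[i, j] = pp
    significant = np.zeros((na, nb), dtype=bool)
    defined = np.isfinite(p)
    if defined.any():
        rej, _ = fdr_bh(p[defined], q=fdr_q)
        significant[defined] = rej
    label_a = f"{seq_a.group}/{seq_a.condition}".strip("/")
    label_b = f"{seq_b.group}/{seq_b.condition}".strip("/")
    return CorrMatrix(r=r, p=p, significant=significant,
                      row_axis=label_a, col_axis=label_b, fdr_q=fdr_q)


def max_alignment_displacement(
    corr: CorrMatrix, exclude_diagonal: bool = False
) -> Tuple[np.ndarray, float]:
    """Per-row column of maximal r and the mean |row - argmax| displacement.

    Ties resolve to the smallest column.  ``exclude_diagonal`` removes the
    trivially-1 diagonal, mandatory when scanning a within-group
    self-correlation matrix.  Rows with no defined cells are skipped (NaN in
    the returned argmax array) with a warning.
    """
    r = corr.r.copy()
    if exclude_diagonal:
        n = min(r.shape)
        r[np.arange(n), np.arange(n)] = np.nan
    argmax = np.full(r.shape[0], np.nan)
    disps = []
    for i in range(r.shape[0]):
        row = r[i]
        if not np.isfinite(row).any():
            warnings.warn(f"row {i} has no defined cells; skipped", stacklevel=2)
            continue
        best = np.nanmax(row)
        j = int(np.flatnonzero(row == best)[0])
        argmax[i] = j
        disps.append(abs(i - j))
    if not disps:
        raise InvalidArgumentError("no rows with defined cells")
    return argmax, float(np.mean(disps))
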