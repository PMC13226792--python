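"""Low-dimensional trajectory reconstruction and geometry, with bootstrap
pseudo-population inference.

The state space is the plane of the first two principal components of the
pooled, channel-mean-centered window topographies (all groups, both
conditions).  Trajectories are the six window topographies projected into
that plane; geometry metrics (inter-trajectory distance, angular separation
relative to the T1 anchor, path length) are invariant to orthogonal maps of
the basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .containers import TopoSequence, center_channels, same_montage
from .errors import InvalidArgumentError
from .topo import group_mean_toposequence

CONDITIONS = ("standard", "target")


@dataclass
class Basis2D:
    loadings: np.ndarray        # 2 x n_channels, orthonormal rows
    explained_var: np.ndarray   # 2 fractions, non-increasing
    channel_mean: np.ndarray    # mean pooled topography (reference only)
    channel_names: tuple

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained_var = np.asarray(self.explained_var, dtype=float)
        if self.loadings.shape[0] != 2:
            raise InvalidArgumentError("Basis2D requires exactly 2 components")


@dataclass
class Trajectory:
    points: np.ndarray          # n_windows x 2
    group: str = ""
    condition: str = ""
    window_labels: tuple = ()

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidArgumentError("trajectory points must be n_windows x 2")
        if not np.all(np.isfinite(self.points)):
            raise InvalidArgumentError("trajectory points must be finite")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class BootstrapResult:
    metric: str
    group: str
    values: np.ndarray
    n_per_group: int
    iterations: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    out = loadings.copy()
    for k in range(out.shape[0]):
        if out[k, np.argmax(np.abs(out[k]))] < 0:
            out[k] = -out[k]
    return out


def fit_basis(toposequences: Sequence[TopoSequence]) -> Basis2D:
    """PCA (SVD) over the pooled channel-mean-centered window topographies.

    Component signs are fixed by making each loading's largest-magnitude
    element positive, so the fit is deterministic.
    """
    if not toposequences:
        raise InvalidArgumentError("need at least one toposequence")
    ref = toposequences[0]
    cols = []
    for s in toposequences:
        if not same_montage(ref, s):
            raise InvalidArgumentError("montage mismatch in pooled toposequences")
        cols.append(center_channels(s.topos))
    x = np.concatenate(cols, axis=1).T          # observations x channels
    if x.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 pooled window topographies")
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    if s.size < 2 or s[1] <= 1e-12 * max(s[0], 1e-300):
        raise InvalidArgumentError("pooled topographies have rank < 2")
    var = s**2 / np.sum(s**2)
    loadings = _fix_signs(vt[:2])
    return Basis2D(
        loadings=loadings,
        explained_var=var[:2],
        channel_mean=x.mean(axis=0),
        channel_names=ref.channel_names,
    )


def project_trajectory(seq: TopoSequence, basis: Basis2D) -> Trajectory:
    """Project each channel-mean-centered window topography onto the basis."""
    if tuple(seq.channel_names) != tuple(basis.channel_names):
        raise InvalidArgumentError("montage mismatch between sequence and basis")
    centered = center_channels(seq.topos)
    points = (basis.loadings @ centered).T      # n_windows x 2
    return Trajectory(points=points, group=seq.group, condition=seq.condition,
                      window_labels=seq.window_labels)


def trajectory_distance(traj_a: Trajectory, traj_b: Trajectory) -> Tuple[float, np.ndarray]:
    """Per-window Euclidean distances between two trajectories and their sum."""
    if traj_a.n_points != traj_b.n_points:
        raise InvalidArgumentError("window count mismatch")
    per_window = np.linalg.norm(traj_a.points - traj_b.points, axis=1)
    return float(per_window.sum()), per_window


def angular_separation(traj_a: Trajectory, traj_b: Trajectory) -> np.ndarray:
    """Angle (degrees) between the two trajectories' displacements from T1.

    For each window w >= 2: u = A(w) - A(T1), v = B(w) - B(T1); the angle is
    arccos of their normalised dot product, in [0, 180].  Windows where
    either displacement is (numerically) zero are NaN.
    """
    if traj_a.n_points != traj_b.n_points:
        raise InvalidArgumentError("window count mismatch")
    u = traj_a.points[1:] - traj_a.points[0]
    v = traj_b.points[1:] - traj_b.points[0]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    out = np.full(traj_a.n_points - 1, np.nan)
    ok = (nu > 1e-12) & (nv > 1e-12)
    cosang = np.einsum("ij,ij->i", u[ok], v[ok]) / (nu[ok] * nv[ok])
    out[ok] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return out


def angular_from_own_t1(traj: Trajectory) -> np.ndarray:
    """Alternative reading: angle of each window's position relative to the
    trajectory's own T1 vector (both measured from the origin)."""
    ref = traj.points[0]
    out = np.full(traj.n_points - 1, np.nan)
    nr = np.linalg.norm(ref)
    if nr < 1e-12:
        return out
    for i, pt in enumerate(traj.points[1:]):
        npnt = np.linalg.norm(pt)
        if npnt < 1e-12:
            continue
        cosang = float(pt @ ref) / (npnt * nr)
        out[i] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return out


def trajectory_length(traj: Trajectory) -> Tuple[float, np.ndarray]:
    """Consecutive inter-window step distances and total path length."""
    if traj.n_points < 2:
        raise InvalidArgumentError("need >= 2 points")
    steps = np.linalg.norm(np.diff(traj.points, axis=0), axis=1)
    return float(steps.sum()), steps


# ---------------------------------------------------------------------------
# bootstrap pseudo-populations


def _align_to_reference(basis: Basis2D, reference: Basis2D) -> Basis2D:
    """Sign-flip each component to correlate positively with its reference
    counterpart (no rotation; geometry metrics are orthogonal-invariant)."""
    loadings = basis.loadings.copy()
    for k in range(2):
        if float(loadings[k] @ reference.loadings[k]) < 0:
            loadings[k] = -loadings[k]
    return Basis2D(loadings=loadings, explained_var=basis.explained_var,
                   channel_mean=basis.channel_mean, channel_names=basis.channel_names)


def _group_metrics(
    group_seqs: Mapping[str, TopoSequence], basis: Basis2D
) -> Dict[str, float]:
    traj_s = project_trajectory(group_seqs["standard"], basis)
    traj_t = project_trajectory(group_seqs["target"], basis)
    dist_total, _ = trajectory_distance(traj_s, traj_t)
    len_s, _ = trajectory_length(traj_s)
    len_t, _ = trajectory_length(traj_t)
    angles = angular_separation(traj_s, traj_t)
    return {
        "intertrajectory_distance": dist_total,
        "trajectory_length_standard": len_s,
        "trajectory_length_target": len_t,
        "mean_angular_separation": float(np.nanmean(angles)) if np.isfinite(angles).any() else np.nan,
    }


def bootstrap_metrics(
    subject_toposequences: Mapping[str, Sequence[Mapping[str, TopoSequence]]],
    n_per_group: int = 15,
    iterations: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> Dict[str, Dict[str, BootstrapResult]]:
    """Pseudo-population bootstrap of trajectory geometry metrics.

    ``subject_toposequences`` maps group -> list of per-subject dicts
    {condition: TopoSequence}.  Each iteration samples ``n_per_group``
    subjects per group (without replacement by default), averages their
    toposequences per group x condition, refits the 2-D basis on the pooled
    averages, aligns it to the full-sample reference by component sign, and
    recomputes all metrics.  Returns metric -> group -> BootstrapResult.
    """
    groups = list(subject_toposequences.keys())
    for g in groups:
        n = len(subject_toposequences[g])
        if n < 2:
            raise InvalidArgumentError(f"group {g} has fewer than 2 subjects")
        if n < n_per_group and not replace:
            warnings.warn(
                f"group {g} has {n} < {n_per_group} subjects; sampling with replacement",
                stacklevel=2,
            )

    def group_averages(indices: Optional[Mapping[str, np.ndarray]] = None):
        avgs: Dict[str, Dict[str, TopoSequence]] = {}
        pooled: List[TopoSequence] = []
        for g in groups:
            subs = subject_toposequences[g]
            sel = subs if indices is None else [subs[i] for i in indices[g]]
            avgs[g] = {}
            for cond in CONDITIONS:
                seq = group_mean_toposequence([s[cond] for s in sel])
                seq.group, seq.condition = g, cond
                avgs[g][cond] = seq
                pooled.append(seq)
        return avgs, pooled

    full_avgs, full_pooled = group_averages()
    reference = fit_basis(full_pooled)

    rng = np.random.default_rng(seed)
    records: Dict[str, Dict[str, List[float]]] = {}
    for _ in range(iterations):
        indices = {}
        for g in groups:
            n = len(subject_toposequences[g])
            use_replace = replace or n < n_per_group
            indices[g] = rng.choice(n, size=n_per_group, replace=use_replace)
        avgs, pooled = group_averages(indices)
        basis = _align_to_reference(fit_basis(pooled), reference)
        for g in groups:
            metrics = _group_metrics(avgs[g], basis)
            for name, val in metrics.items():
                records.setdefault(name, {}).setdefault(g, []).append(val)

    return {
        name: {
            g: BootstrapResult(
                metric=name, group=g, values=np.asarray(vals),
                n_per_group=n_per_group, iterations=iterations, seed=seed,
            )
            for g, vals in by_group.items()
        }
        for name, by_group in records.items()
    }
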