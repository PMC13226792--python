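"""Synthetic oddball-ERP cohort generator with planted ground truth.

Each subject's response is built from a small set of orthonormal, channel-mean-
centered scalp templates whose activation time courses are specified as
coefficients on the six canonical 100-ms windows (0-600 ms).  Trials add
i.i.d. Gaussian sensor noise and a per-trial latency shift of the activation
curves.  Clinical covariates are drawn around group means with an optional
linear loading on each subject's latent condition-separation scalar, so that
downstream brain-behaviour correlation analyses have a known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import CONDITIONS, GROUPS, TEN_TWENTY_19, EpochSet
from .errors import InvalidArgumentError

N_WINDOWS = 6
WINDOW_MS = 100.0

# ---------------------------------------------------------------------------
# configuration


@dataclass
class ClinicalVar:
    """One clinical covariate: per-group mean, residual SD and latent loading.

    Generated value = group_mean + loading * (separation - 1) + N(0, sd),
    truncated at ``floor``.  ``loading`` links the covariate to the subject's
    latent condition-separation scalar (mean 1 across the population).
    """

    name: str
    means: Dict[str, float]
    sd: float
    loading: float = 0.0
    floor: Optional[float] = 0.0


def loading_for_correlation(r: float, sd_latent: float, sd_noise: float) -> float:
    """Loading that yields population Pearson r between covariate and latent scalar."""
    if not -1.0 < r < 1.0:
        raise InvalidArgumentError("r must be in (-1, 1)")
    return r / np.sqrt(1.0 - r * r) * sd_noise / sd_latent


def default_clinical_vars() -> List[ClinicalVar]:
    return [
        ClinicalVar("age", {"TD": 9.0, "ADHD-I": 9.6, "ADHD-C": 8.7}, 1.9, floor=None),
        ClinicalVar("iq", {"TD": 88.2, "ADHD-I": 91.4, "ADHD-C": 92.9}, 13.0, floor=None),
        ClinicalVar("rt_ms", {"TD": 579.0, "ADHD-I": 539.0, "ADHD-C": 584.0}, 130.0),
        ClinicalVar("acc_pct", {"TD": 98.1, "ADHD-I": 98.7, "ADHD-C": 97.7}, 3.0),
        ClinicalVar("snap_attention", {"TD": 1.12, "ADHD-I": 1.74, "ADHD-C": 2.03}, 0.55,
                    loading=-0.8),
        ClinicalVar("snap_hyperactive", {"TD": 0.68, "ADHD-I": 0.87, "ADHD-C": 1.70}, 0.55),
        ClinicalVar("conners_hyperactivity", {"TD": 0.73, "ADHD-I": 1.14, "ADHD-C": 1.42}, 0.40,
                    loading=-0.3),
        ClinicalVar("weiss_family", {"TD": 0.32, "ADHD-I": 0.60, "ADHD-C": 0.82}, 0.35),
    ]


def default_activation_curves() -> Dict[Tuple[str, str], np.ndarray]:
    """Default per group x condition activation coefficients (n_states x 6).

    The four states occupy disjoint window supports, so state time courses
    are mutually orthogonal over the pooled responses and the planted
    templates are exactly recoverable by PCA on noiseless data.  Target
    responses scale each state's standard-condition coefficients by a
    per-group gain: near-unity gains for ADHD-I (conditions barely
    separate), intermediate for TD, exaggerated for ADHD-C.
    """
    standard = np.array(
        [
            [1.00, 0.60, 0.00, 0.00, 0.00, 0.00],   # early sensory
            [0.00, 0.00, 0.80, 0.00, 0.00, 0.00],   # N2-like
            [0.00, 0.00, 0.00, 0.90, 0.63, 0.00],   # P3-like
            [0.00, 0.00, 0.00, 0.00, 0.00, 0.60],   # late
        ]
    )
    target_gain = {
        "TD": np.array([0.80, 1.30, 1.80, 1.20]),
        "ADHD-I": np.array([0.95, 1.10, 1.25, 1.05]),
        "ADHD-C": np.array([0.55, 1.70, 2.80, 1.65]),
    }
    curves: Dict[Tuple[str, str], np.ndarray] = {}
    for g in GROUPS:
        curves[(g, "standard")] = standard.copy()
        curves[(g, "target")] = target_gain[g][:, None] * standard
    return curves


@dataclass
class GeneratorConfig:
    """Full parameterisation of a synthetic cohort."""

    n_per_group: int = 15
    n_channels: int = 19
    channel_names: tuple = TEN_TWENTY_19
    fs: float = 500.0
    epoch_window_ms: Tuple[float, float] = (-200.0, 800.0)
    n_standard: int = 278
    n_target: int = 80
    n_states: int = 4
    activation_curves: Optional[Dict[Tuple[str, str], np.ndarray]] = None
    ramp_ms: float = 20.0
    trial_noise_sd: float = 1.0
    latency_jitter_sd_ms: float = 10.0
    amplitude_range: Tuple[float, float] = (2.0, 10.0)
    separation_sd: float = 0.15
    clinical_vars: Optional[List[ClinicalVar]] = None
    male_fraction: Dict[str, float] = field(
        default_factory=lambda: {"TD": 0.73, "ADHD-I": 0.71, "ADHD-C": 0.76}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states > self.n_channels - 1 or self.n_states < 1:
            raise InvalidArgumentError("need 1 <= n_states <= n_channels - 1")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        lo, hi = self.epoch_window_ms
        if not (lo <= 0.0 and hi >= 600.0):
            raise InvalidArgumentError("epoch window must span at least 0..600 ms")
        if self.n_standard <= 0 or self.n_target <= 0:
            raise InvalidArgumentError("trial counts must be positive")
        if self.trial_noise_sd < 0 or self.latency_jitter_sd_ms < 0:
            raise InvalidArgumentError("noise/jitter SDs must be non-negative")
        if self.amplitude_range[0] <= 0 or self.amplitude_range[1] < self.amplitude_range[0]:
            raise InvalidArgumentError("amplitude_range must be positive and ordered")
        if self.activation_curves is None:
            self.activation_curves = default_activation_curves()
        for key, arr in self.activation_curves.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.n_states, N_WINDOWS):
                raise InvalidArgumentError(
                    f"activation curve {key} must be n_states x 6, got {arr.shape}"
                )
            self.activation_curves[key] = arr
        if self.clinical_vars is None:
            self.clinical_vars = default_clinical_vars()
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.n_channels:
            raise InvalidArgumentError("channel_names length must equal n_channels")

    @property
    def n_samples(self) -> int:
        lo, hi = self.epoch_window_ms
        return int(round((hi - lo) * self.fs / 1000.0))

    def trials_for(self, condition: str) -> int:
        return self.n_standard if condition == "standard" else self.n_target


@dataclass
class GroundTruth:
    """Planted latent structure of a generated cohort."""

    templates: np.ndarray                       # n_states x n_channels
    activation: Dict[Tuple[str, str], np.ndarray]  # (subject, condition) -> n_states x 6
    separation: Dict[str, float]                # subject -> latent scalar
    amplitude: Dict[str, float]                 # subject -> uV scale
    clinical_loadings: Dict[str, float]         # covariate -> loading
    seed: int


# ---------------------------------------------------------------------------
# templates


def make_state_templates(n_channels: int, n_states: int, seed: int) -> np.ndarray:
    """Random orthonormal, channel-mean-centered templates (n_states x n_channels).

    Deterministic given the seed.  The zero-mean constraint restricts the
    available subspace to dimension n_channels - 1, hence the precondition.
    """
    if not 1 <= n_states <= n_channels - 1:
        raise InvalidArgumentError(
            f"n_states must be in [1, {n_channels - 1}], got {n_states}"
        )
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_channels, n_states))
    x -= x.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(x)
    if np.min(np.abs(np.diag(r))) < 1e-10:
        raise InvalidArgumentError("degenerate random draw; use a different seed")
    # fix signs so the result does not depend on LAPACK conventions
    q *= np.sign(np.diag(r))
    templates = q.T
    for k in range(n_states):
        if templates[k, np.argmax(np.abs(templates[k]))] < 0:
            templates[k] = -templates[k]
    return templates


# ---------------------------------------------------------------------------
# activation curve sampling


def sample_activation(
    coeffs: np.ndarray,
    fs: float,
    epoch_window_ms: Tuple[float, float],
    ramp_ms: float = 20.0,
) -> np.ndarray:
    """Expand per-window coefficients to sample resolution over the epoch.

    Piecewise-constant on the six half-open 100-ms windows, zero before
    stimulus onset and after 600 ms.  With ``ramp_ms`` > 0 each boundary
    transition is linearised over [b, b + ramp_ms]; with ramp_ms == 0 the
    curve is exactly piecewise-constant with half-open windows.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    lo, hi = epoch_window_ms
    n = int(round((hi - lo) * fs / 1000.0))
    t = lo + np.arange(n) * 1000.0 / fs
    edges = np.arange(N_WINDOWS + 1) * WINDOW_MS
    if coeffs.ndim == 1:
        coeffs = coeffs[None, :]
        squeeze = True
    else:
        squeeze = False
    out = np.zeros((coeffs.shape[0], n))
    if ramp_ms <= 0:
        idx = np.searchsorted(edges, t, side="right") - 1
        valid = (idx >= 0) & (idx < N_WINDOWS) & (t >= 0)
        out[:, valid] = coeffs[:, idx[valid]]
    else:
        # knot sequence: value holds until each boundary, then ramps to the
        # next window's value over ramp_ms
        for k in range(coeffs.shape[0]):
            vals = np.concatenate([[0.0], coeffs[k], [0.0]])
            xs = [lo]
            ys = [0.0]
            for j, b in enumerate(edges):
                xs.extend([b, b + ramp_ms])
                ys.extend([vals[j], vals[j + 1]])
            xs.append(hi)
            ys.append(0.0)
            out[k] = np.interp(t, xs, ys)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# subject / cohort simulation


def _subject_curves(
    config: GeneratorConfig, group: str, condition: str, separation: float
) -> np.ndarray:
    """Per-window coefficients for this subject (n_states x 6).

    The subject's target response is the group standard curve plus
    ``separation`` times the group-level (target - standard) deviation, so
    the latent scalar directly controls condition separation in state space.
    """
    std = config.activation_curves[(group, "standard")]
    if condition == "standard":
        return std.copy()
    tgt = config.activation_curves[(group, "target")]
    return std + separation * (tgt - std)


def simulate_subject(
    config: GeneratorConfig,
    group: str,
    condition: str,
    templates: np.ndarray,
    subject_seed: int,
    *,
    subject_id: Optional[str] = None,
    amplitude: Optional[float] = None,
    separation: Optional[float] = None,
) -> EpochSet:
    """Simulate one subject/condition EpochSet.

    Trial t, sample s:  sum_k a_k(s - delta_t) * template_k + noise, with
    delta_t a truncated-normal latency shift applied to the activation
    curves only and noise i.i.d. Gaussian per channel/sample.
    """
    if group not in GROUPS:
        raise InvalidArgumentError(f"unknown group {group!r}")
    if condition not in CONDITIONS:
        raise InvalidArgumentError(f"unknown condition {condition!r}")
    templates = np.asarray(templates, dtype=float)
    if templates.shape != (config.n_states, config.n_channels):
        raise InvalidArgumentError("templates shape mismatch with config")

    rng = np.random.default_rng(subject_seed)
    if amplitude is None:
        amplitude = rng.uniform(*config.amplitude_range)
    if separation is None:
        separation = max(rng.normal(1.0, config.separation_sd), 0.0)

    coeffs = amplitude * _subject_curves(config, group, condition, separation)
    act = sample_activation(coeffs, config.fs, config.epoch_window_ms, config.ramp_ms)
    clean = templates.T @ act                      # channels x samples
    n_samples = clean.shape[1]
    n_trials = config.trials_for(condition)

    # per-trial latency shifts in samples, truncated at +-3 SD
    if config.latency_jitter_sd_ms > 0:
        d_ms = rng.normal(0.0, config.latency_jitter_sd_ms, size=n_trials)
        lim = 3.0 * config.latency_jitter_sd_ms
        d_ms = np.clip(d_ms, -lim, lim)
        shifts = np.round(d_ms * config.fs / 1000.0).astype(int)
    else:
        shifts = np.zeros(n_trials, dtype=int)

    data = np.empty((config.n_channels, n_samples, n_trials))
    active = np.abs(clean).max(axis=0) > 0
    clipped = False
    for t_idx, sh in enumerate(shifts):
        if sh == 0:
            trial = clean
        else:
            trial = np.zeros_like(clean)
            if sh > 0:
                trial[:, sh:] = clean[:, :-sh]
                clipped = clipped or bool(active[-sh:].any())
            else:
                trial[:, :sh] = clean[:, -sh:]
                clipped = clipped or bool(active[:-sh].any())
        data[:, :, t_idx] = trial
    if clipped:
        warnings.warn(
            "latency jitter shifted activation outside the epoch; clipped",
            stacklevel=2,
        )
    if config.trial_noise_sd > 0:
        data += rng.normal(0.0, config.trial_noise_sd, size=data.shape)

    return EpochSet(
        subject_id=subject_id or f"{group}-s{subject_seed}",
        group=group,
        condition=condition,
        data=data,
        channel_names=config.channel_names,
        fs=config.fs,
        t0_offset_ms=config.epoch_window_ms[0],
    )


def simulate_cohort(
    config: GeneratorConfig,
) -> Tuple[List[EpochSet], pd.DataFrame, GroundTruth]:
    """Generate the full cohort: 3 * n_per_group subjects, both conditions each.

    Returns (epoch sets, clinical table, ground truth).  Reproducible and
    byte-identical given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    template_seed, clin_seed = [int(s.generate_state(1)[0]) for s in ss.spawn(2)]
    templates = make_state_templates(config.n_channels, config.n_states, template_seed)

    subj_ss = np.random.SeedSequence((config.seed, 1))
    children = subj_ss.spawn(3 * config.n_per_group * 3)

    epochsets: List[EpochSet] = []
    activation: Dict[Tuple[str, str], np.ndarray] = {}
    separation: Dict[str, float] = {}
    amplitude: Dict[str, float] = {}
    rows = []
    clin_rng = np.random.default_rng(clin_seed)

    idx = 0
    for group in GROUPS:
        n_male = int(round(config.male_fraction.get(group, 0.5) * config.n_per_group))
        for i in range(config.n_per_group):
            sid = f"{group}-{i + 1:03d}"
            draw_rng = np.random.default_rng(children[idx])
            amp = draw_rng.uniform(*config.amplitude_range)
            sep = max(draw_rng.normal(1.0, config.separation_sd), 0.0)
            amplitude[sid] = amp
            separation[sid] = sep
            for j, condition in enumerate(CONDITIONS):
                seed_k = int(children[idx + 1 + j].generate_state(1)[0])
                ep = simulate_subject(
                    config, group, condition, templates, seed_k,
                    subject_id=sid, amplitude=amp, separation=sep,
                )
                epochsets.append(ep)
                activation[(sid, condition)] = amp * _subject_curves(
                    config, group, condition, sep
                )
            idx += 3

            row = {"subject": sid, "group": group, "sex": "M" if i < n_male else "F"}
            for var in config.clinical_vars:
                val = (
                    var.means[group]
                    + var.loading * (sep - 1.0)
                    + clin_rng.normal(0.0, var.sd)
                )
                if var.floor is not None:
                    val = max(val, var.floor)
                row[var.name] = val
            rows.append(row)

    clinical = pd.DataFrame(rows)
    truth = GroundTruth(
        templates=templates,
        activation=activation,
        separation=separation,
        amplitude=amplitude,
        clinical_loadings={v.name: v.loading for v in config.clinical_vars},
        seed=config.seed,
    )
    return epochsets, clinical, truth
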