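import numpy as np
import pytest

from erpdyn.containers import CONDITIONS, GROUPS, EpochSet
from erpdyn.preprocess import condition_average, preprocess_epochs, window_means
from erpdyn.synthetic import GeneratorConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_channel_names(n):
    return tuple(f"ch{i}" for i in range(n))


@pytest.fixture
def make_epochs():
    """Factory for small EpochSet fixtures from raw arrays."""

    def _make(data, fs=500.0, t0=-200.0, condition="standard", group="TD",
              subject="s1"):
        data = np.asarray(data, dtype=float)
        return EpochSet(
            subject_id=subject, group=group, condition=condition, data=data,
            channel_names=small_channel_names(data.shape[0]), fs=fs,
            t0_offset_ms=t0,
        )

    return _make


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small default-noise cohort shared across tests (4/group, few trials)."""
    cfg = GeneratorConfig(n_per_group=4, n_standard=24, n_target=16, seed=101)
    epochsets, clinical, truth = simulate_cohort(cfg)
    return cfg, epochsets, clinical, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero-noise, zero-jitter, no-ramp cohort: downstream estimates exact."""
    cfg = GeneratorConfig(
        n_per_group=3, n_standard=6, n_target=6, trial_noise_sd=0.0,
        latency_jitter_sd_ms=0.0, ramp_ms=0.0, seed=202,
    )
    epochsets, clinical, truth = simulate_cohort(cfg)
    return cfg, epochsets, clinical, truth


def cohort_erps(epochsets):
    """Preprocess and average a cohort; returns (erps dict, group-of dict)."""
    erps, groups_of = {}, {}
    for ep in epochsets:
        clean, _ = preprocess_epochs(ep)
        erps[(ep.subject_id, ep.condition)] = condition_average(clean)
        groups_of[ep.subject_id] = ep.group
    return erps, groups_of


def cohort_toposequences(epochsets):
    erps, groups_of = cohort_erps(epochsets)
    seqs = {key: window_means(erp) for key, erp in erps.items()}
    return seqs, groups_of


@pytest.fixture(scope="session")
def tiny_cohort_erps(tiny_cohort):
    _, epochsets, _, _ = tiny_cohort
    return cohort_erps(epochsets)


@pytest.fixture(scope="session")
def noiseless_cohort_erps(noiseless_cohort):
    _, epochsets, _, _ = noiseless_cohort
    return cohort_erps(epochsets)
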