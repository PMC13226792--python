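import numpy as np
import pytest

from erpdyn.containers import CONDITIONS, GROUPS
from erpdyn.errors import InvalidArgumentError
from erpdyn.synthetic import (
    ClinicalVar,
    GeneratorConfig,
    default_activation_curves,
    loading_for_correlation,
    make_state_templates,
    sample_activation,
    simulate_cohort,
    simulate_subject,
)


class TestMakeStateTemplates:
    def test_orthonormal_zero_mean(self):
        t = make_state_templates(19, 4, seed=1)
        assert t.shape == (4, 19)
        assert np.abs(t.mean(axis=1)).max() < 1e-12
        gram = t @ t.T
        assert np.abs(gram - np.eye(4)).max() < 1e-10

    def test_two_states_three_channels(self):
        t = make_state_templates(3, 2, seed=9)
        assert abs(t[0] @ t[1]) < 1e-10
        assert np.abs(t.mean(axis=1)).max() < 1e-12

    def test_deterministic(self):
        a = make_state_templates(19, 4, seed=1)
        b = make_state_templates(19, 4, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_too_many_states_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_state_templates(4, 4, seed=0)
        with pytest.raises(InvalidArgumentError):
            make_state_templates(4, 0, seed=0)


class TestSampleActivation:
    def test_piecewise_constant_no_ramp(self):
        coeffs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        a = sample_activation(coeffs, fs=500.0, epoch_window_ms=(-200, 800),
                              ramp_ms=0.0)
        t = -200 + np.arange(len(a)) * 2.0
        # pre-stimulus and post-600 zero
        assert np.all(a[t < 0] == 0)
        assert np.all(a[t >= 600] == 0)
        # sample at exactly 100 ms belongs to window 2 (half-open windows)
        assert a[np.flatnonzero(t == 100.0)[0]] == 2.0
        # window means reproduce the coefficients exactly
        for w in range(6):
            mask = (t >= w * 100) & (t < (w + 1) * 100)
            assert a[mask].mean() == pytest.approx(coeffs[w], abs=1e-12)

    def test_ramp_is_continuous_and_bounded(self):
        coeffs = np.array([0.0, 1.0, 0.0, 2.0, 0.0, 1.0])
        a = sample_activation(coeffs, fs=500.0, epoch_window_ms=(-200, 800),
                              ramp_ms=20.0)
        assert np.abs(np.diff(a)).max() < 0.5  # no jumps at sample resolution
        assert a.min() >= 0.0 and a.max() <= 2.0
        t = -200 + np.arange(len(a)) * 2.0
        assert np.all(a[t < 0] == 0)


class TestSimulateSubject:
    def _config(self, **kw):
        defaults = dict(n_per_group=2, n_channels=6, n_states=2,
                        channel_names=tuple(f"c{i}" for i in range(6)),
                        n_standard=8, n_target=8,
                        activation_curves={
                            (g, c): np.array([[0, 1.0, 0.5, 0, 0, 0],
                                              [0, 0, 0, 1.0, 0.5, 0]])
                            for g in GROUPS for c in CONDITIONS
                        },
                        ramp_ms=0.0, seed=5)
        defaults.update(kw)
        return GeneratorConfig(**defaults)

    def test_zero_noise_trials_identical(self):
        cfg = self._config(trial_noise_sd=0.0, latency_jitter_sd_ms=0.0)
        tpl = make_state_templates(6, 2, seed=3)
        ep = simulate_subject(cfg, "TD", "standard", tpl, subject_seed=1)
        for t in range(1, ep.n_trials):
            np.testing.assert_array_equal(ep.data[:, :, t], ep.data[:, :, 0])
        np.testing.assert_allclose(ep.data.mean(axis=2), ep.data[:, :, 0])

    def test_window_projection_recovers_curves(self):
        # noiseless piecewise-constant signal: window means projected onto
        # the templates reproduce the configured coefficients
        cfg = self._config(trial_noise_sd=0.0, latency_jitter_sd_ms=0.0)
        tpl = make_state_templates(6, 2, seed=3)
        amp = 4.0
        ep = simulate_subject(cfg, "TD", "standard", tpl, subject_seed=1,
                              amplitude=amp, separation=1.0)
        times = ep.times_ms
        for w in range(6):
            mask = (times >= w * 100) & (times < (w + 1) * 100)
            topo = ep.data[:, mask, 0].mean(axis=1)
            proj = tpl @ topo
            expected = amp * cfg.activation_curves[("TD", "standard")][:, w]
            np.testing.assert_allclose(proj, expected, atol=1e-9)

    def test_unknown_group_condition(self):
        cfg = self._config()
        tpl = make_state_templates(6, 2, seed=3)
        with pytest.raises(InvalidArgumentError):
            simulate_subject(cfg, "XX", "standard", tpl, 1)
        with pytest.raises(InvalidArgumentError):
            simulate_subject(cfg, "TD", "oddball", tpl, 1)

    def test_trial_average_noise_scaling(self):
        # SD of the trial average at a fixed (channel, sample) over replicate
        # cohorts approaches noise_sd / sqrt(n_trials)
        n_trials = 64
        cfg = self._config(trial_noise_sd=1.0, latency_jitter_sd_ms=0.0,
                           n_standard=n_trials)
        tpl = make_state_templates(6, 2, seed=3)
        means = []
        for rep in range(100):
            ep = simulate_subject(cfg, "TD", "standard", tpl, subject_seed=rep,
                                  amplitude=3.0, separation=1.0)
            means.append(ep.data[2, 150, :].mean())
        sd = np.std(means, ddof=1)
        expected = 1.0 / np.sqrt(n_trials)
        assert expected * 0.8 < sd < expected * 1.2

    def test_jitter_shifts_whole_curve(self):
        cfg = self._config(trial_noise_sd=0.0, latency_jitter_sd_ms=12.0)
        tpl = make_state_templates(6, 2, seed=3)
        ep = simulate_subject(cfg, "TD", "standard", tpl, subject_seed=4)
        # trials are shifted copies: every trial's set of column values is a
        # subset of the unshifted signal's columns plus zeros
        base = simulate_subject(
            self._config(trial_noise_sd=0.0, latency_jitter_sd_ms=0.0),
            "TD", "standard", tpl, subject_seed=4).data[:, :, 0]
        for t in range(ep.n_trials):
            trial = ep.data[:, :, t]
            nz = np.abs(trial).sum(axis=0) > 0
            if not nz.any():
                continue
            first = np.flatnonzero(nz)[0]
            base_first = np.flatnonzero(np.abs(base).sum(axis=0) > 0)[0]
            shift = first - base_first
            assert abs(shift) <= int(np.ceil(3 * 12.0 * 500 / 1000)) + 1


class TestSimulateCohort:
    def test_counts(self):
        cfg = GeneratorConfig(n_per_group=2, n_standard=4, n_target=4, seed=0)
        eps, clinical, truth = simulate_cohort(cfg)
        assert len(eps) == 12          # 6 subjects x 2 conditions
        assert len(clinical) == 6
        assert set(clinical["group"]) == set(GROUPS)
        assert len(truth.separation) == 6

    def test_reproducible(self):
        cfg = GeneratorConfig(n_per_group=2, n_standard=4, n_target=4, seed=7)
        a = simulate_cohort(cfg)
        b = simulate_cohort(GeneratorConfig(n_per_group=2, n_standard=4,
                                            n_target=4, seed=7))
        for ea, eb in zip(a[0], b[0]):
            np.testing.assert_array_equal(ea.data, eb.data)
        assert a[1].equals(b[1])

    def test_zero_loading_null_correlation(self):
        clin = [ClinicalVar("score", {g: 2.0 for g in GROUPS}, sd=0.5,
                            loading=0.0)]
        cfg = GeneratorConfig(n_per_group=20, n_standard=2, n_target=2,
                              n_channels=5, n_states=2,
                              channel_names=tuple(f"c{i}" for i in range(5)),
                              activation_curves={
                                  (g, c): np.eye(2, 6) for g in GROUPS
                                  for c in CONDITIONS},
                              clinical_vars=clin, seed=31)
        _, clinical, truth = simulate_cohort(cfg)
        seps = np.array([truth.separation[s] for s in clinical["subject"]])
        r = np.corrcoef(seps, clinical["score"])[0, 1]
        assert abs(r) < 0.3

    def test_planted_loading_recovers_correlation(self):
        # loading chosen for population r = 0.6; recovered r within +-0.2
        # in >= 95% of replicate cohorts
        sd_latent, sd_noise = 0.25, 0.5
        loading = loading_for_correlation(0.6, sd_latent, sd_noise)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            clin = [ClinicalVar("score", {g: 5.0 for g in GROUPS}, sd=sd_noise,
                                loading=loading, floor=None)]
            cfg = GeneratorConfig(n_per_group=20, n_standard=2, n_target=2,
                                  n_channels=5, n_states=2,
                                  channel_names=tuple(f"c{i}" for i in range(5)),
                                  activation_curves={
                                      (g, c): np.eye(2, 6) for g in GROUPS
                                      for c in CONDITIONS},
                                  separation_sd=sd_latent,
                                  clinical_vars=clin, seed=1000 + rep)
            _, clinical, truth = simulate_cohort(cfg)
            seps = np.array([truth.separation[s] for s in clinical["subject"]])
            r = np.corrcoef(seps, clinical["score"])[0, 1]
            hits += abs(r - 0.6) <= 0.2
        assert hits / n_rep >= 0.90

    def test_config_validation(self):
        with pytest.raises(InvalidArgumentError):
            GeneratorConfig(n_states=19)          # > n_channels - 1
        with pytest.raises(InvalidArgumentError):
            GeneratorConfig(epoch_window_ms=(-200, 500))
        with pytest.raises(InvalidArgumentError):
            GeneratorConfig(n_standard=0)
        with pytest.raises(InvalidArgumentError):
            GeneratorConfig(trial_noise_sd=-1.0)


class TestDefaultGeometry:
    def test_default_curves_disjoint_supports(self):
        curves = default_activation_curves()
        for (g, c), arr in curves.items():
            support = arr != 0
            overlap = support.astype(int).sum(axis=0)
            assert overlap.max() <= 1  # one state active per window

    def test_group_separation_ordering(self):
        # deviation magnitude (target - standard) orders ADHD-I < TD < ADHD-C
        curves = default_activation_curves()
        devs = {g: np.linalg.norm(curves[(g, "target")] - curves[(g, "standard")])
                for g in GROUPS}
        assert devs["ADHD-I"] < devs["TD"] < devs["ADHD-C"]
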