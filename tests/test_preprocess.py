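import numpy as np
import pytest
from scipy.signal import periodogram

from ftcdlat.io_formats import PipelineConfig, RawRecording, ProcessingError, ValidationError
from ftcdlat.preprocess import (
    Epoch,
    baseline_correct,
    despike,
    downsample,
    integrate_heart_cycles,
    normalise,
    preprocess_recording,
    reject_artifacts,
    segment_epochs,
)
from ftcdlat.synthetic import SimulationConfig, cardiac_waveform, simulate_recording


def _rec(left, right=None, marker=None, rate=100):
    left = np.asarray(left, dtype=float)
    right = left.copy() if right is None else np.asarray(right, dtype=float)
    marker = np.zeros(len(left), dtype=int) if marker is None else marker
    return RawRecording(rate, left, right, marker)


def _epoch(left, right=None, state="raw", rate=25, task="sentence", trial=0):
    left = np.asarray(left, dtype=float)
    right = left.copy() if right is None else np.asarray(right, dtype=float)
    return Epoch(trial, task, 125, rate, left, right, state=state)


class TestDownsample:
    def test_constant_signal_block_mean(self):
        rec = _rec(np.full(101, 80.0))
        out = downsample(rec, 4)
        assert out.n_samples == 25
        assert np.all(out.left == 80.0)
        assert out.sample_rate == 25

    def test_length_and_rate_arithmetic(self):
        out = downsample(_rec(np.arange(3000, dtype=float)), 4)
        assert out.n_samples == 750 and out.sample_rate == 25

    def test_marker_relocated_to_block(self):
        marker = np.zeros(100, dtype=int)
        marker[42] = 3  # lands in block 10
        out = downsample(_rec(np.ones(100), marker=marker), 4)
        assert out.triggers() == [(10, "word")]

    def test_sinusoid_attenuation_matches_block_mean_oracle(self):
        # 1 Hz sinusoid at 100 Hz, factor 4: compare against an explicit
        # per-block mean computed sample by sample, and against the
        # analytic attenuation of a block average (Dirichlet factor).
        t = np.arange(4000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t) + 60.0
        out = downsample(_rec(x), 4)
        oracle = np.array([x[4 * i: 4 * i + 4].mean() for i in range(1000)])
        assert np.allclose(out.left, oracle)
        attenuation = np.ptp(out.left) / np.ptp(x)
        analytic = abs(np.sin(np.pi * 1.0 * 4 / 100) / (4 * np.sin(np.pi * 1.0 / 100)))
        assert attenuation == pytest.approx(analytic, abs=0.01)
        assert attenuation > 0.99

    def test_bad_factor_rejected(self):
        with pytest.raises(ValidationError):
            downsample(_rec(np.ones(10)), 0)
        with pytest.raises(ValidationError):
            downsample(_rec(np.ones(10)), 3)  # does not divide 100


class TestSegmentEpochs:
    def test_complete_epoch_covers_5s_pre_to_25s_post(self, cfg):
        marker = np.zeros(40 * 25, dtype=int)
        marker[10 * 25] = 2
        rec = _rec(np.arange(1000, dtype=float), marker=marker, rate=25)
        (ep,) = segment_epochs(rec, cfg)
        assert ep.included and ep.n_samples == 750
        assert ep.left[0] == (10 - 5) * 25  # epoch starts 5 s before trigger
        assert ep.task == "sentence"

    def test_early_marker_flagged_incomplete(self, cfg):
        marker = np.zeros(1000, dtype=int)
        marker[2 * 25] = 1  # needs data from -3 s
        rec = _rec(np.ones(1000), marker=marker, rate=25)
        (ep,) = segment_epochs(rec, cfg)
        assert not ep.included and ep.exclusion_reason == "incomplete_epoch"
        assert ep.n_samples == 750  # padded, data retained

    def test_no_markers_gives_empty_list(self, cfg):
        assert segment_epochs(_rec(np.ones(100), rate=25), cfg) == []

    def test_simulator_default_counts(self, clean_recording, cfg):
        rec, truth = clean_recording
        eps = segment_epochs(downsample(rec, 4), cfg)
        assert len(eps) == 60
        tasks = [ep.task for ep in eps]
        assert all(tasks.count(t) == 20 for t in ("list", "sentence", "word"))


class TestDespike:
    def _noise_epochs(self, n_epochs=4, n=750, seed=0):
        rng = np.random.default_rng(seed)
        return [
            _epoch(100 + rng.normal(0, 1, n), 100 + rng.normal(0, 1, n), trial=i)
            for i in range(n_epochs)
        ]

    def test_isolated_spike_linear_midpoint(self, cfg):
        eps = self._noise_epochs()
        x = eps[1].left
        x[400] = 10 * np.max(np.abs(x))  # far beyond the signal ceiling
        x[399], x[401] = 100.0, 102.0
        despike(eps, cfg)
        assert eps[1].left[400] == pytest.approx(101.0)
        assert eps[1].included

    def test_long_flatline_excludes_dropout_run(self, cfg):
        eps = self._noise_epochs()
        eps[2].right[300:315] = 0.0  # 0.6 s of signal loss at 25 Hz
        despike(eps, cfg)
        assert not eps[2].included
        assert eps[2].exclusion_reason == "dropout_run"

    def test_clean_simulation_epochs_essentially_untouched(self, clean_recording, cfg):
        rec, _ = clean_recording
        eps = segment_epochs(downsample(rec, 4), cfg)
        before = [ep.left.copy() for ep in eps]
        despike(eps, cfg)
        assert all(ep.included for ep in eps)
        changed = sum(int((b != ep.left).sum()) for b, ep in zip(before, eps))
        # empirical quantiles flag ~5 samples per tail by construction
        assert changed <= 15
        untouched = sum(bool((b == ep.left).all()) for b, ep in zip(before, eps))
        assert untouched >= len(eps) - 10

    def test_wrong_state_refused(self, cfg):
        eps = self._noise_epochs()
        despike(eps, cfg)
        with pytest.raises(ProcessingError):
            despike(eps, cfg)


class TestNormalise:
    def test_constant_channel_becomes_100(self, cfg):
        eps = [_epoch(np.full(750, 54.0), np.full(750, 27.0), state="despiked")]
        normalise(eps)
        assert np.allclose(eps[0].left, 100.0)
        assert np.allclose(eps[0].right, 100.0)

    def test_scale_invariance_left_twice_right(self, cfg):
        rng = np.random.default_rng(1)
        base = 50 + rng.normal(0, 2, 750)
        eps = [_epoch(2 * base, base, state="despiked")]
        normalise(eps)
        assert np.allclose(eps[0].left, eps[0].right)

    def test_grand_mean_exactly_100(self, clean_recording, cfg):
        rec, _ = clean_recording
        eps = despike(segment_epochs(downsample(rec, 4), cfg), cfg)
        normalise(eps)
        for chan in ("left", "right"):
            pool = np.concatenate([getattr(ep, chan) for ep in eps if ep.included])
            assert abs(pool.mean() - 100.0) < 1e-9

    def test_zero_mean_channel_refused(self):
        eps = [_epoch(np.zeros(750), np.ones(750), state="despiked")]
        with pytest.raises(ProcessingError):
            normalise(eps)


class TestHeartCycleIntegration:
    def _pulsed_epoch(self, rate=25, bpm=72.0, depth=0.25, n=750):
        t = np.arange(n) / rate
        phase = (t * bpm / 60.0) % 1.0
        x = 100.0 * (1.0 + depth * cardiac_waveform(phase))
        return _epoch(x, x.copy(), state="normalised")

    def test_pulse_train_flattens_to_mean(self, cfg):
        ep = self._pulsed_epoch()
        integrate_heart_cycles([ep], cfg)
        assert ep.included
        # interior cycles: per-cycle mean of a zero-mean pulse is ~100
        interior = ep.left[50:-50]
        assert np.all(np.abs(interior - 100.0) < 1.0)

    def test_constant_signal_cannot_integrate(self, cfg):
        ep = _epoch(np.full(750, 100.0), state="normalised")
        integrate_heart_cycles([ep], cfg)
        assert not ep.included and ep.exclusion_reason == "cannot_integrate"

    def test_cardiac_band_power_reduced_90pct(self, cfg, clean_recording):
        rec, _ = clean_recording
        eps = normalise(despike(segment_epochs(downsample(rec, 4), cfg), cfg))
        pre = [ep.left.copy() for ep in eps if ep.included][:10]
        integrate_heart_cycles(eps, cfg)
        post = [ep.left for ep in eps if ep.included][:10]
        hr_hz = 70.0 / 60.0
        for x_pre, x_post in zip(pre, post):
            f, p_pre = periodogram(x_pre, fs=25)
            _, p_post = periodogram(x_post, fs=25)
            band = (f > hr_hz - 0.3) & (f < hr_hz + 0.3)
            assert p_post[band].sum() < 0.1 * p_pre[band].sum()


class TestBaselineCorrect:
    def test_constant_channel_goes_to_zero(self, cfg):
        ep = _epoch(np.full(750, 103.0), state="normalised")
        integrate_heart_cycles([ep], cfg)  # excludes (no pulse) — craft manually
        ep2 = _epoch(np.full(750, 103.0), state="integrated")
        baseline_correct([ep2], cfg)
        assert np.allclose(ep2.left, 0.0)
        assert ep2.baseline_offset[0] == pytest.approx(103.0)

    def test_covert_window_offset_preserved(self, cfg):
        x = np.full(750, 100.0)
        x[175:425] = 105.0  # POI window elevated by 5
        ep = _epoch(x, state="integrated")
        baseline_correct([ep], cfg)
        assert np.mean(ep.left[:125]) == pytest.approx(0.0)
        assert np.mean(ep.left[175:425]) == pytest.approx(5.0)

    def test_planted_bilateral_rise_recovered(self, clean_result, cfg):
        (result, truth) = clean_result
        # list task has planted LI 0, so both channels carry only the 3 %
        # bilateral rise during the covert plateau
        eps = [ep for ep in result["epochs"] if ep.task == "list" and ep.included]
        plateau = slice(9 * 25, 17 * 25)
        left = np.mean([np.mean(ep.left[plateau]) for ep in eps])
        right = np.mean([np.mean(ep.right[plateau]) for ep in eps])
        assert left == pytest.approx(3.0, abs=0.5)
        assert right == pytest.approx(3.0, abs=0.5)
        assert left - right == pytest.approx(0.0, abs=0.1)  # planted LI 0
        for ep in eps[:5]:
            assert np.mean(ep.left[:125]) == pytest.approx(0.0, abs=1e-9)


class TestRejectArtifacts:
    def _baselined(self, values):
        ep = _epoch(values, state="integrated")
        return baseline_correct([ep], PipelineConfig())[0]

    def test_sample_above_140_excluded(self, cfg):
        x = np.full(750, 100.0)
        x[500] = 150.0
        ep = self._baselined(x)
        reject_artifacts([ep], cfg)
        assert not ep.included and ep.exclusion_reason == "artifact_out_of_range"

    def test_range_61_139_retained(self, cfg):
        x = np.linspace(61.0, 139.0, 750)
        ep = self._baselined(x)
        reject_artifacts([ep], cfg)
        assert ep.included

    def test_exclusion_monotone_under_extra_artifact(self, cfg):
        x = np.full(750, 100.0)
        ep = self._baselined(x.copy())
        reject_artifacts([ep], cfg)
        assert ep.included
        ep2 = self._baselined(x)
        ep2.left[10] = 200.0 - ep2.baseline_offset[0]  # pre-baseline value 200
        reject_artifacts([ep2], cfg)
        assert not ep2.included

    def test_clean_simulation_zero_rejections(self, clean_result):
        result, _ = clean_result
        qc = result["qc"]
        assert (qc.exclusion_reason == "artifact_out_of_range").sum() == 0
        assert qc.included.all()


class TestPipelineProperties:
    def test_clean_included_equals_triggers(self, clean_result, clean_recording):
        result, _ = clean_result
        rec, _ = clean_recording
        assert result["qc"].included.sum() == len(rec.marker_indices)

    def test_channel_swap_equivariance(self, cfg):
        sim = SimulationConfig(n_trials_per_task=3, rng_seed=21)
        rec, _ = simulate_recording(sim)
        swapped = RawRecording(rec.sample_rate, rec.right.copy(), rec.left.copy(),
                               rec.marker.copy())
        eps = preprocess_recording(rec, cfg)
        eps_sw = preprocess_recording(swapped, cfg)
        for a, b in zip(eps, eps_sw):
            assert a.included == b.included
            if a.included:
                assert np.allclose(a.left, b.right)
                assert np.allclose(a.right, b.left)

    def test_stage_order_enforced(self, cfg):
        eps = [_epoch(np.random.default_rng(0).normal(100, 1, 750))]
        with pytest.raises(ProcessingError):
            normalise(eps)  # raw epochs cannot skip despiking
        with pytest.raises(ProcessingError):
            baseline_correct(eps, cfg)
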