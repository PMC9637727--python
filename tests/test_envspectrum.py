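"""Colliding-window planner, per-window periodograms, aggregation, smoothing."""

import numpy as np
import pytest

import sleepenv as se
from sleepenv.envspectrum import (
    ENVELOPE_FREQS,
    SamplingWindow,
    WindowSpectrum,
    aggregate_psd,
    flag_abnormal_spectra,
    plan_windows,
    plan_windows_both,
    postprocess_psd,
    window_psd,
)


def clean_nrem(duration, artifacts=()):
    return se.make_mask_and_stages(duration, list(artifacts), [(0.0, duration, "N2")])


class TestPlanWindows:
    def test_clean_600s_forward_grid(self):
        mask, stages = clean_nrem(600.0)
        windows = plan_windows(mask, stages, "NREM", "forward")
        assert len(windows) == 26  # floor((600-100)/20) + 1
        assert [w.start for w in windows] == [20.0 * k for k in range(26)]
        assert all(w.length == 100.0 for w in windows)

    def test_forward_backward_mirror_on_clean_data(self):
        mask, stages = clean_nrem(600.0)
        fwd = plan_windows(mask, stages, "NREM", "forward")
        bwd = plan_windows(mask, stages, "NREM", "backward")
        assert sorted((w.start, w.length) for w in fwd) == sorted(
            (w.start, w.length) for w in bwd
        )

    def test_isolated_artifact_shortens_then_restarts(self):
        mask, stages = clean_nrem(600.0, [(300.0, 304.0)])
        windows = plan_windows(mask, stages, "NREM", "forward")
        shortened = {(w.start, w.length) for w in windows if w.length < 100.0}
        assert shortened == {(220.0, 80.0), (240.0, 60.0), (260.0, 40.0), (280.0, 20.0)}
        after = [w for w in windows if w.start >= 304.0]
        assert after[0].start == 320.0 and after[0].length == 100.0

    def test_short_clean_run_yields_nothing(self):
        # only a 20-s clean run, off the 20-s grid
        mask, stages = clean_nrem(100.0, [(0.0, 4.0), (24.0, 100.0)])
        assert plan_windows(mask, stages, "NREM") == []

    def test_no_windows_in_absent_state(self):
        mask, stages = clean_nrem(600.0)
        assert plan_windows(mask, stages, "REM") == []

    def test_every_window_artifact_free_by_mask_lookup(self):
        rng = np.random.default_rng(4)
        artifacts = [(float(s), float(s + 4)) for s in rng.choice(299, 30) * 4]
        mask, stages = clean_nrem(1200.0, artifacts)
        for w in plan_windows_both(mask, stages, "NREM"):
            assert mask.is_clean(w.start, w.stop)

    def test_stage_boundary_collides_like_artifact(self):
        _, stages = se.make_mask_and_stages(
            600.0, [], [(0.0, 300.0, "N2"), (300.0, 600.0, "R")]
        )
        mask = se.ArtifactMask(np.zeros(150, dtype=bool))
        windows = plan_windows(mask, stages, "NREM", "forward")
        assert max(w.stop for w in windows) <= 300.0
        assert {w.length for w in windows if w.start >= 220.0} == {80.0, 60.0, 40.0, 20.0}

    def test_window_invariants(self):
        with pytest.raises(ValueError):
            SamplingWindow(0.0, 10.0)
        w = SamplingWindow(0.0, 50.0)
        assert w.weight == 0.5 and w.min_valid_freq == 0.02

    def test_whole_short_recording_emits_single_truncated_window(self):
        mask, stages = clean_nrem(60.0)
        windows = plan_windows_both(mask, stages, "NREM")
        assert [(w.start, w.length) for w in windows] == [(0.0, 60.0)]


class TestWindowPSD:
    def test_pure_tone_peaks_at_its_bin(self):
        rate = 100.0
        t = np.arange(int(100 * rate)) / rate
        spec = window_psd(np.sin(2 * np.pi * 0.2 * t), rate)
        assert ENVELOPE_FREQS[np.argmax(spec.density)] == pytest.approx(0.20)

    def test_sub_one_over_L_bins_invalid(self):
        spec = window_psd(np.random.default_rng(0).standard_normal(50 * 100), 100.0)
        invalid = ENVELOPE_FREQS[~spec.valid]
        assert list(np.round(invalid, 2)) == [0.01]
        spec100 = window_psd(np.random.default_rng(0).standard_normal(100 * 100), 100.0)
        assert spec100.valid.all()

    def test_constant_segment_all_zero(self):
        spec = window_psd(np.full(100 * 100, 7.0), 100.0)
        assert np.allclose(spec.density, 0.0, atol=1e-12)

    def test_non_finite_values_raise(self):
        x = np.zeros(2000)
        x[5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            window_psd(x, 100.0)

    def test_out_of_range_length_raises(self):
        with pytest.raises(ValueError, match="expected"):
            window_psd(np.zeros(100), 100.0)  # 1-s segment

    def test_matches_plain_periodogram_on_shared_bins(self):
        # 100-s window at 4 Hz: all 400 grid freqs are Fourier bins of the DFT
        rate = 8.0
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(100 * rate))
        spec = window_psd(x, rate)
        from scipy import signal as sps

        f, pxx = sps.periodogram(
            sps.detrend(x), fs=rate, window="hamming", detrend=False
        )
        idx = [int(round(fq / f[1])) for fq in ENVELOPE_FREQS]
        assert np.allclose(spec.density, pxx[idx], rtol=1e-8, atol=1e-12)


def _uniform_spectrum(value, length):
    density = np.full(len(ENVELOPE_FREQS), float(value))
    valid = ENVELOPE_FREQS >= 1.0 / length - 1e-9
    return WindowSpectrum(density, valid)


class TestAggregate:
    def test_identical_windows_idempotent(self):
        w = SamplingWindow(0.0, 100.0)
        spec = _uniform_spectrum(2.0, 100.0)
        agg = aggregate_psd([(w, spec), (w, spec)])
        assert np.allclose(agg.density[0, 0], 2.0)

    def test_weighted_mean_worked_example(self):
        # (1.0 * 2 + 0.5 * 1) / 1.5 = 5/3 at bins both windows support
        pairs = [
            (SamplingWindow(0.0, 100.0), _uniform_spectrum(2.0, 100.0)),
            (SamplingWindow(200.0, 50.0), _uniform_spectrum(1.0, 50.0)),
        ]
        agg = aggregate_psd(pairs)
        k = int(np.argmin(np.abs(ENVELOPE_FREQS - 0.5)))
        assert agg.density[0, 0, k] == pytest.approx(5.0 / 3.0)

    def test_unsupported_bin_flagged_missing(self):
        pairs = [(SamplingWindow(0.0, 50.0), _uniform_spectrum(1.0, 50.0))]
        agg = aggregate_psd(pairs)
        assert np.isnan(agg.density[0, 0, 0]) and agg.weight[0, 0, 0] == 0.0
        assert agg.density[0, 0, 1] == pytest.approx(1.0)  # 0.02 Hz supported

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pairs = []
        for i in range(12):
            length = float(rng.choice([20, 40, 60, 100]))
            density = rng.random(len(ENVELOPE_FREQS))
            valid = ENVELOPE_FREQS >= 1.0 / length - 1e-9
            pairs.append((SamplingWindow(20.0 * i, length), WindowSpectrum(density, valid)))
        a = aggregate_psd(pairs).density
        order = rng.permutation(len(pairs))
        b = aggregate_psd([pairs[i] for i in order]).density
        assert np.allclose(a, b, atol=1e-12, equal_nan=True)

    def test_matches_bruteforce_loop_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = rng.integers(1, 8)
            pairs = []
            for i in range(n):
                length = float(rng.choice([20, 50, 100]))
                density = rng.random(len(ENVELOPE_FREQS))
                valid = ENVELOPE_FREQS >= 1.0 / length - 1e-9
                pairs.append(
                    (SamplingWindow(20.0 * i, length), WindowSpectrum(density, valid))
                )
            agg = aggregate_psd(pairs).density[0, 0]
            for k in (0, 1, 7, 399):
                num = den = 0.0
                for w, s in pairs:
                    if s.valid[k]:
                        num += w.weight * s.density[k]
                        den += w.weight
                expect = num / den if den > 0 else np.nan
                assert np.isclose(agg[k], expect, atol=1e-12, equal_nan=True)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate_psd([])


class TestPostprocess:
    def test_z_stage_contract(self, demo_spectrum):
        z = demo_spectrum.z
        sub = z.analysis_slice
        for bi in range(len(z.bands)):
            vals = z.density[bi, 0, sub]
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std() - 1.0) < 1e-9

    def test_flat_spectrum_rejected(self):
        pairs = [(SamplingWindow(0.0, 100.0), _uniform_spectrum(1.0, 100.0))]
        agg = aggregate_psd(pairs)
        with pytest.raises(ValueError, match="flat|zero spread"):
            postprocess_psd(agg)

    def test_requires_raw_stage(self, demo_spectrum):
        with pytest.raises(ValueError, match="raw-average"):
            postprocess_psd(demo_spectrum.z)


class TestFullPipeline:
    def test_sigma_z_spectrum_maximum_at_high_carrier(self, demo_spectrum):
        z = demo_spectrum.z
        sigma = z.band("sigma")
        sub = z.analysis_slice
        peak = z.freqs[sub][np.argmax(sigma[sub])]
        assert peak == pytest.approx(1.0, abs=0.02)

    def test_isolated_artifact_loses_at_most_20s_of_clean_signal(self):
        mask, stages = clean_nrem(600.0, [(300.0, 304.0)])
        windows = plan_windows_both(mask, stages, "NREM")
        grid = np.zeros(600 * 10, dtype=bool)
        for w in windows:
            grid[int(w.start * 10) : int(w.stop * 10)] = True
        clean = np.ones_like(grid)
        clean[3000:3040] = False
        assert (clean & ~grid).sum() / 10.0 <= 20.0

    def test_artifacts_do_not_move_the_delta_peak(self):
        spec = se.SimSpec(duration=600.0, rate=100.0, seed=2)
        rec = se.make_demo_signal(spec)
        clean_mask, stages = clean_nrem(600.0)
        rng = np.random.default_rng(7)
        cells = rng.random(150) < 0.2  # 20% of 4-s cells marked
        dirty_mask = se.ArtifactMask(cells)

        def delta_peak(mask):
            res = se.compute_envelope_spectrum(
                rec, mask, stages, "NREM", (se.DEMO_DELTA,)
            )
            z = res.z.density[0, 0]
            sel = res.z.freqs < 1.0
            return res.z.freqs[sel][np.argmax(z[sel])]

        assert delta_peak(dirty_mask) == pytest.approx(delta_peak(clean_mask), abs=0.02)

    def test_rem_request_on_all_nrem_staging_errors(self, demo_recording):
        mask, stages = clean_nrem(demo_recording.duration)
        with pytest.raises(ValueError, match="no usable sampling window"):
            se.compute_envelope_spectrum(
                demo_recording, mask, stages, "REM", (se.DEMO_DELTA,)
            )


def test_flag_abnormal_spectra_detects_gross_outlier():
    rng = np.random.default_rng(8)
    cohort = rng.normal(0.0, 1.0, size=(30, 2, 100))
    cohort[3, 1, :40] += 50.0  # 40% of bins far outside the cohort spread
    with pytest.warns(UserWarning):
        flags = flag_abnormal_spectra(cohort)
    assert flags[3, 1]
    assert flags.sum() == 1
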