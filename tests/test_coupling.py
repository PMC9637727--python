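"""Coupling statistics, surrogate inference, p-value pooling and FDR control."""

import numpy as np
import pytest
from scipy import stats as spstats

import sleepenv as se
from sleepenv.coupling import (
    COHERENCE_FREQS,
    N_PHASE_BINS,
    coupling_statistics,
    modulation_index,
)


class TestCrossCorr:
    def test_autocorrelation_peaks_at_zero(self):
        x = np.random.default_rng(0).standard_normal(5000)
        lags, r = se.crosscorr_norm(x, x, 250.0)
        assert lags[np.argmax(r)] == 0.0
        assert r.max() == pytest.approx(1.0)

    def test_anticorrelation_dips_at_zero(self):
        x = np.random.default_rng(0).standard_normal(5000)
        lags, r = se.crosscorr_norm(x, -x, 250.0)
        assert lags[np.argmin(r)] == 0.0
        assert r.min() == pytest.approx(-1.0)

    def test_delayed_copy_moves_extremum(self):
        rate = 250.0
        x = np.random.default_rng(1).standard_normal(5000)
        y = np.roll(x, int(0.2 * rate))
        lags, r = se.crosscorr_norm(x, y, rate)
        assert abs(lags[np.argmax(r)] - 0.2) <= 1.0 / rate

    def test_values_bounded(self):
        rng = np.random.default_rng(2)
        _, r = se.crosscorr_norm(rng.standard_normal(1000), rng.standard_normal(1000), 50.0)
        assert np.all(np.abs(r) <= 1.0 + 1e-12)

    def test_zero_variance_flagged_missing(self):
        _, r = se.crosscorr_norm(np.zeros(100), np.ones(100), 50.0)
        assert np.all(np.isnan(r))


class TestCoherence:
    def test_identical_signals_unit_coherence(self):
        x = np.random.default_rng(0).standard_normal(int(20 * 50))
        c = se.mscoherence(x, x, 50.0)
        assert np.allclose(c, 1.0)

    def test_equal_power_noise_halves_coherence_in_long_segment(self):
        # y = x + independent noise at equal power -> true coherence 0.5;
        # a 2000-s segment leaves only a tiny estimator bias
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(2000 * 50))
        y = x + rng.standard_normal(len(x))
        c = se.mscoherence(x, y, 50.0)
        assert np.all(np.abs(c - 0.5) < 0.1)

    def test_independent_pair_sits_at_simulated_bias_floor(self):
        # three half-overlapping sub-windows keep a substantial small-sample
        # bias (~0.35, frozen from a simulation oracle) under independence
        rng = np.random.default_rng(2)
        seg = int(20 * 50)
        vals = [
            se.mscoherence(rng.standard_normal(seg), rng.standard_normal(seg), 50.0)
            for _ in range(200)
        ]
        mean = np.mean(vals, axis=0)
        assert np.all(np.abs(mean - 0.35) < 0.06)

    def test_zero_variance_missing(self):
        assert np.all(np.isnan(se.mscoherence(np.zeros(1000), np.ones(1000), 50.0)))


class TestPhaseProfile:
    def test_independent_amplitude_gives_flat_profile(self):
        rng = np.random.default_rng(3)
        rate, seg = 50.0, int(20 * 50)
        profiles = [
            se.phase_amplitude_profile(
                np.sin(2 * np.pi * 0.5 * np.arange(seg) / rate + rng.uniform(0, 2 * np.pi)),
                1 + 0.3 * np.abs(rng.standard_normal(seg)),
            )
            for _ in range(100)
        ]
        assert np.nanmax(np.abs(np.nanmean(profiles, axis=0))) < 0.1

    def test_sinusoidal_dependence_gives_sinusoidal_profile(self):
        rate = 50.0
        t = np.arange(int(20 * rate)) / rate
        mua = np.sin(2 * np.pi * 0.5 * t)
        # phase 0 deg sits at the positive peak of the oscillation, so an
        # amplitude following the oscillation gives a cosine-shaped profile
        env = 2.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        profile = se.phase_amplitude_profile(mua, env)
        centers = np.deg2rad(np.arange(N_PHASE_BINS) * 30.0 + 15.0)
        template = np.cos(centers)
        ok = np.isfinite(profile)
        r = np.corrcoef(profile[ok], template[ok])[0, 1]
        assert r > 0.99

    def test_zero_variance_missing(self):
        assert np.all(np.isnan(se.phase_amplitude_profile(np.zeros(100), np.ones(100))))


class TestSurrogates:
    @staticmethod
    def corr_stat(e, m):
        return np.array([np.corrcoef(e, m)[0, 1]])

    def test_zero_observed_is_never_extreme(self):
        rng = np.random.default_rng(4)
        segs = [rng.standard_normal(50) for _ in range(6)]
        null = se.surrogate_p(
            self_stat := self.corr_stat, segs, segs, n=99, seed=1, observed=np.array([0.0])
        )
        assert null.p[0] >= 0.9  # nothing can be closer to zero than zero, up to ties

    def test_extreme_observed_hits_floor(self):
        rng = np.random.default_rng(5)
        segs = [rng.standard_normal(50) for _ in range(6)]
        null = se.surrogate_p(
            self.corr_stat, segs, segs, n=99, seed=1, observed=np.array([5.0])
        )
        assert null.p[0] == pytest.approx(1.0 / 100.0)

    def test_p_bounds_and_validation(self):
        rng = np.random.default_rng(6)
        segs = [rng.standard_normal(50) for _ in range(5)]
        null = se.surrogate_p(self.corr_stat, segs, segs, n=49, seed=0)
        assert 1.0 / 50.0 <= null.p[0] <= 1.0
        with pytest.raises(ValueError):
            se.surrogate_p(self.corr_stat, segs, segs, n=0)
        with pytest.raises(ValueError):
            se.surrogate_p(self.corr_stat, segs[:1], segs[:1], n=10)

    def test_type_one_error_calibrated_under_independence(self):
        # distribution-free under exchangeability: rejection rate at alpha=0.05
        # stays inside the binomial 95% band over 200 replicates
        reps, rej = 200, 0
        for ss in np.random.SeedSequence(42).spawn(reps):
            rng = np.random.default_rng(ss)
            ev = [rng.standard_normal(100) for _ in range(8)]
            mu = [rng.standard_normal(100) for _ in range(8)]
            null = se.surrogate_p(self.corr_stat, ev, mu, n=200, seed=rng)
            rej += null.p[0] <= 0.05
        assert 0.02 <= rej / reps <= 0.09


class TestPoolPvalues:
    def test_equal_pvalues_pool_to_themselves(self):
        assert se.pool_pvalues([0.05, 0.05, 0.05]) == pytest.approx(0.05, abs=1e-12)

    def test_worked_example(self):
        # z = {1.645, 0}; mean 0.822; 1 - Phi(0.822) ~ 0.2056
        assert se.pool_pvalues([0.05, 0.5]) == pytest.approx(0.2056, abs=5e-4)

    def test_single_subject_passthrough(self):
        assert se.pool_pvalues([0.123]) == pytest.approx(0.123, abs=1e-12)

    def test_zero_p_floored(self):
        pooled = se.pool_pvalues([0.0, 0.5], n_surrogates=1000)
        expected = se.pool_pvalues([1.0 / 1001.0, 0.5])
        assert pooled == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            se.pool_pvalues([1.2])


def bh_oracle(p):
    """Brute-force step-up: adj_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFDR:
    def test_hand_worked_example(self):
        adj, rej = se.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)
        assert rej.all()

    def test_all_ones_never_rejected(self):
        adj, rej = se.fdr_bh(np.ones(10))
        assert np.allclose(adj, 1.0) and not rej.any()

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.random(50)
            adj, rej = se.fdr_bh(p, q=0.05)
            oracle = bh_oracle(p)
            assert np.allclose(adj, oracle, atol=1e-12)
            assert np.array_equal(rej, oracle <= 0.05)

    def test_empty_and_nan_handling(self):
        adj, rej = se.fdr_bh(np.array([]))
        assert adj.size == 0 and rej.size == 0
        adj, rej = se.fdr_bh(np.array([0.001, np.nan]))
        assert np.isnan(adj[1]) and not rej[1] and rej[0]


class TestModulationIndex:
    def test_flat_amplitude_zero_index(self):
        rng = np.random.default_rng(8)
        phase = rng.uniform(0, 360, 20000)
        amp = np.ones_like(phase)
        assert modulation_index(amp, phase) == pytest.approx(0.0, abs=1e-12)

    def test_concentrated_amplitude_near_one(self):
        phase = np.concatenate([np.full(1000, 15.0), np.linspace(0, 359, 1100)])
        amp = np.concatenate([np.full(1000, 1000.0), np.full(1100, 1e-9)])
        assert modulation_index(amp, phase) > 0.9

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(np.array([-1.0, 1.0]), np.array([10.0, 200.0]))


class TestStudy1Pipeline:
    def test_antiphase_coupling_recovers_negative_delta_pattern(self):
        """Suppressing firing at envelope peaks yields a negative central
        cross-correlation and an anti-phase amplitude profile."""
        rate = 250.0
        spec = se.CoupledPairSpec(
            band=se.band_by_name("low_delta"),
            preferred_phase=180.0,
            coupling_strength=0.8,
            seed=11,
        )
        ecog, mua = se.make_coupled_ecog_mua(spec, 600.0, rate)
        from sleepenv.preprocess import (
            MUASeries,
            band_filter,
            hilbert_envelope,
            smooth_mua_for_band,
        )

        band = spec.band
        env = hilbert_envelope(band_filter(ecog, band))[0]
        sm = smooth_mua_for_band(MUASeries(mua.samples, rate), band).smoothed[
            band.name
        ][0]
        seg = int(20 * rate)
        n_seg = len(env) // seg
        env_segments = [env[i * seg : (i + 1) * seg] for i in range(n_seg)]
        mua_segments = [sm[i * seg : (i + 1) * seg] for i in range(n_seg)]
        result = coupling_statistics(env_segments, mua_segments, rate, 200, seed=0)
        mid = len(result.lags) // 2
        central = result.crosscorr[mid - 25 : mid + 26]
        assert central.min() < -0.2  # firing suppressed around envelope peaks
        # the coupled pair is detected as significant
        assert result.crosscorr_p.min() <= 0.05
        centers = np.arange(12) * 30.0 + 15.0
        best = centers[np.nanargmax(result.phase_profile)]
        assert min(abs(best - 180.0), 360.0 - abs(best - 180.0)) <= 45.0


class TestRespiration:
    @staticmethod
    def _drifting_respiration(rng, n, rate):
        from scipy.ndimage import gaussian_filter1d

        inst_f = 0.25 + gaussian_filter1d(rng.standard_normal(n), 2000) * 3
        phase = 2 * np.pi * np.cumsum(inst_f) / rate
        return np.sin(phase) + 0.05 * rng.standard_normal(n), phase

    def test_independent_pair_not_significant_after_fdr(self):
        rate = 50.0
        n = int(600 * rate)
        rng = np.random.default_rng(0)
        resp, _ = self._drifting_respiration(rng, n, rate)
        env = 1 + 0.3 * np.abs(rng.standard_normal(n))
        res = se.respiration_coupling(env, resp, rate, n_surrogates=200, seed=0)
        family = np.concatenate([res.coherence_p, [res.mi_p]])
        _, rej = se.fdr_bh(family)
        assert not rej.any()

    def test_respiration_gated_envelope_detected(self):
        rate = 50.0
        n = int(600 * rate)
        rng = np.random.default_rng(1)
        resp, phase = self._drifting_respiration(rng, n, rate)
        env = (1 + 0.8 * np.sin(phase)) * (1 + 0.3 * np.abs(rng.standard_normal(n)))
        res = se.respiration_coupling(env, resp, rate, n_surrogates=200, seed=0)
        assert res.mi_p == pytest.approx(1.0 / 201.0)

    def test_constant_respiration_errors(self):
        with pytest.raises(ValueError, match="phase undefined"):
            se.respiration_coupling(np.ones(20000), np.ones(20000), 50.0)
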