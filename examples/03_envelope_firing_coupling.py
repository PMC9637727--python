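"""Detecting coupling between an EEG band envelope and population firing.

Simulates an ECoG-like signal and a multi-unit-activity (MUA) proxy whose
gain is locked to the low-delta envelope with a known preferred phase of
180 degrees (firing suppressed at envelope peaks).  The analysis should
recover that phase, show a negative central cross-correlation, and reject
the no-coupling null via the surrogate test.
"""

import numpy as np

import sleepenv as se
from sleepenv.preprocess import (
    MUASeries,
    band_filter,
    hilbert_envelope,
    smooth_mua_for_band,
)

rate = 250.0
band = se.band_by_name("low_delta")
spec = se.CoupledPairSpec(
    band=band, preferred_phase=180.0, coupling_strength=0.8, seed=1
)
ecog, mua = se.make_coupled_ecog_mua(spec, duration=600.0, rate=rate)

env = hilbert_envelope(band_filter(ecog, band))[0]
smoothed = smooth_mua_for_band(MUASeries(mua.samples, rate), band).smoothed[band.name][0]

seg = int(20 * rate)  # non-overlapping 20-s segments
n_seg = len(env) // seg
env_segments = [env[i * seg : (i + 1) * seg] for i in range(n_seg)]
mua_segments = [smoothed[i * seg : (i + 1) * seg] for i in range(n_seg)]

result = se.coupling_statistics(env_segments, mua_segments, rate, n_surrogates=500, seed=0)

mid = len(result.lags) // 2
print(f"{n_seg} segments of 20 s")
print(f"cross-correlation at lag 0: {result.crosscorr[mid]:+.3f} "
      f"(negative: firing dips when the envelope is high)")
print(f"smallest surrogate p over lags: {result.crosscorr_p.min():.4f}")
print(f"mean coherence 0.1-1 Hz: {result.coherence.mean():.3f}")
centers = np.arange(12) * 30 + 15
best = centers[np.nanargmax(result.phase_profile)]
print(f"envelope amplitude is largest at MUA phase ~{best:.0f} deg "
      f"(simulated preferred phase: 180 deg)")
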