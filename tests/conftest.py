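import numpy as np
import pytest

import sleepenv as se


@pytest.fixture(scope="session")
def demo_recording() -> se.Recording:
    """Default two-component amplitude-modulated signal in pink noise."""
    return se.make_demo_signal(se.SimSpec())


@pytest.fixture(scope="session")
def demo_spectrum(demo_recording):
    """Colliding-window envelope spectra of the demo signal (delta + sigma)."""
    mask, stages = se.make_mask_and_stages(
        demo_recording.duration, [], [(0.0, demo_recording.duration, "N2")]
    )
    return se.compute_envelope_spectrum(
        demo_recording, mask, stages, "NREM", (se.DEMO_DELTA, se.DEMO_SIGMA)
    )


def largest_peak_frequency(freqs: np.ndarray, values: np.ndarray, fmax: float) -> float:
    """Frequency of the largest local maximum below fmax (DC background excluded)."""
    from scipy.signal import find_peaks

    sel = freqs < fmax
    peaks, _ = find_peaks(values[sel])
    assert peaks.size > 0, "no local maximum found"
    return float(freqs[sel][peaks[np.argmax(values[sel][peaks])]])
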