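"""Artifact-tolerant ("colliding window") estimation of the envelope power spectrum.

Very low envelope frequencies need long (100 s) analysis windows, so
discarding a whole window because of a short artifact wastes data.  The
colliding-window scheme instead shortens a window to end just before the
obstruction, down to a 20-s minimum, then resumes full-length windows on
the next clean 20-s grid point after it.  Shortened windows of length L are
under-weighted by L/100 in the spectral average and contribute nothing
below 1/L Hz, where they carry no information.  Windows are placed both
forward from the recording start and backward from its end so the data
just *after* an obstruction is sampled as densely as the data before it;
with this, at most 20 s of clean signal around an isolated artifact goes
unused (instead of up to 100 s).

Per-window spectra are linearly detrended, Hamming-tapered periodograms
evaluated on a fixed 0.01-Hz grid from 0.01 to 4 Hz (chirp-z transform,
i.e. the DTFT at exactly those frequencies).  The weighted average is then
Savitzky-Golay smoothed, log10-transformed and z-scored across the
0.01-2 Hz analysis sub-grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .annotations import (
    ARTIFACT_CELL_SECONDS,
    ArtifactMask,
    StageAnnotation,
    valid_cells,
)
from .preprocess import extract_envelopes
from .signal import CANONICAL_BANDS, BandDefinition, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingWindow",
    "WindowSpectrum",
    "EnvelopePSD",
    "EnvelopeSpectrumResult",
    "ENVELOPE_FREQS",
    "ANALYSIS_MAX_HZ",
    "plan_windows",
    "plan_windows_both",
    "window_psd",
    "aggregate_psd",
    "postprocess_psd",
    "compute_envelope_spectrum",
    "flag_abnormal_spectra",
]

WINDOW_SECONDS = 100.0
STEP_SECONDS = 20.0
MIN_WINDOW_SECONDS = 20.0

#: Fixed estimation grid: 0.01 .. 4.00 Hz in 0.01 Hz steps (400 bins).
ENVELOPE_FREQS = np.round(np.arange(1, 401) * 0.01, 10)
#: Envelope frequencies analyzed downstream (z-scoring range).
ANALYSIS_MAX_HZ = 2.0
N_ANALYSIS_BINS = 200

#: Savitzky-Golay smoothing of the averaged spectrum: polynomial order 10
#: over a 21-bin (0.21 Hz) frame, the smallest odd frame comfortably above
#: the polynomial order.
SAVGOL_POLYORDER = 10
SAVGOL_FRAME = 21


@dataclass(frozen=True)
class SamplingWindow:
    """An artifact-free, possibly shortened analysis window.

    `weight` is length/100 and `min_valid_freq` is 1/length: a window of
    length L carries no spectral information below 1/L Hz.
    """

    start: float
    length: float
    direction: str = "forward"

    def __post_init__(self) -> None:
        if not MIN_WINDOW_SECONDS <= self.length <= WINDOW_SECONDS:
            raise ValueError(
                f"window length {self.length:g} s outside "
                f"[{MIN_WINDOW_SECONDS:g}, {WINDOW_SECONDS:g}]"
            )
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def stop(self) -> float:
        return self.start + self.length

    @property
    def weight(self) -> float:
        return self.length / WINDOW_SECONDS

    @property
    def min_valid_freq(self) -> float:
        return 1.0 / self.length


def _runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True cells."""
    padded = np.diff(np.concatenate(([0], valid.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def _plan_forward(valid: np.ndarray, duration: float) -> list[tuple[float, float]]:
    """(start, length) pairs of a forward pass over the 4-s validity cells.

    Candidate starts sit on the absolute 20-s grid inside each contiguous
    clean run.  A candidate colliding with an obstruction (artifact or
    state boundary) is truncated to end at it, down to the 20-s minimum;
    at the recording end no truncation occurs (the mirrored backward pass
    covers that edge), so only full-length windows are emitted there.
    """
    out: list[tuple[float, float]] = []
    for c0, c1 in _runs(valid):
        run_start = c0 * ARTIFACT_CELL_SECONDS
        run_end = c1 * ARTIFACT_CELL_SECONDS
        ends_at_recording_end = run_end >= duration - 1e-9
        emitted_in_run = False
        s = abs(np.ceil(run_start / STEP_SECONDS - 1e-9)) * STEP_SECONDS
        while s + MIN_WINDOW_SECONDS <= run_end + 1e-9:
            length = min(WINDOW_SECONDS, run_end - s)
            if ends_at_recording_end and length < WINDOW_SECONDS - 1e-9:
                # The mirrored pass covers the far edge; shorten at the
                # recording end only when the run holds no full window at all.
                if not emitted_in_run:
                    out.append((float(s), float(length)))
                break
            out.append((float(s), float(length)))
            emitted_in_run = True
            s += STEP_SECONDS
    return out


def plan_windows(
    mask: ArtifactMask,
    stages: StageAnnotation,
    state: str,
    direction: str = "forward",
) -> list[SamplingWindow]:
    """Place colliding windows over the artifact-free, in-state signal.

    The backward pass is the forward pass run on the time-reversed validity
    cells and mapped back, so obstructions shorten windows on their *other*
    side.  Returns an empty list (with a warning) when no clean in-state
    run of at least 20 s exists.
    """
    valid = valid_cells(mask, stages, state)
    duration = len(valid) * ARTIFACT_CELL_SECONDS
    if direction == "forward":
        pairs = _plan_forward(valid, duration)
    elif direction == "backward":
        pairs = [
            (duration - s - length, length)
            for s, length in _plan_forward(valid[::-1], duration)
        ]
        pairs.sort()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if not pairs:
        logger.warning(
            "no clean %s run of at least %g s; no sampling windows emitted",
            state,
            MIN_WINDOW_SECONDS,
        )
    return [SamplingWindow(s, length, direction) for s, length in pairs]


def plan_windows_both(
    mask: ArtifactMask, stages: StageAnnotation, state: str
) -> list[SamplingWindow]:
    """Pooled forward+backward window set, duplicates counted once.

    A window emitted identically by both passes (same start and length)
    contributes a single entry: the two passes exist to balance coverage
    around obstructions, not to double-weight clean stretches.
    """
    fwd = plan_windows(mask, stages, state, "forward")
    seen = {(w.start, w.length) for w in fwd}
    merged = list(fwd)
    for w in plan_windows(mask, stages, state, "backward"):
        if (w.start, w.length) not in seen:
            merged.append(w)
    merged.sort(key=lambda w: (w.start, w.length))
    return merged


@dataclass
class WindowSpectrum:
    """Single-window periodogram on the fixed grid, with per-bin validity."""

    density: np.ndarray  # (400,)
    valid: np.ndarray  # (400,) bool; False below 1/L Hz


def window_psd(segment: np.ndarray, rate: float) -> WindowSpectrum:
    """Detrended, Hamming-tapered periodogram of one envelope window.

    Evaluated at exactly 0.01..4.00 Hz via the chirp-z transform (a DTFT at
    the requested frequencies, matching a frequency-vector periodogram).
    Bins below 1/L Hz for a window of L seconds are marked invalid.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("window_psd expects a single-channel 1-D segment")
    if not np.all(np.isfinite(segment)):
        raise ValueError("non-finite values in window segment (artifact leakage?)")
    n = len(segment)
    length_s = n / rate
    if not MIN_WINDOW_SECONDS - 1e-9 <= length_s <= WINDOW_SECONDS + 1e-9:
        raise ValueError(
            f"segment spans {length_s:g} s; expected "
            f"[{MIN_WINDOW_SECONDS:g}, {WINDOW_SECONDS:g}]"
        )
    x = sps.detrend(segment, type="linear")
    taper = sps.get_window("hamming", n)
    xw = x * taper
    # DTFT at f0 + k*df, k = 0..399
    df = float(ENVELOPE_FREQS[1] - ENVELOPE_FREQS[0])
    f0 = float(ENVELOPE_FREQS[0])
    w = np.exp(-2j * np.pi * df / rate)
    a = np.exp(2j * np.pi * f0 / rate)
    spec = sps.czt(xw, m=len(ENVELOPE_FREQS), w=w, a=a)
    # one-sided scaling: double every bin except one landing on Nyquist
    fold = np.where(np.isclose(ENVELOPE_FREQS, rate / 2.0), 1.0, 2.0)
    density = fold * np.abs(spec) ** 2 / (rate * np.sum(taper**2))
    valid = ENVELOPE_FREQS >= (1.0 / length_s) - 1e-9
    return WindowSpectrum(density, valid)


@dataclass
class EnvelopePSD:
    """Averaged envelope power spectral density on the fixed 0.01-Hz grid.

    `density` has shape (n_bands, n_channels, 400); `weight` records the
    per-bin total window weight behind each estimate (zero marks a missing
    bin).  `stage` tracks the processing state: ``raw-average``,
    ``smoothed``, ``log`` or ``z``.
    """

    density: np.ndarray
    bands: list[str]
    channels: list[str]
    weight: np.ndarray
    stage: str = "raw-average"
    freqs: np.ndarray = field(default_factory=lambda: ENVELOPE_FREQS.copy())

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (len(self.bands), len(self.channels), len(self.freqs)):
            raise ValueError(
                f"density shape {self.density.shape} does not match "
                f"{len(self.bands)} bands x {len(self.channels)} channels x "
                f"{len(self.freqs)} bins"
            )

    def band(self, name: str, channel: int = 0) -> np.ndarray:
        return self.density[self.bands.index(name), channel]

    @property
    def analysis_slice(self) -> slice:
        """Bins of the 0.01-2 Hz analysis sub-grid."""
        return slice(0, int(np.sum(self.freqs <= ANALYSIS_MAX_HZ + 1e-9)))


def aggregate_psd(
    windows: list[tuple[SamplingWindow, WindowSpectrum]],
    band: str = "band",
    channel: str = "ch0",
) -> EnvelopePSD:
    """Weighted per-frequency mean over windows (weight L/100).

    At each frequency only windows whose length supports it (f >= 1/L)
    contribute.  Bins with zero total weight are NaN and flagged by a zero
    weight entry.
    """
    if not windows:
        raise ValueError("aggregate_psd needs at least one window")
    nbins = len(ENVELOPE_FREQS)
    num = np.zeros(nbins)
    wsum = np.zeros(nbins)
    for win, spec in windows:
        contrib = win.weight * spec.valid
        num += contrib * np.where(spec.valid, spec.density, 0.0)
        wsum += contrib
    if not np.any(wsum > 0):
        raise ValueError("all windows invalid at every frequency")
    with np.errstate(invalid="ignore"):
        density = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), np.nan)
    return EnvelopePSD(
        density[np.newaxis, np.newaxis, :],
        [band],
        [channel],
        wsum[np.newaxis, np.newaxis, :],
        stage="raw-average",
    )


def postprocess_psd(p: EnvelopePSD) -> EnvelopePSD:
    """Savitzky-Golay smoothing, log10, and z-scoring across 0.01-2 Hz.

    Missing bins inside the analysis sub-grid are linearly interpolated
    (logged).  Densities driven non-positive by smoothing overshoot are
    clipped to the smallest positive density of that spectrum (logged).
    A flat spectrum has zero spread and cannot be z-scored: ValueError.
    """
    if p.stage != "raw-average":
        raise ValueError(f"expected a raw-average spectrum, got stage {p.stage!r}")
    density = p.density.copy()
    sub = p.analysis_slice
    flat = density.reshape(-1, density.shape[-1])
    for row in flat:
        missing = ~np.isfinite(row)
        if missing.any():
            if missing.all():
                raise ValueError("spectrum entirely missing; cannot post-process")
            logger.info("interpolating %d missing bins", int(missing.sum()))
            idx = np.arange(len(row))
            row[missing] = np.interp(idx[missing], idx[~missing], row[~missing])
    smoothed = sps.savgol_filter(
        density, SAVGOL_FRAME, SAVGOL_POLYORDER, axis=-1, mode="interp"
    )
    flat = smoothed.reshape(-1, smoothed.shape[-1])
    for row in flat:
        bad = row <= 0
        if bad.any():
            positive = row[row > 0]
            if positive.size == 0:
                raise ValueError("spectrum non-positive everywhere after smoothing")
            logger.info(
                "clipping %d non-positive bins to smallest positive density",
                int(bad.sum()),
            )
            row[bad] = positive.min()
    logged = np.log10(smoothed)
    mean = logged[..., sub].mean(axis=-1, keepdims=True)
    sd = logged[..., sub].std(axis=-1, keepdims=True)
    # a constant spectrum still carries ~1e-8 jitter from the ill-conditioned
    # order-10 polynomial fit; anything below this spread is degenerate
    if np.any(sd <= 1e-6):
        raise ValueError("flat spectrum: zero spread on the analysis sub-grid")
    z = (logged - mean) / sd
    return EnvelopePSD(z, list(p.bands), list(p.channels), p.weight.copy(), stage="z")


@dataclass
class EnvelopeSpectrumResult:
    """Full colliding-window result: z and raw stages plus per-window spectra."""

    z: EnvelopePSD
    raw: EnvelopePSD
    windows: list[SamplingWindow]
    #: per-window spectra indexed [window][band][channel] -> WindowSpectrum
    window_spectra: list[list[list[WindowSpectrum]]]


def compute_envelope_spectrum(
    rec: Recording,
    mask: ArtifactMask,
    stages: StageAnnotation,
    state: str = "NREM",
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
) -> EnvelopeSpectrumResult:
    """Band filter -> Hilbert envelope -> colliding windows -> averaged PSD.

    Windows are planned once from the artifact mask and staging (both
    directions pooled) and applied to every band x channel envelope.
    Returns the z-stage spectrum, the raw-average stage (needed for
    reliability analyses) and the per-window spectra.
    """
    windows = plan_windows_both(mask, stages, state)
    if not windows:
        raise ValueError(f"no usable sampling window in state {state!r}")
    envset = extract_envelopes(rec, bands)
    band_names = [b.name for b in bands]
    n_bins = len(ENVELOPE_FREQS)
    raw = np.empty((len(bands), rec.n_channels, n_bins))
    wsum = np.empty_like(raw)
    per_window: list[list[list[WindowSpectrum]]] = [
        [[None] * rec.n_channels for _ in bands] for _ in windows  # type: ignore
    ]
    for bi, bname in enumerate(band_names):
        env = envset.envelopes[bname]
        for ci in range(rec.n_channels):
            pairs = []
            for wi, win in enumerate(windows):
                i0 = int(round(win.start * rec.rate))
                i1 = int(round(win.stop * rec.rate))
                spec = window_psd(env[ci, i0:i1], rec.rate)
                per_window[wi][bi][ci] = spec
                pairs.append((win, spec))
            agg = aggregate_psd(pairs, bname, rec.labels[ci])
            raw[bi, ci] = agg.density[0, 0]
            wsum[bi, ci] = agg.weight[0, 0]
    raw_psd = EnvelopePSD(raw, band_names, list(rec.labels), wsum, stage="raw-average")
    z_psd = postprocess_psd(raw_psd)
    return EnvelopeSpectrumResult(z_psd, raw_psd, windows, per_window)


def flag_abnormal_spectra(
    cohort: np.ndarray, sd_threshold: float = 5.0, bin_fraction: float = 0.10
) -> np.ndarray:
    """Flag subject x band log-spectra deviating grossly from the cohort mean.

    `cohort` has shape (n_subjects, n_bands, n_bins) of log-scale spectra.
    A subject/band is flagged when more than `bin_fraction` of bins lie
    further than `sd_threshold` cohort SDs from the cohort mean.  This is a
    reproducible screen for grossly abnormal spectra; flagged entries are
    reported, never silently dropped.
    """
    cohort = np.asarray(cohort, dtype=float)
    mean = cohort.mean(axis=0, keepdims=True)
    sd = cohort.std(axis=0, keepdims=True)
    sd = np.where(sd == 0, np.inf, sd)
    outlier_bins = np.abs(cohort - mean) > sd_threshold * sd
    frac = outlier_bins.mean(axis=-1)
    flags = frac > bin_fraction
    if flags.any():
        warnings.warn(
            f"{int(flags.sum())} subject/band spectra flagged as abnormal",
            stacklevel=2,
        )
    return flags
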