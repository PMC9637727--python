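"""Envelope-firing and envelope-respiration coupling with surrogate inference.

Coupling between a band-limited EEG envelope and multi-unit activity (MUA)
is summarized per 20-s artifact-free NREM segment by three statistics,
each averaged across segments:

* normalized cross-correlation over lags of -1..+1 s,
* Welch magnitude-squared coherence at 0.1..1.0 Hz,
* mean z-scored envelope amplitude in twelve 30-degree bins of the MUA
  oscillation phase (phase from the analytic signal of the demeaned,
  band-smoothed MUA).

Significance is assessed against surrogate nulls built by re-pairing
envelope segments with randomly drawn MUA segments (sampling with
replacement, 1000 draws by default), giving empirical two-sided p-values
with the +1 correction.  Per-subject p-values are pooled by averaging
their standard-normal deviates (an unweighted, conservative variant of
Fisher's method), and families of tests are corrected with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "N_PHASE_BINS",
    "COHERENCE_FREQS",
    "CouplingResult",
    "SurrogateNull",
    "crosscorr_norm",
    "mscoherence",
    "phase_amplitude_profile",
    "segment_average",
    "surrogate_p",
    "pool_pvalues",
    "fdr_bh",
    "modulation_index",
    "respiration_coupling",
    "coupling_statistics",
]

N_PHASE_BINS = 12
PHASE_BIN_EDGES = np.arange(N_PHASE_BINS + 1) * (360.0 / N_PHASE_BINS)
COHERENCE_FREQS = np.round(np.arange(1, 11) * 0.1, 10)  # 0.1 .. 1.0 Hz
MAX_LAG_SECONDS = 1.0
COHERENCE_SUBWINDOW_SECONDS = 10.0  # 0.1 Hz native resolution, 3 half-overlapping


def crosscorr_norm(
    env: np.ndarray, mua: np.ndarray, rate: float, max_lag: float = MAX_LAG_SECONDS
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient-normalized cross-correlation over lags in [-max_lag, +max_lag].

    Both inputs are linearly detrended (which includes demeaning) first.
    The value at lag tau correlates env(t) with mua(t + tau): a positive
    extremum lag means the MUA pattern trails the envelope.  Returns
    (lags_seconds, coefficients); zero-variance input yields NaNs.
    """
    env = sps.detrend(np.asarray(env, dtype=float), type="linear")
    mua = sps.detrend(np.asarray(mua, dtype=float), type="linear")
    if len(env) != len(mua):
        raise ValueError("segments must have equal length")
    max_shift = int(round(max_lag * rate))
    lags = np.arange(-max_shift, max_shift + 1) / rate
    denom = np.sqrt(np.sum(env**2) * np.sum(mua**2))
    if denom == 0:
        return lags, np.full(len(lags), np.nan)
    full = sps.correlate(mua, env, mode="full")
    mid = len(env) - 1
    return lags, full[mid - max_shift : mid + max_shift + 1] / denom


def mscoherence(env: np.ndarray, mua: np.ndarray, rate: float) -> np.ndarray:
    """Welch magnitude-squared coherence at 0.1..1.0 Hz.

    Uses 10-s Hamming sub-windows with 50% overlap (three sub-windows in a
    20-s segment), whose native resolution places the evaluation
    frequencies exactly on Fourier bins.
    """
    env = np.asarray(env, dtype=float)
    mua = np.asarray(mua, dtype=float)
    if env.std() == 0 or mua.std() == 0:
        return np.full(len(COHERENCE_FREQS), np.nan)
    nperseg = int(round(COHERENCE_SUBWINDOW_SECONDS * rate))
    nperseg = min(nperseg, len(env))
    f, cxy = sps.coherence(
        env,
        mua,
        fs=rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="linear",
    )
    idx = [int(np.argmin(np.abs(f - target))) for target in COHERENCE_FREQS]
    return cxy[idx]


def phase_amplitude_profile(
    mua_smoothed: np.ndarray, env: np.ndarray
) -> np.ndarray:
    """Mean z-scored envelope amplitude per 30-degree MUA phase bin.

    Phase is the angle of the analytic signal of the demeaned smoothed MUA
    (0 degrees at the positive peak of its real part), mapped to [0, 360)
    with left-closed bins.  The envelope is z-scored within the segment, so
    bin means are in within-segment SD units.  Empty bins are NaN.
    """
    mua_smoothed = np.asarray(mua_smoothed, dtype=float)
    env = np.asarray(env, dtype=float)
    if env.std() == 0 or mua_smoothed.std() == 0:
        return np.full(N_PHASE_BINS, np.nan)
    phase = np.angle(sps.hilbert(mua_smoothed - mua_smoothed.mean()))
    phase_deg = np.rad2deg(phase) % 360.0
    z_env = (env - env.mean()) / env.std()
    bins = np.minimum(
        (phase_deg / (360.0 / N_PHASE_BINS)).astype(int), N_PHASE_BINS - 1
    )
    profile = np.full(N_PHASE_BINS, np.nan)
    for b in range(N_PHASE_BINS):
        sel = bins == b
        if sel.any():
            profile[b] = z_env[sel].mean()
    return profile


def segment_average(values: Sequence[np.ndarray]) -> np.ndarray:
    """Average a per-segment statistic across segments, ignoring NaN entries."""
    stacked = np.stack([np.asarray(v, dtype=float) for v in values])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


@dataclass
class SurrogateNull:
    """Null distribution from randomized segment pairings.

    `p` is the two-sided empirical p-value with the +1 correction:
    (1 + #{|surrogate| >= |observed|}) / (n + 1), bounded in
    [1/(n+1), 1].
    """

    observed: np.ndarray
    surrogates: np.ndarray  # (n_surrogates, ...) same trailing shape as observed
    p: np.ndarray

    @property
    def n_surrogates(self) -> int:
        return self.surrogates.shape[0]


def surrogate_p(
    pair_stat: Callable[[np.ndarray, np.ndarray], np.ndarray],
    env_segments: Sequence[np.ndarray],
    mua_segments: Sequence[np.ndarray],
    n: int = 1000,
    seed: int | None = None,
    observed: np.ndarray | None = None,
) -> SurrogateNull:
    """Empirical null by re-pairing envelope segments with random MUA segments.

    `pair_stat(env_seg, mua_seg)` returns a scalar or vector statistic; the
    segment-averaged statistic is recomputed for each of `n` surrogate
    pairings (drawn uniformly with replacement; self-pairing allowed, its
    probability vanishes with the segment count).  The observed statistic,
    if not supplied, uses the matched (diagonal) pairing.
    """
    if n < 1:
        raise ValueError("need at least one surrogate")
    n_seg = len(env_segments)
    if n_seg < 2 or len(mua_segments) != n_seg:
        raise ValueError("need >= 2 segments and matched segment counts")
    rng = np.random.default_rng(seed)
    # All statistics here are averages of per-pair values, so precompute the
    # pairwise matrix once and each surrogate reduces to indexing.
    pair_vals = np.array(
        [
            [np.atleast_1d(pair_stat(env_segments[i], mua_segments[j])) for j in range(n_seg)]
            for i in range(n_seg)
        ]
    )  # (n_seg, n_seg, dim)
    if observed is None:
        obs = np.nanmean(pair_vals[np.arange(n_seg), np.arange(n_seg)], axis=0)
    else:
        obs = np.atleast_1d(np.asarray(observed, dtype=float))
    draws = rng.integers(0, n_seg, size=(n, n_seg))
    surr = np.nanmean(pair_vals[np.arange(n_seg)[np.newaxis, :], draws], axis=1)
    exceed = np.sum(np.abs(surr) >= np.abs(obs)[np.newaxis, :], axis=0)
    p = (1.0 + exceed) / (n + 1.0)
    return SurrogateNull(obs, surr, p)


def pool_pvalues(p_per_subject: Sequence[float], n_surrogates: int = 1000) -> float:
    """Pool per-subject empirical p-values via averaged normal deviates.

    z_i = Phi^-1(1 - p_i); pooled p = 1 - Phi(mean z).  Unweighted across
    subjects, so pooling never gains power a single subject lacked.  Zero
    p-values are floored to 1/(n_surrogates + 1) before the transform.
    """
    p = np.asarray(p_per_subject, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    floor = 1.0 / (n_surrogates + 1)
    if np.any(p == 0):
        logger.info("flooring zero p-values to %g", floor)
        p = np.maximum(p, floor)
    z = spstats.norm.ppf(1.0 - p)
    return float(1.0 - spstats.norm.cdf(z.mean()))


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control within one family of tests.

    Returns (adjusted p-values, boolean rejection set at level q).  NaN
    entries are passed through unrejected.
    """
    pvals = np.asarray(pvals, dtype=float)
    adjusted = np.full(pvals.shape, np.nan)
    reject = np.zeros(pvals.shape, dtype=bool)
    ok = np.isfinite(pvals)
    if ok.sum() == 0:
        return adjusted, reject
    rej, adj, _, _ = multipletests(pvals[ok].ravel(), alpha=q, method="fdr_bh")
    adjusted[ok] = adj
    reject[ok] = rej
    return adjusted, reject


@dataclass
class CouplingResult:
    """Segment-averaged coupling statistics for one band/channel pair."""

    lags: np.ndarray
    crosscorr: np.ndarray
    crosscorr_p: np.ndarray
    coherence_freqs: np.ndarray
    coherence: np.ndarray
    coherence_p: np.ndarray
    phase_bin_edges: np.ndarray
    phase_profile: np.ndarray
    phase_profile_p: np.ndarray
    n_segments: int
    adjusted: dict[str, np.ndarray] = field(default_factory=dict)


def coupling_statistics(
    env_segments: Sequence[np.ndarray],
    mua_segments: Sequence[np.ndarray],
    rate: float,
    n_surrogates: int = 1000,
    seed: int | None = None,
) -> CouplingResult:
    """All three coupling statistics with surrogate p-values.

    `env_segments` are band-envelope segments and `mua_segments` the
    matching band-smoothed MUA segments (equal length and rate, typically
    20 s each).  FDR adjustment across each statistic's own family (lags,
    frequencies, phase bins) is stored under `adjusted`.
    """
    max_shift = int(round(MAX_LAG_SECONDS * rate))
    lags = np.arange(-max_shift, max_shift + 1) / rate

    def cc(e: np.ndarray, m: np.ndarray) -> np.ndarray:
        return crosscorr_norm(e, m, rate)[1]

    def coh(e: np.ndarray, m: np.ndarray) -> np.ndarray:
        return mscoherence(e, m, rate)

    def pac(e: np.ndarray, m: np.ndarray) -> np.ndarray:
        return phase_amplitude_profile(m, e)

    seeds = np.random.SeedSequence(seed).spawn(3)
    nulls = [
        surrogate_p(stat, env_segments, mua_segments, n_surrogates, np.random.default_rng(s))
        for stat, s in zip((cc, coh, pac), seeds)
    ]
    result = CouplingResult(
        lags=lags,
        crosscorr=nulls[0].observed,
        crosscorr_p=nulls[0].p,
        coherence_freqs=COHERENCE_FREQS.copy(),
        coherence=nulls[1].observed,
        coherence_p=nulls[1].p,
        phase_bin_edges=PHASE_BIN_EDGES.copy(),
        phase_profile=nulls[2].observed,
        phase_profile_p=nulls[2].p,
        n_segments=len(env_segments),
    )
    for name, p in (
        ("crosscorr", result.crosscorr_p),
        ("coherence", result.coherence_p),
        ("phase_profile", result.phase_profile_p),
    ):
        result.adjusted[name] = fdr_bh(p)[0]
    return result


def modulation_index(amplitude: np.ndarray, phase_deg: np.ndarray) -> float:
    """Kullback-Leibler modulation index of amplitude by phase (12 bins).

    The mean amplitude per phase bin is normalized to a distribution P and
    MI = (log N - H(P)) / log N, zero for a flat profile and 1 when all
    amplitude concentrates in one bin.  Requires non-negative amplitudes
    with positive total.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(amplitude < 0):
        raise ValueError("modulation index needs non-negative amplitudes")
    bins = np.minimum(
        (np.asarray(phase_deg) / (360.0 / N_PHASE_BINS)).astype(int), N_PHASE_BINS - 1
    )
    means = np.zeros(N_PHASE_BINS)
    for b in range(N_PHASE_BINS):
        sel = bins == b
        if not sel.any():
            return np.nan
        means[b] = np.mean(amplitude[sel])
    if means.min() < 0 or means.sum() <= 0:
        raise ValueError("modulation index needs non-negative amplitudes")
    pdist = means / means.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.sum(np.where(pdist > 0, pdist * np.log(pdist), 0.0))
    return float((np.log(N_PHASE_BINS) - h) / np.log(N_PHASE_BINS))


@dataclass
class RespirationCouplingResult:
    coherence: np.ndarray
    coherence_p: np.ndarray
    mi: float
    mi_p: float
    n_windows: int


def respiration_coupling(
    env: np.ndarray,
    resp: np.ndarray,
    rate: float,
    window_seconds: float = 100.0,
    overlap: float = 0.5,
    n_surrogates: int = 1000,
    seed: int | None = None,
) -> RespirationCouplingResult:
    """Coherence and modulation index between an EEG envelope and respiration.

    Both series are cut into `window_seconds` windows with 50% overlap;
    per-window coherence (0.1-1 Hz) and the phase-amplitude modulation
    index (envelope amplitude binned by respiration phase, 12 bins) are
    averaged across windows and compared with window-shuffled surrogate
    pairings.  Constant respiration has no defined phase and raises.
    """
    env = np.asarray(env, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if len(env) != len(resp):
        raise ValueError("series must have equal length")
    if resp.std() == 0:
        raise ValueError("constant respiration signal: phase undefined")
    step = int(round(window_seconds * rate * (1.0 - overlap)))
    width = int(round(window_seconds * rate))
    starts = range(0, len(env) - width + 1, step)
    env_wins = [env[s : s + width] for s in starts]
    resp_wins = [resp[s : s + width] for s in starts]
    if len(env_wins) < 2:
        raise ValueError("fewer than two valid windows")

    def coh(e: np.ndarray, r: np.ndarray) -> np.ndarray:
        return mscoherence(e, r, rate)

    def mi(e: np.ndarray, r: np.ndarray) -> np.ndarray:
        phase = np.rad2deg(np.angle(sps.hilbert(r - r.mean()))) % 360.0
        return np.array([modulation_index(e, phase)])

    seeds = np.random.SeedSequence(seed).spawn(2)
    null_coh = surrogate_p(
        coh, env_wins, resp_wins, n_surrogates, np.random.default_rng(seeds[0])
    )
    null_mi = surrogate_p(
        mi, env_wins, resp_wins, n_surrogates, np.random.default_rng(seeds[1])
    )
    return RespirationCouplingResult(
        coherence=null_coh.observed,
        coherence_p=null_coh.p,
        mi=float(null_mi.observed[0]),
        mi_p=float(null_mi.p[0]),
        n_windows=len(env_wins),
    )
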