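"""Within-subject reliability of envelope spectra and univariate associations.

Even-odd reliability treats interleaved window subsets as repeated
measurements of the same spectrum: windows are thinned to every fifth
(100-s windows on a 20-s step overlap by 80 s, so every fifth window is
the first with non-overlapping samples), split by parity, averaged per
half, and compared across subjects with an intraclass correlation
computed as the covariance over the pooled variance of the two half
measurements.  Split-half reliability compares the first and last 50% of
windows with an ordinary Pearson correlation, which a common additive
drift between night halves cannot depress.  Coefficients are reported
unsquared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .annotations import (
    ARTIFACT_CELL_SECONDS,
    ArtifactMask,
    StageAnnotation,
    valid_cells,
)
from .coupling import fdr_bh
from .envspectrum import SamplingWindow, WindowSpectrum, aggregate_psd
from .signal import Recording

__all__ = [
    "ReliabilityResult",
    "icc_pooled",
    "half_average_spectra",
    "even_odd_reliability",
    "split_half_reliability",
    "signal_psd_welch",
    "SIGNAL_PSD_FREQS",
    "cross_measure_correlation",
    "phenotype_correlations",
]

EVERY_NTH_WINDOW = 5

#: Ordinary signal-spectrum grid: 0 to 48 Hz inclusive at 0.25 Hz (193 bins).
SIGNAL_PSD_FREQS = np.round(np.arange(193) * 0.25, 10)


@dataclass
class ReliabilityResult:
    """Per-frequency reliability coefficients for one band/channel."""

    coefficients: np.ndarray  # (n_bins,), NaN where a half is missing
    kind: str  # "even-odd" or "split-half"

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.coefficients))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.coefficients))


def icc_pooled(a: np.ndarray, b: np.ndarray) -> float:
    """Intraclass correlation of two measurements with pooled moments.

    A Pearson-style coefficient that pools the mean and SD over both
    measurements: sum((a - m)(b - m)) / (n * s^2) with the grand mean m and
    pooled population variance s^2.  Unlike the ordinary Pearson
    coefficient it is depressed by a systematic mean difference between the
    two measurements, and it equals the two-measurement one-way ANOVA
    intraclass correlation (MSB - MSW) / (MSB + MSW) with population mean
    squares.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    grand = np.concatenate([a, b]).mean()
    pooled = (np.mean((a - grand) ** 2) + np.mean((b - grand) ** 2)) / 2.0
    if pooled == 0:
        return np.nan
    cov = np.mean((a - grand) * (b - grand))
    return float(cov / pooled)


SubjectWindows = list[tuple[SamplingWindow, WindowSpectrum]]


def half_average_spectra(
    windows: SubjectWindows, scheme: str
) -> tuple[np.ndarray, np.ndarray] | None:
    """Average spectra of the two halves of one subject's windows.

    scheme "even-odd": thin to every fifth window (time order, anchored at
    the first), then split the thinned sequence by parity — consecutive
    retained windows are 100 s apart, so the halves share no samples.
    scheme "split-half": first vs last 50% of all windows.  Returns None
    when either half is empty.
    """
    ordered = sorted(windows, key=lambda pair: (pair[0].start, pair[0].length))
    if scheme == "even-odd":
        thinned = ordered[::EVERY_NTH_WINDOW]
        half_a, half_b = thinned[0::2], thinned[1::2]
    elif scheme == "split-half":
        mid = len(ordered) // 2
        half_a, half_b = ordered[:mid], ordered[mid:]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not half_a or not half_b:
        return None
    return (
        aggregate_psd(half_a).density[0, 0],
        aggregate_psd(half_b).density[0, 0],
    )


def _reliability(
    per_subject_windows: list[SubjectWindows], scheme: str, min_subjects: int
) -> ReliabilityResult:
    halves = [half_average_spectra(w, scheme) for w in per_subject_windows]
    halves = [h for h in halves if h is not None]
    kind = "even-odd" if scheme == "even-odd" else "split-half"
    nbins = halves[0][0].shape[0] if halves else 0
    if len(halves) < min_subjects:
        return ReliabilityResult(np.full(max(nbins, 1), np.nan), kind)
    a = np.stack([h[0] for h in halves])
    b = np.stack([h[1] for h in halves])
    coef = np.full(a.shape[1], np.nan)
    for k in range(a.shape[1]):
        ak, bk = a[:, k], b[:, k]
        ok = np.isfinite(ak) & np.isfinite(bk)
        if ok.sum() < min_subjects:
            continue
        if scheme == "even-odd":
            coef[k] = icc_pooled(ak[ok], bk[ok])
        else:
            if ak[ok].std() == 0 or bk[ok].std() == 0:
                continue
            coef[k] = spstats.pearsonr(ak[ok], bk[ok])[0]
    return ReliabilityResult(coef, kind)


def even_odd_reliability(
    per_subject_windows: list[SubjectWindows],
) -> ReliabilityResult:
    """Across-subject ICC between even/odd thinned-window half spectra."""
    return _reliability(per_subject_windows, "even-odd", min_subjects=2)


def split_half_reliability(
    per_subject_windows: list[SubjectWindows],
) -> ReliabilityResult:
    """Across-subject Pearson correlation between night-half spectra."""
    return _reliability(per_subject_windows, "split-half", min_subjects=3)


def signal_psd_welch(
    rec: Recording,
    mask: ArtifactMask | None = None,
    stages: StageAnnotation | None = None,
    state: str = "NREM",
) -> np.ndarray:
    """Ordinary log10 signal PSD: Welch over clean in-state 4-s epochs.

    4-s Hamming epochs with 50% overlap give a 0.25 Hz resolution; the
    result covers 0-48 Hz (193 bins) per channel, log10-transformed
    (non-positive densities clipped to the smallest positive one).  With no
    mask/staging the whole recording is used.
    """
    if mask is not None and stages is not None:
        valid = valid_cells(mask, stages, state)
    else:
        valid = np.ones(int(rec.duration / ARTIFACT_CELL_SECONDS), dtype=bool)
    nperseg = int(round(4 * rec.rate))
    noverlap = nperseg // 2
    psds = []
    padded = np.diff(np.concatenate(([0], valid.astype(int), [0])))
    for c0, c1 in zip(np.flatnonzero(padded == 1), np.flatnonzero(padded == -1)):
        i0 = int(round(c0 * ARTIFACT_CELL_SECONDS * rec.rate))
        i1 = int(round(c1 * ARTIFACT_CELL_SECONDS * rec.rate))
        if i1 - i0 < nperseg:
            continue
        n_epochs = (i1 - i0 - noverlap) // (nperseg - noverlap)
        f, pxx = sps.welch(
            rec.samples[:, i0:i1],
            fs=rec.rate,
            window="hamming",
            nperseg=nperseg,
            noverlap=noverlap,
            detrend="constant",
            axis=-1,
        )
        psds.append((n_epochs, pxx))
    if not psds:
        raise ValueError(f"no clean in-state run of at least 4 s in state {state!r}")
    total = sum(n for n, _ in psds)
    avg = sum(n * p for n, p in psds) / total
    sel = [int(round(fq / 0.25)) for fq in SIGNAL_PSD_FREQS]
    avg = avg[:, sel]
    positive_min = avg[avg > 0].min()
    return np.log10(np.clip(avg, positive_min, None))


def cross_measure_correlation(
    env_features: np.ndarray, signal_features: np.ndarray
) -> np.ndarray:
    """Across-subject Pearson correlation of every envelope/signal bin pair.

    `env_features` is (n_subjects, n_env_bins) — typically the 0.01-1 Hz
    envelope spectrum — and `signal_features` (n_subjects, n_signal_bins)
    the 0-48 Hz signal spectrum; the result is
    (n_env_bins, n_signal_bins).  Zero-variance features give NaN cells.
    """
    env_features = np.asarray(env_features, dtype=float)
    signal_features = np.asarray(signal_features, dtype=float)
    if env_features.shape[0] != signal_features.shape[0]:
        raise ValueError("subject counts differ between measures")
    if env_features.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    ez = env_features - env_features.mean(axis=0)
    sz = signal_features - signal_features.mean(axis=0)
    esd = ez.std(axis=0)
    ssd = sz.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (ez.T @ sz) / env_features.shape[0] / np.outer(esd, ssd)
    corr[esd == 0, :] = np.nan
    corr[:, ssd == 0] = np.nan
    return corr


def phenotype_correlations(
    features: np.ndarray,
    phenotypes: pd.DataFrame,
    columns: tuple[str, ...] = ("age", "sex", "iq"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and BH-adjusted p per feature x phenotype.

    `features` is (n_subjects, n_features) for one channel (the FDR family
    is all features of a channel for one phenotype).  Missing phenotype
    values are dropped pairwise; constant phenotypes give NaN rows.
    Returns a tidy frame with columns phenotype, feature, r, p, p_adj,
    reject.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    rows = []
    for col in columns:
        y = phenotypes[col].to_numpy(dtype=float)
        r = np.full(features.shape[1], np.nan)
        p = np.full(features.shape[1], np.nan)
        for k in range(features.shape[1]):
            x = features[:, k]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            r[k], p[k] = spstats.pearsonr(x[ok], y[ok])
        p_adj, reject = fdr_bh(p, q)
        for k in range(features.shape[1]):
            rows.append(
                {
                    "phenotype": col,
                    "feature": k,
                    "r": r[k],
                    "p": p[k],
                    "p_adj": p_adj[k],
                    "reject": bool(reject[k]),
                }
            )
    return pd.DataFrame(rows)
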