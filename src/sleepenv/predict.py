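"""Multivariate phenotype prediction from envelope spectra via elastic net.

The feature matrix holds the envelope PSD at 0.01-1.00 Hz (100 bins) for
each of the eight bands — 800 predictors per channel and vigilance state.
A validation split takes every 8th participant after ordering by the
phenotype (maximal-variance hold-out); the remainder trains an elastic
net (L1-L2 mixture 0.5) whose penalty is chosen by fivefold
cross-validated mean squared error over a descending 100-point penalty
path.  Performance is the Pearson correlation between predicted and
actual phenotype in the held-out sample; channels whose fit does not
converge report r = 0 and are excluded from cross-channel averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV

from .envspectrum import ENVELOPE_FREQS, EnvelopePSD

__all__ = [
    "N_PREDICTOR_BINS",
    "FitResult",
    "build_feature_matrix",
    "split_validation",
    "fit_elastic_net",
    "evaluate_prediction",
    "run_prediction",
]

N_PREDICTOR_BINS = 100  # 0.01 .. 1.00 Hz
VALIDATION_EVERY = 8
L1_RATIO = 0.5
N_ALPHAS = 100
ALPHA_EPS = 1e-4
CV_FOLDS = 5


def build_feature_matrix(
    spectra: list[EnvelopePSD], channel: int = 0
) -> tuple[np.ndarray, list[tuple[str, float]]]:
    """Stack per-subject spectra into (n_subjects, 800) with column metadata.

    Columns are ordered band-major: all 100 frequency bins (0.01-1 Hz) of
    the first band, then the second, and so on.  Metadata pairs are
    (band, frequency).
    """
    first = spectra[0]
    meta = [
        (band, float(ENVELOPE_FREQS[k]))
        for band in first.bands
        for k in range(N_PREDICTOR_BINS)
    ]
    X = np.stack(
        [
            psd.density[:, channel, :N_PREDICTOR_BINS].reshape(-1)
            for psd in spectra
        ]
    )
    return X, meta


def split_validation(
    subject_ids: list[str], phenotype: np.ndarray, every: int = VALIDATION_EVERY
) -> tuple[list[str], list[str]]:
    """Maximal-variance hold-out: every `every`-th subject in phenotype order.

    Subjects are sorted ascending by phenotype with a stable tie-break on
    subject id; the validation set takes indices 0, every, 2*every, ...
    For 176 subjects this yields 22 validation and 154 training subjects.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if len(subject_ids) != len(phenotype):
        raise ValueError("ids and phenotype lengths differ")
    if len(subject_ids) < every:
        raise ValueError(f"need at least {every} subjects")
    if np.unique(phenotype).size == 1:
        warnings.warn("constant phenotype: split determined by id tie-break only")
    order = sorted(range(len(subject_ids)), key=lambda i: (phenotype[i], subject_ids[i]))
    val = {subject_ids[i] for i in order[0::every]}
    train_ids = [subject_ids[i] for i in order if subject_ids[i] not in val]
    val_ids = [subject_ids[i] for i in order[0::every]]
    return train_ids, val_ids


@dataclass
class FitResult:
    """A fitted elastic net plus the train-set standardization it needs."""

    converged: bool
    coef: np.ndarray | None = None
    intercept: float = 0.0
    alpha: float = np.nan
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    validation_r: float = 0.0
    meta: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.converged:
            raise ValueError("cannot predict from a non-converged fit")
        Xs = (X - self.feature_mean) / self.feature_sd
        return Xs @ self.coef + self.intercept


def _quantile_stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded fold assignment stratified by phenotype quantile.

    Subjects are ordered by y and partitioned into consecutive blocks of
    `folds`; within each block fold labels are randomly permuted, so every
    fold spans the phenotype range.
    """
    n = len(y)
    order = np.argsort(y, kind="stable")
    assignment = np.empty(n, dtype=int)
    for start in range(0, n, folds):
        block = order[start : start + folds]
        labels = rng.permutation(folds)[: len(block)]
        assignment[block] = labels
    return [
        (np.flatnonzero(assignment != f), np.flatnonzero(assignment == f))
        for f in range(folds)
        if np.any(assignment == f)
    ]


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = CV_FOLDS,
    mixing: float = L1_RATIO,
    seed: int | None = None,
) -> FitResult:
    """Elastic-net fit on training rows with CV-selected penalty strength.

    Features are standardized with training statistics only (constant
    columns are zeroed).  The penalty path has 100 log-spaced values from
    the data-derived maximum down by a factor of 1e-4; the minimum
    cross-validated MSE picks the penalty and the model is refit on the
    full training set.  A constant target or a non-finite/non-converged
    path yields ``converged=False`` rather than an exception.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("missing phenotype values in the training target")
    if y.std() == 0:
        return FitResult(converged=False)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xs = (X - mean) / sd_safe
    Xs[:, sd == 0] = 0.0
    yc = y - y.mean()
    alpha_max = np.max(np.abs(Xs.T @ yc)) / (len(y) * mixing)
    if alpha_max <= 0 or not np.isfinite(alpha_max):
        return FitResult(converged=False)
    alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max * ALPHA_EPS), N_ALPHAS)
    rng = np.random.default_rng(seed)
    cv = _quantile_stratified_folds(y, folds, rng)
    model = ElasticNetCV(l1_ratio=mixing, alphas=alphas, cv=cv, max_iter=5000)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            model.fit(Xs, y)
        except (ValueError, FloatingPointError):
            return FitResult(converged=False)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    if not np.all(np.isfinite(model.coef_)):
        converged = False
    if not converged:
        return FitResult(converged=False)
    return FitResult(
        converged=True,
        coef=model.coef_,
        intercept=float(model.intercept_),
        alpha=float(model.alpha_),
        feature_mean=mean,
        feature_sd=sd_safe,
    )


def evaluate_prediction(fit: FitResult, X_val: np.ndarray, y_val: np.ndarray) -> float:
    """Pearson r between predicted and actual phenotype in the hold-out.

    For a 0/1-coded phenotype this is the point-biserial correlation.
    Non-converged fits and zero-variance predictions return NaN (the
    channel is excluded from averages; its reported accuracy is 0).
    """
    if not fit.converged:
        return np.nan
    pred = fit.predict(X_val)
    y_val = np.asarray(y_val, dtype=float)
    if pred.std() == 0 or y_val.std() == 0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-constant predictions
        r = spstats.pearsonr(pred, y_val)[0]
    return float(r) if np.isfinite(r) else np.nan


def run_prediction(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: list[str] | None = None,
    seed: int | None = None,
) -> FitResult:
    """Full split -> fit -> evaluate pipeline for one channel and phenotype."""
    n = len(y)
    ids = subject_ids or [f"s{i:04d}" for i in range(n)]
    train_ids, val_ids = split_validation(ids, y)
    idx = {s: i for i, s in enumerate(ids)}
    tr = np.array([idx[s] for s in train_ids])
    va = np.array([idx[s] for s in val_ids])
    fit = fit_elastic_net(X[tr], np.asarray(y, dtype=float)[tr], seed=seed)
    if fit.converged:
        fit.validation_r = evaluate_prediction(fit, X[va], np.asarray(y, dtype=float)[va])
        if np.isnan(fit.validation_r):
            fit.validation_r = 0.0
    fit.meta = {"n_train": len(tr), "n_validation": len(va)}
    return fit
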