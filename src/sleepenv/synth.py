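"""Synthetic inputs with the statistical structure the analyses assume.

Three generators cover the three study settings:

* a two-component amplitude-modulated test signal in pink noise, whose
  band envelopes oscillate at known "carrier" (modulation) frequencies;
* a coupled ECoG/MUA pair with configurable preferred phase, strength and
  lag, for validating the coupling statistics against ground truth;
* a cohort of envelope spectra carrying declared phenotype effects at
  chosen (band, frequency) loci, for validating association and
  prediction analyses.

All generators are fully seeded: the same seed yields bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .annotations import (
    ARTIFACT_CELL_SECONDS,
    STAGE_EPOCH_SECONDS,
    ArtifactMask,
    StageAnnotation,
)
from .envspectrum import ENVELOPE_FREQS, EnvelopePSD
from .preprocess import band_filter, hilbert_envelope
from .signal import BandDefinition, Recording

__all__ = [
    "ModulatedComponent",
    "SimSpec",
    "CoupledPairSpec",
    "CohortEffect",
    "CohortSpec",
    "DEMO_DELTA",
    "DEMO_SIGMA",
    "pink_noise",
    "make_demo_signal",
    "make_coupled_ecog_mua",
    "make_cohort",
    "make_mask_and_stages",
]

#: Band definitions used by the two-component demonstration signal (a wide
#: delta and sigma band, unlike the canonical eight-band set).
DEMO_DELTA = BandDefinition("delta", 1.0, 4.0)
DEMO_SIGMA = BandDefinition("sigma", 10.0, 16.0)


@dataclass(frozen=True)
class ModulatedComponent:
    """A sinusoid of `frequency` Hz amplitude-modulated at `carrier` Hz.

    The modulation law is non-negative:
    ``a(t) = amplitude * (1 - depth + depth * (1 + sin(2*pi*carrier*t)) / 2)``
    so at depth 1 the instantaneous amplitude swings between 0 and the full
    amplitude, and at depth 0 the tone is unmodulated.
    """

    frequency: float
    carrier: float
    depth: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError(f"modulation depth must be in [0, 1], got {self.depth}")

    def render(self, t: np.ndarray) -> np.ndarray:
        a = 1.0 - self.depth + self.depth * (1.0 + np.sin(2 * np.pi * self.carrier * t)) / 2.0
        return self.amplitude * a * np.sin(2 * np.pi * self.frequency * t)


@dataclass
class SimSpec:
    """Specification of the amplitude-modulated test signal in pink noise.

    Defaults reproduce the canonical demonstration: a 2 Hz sinusoid
    modulated at 0.2 Hz plus a 12 Hz sinusoid modulated at 1 Hz, both at
    full depth and unit amplitude, in 1/f noise with total SD 1 (roughly
    0 dB in-band SNR for the delta component over a 300-s record).
    """

    duration: float = 300.0
    rate: float = 250.0
    components: tuple[ModulatedComponent, ...] = (
        ModulatedComponent(2.0, 0.2),
        ModulatedComponent(12.0, 1.0),
    )
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        fmax = max((c.frequency for c in self.components), default=0.0)
        if self.components and self.rate <= 2 * fmax:
            raise ValueError(
                f"rate {self.rate:g} Hz violates the Nyquist criterion for a "
                f"{fmax:g} Hz component (need > {2 * fmax:g} Hz)"
            )


def pink_noise(
    n: int, exponent: float = 1.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Unit-SD 1/f^exponent noise via spectral shaping of white Gaussian noise.

    The white spectrum is scaled by f^(-exponent/2) (zero at DC), giving
    exact slope control and full seedability.
    """
    rng = np.random.default_rng(rng)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def make_demo_signal(spec: SimSpec | None = None) -> Recording:
    """Sum of amplitude-modulated sinusoids plus seeded pink noise."""
    spec = spec or SimSpec()
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    x = np.zeros(n)
    for comp in spec.components:
        x += comp.render(t)
    if spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + spec.noise_amplitude * pink_noise(n, spec.noise_exponent, rng)
    return Recording(x, spec.rate, ["sim"])


@dataclass
class CoupledPairSpec:
    """Ground truth for an envelope/MUA coupled pair.

    `preferred_phase` (degrees) is the MUA oscillation phase at which the
    band envelope is largest; `coupling_strength` in [0, 1] scales the
    phase-locked gain (0 means independent signals); `lag` (seconds,
    |lag| <= 1) delays the MUA relative to the envelope.
    """

    band: BandDefinition
    preferred_phase: float = 0.0
    coupling_strength: float = 0.5
    lag: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.preferred_phase < 360.0:
            raise ValueError("preferred_phase must be in [0, 360)")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")
        if abs(self.lag) > 1.0:
            raise ValueError("|lag| must be at most 1 s")


def make_coupled_ecog_mua(
    spec: CoupledPairSpec, duration: float, rate: float
) -> tuple[Recording, Recording]:
    """Simulate an ECoG-like signal and a MUA-like signal with known coupling.

    The ECoG is pink noise; its band envelope's oscillatory phase drives a
    rectified-Gaussian MUA through a phase-locked gain, rotated so that the
    envelope is maximal when the MUA oscillation sits at the preferred
    phase, and delayed by `lag`.  At coupling_strength 0 the MUA gain is
    constant and the signals are independent.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration * rate))
    ecog = pink_noise(n, 1.0, rng)
    rec = Recording(ecog, rate, ["ecog"])
    env = hilbert_envelope(band_filter(rec, spec.band))[0]
    analytic = sps.hilbert(env - env.mean())
    theta = np.deg2rad(spec.preferred_phase)
    osc = np.real(analytic * np.exp(1j * theta))
    osc = osc / osc.std()
    shift = int(round(spec.lag * rate))
    osc = np.roll(osc, shift)
    gain = np.clip(1.0 + spec.coupling_strength * osc, 0.0, None)
    mua = gain * np.abs(rng.standard_normal(n))
    return rec, Recording(mua, rate, ["mua"])


@dataclass(frozen=True)
class CohortEffect:
    """A standardized phenotype effect injected at a (band, frequency) locus."""

    band: str
    freq_lo: float
    freq_hi: float
    phenotype: str
    beta: float


@dataclass
class CohortSpec:
    """A synthetic cohort of envelope spectra with declared phenotype effects.

    `effects` is the ground truth: at each declared locus the expected
    feature-phenotype correlation equals `beta`.  `noise_sd` scales the
    per-bin between-subject spread (log10 units) around a smooth 1/f-like
    base spectrum.
    """

    n_subjects: int = 176
    age_range: tuple[float, float] = (17.0, 69.0)
    effects: tuple[CohortEffect, ...] = ()
    noise_sd: float = 0.3
    bands: tuple[str, ...] = (
        "low_delta",
        "high_delta",
        "theta",
        "alpha",
        "low_sigma",
        "high_sigma",
        "beta",
        "gamma",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def make_cohort(spec: CohortSpec) -> tuple[list[EnvelopePSD], pd.DataFrame]:
    """Per-subject log-scale envelope spectra plus a phenotype table.

    Phenotypes: age uniform over `age_range`, sex Bernoulli(0.5) coded 0/1,
    IQ normal(100, 15).  At effect loci the per-bin residual is
    ``sum(beta_p * z_p) + sqrt(1 - sum(beta^2)) * eta`` with standard normal
    eta, so the expected correlation with each phenotype equals its beta;
    elsewhere residuals are pure noise.  All residuals are scaled by
    `noise_sd`.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    age = rng.uniform(*spec.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    iq = rng.normal(100.0, 15.0, size=n)
    table = pd.DataFrame(
        {
            "subject": [f"s{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "iq": iq,
        }
    )
    zpheno = {
        "age": _standardize(age),
        "sex": _standardize(sex),
        "iq": _standardize(iq),
    }
    nbins = len(ENVELOPE_FREQS)
    base = -np.log10(ENVELOPE_FREQS)  # smooth 1/f-like log-spectrum shape
    # accumulate per (band, bin) effect vectors
    beta_map: dict[tuple[int, int], dict[str, float]] = {}
    for eff in spec.effects:
        if eff.band not in spec.bands:
            raise ValueError(f"effect references unknown band {eff.band!r}")
        bi = spec.bands.index(eff.band)
        bins = np.flatnonzero(
            (ENVELOPE_FREQS >= eff.freq_lo - 1e-9)
            & (ENVELOPE_FREQS <= eff.freq_hi + 1e-9)
        )
        for k in bins:
            beta_map.setdefault((bi, int(k)), {})
            beta_map[(bi, int(k))][eff.phenotype] = (
                beta_map[(bi, int(k))].get(eff.phenotype, 0.0) + eff.beta
            )
    values = np.empty((n, len(spec.bands), nbins))
    eta = rng.standard_normal((n, len(spec.bands), nbins))
    values[:] = base[np.newaxis, np.newaxis, :] + spec.noise_sd * eta
    for (bi, k), betas in beta_map.items():
        total = sum(b * b for b in betas.values())
        if total > 1.0:
            raise ValueError(
                f"effects at band {spec.bands[bi]!r} bin {k} have sum(beta^2) "
                f"= {total:.3f} > 1; correlations cannot all be attained"
            )
        signal_part = sum(b * zpheno[p] for p, b in betas.items())
        resid = np.sqrt(1.0 - total) * eta[:, bi, k]
        values[:, bi, k] = base[k] + spec.noise_sd * (signal_part + resid)
    spectra = [
        EnvelopePSD(
            values[i][:, np.newaxis, :],
            list(spec.bands),
            ["synth"],
            np.ones((len(spec.bands), 1, nbins)),
            stage="log",
        )
        for i in range(n)
    ]
    return spectra, table


def make_mask_and_stages(
    duration: float,
    artifact_intervals: list[tuple[float, float]] = (),
    stage_blocks: list[tuple[float, float, str]] = (),
) -> tuple[ArtifactMask, StageAnnotation]:
    """Build a 4-s artifact mask and 20-s stage labels from interval lists.

    `duration` must be a multiple of 20 s.  Artifact intervals are half-open
    [start, end) in seconds; any 4-s cell they overlap is marked.  Stage
    blocks are (start, end, label) with ends on the 20-s grid; uncovered
    epochs are labelled 'U' (unscored).  Overlapping stage blocks raise.
    """
    if duration <= 0 or abs(duration / STAGE_EPOCH_SECONDS % 1.0) > 1e-9:
        raise ValueError(f"duration must be a positive multiple of 20 s, got {duration}")
    n_cells = int(round(duration / ARTIFACT_CELL_SECONDS))
    n_epochs = int(round(duration / STAGE_EPOCH_SECONDS))
    cells = np.zeros(n_cells, dtype=bool)
    for start, end in artifact_intervals:
        if not (0 <= start < end <= duration):
            raise ValueError(f"artifact interval [{start}, {end}) outside [0, {duration})")
        i0 = int(np.floor(start / ARTIFACT_CELL_SECONDS))
        i1 = int(np.ceil(end / ARTIFACT_CELL_SECONDS))
        cells[i0:i1] = True
    epochs = np.array(["U"] * n_epochs, dtype=object)
    covered = np.zeros(n_epochs, dtype=bool)
    for start, end, label in stage_blocks:
        for name, value in (("start", start), ("end", end)):
            if abs(value / STAGE_EPOCH_SECONDS % 1.0) > 1e-9:
                raise ValueError(f"stage block {name} {value} not on the 20-s grid")
        if not (0 <= start < end <= duration):
            raise ValueError(f"stage block [{start}, {end}) outside [0, {duration})")
        e0 = int(round(start / STAGE_EPOCH_SECONDS))
        e1 = int(round(end / STAGE_EPOCH_SECONDS))
        if covered[e0:e1].any():
            raise ValueError(f"stage block [{start}, {end}) overlaps a previous block")
        covered[e0:e1] = True
        epochs[e0:e1] = label
    return ArtifactMask(cells), StageAnnotation(epochs)
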