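"""Readers, writers and run configuration.

Signals travel either as EDF/EDF+ (read through mne) or as a CSV matrix
(one column per channel, header row of labels) with a JSON side-car named
``<stem>.json`` carrying at least ``{"rate": <Hz>}`` and optionally labels
and the generating spec.  Stage annotations are CSV ``epoch_index,stage``
on the 20-s grid and artifact masks CSV ``cell_index,is_artifact`` on the
4-s grid.  Results are written as TSV with explicit frequency/lag/bin
headers plus a JSON metadata file; floats use 17 significant digits so
round-trips are exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import (
    ARTIFACT_CELL_SECONDS,
    STAGE_EPOCH_SECONDS,
    ArtifactMask,
    StageAnnotation,
)
from .coupling import CouplingResult
from .envspectrum import EnvelopePSD
from .signal import Recording

__all__ = [
    "RunConfig",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "write_results",
    "read_envelope_psd",
]

FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    """Run parameters; defaults are the analysis defaults throughout."""

    state: str = "NREM"
    window_seconds: float = 100.0
    step_seconds: float = 20.0
    min_window_seconds: float = 20.0
    n_surrogates: int = 1000
    seed: int = 0
    resample_rate: float | None = 250.0

    def __post_init__(self) -> None:
        for name in ("window_seconds", "step_seconds", "min_window_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_recording(
    path: str | Path, resample_to: float | None = None
) -> Recording:
    """Read an EDF/EDF+ file or a CSV matrix with a JSON side-car."""
    path = Path(path)
    if path.suffix.lower() in (".edf", ".bdf"):
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        rates = {info["sfreq"] for info in [raw.info]}
        rec = Recording(raw.get_data(), float(rates.pop()), list(raw.ch_names))
    elif path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, float_precision="round_trip")
        meta_path = _sidecar(path)
        if not meta_path.exists():
            raise FileNotFoundError(
                f"missing side-car {meta_path.name} (must carry the sampling rate)"
            )
        meta = json.loads(meta_path.read_text())
        if "rate" not in meta:
            raise ValueError(f"side-car {meta_path.name} lacks a 'rate' entry")
        rate = meta["rate"]
        if isinstance(rate, (list, tuple)):
            if len(set(rate)) != 1:
                raise ValueError(f"non-uniform rate declaration {rate} in side-car")
            rate = rate[0]
        labels = meta.get("labels", list(frame.columns))
        rec = Recording(frame.to_numpy().T, float(rate), list(labels))
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r}")
    if resample_to is not None and abs(rec.rate - resample_to) > 1e-9:
        from scipy.signal import resample_poly
        from fractions import Fraction

        frac = Fraction(resample_to / rec.rate).limit_denominator(1000)
        data = resample_poly(rec.samples, frac.numerator, frac.denominator, axis=-1)
        rec = Recording(data, resample_to, list(rec.labels), rec.start_offset)
    return rec


def write_recording(rec: Recording, path: str | Path, extra: dict | None = None) -> None:
    """Write a CSV matrix (header = labels) plus a JSON side-car with the rate."""
    path = Path(path)
    frame = pd.DataFrame(rec.samples.T, columns=rec.labels)
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {"rate": rec.rate, "labels": rec.labels, "start_offset": rec.start_offset}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_annotations(
    stage_path: str | Path, artifact_path: str | Path, duration: float
) -> tuple[StageAnnotation, ArtifactMask]:
    """Read stage (20-s epochs) and artifact (4-s cells) CSVs, validated."""
    stages_frame = pd.read_csv(stage_path)
    n_epochs = int(round(duration / STAGE_EPOCH_SECONDS))
    if len(stages_frame) != n_epochs:
        raise ValueError(
            f"{len(stages_frame)} stage epochs for a {duration:g}-s recording; "
            f"expected {n_epochs}"
        )
    order = stages_frame.sort_values("epoch_index")
    if not np.array_equal(order["epoch_index"].to_numpy(), np.arange(n_epochs)):
        raise ValueError("stage epoch indices must be 0..n-1 without gaps")
    stages = StageAnnotation(order["stage"].to_numpy())

    mask_frame = pd.read_csv(artifact_path)
    n_cells = int(round(duration / ARTIFACT_CELL_SECONDS))
    cells = np.zeros(n_cells, dtype=bool)
    idx = mask_frame["cell_index"].to_numpy(dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n_cells):
        raise ValueError(
            f"artifact cell index outside 0..{n_cells - 1} for duration {duration:g} s"
        )
    cells[idx] = mask_frame["is_artifact"].to_numpy(dtype=bool)
    return stages, ArtifactMask(cells)


def write_annotations(
    stages: StageAnnotation, mask: ArtifactMask, stage_path: str | Path, artifact_path: str | Path
) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(stages.epochs)), "stage": stages.epochs}
    ).to_csv(stage_path, index=False)
    pd.DataFrame(
        {
            "cell_index": np.arange(len(mask.cells)),
            "is_artifact": mask.cells.astype(int),
        }
    ).to_csv(artifact_path, index=False)


def _psd_frame(psd: EnvelopePSD) -> pd.DataFrame:
    cols = {"frequency_hz": psd.freqs}
    for bi, band in enumerate(psd.bands):
        for ci, ch in enumerate(psd.channels):
            cols[f"{band}|{ch}"] = psd.density[bi, ci]
    return pd.DataFrame(cols)


def read_envelope_psd(path: str | Path) -> EnvelopePSD:
    """Read back a TSV written by :func:`write_results` (stage in side-car)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    pairs = [c.split("|") for c in frame.columns if c != "frequency_hz"]
    bands = list(dict.fromkeys(p[0] for p in pairs))
    channels = list(dict.fromkeys(p[1] for p in pairs))
    nbins = len(frame)
    density = np.empty((len(bands), len(channels), nbins))
    for bi, band in enumerate(bands):
        for ci, ch in enumerate(channels):
            density[bi, ci] = frame[f"{band}|{ch}"].to_numpy()
    weight = np.asarray(meta.get("weight", np.ones_like(density).tolist()))
    return EnvelopePSD(
        density, bands, channels, weight, stage=meta.get("stage", "raw-average")
    )


def write_results(objects: dict[str, object], outdir: str | Path) -> list[Path]:
    """Write result objects as TSV/JSON files with deterministic layout.

    EnvelopePSD -> ``<name>.tsv`` (+ side-car with stage and weights);
    CouplingResult -> three TSVs (lags, frequencies, phase bins) and a JSON
    of p-values; RunConfig and plain dicts -> JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_frame(frame: pd.DataFrame, path: Path) -> None:
        frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        written.append(path)

    for name, obj in sorted(objects.items()):
        if isinstance(obj, EnvelopePSD):
            path = outdir / f"{name}.tsv"
            _write_frame(_psd_frame(obj), path)
            _sidecar(path).write_text(
                json.dumps({"stage": obj.stage, "weight": obj.weight.tolist()})
            )
            written.append(_sidecar(path))
        elif isinstance(obj, CouplingResult):
            _write_frame(
                pd.DataFrame(
                    {"lag_s": obj.lags, "r": obj.crosscorr, "p": obj.crosscorr_p}
                ),
                outdir / f"{name}_crosscorr.tsv",
            )
            _write_frame(
                pd.DataFrame(
                    {
                        "frequency_hz": obj.coherence_freqs,
                        "coherence": obj.coherence,
                        "p": obj.coherence_p,
                    }
                ),
                outdir / f"{name}_coherence.tsv",
            )
            _write_frame(
                pd.DataFrame(
                    {
                        "phase_bin_deg": obj.phase_bin_edges[:-1],
                        "mean_z_amplitude": obj.phase_profile,
                        "p": obj.phase_profile_p,
                    }
                ),
                outdir / f"{name}_phasebins.tsv",
            )
            path = outdir / f"{name}_pvalues.json"
            path.write_text(
                json.dumps(
                    {
                        "n_segments": obj.n_segments,
                        "adjusted": {k: v.tolist() for k, v in obj.adjusted.items()},
                    },
                    indent=2,
                )
            )
            written.append(path)
        elif isinstance(obj, RunConfig):
            path = outdir / f"{name}.json"
            obj.to_json(path)
            written.append(path)
        elif isinstance(obj, (dict, list)):
            path = outdir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, default=str))
            written.append(path)
        elif isinstance(obj, pd.DataFrame):
            _write_frame(obj, outdir / f"{name}.tsv")
        else:
            raise TypeError(f"cannot serialize result {name!r} of type {type(obj)}")
    return written
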