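"""Artifact masks (4-s cells) and sleep-stage annotations (20-s epochs).

Visual artifact scoring is conventionally done on a 4-s grid and sleep
staging on a 20-s grid; both structures are aligned to recording start
(t = 0) and use half-open intervals.  Stage vocabulary: W (wake), N1/N2/N3
(NREM stages), R (REM), A (artifact), U (unscored).  NREM pooling treats
N1, N2 and N3 as a single state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ARTIFACT_CELL_SECONDS = 4.0
STAGE_EPOCH_SECONDS = 20.0

STAGE_LABELS = frozenset({"W", "N1", "N2", "N3", "R", "A", "U"})
NREM_STAGES = frozenset({"N1", "N2", "N3"})

__all__ = [
    "ArtifactMask",
    "StageAnnotation",
    "ARTIFACT_CELL_SECONDS",
    "STAGE_EPOCH_SECONDS",
    "NREM_STAGES",
    "STAGE_LABELS",
    "valid_cells",
]


@dataclass
class ArtifactMask:
    """Boolean artifact mask on a 4-s cell grid; True marks an artifact."""

    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.ndim != 1:
            raise ValueError("artifact mask must be one-dimensional")

    @property
    def duration(self) -> float:
        return len(self.cells) * ARTIFACT_CELL_SECONDS

    def is_clean(self, start: float, stop: float) -> bool:
        """True if the half-open interval [start, stop) contains no artifact cell."""
        i0 = int(np.floor(start / ARTIFACT_CELL_SECONDS))
        i1 = int(np.ceil(stop / ARTIFACT_CELL_SECONDS))
        return not self.cells[i0:i1].any()


@dataclass
class StageAnnotation:
    """Sleep-stage labels on a 20-s epoch grid."""

    epochs: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=object)
        bad = set(self.epochs) - STAGE_LABELS
        if bad:
            raise ValueError(f"unknown stage labels {sorted(bad)}")

    @property
    def duration(self) -> float:
        return len(self.epochs) * STAGE_EPOCH_SECONDS

    def in_state(self, state: str) -> np.ndarray:
        """Boolean per-epoch membership for 'NREM', 'REM' or a literal label."""
        if state.upper() == "NREM":
            wanted = NREM_STAGES
        elif state.upper() == "REM":
            wanted = {"R"}
        else:
            wanted = {state}
        return np.array([e in wanted for e in self.epochs], dtype=bool)


def valid_cells(mask: ArtifactMask, stages: StageAnnotation, state: str) -> np.ndarray:
    """Per-4-s-cell validity: artifact-free AND in the requested vigilance state.

    The mask and staging must cover the same duration (the stage grid is 5x
    coarser).  Returns a boolean array on the 4-s grid.
    """
    n_cells = len(mask.cells)
    cells_per_epoch = int(STAGE_EPOCH_SECONDS / ARTIFACT_CELL_SECONDS)
    if len(stages.epochs) * cells_per_epoch != n_cells:
        raise ValueError(
            f"mask covers {mask.duration:g} s but staging covers "
            f"{stages.duration:g} s"
        )
    state_cells = np.repeat(stages.in_state(state), cells_per_epoch)
    return state_cells & ~mask.cells
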