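"""Reference-label gating: rectangular 2-D gates, singlet gating, index files.

Ground-truth population labels for sort-cluster ranking come from gates
on scalar features (stain intensities or pulse parameters), mirroring
the usual workflow: gate, export the event indices of each gate to a
plain-text file, feed those index lists to the cluster analysis.

Conventions: gates are half-open boxes (min ≤ value < max), indices are
0-based, index files hold one integer per line with LF endings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RectGate",
    "apply_gate",
    "singlet_gate",
    "merge_labeled_files",
    "write_index_file",
    "read_index_file",
    "labels_from_gates",
]


@dataclass(frozen=True)
class RectGate:
    """Axis-aligned rectangular gate on two scalar features."""

    x_feature: str
    y_feature: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("gate bounds must satisfy min < max on both axes")


def apply_gate(features: pd.DataFrame, gate: RectGate) -> np.ndarray:
    """Sorted 0-based indices of events inside the gate (half-open box)."""
    for f in (gate.x_feature, gate.y_feature):
        if f not in features.columns:
            raise KeyError(f"unknown feature {f!r}")
    x = features[gate.x_feature].to_numpy()
    y = features[gate.y_feature].to_numpy()
    mask = (x >= gate.x_min) & (x < gate.x_max) & (y >= gate.y_min) & (y < gate.y_max)
    return np.flatnonzero(mask)


def singlet_gate(
    width: np.ndarray, area: np.ndarray, ratio_bounds: tuple[float, float]
) -> np.ndarray:
    """Indices of singlet events by area/width ratio.

    Doublets (two particles in one trigger window) have roughly doubled
    width at similar height, depressing A/W relative to singlets — a
    band on the ratio keeps singlets.  Events with W = 0 are excluded.
    """
    lo, hi = ratio_bounds
    w = np.asarray(width, dtype=float)
    a = np.asarray(area, dtype=float)
    if w.shape != a.shape:
        raise ValueError("width and area must have the same length")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(w > 0, a / np.where(w > 0, w, 1.0), np.nan)
    mask = (w > 0) & (ratio >= lo) & (ratio <= hi)
    return np.flatnonzero(mask)


def merge_labeled_files(datasets: list[tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    """Concatenate per-label event tables into one with a ``file_id`` column.

    Original order is preserved within each source; event ids are
    re-assigned 0-based over the merged table.  This mirrors building a
    merged dataset from separately acquired reference-sorted fractions,
    where the file id carries the ground-truth label.
    """
    frames = []
    for label, df in datasets:
        f = df.copy()
        f["file_id"] = label
        frames.append(f)
    merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    merged.index.name = "event_id"
    return merged


def write_index_file(path: str | Path, indices: np.ndarray) -> None:
    """One 0-based integer per line, sorted unique, LF endings."""
    idx = np.unique(np.asarray(indices, dtype=np.int64))
    if idx.size and idx[0] < 0:
        raise ValueError("indices must be non-negative")
    Path(path).write_text("".join(f"{i}\n" for i in idx))


def read_index_file(path: str | Path, base: int = 0) -> np.ndarray:
    """Read an index file; ``base=1`` converts 1-based exports to 0-based."""
    if base not in (0, 1):
        raise ValueError("base must be 0 or 1")
    text = Path(path).read_text().split()
    idx = np.array([int(t) for t in text], dtype=np.int64) - base
    if idx.size and idx.min() < 0:
        raise ValueError("negative index after base conversion")
    return np.unique(idx)


def labels_from_gates(
    n_events: int, gate_indices: dict[str, np.ndarray], default: str = "ungated"
) -> np.ndarray:
    """Per-event label array from named index lists (later gates win)."""
    labels = np.full(n_events, default, dtype=object)
    for name, idx in gate_indices.items():
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= n_events):
            raise ValueError(f"gate {name!r} has indices outside [0, {n_events})")
        labels[idx] = name
    return labels
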