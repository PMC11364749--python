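"""Pulse features: area/height/width and the 5-coefficient Haar vector.

The sort feature space is the deepest-level Haar detail of the 80-sample
trigger window: each coefficient contrasts the summed intensity of the
first and second half of a 16-sample block, so an 80-sample pulse yields
exactly 5 coefficients per channel.  With the orthonormal (per-level
1/sqrt(2)) convention the 4-level cascade collapses to

    c_b = (sum of first 8 samples of block b − sum of last 8) / 4.

A streaming variant emits one coefficient per 16 consecutive samples at
an adjustable offset, mirroring real-time computation on a continuous
data stream; on aligned windows it reproduces the batch result exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "AHWRecord",
    "compute_ahw",
    "haar_coefficients",
    "streaming_haar",
    "HaarFeatures",
    "ahw_table",
    "coefficient_matrix",
]

BLOCK = 16  # samples per deepest-level Haar atom


@dataclass(frozen=True)
class AHWRecord:
    """Conventional per-channel pulse parameters."""

    area: float  # a.u. · samples, baseline-subtracted, clipped at 0
    height: float  # a.u., max baseline-subtracted sample
    width: int  # samples above 50% of height


def estimate_baseline(waveform: np.ndarray) -> float:
    """Median of the first and last 4 samples of the window."""
    w = np.asarray(waveform, dtype=float)
    return float(np.median(np.concatenate([w[:4], w[-4:]])))


def compute_ahw(waveform: np.ndarray, baseline_estimate: float | None = None) -> AHWRecord:
    """Area, height and width of one baseline-subtracted pulse.

    Width counts samples strictly above 50% of the height.  A flat
    (all-baseline) waveform yields (0, 0, 0).
    """
    w = np.asarray(waveform, dtype=float)
    if baseline_estimate is None:
        baseline_estimate = estimate_baseline(w)
    x = w - baseline_estimate
    height = float(x.max(initial=0.0))
    if height <= 0:
        return AHWRecord(0.0, 0.0, 0)
    area = float(np.clip(x, 0.0, None).sum())
    width = int(np.count_nonzero(x > 0.5 * height))
    return AHWRecord(area, height, width)


def haar_coefficients(waveform: np.ndarray) -> np.ndarray:
    """Deepest-level orthonormal Haar detail coefficients of one window.

    Requires the window length to be divisible by 16; an 80-sample
    window yields 5 coefficients.  Raises on any other length — no
    silent padding.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    if w.size == 0 or w.size % BLOCK != 0:
        raise ValueError(
            f"waveform length {w.size} is not a positive multiple of {BLOCK}"
        )
    blocks = w.reshape(-1, BLOCK)
    return (blocks[:, : BLOCK // 2].sum(axis=1) - blocks[:, BLOCK // 2 :].sum(axis=1)) / 4.0


def haar_approximation(waveform: np.ndarray) -> np.ndarray:
    """Deepest-level approximation branch (block means × 4); same length.

    Offered behind a switch in :class:`HaarFeatures` for instruments
    that store the approximation rather than the detail coefficients.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size == 0 or w.size % BLOCK != 0:
        raise ValueError(
            f"waveform length {w.size} is not a positive multiple of {BLOCK}"
        )
    return w.reshape(-1, BLOCK).sum(axis=1) / 4.0


def streaming_haar(sample_stream: Iterable[float], offset: int = 0) -> Iterator[float]:
    """Haar detail coefficients of a continuous sample stream.

    Emits one coefficient per 16 consecutive samples starting at
    ``offset`` (in [0, 16)).  On windows aligned with batch blocks the
    output equals :func:`haar_coefficients` of those windows.  A stream
    shorter than ``offset + 16`` yields nothing.
    """
    if not 0 <= offset < BLOCK:
        raise ValueError(f"offset must lie in [0, {BLOCK}), got {offset}")
    buf = np.empty(BLOCK)
    n_in_block = 0
    skipped = 0
    for s in sample_stream:
        if skipped < offset:
            skipped += 1
            continue
        buf[n_in_block] = s
        n_in_block += 1
        if n_in_block == BLOCK:
            yield float((buf[: BLOCK // 2].sum() - buf[BLOCK // 2 :].sum()) / 4.0)
            n_in_block = 0


class HaarFeatures:
    """Transformer from pulse waveforms to Haar coefficient vectors.

    Stateless sklearn-style transformer: ``transform`` maps an array of
    shape (n_events, n_channels, n_samples) to (n_events, n_channels,
    n_samples/16) coefficient vectors, concatenated per channel.

    Parameters
    ----------
    branch : {"detail", "approximation"}
        Which deepest-level branch to emit; both have 5 values on an
        80-sample window, detail is the default sort feature.
    flatten : bool
        If True, transform returns (n_events, n_channels × n_coeffs),
        the layout sklearn clusterers expect.
    """

    def __init__(self, branch: str = "detail", flatten: bool = False):
        self.branch = branch
        self.flatten = flatten

    def get_params(self, deep: bool = True) -> dict:
        return {"branch": self.branch, "flatten": self.flatten}

    def set_params(self, **params) -> "HaarFeatures":
        for k, v in params.items():
            if k not in ("branch", "flatten"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "HaarFeatures":
        self._validate(X)
        return self

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim not in (2, 3):
            raise ValueError("expected (n_events, n_samples) or (n_events, n_channels, n_samples)")
        if X.shape[-1] % BLOCK != 0 or X.shape[-1] == 0:
            raise ValueError(
                f"window length {X.shape[-1]} is not a positive multiple of {BLOCK}"
            )
        if self.branch not in ("detail", "approximation"):
            raise ValueError(f"unknown branch {self.branch!r}")
        return X

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        squeeze = X.ndim == 2
        if squeeze:
            X = X[:, None, :]
        n_ev, n_ch, n_s = X.shape
        blocks = X.reshape(n_ev, n_ch, n_s // BLOCK, BLOCK)
        if self.branch == "detail":
            out = (blocks[..., : BLOCK // 2].sum(-1) - blocks[..., BLOCK // 2 :].sum(-1)) / 4.0
        else:
            out = blocks.sum(-1) / 4.0
        if squeeze:
            out = out[:, 0, :]
        elif self.flatten:
            out = out.reshape(n_ev, -1)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def coefficient_matrix(events, channel: int | None = None) -> np.ndarray:
    """Haar coefficient vectors for a list of events.

    Returns (n_events, n_channels, n_coeffs), or (n_events, n_coeffs)
    for a single channel.
    """
    waves = np.stack([ev.waveforms for ev in events])
    coeffs = HaarFeatures().transform(waves)
    if channel is not None:
        return coeffs[:, channel, :]
    return coeffs


def ahw_table(events, baseline: float | None = None):
    """A/H/W per channel for a list of events as a pandas DataFrame.

    Columns are ``ch{i}-A``, ``ch{i}-H``, ``ch{i}-W`` — the naming used
    for FCS export.
    """
    import pandas as pd

    rows = []
    for ev in events:
        row = {}
        for ci, w in enumerate(ev.waveforms):
            rec = compute_ahw(w, baseline)
            row[f"ch{ci}-A"] = rec.area
            row[f"ch{ci}-H"] = rec.height
            row[f"ch{ci}-W"] = rec.width
        rows.append(row)
    return pd.DataFrame(rows)
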