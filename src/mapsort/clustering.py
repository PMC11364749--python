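"""Per-channel k-means in Haar-coefficient space and the real-time
nearest-centroid decision rule.

Each scattered-light channel gets its own k-means model (default k=6,
hardware bound 8) fitted on the 5-D wavelet coefficient vectors of all
events.  The fitted centroid coordinates are exactly what would be
transferred to the signal-processing electronics: the real-time sort
decision assigns an incoming event to the closest centroid (Euclidean
distance) independently per channel.

Assignment is an explicit argmin so the tie-break (lowest cluster index
wins) is pinned, independent of library internals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "ChannelModel",
    "MultiChannelKMeans",
    "fit_channel",
    "assign_nearest",
    "export_centroids",
    "import_centroids",
]

MAX_CLUSTERS = 8  # per-channel hardware bound


@dataclass
class ChannelModel:
    """Fitted k-means model of one channel: k centroids in 5-D space."""

    channel: int
    centroids: np.ndarray  # (k, n_coeffs)
    seed: int | None = None
    n_iter: int = 0
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2:
            raise ValueError("centroids must be a (k, n_coeffs) matrix")
        k = self.centroids.shape[0]
        if not 1 <= k <= MAX_CLUSTERS:
            raise ValueError(f"k must lie in [1, {MAX_CLUSTERS}], got {k}")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def fit_channel(
    coeffs: np.ndarray,
    k: int = 6,
    seed: int | None = None,
    *,
    channel: int = 0,
    n_init: int = 10,
) -> ChannelModel:
    """Fit k-means on one channel's coefficient vectors.

    Lloyd's algorithm with k-means++ initialisation, ``n_init`` restarts
    keeping the best inertia, tolerance 1e-6 on centroid movement, at
    most 300 iterations.  All events are included; no pre-filtering.
    """
    X = np.asarray(coeffs, dtype=float)
    if X.ndim != 2:
        raise ValueError("coeffs must be (n_events, n_coeffs)")
    if not 1 <= k <= MAX_CLUSTERS:
        raise ValueError(f"k must lie in [1, {MAX_CLUSTERS}], got {k}")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} events, got {X.shape[0]}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        tol=1e-6,
        max_iter=300,
        random_state=seed,
    ).fit(X)
    return ChannelModel(
        channel=channel,
        centroids=km.cluster_centers_,
        seed=seed,
        n_iter=int(km.n_iter_),
        inertia=float(km.inertia_),
    )


def assign_nearest(vectors: np.ndarray, model: ChannelModel) -> np.ndarray:
    """Nearest-centroid assignment, ties broken by lowest cluster index.

    Accepts a single coefficient vector or an (n, n_coeffs) batch;
    returns the cluster id(s).
    """
    V = np.asarray(vectors, dtype=float)
    single = V.ndim == 1
    if single:
        V = V[None, :]
    if not np.all(np.isfinite(V)):
        raise ValueError("coefficient vectors must be finite")
    if V.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"vector dimension {V.shape[1]} does not match centroids "
            f"({model.centroids.shape[1]})"
        )
    d2 = ((V[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    ids = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties
    return int(ids[0]) if single else ids


class MultiChannelKMeans:
    """Independent per-channel k-means over wavelet-coefficient space.

    sklearn-style estimator.  ``fit`` takes an array of shape
    (n_events, n_channels, n_coeffs) and fits one k-means per channel;
    ``predict`` returns per-channel nearest-centroid assignments of
    shape (n_events, n_channels) using the pinned tie-break rule.

    Parameters
    ----------
    k : int or sequence of int
        Clusters per channel (same for all, or one value per channel).
    random_state : int or None
        Seed; channel ``c`` uses ``random_state + c`` so channels are
        decoupled but reproducible.
    scale : bool
        Standardise coefficients per channel before clustering.  Off by
        default: the method clusters raw wavelet coefficients.

    Attributes
    ----------
    models_ : list of ChannelModel
    labels_ : (n_events, n_channels) training assignments
    """

    def __init__(self, k: int | list[int] = 6, random_state: int | None = None,
                 n_init: int = 10, scale: bool = False):
        self.k = k
        self.random_state = random_state
        self.n_init = n_init
        self.scale = scale

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k": self.k,
            "random_state": self.random_state,
            "n_init": self.n_init,
            "scale": self.scale,
        }

    def set_params(self, **params) -> "MultiChannelKMeans":
        valid = self.get_params()
        for key, v in params.items():
            if key not in valid:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, v)
        return self

    def _per_channel_k(self, n_channels: int) -> list[int]:
        if np.isscalar(self.k):
            return [int(self.k)] * n_channels
        ks = list(self.k)
        if len(ks) != n_channels:
            raise ValueError(f"k list length {len(ks)} != n_channels {n_channels}")
        return [int(x) for x in ks]

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected (n_events, n_channels, n_coeffs)")
        if not np.all(np.isfinite(X)):
            raise ValueError("coefficients must be finite")
        return X

    def fit(self, X, y=None) -> "MultiChannelKMeans":
        X = self._check_X(X)
        n_ev, n_ch, _ = X.shape
        ks = self._per_channel_k(n_ch)
        self.scale_mean_ = np.zeros((n_ch, X.shape[2]))
        self.scale_sd_ = np.ones((n_ch, X.shape[2]))
        if self.scale:
            self.scale_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_sd_ = np.where(sd > 0, sd, 1.0)
        self.models_ = []
        for ci in range(n_ch):
            Xc = (X[:, ci, :] - self.scale_mean_[ci]) / self.scale_sd_[ci]
            seed = None if self.random_state is None else int(self.random_state) + ci
            self.models_.append(
                fit_channel(Xc, ks[ci], seed, channel=ci, n_init=self.n_init)
            )
        self.labels_ = self.predict(X)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "models_"):
            raise RuntimeError("model is not fitted")
        X = self._check_X(X)
        if X.shape[1] != len(self.models_):
            raise ValueError("channel count mismatch with fitted model")
        out = np.empty((X.shape[0], X.shape[1]), dtype=np.int64)
        for ci, model in enumerate(self.models_):
            Xc = (X[:, ci, :] - self.scale_mean_[ci]) / self.scale_sd_[ci]
            out[:, ci] = assign_nearest(Xc, model)
        return out

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def export_centroids(models: list[ChannelModel], path: str | Path | None = None) -> str:
    """Serialise centroid coordinates as the electronics exchange table.

    Tab-separated text with header ``channel cluster c0..c4`` (the
    coefficient count follows the models).  Floats are written with
    ``repr`` precision so import reproduces assignments bit-identically.
    """
    keys = set()
    buf = io.StringIO()
    n_coeffs = models[0].centroids.shape[1] if models else 5
    cols = "\t".join(f"c{i}" for i in range(n_coeffs))
    buf.write(f"channel\tcluster\t{cols}\n")
    for m in models:
        for cid, row in enumerate(m.centroids):
            key = (m.channel, cid)
            if key in keys:
                raise ValueError(f"duplicate (channel, cluster) key {key}")
            keys.add(key)
            vals = "\t".join(np.format_float_positional(v, unique=True) for v in row)
            buf.write(f"{m.channel}\t{cid}\t{vals}\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def import_centroids(source: str | Path) -> list[ChannelModel]:
    """Inverse of :func:`export_centroids` (accepts a path or the text)."""
    if isinstance(source, Path) or (isinstance(source, str) and "\t" not in source):
        text = Path(source).read_text()
    else:
        text = source
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[:2] != ["channel", "cluster"]:
        raise ValueError("unrecognised centroid table header")
    rows: dict[int, dict[int, np.ndarray]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        ch, cid = int(parts[0]), int(parts[1])
        vec = np.array([float(x) for x in parts[2:]])
        if cid in rows.setdefault(ch, {}):
            raise ValueError(f"duplicate (channel, cluster) key {(ch, cid)}")
        rows[ch][cid] = vec
    models = []
    for ch in sorted(rows):
        cids = sorted(rows[ch])
        if cids != list(range(len(cids))):
            raise ValueError(f"channel {ch}: cluster ids are not contiguous from 0")
        models.append(ChannelModel(channel=ch, centroids=np.stack([rows[ch][c] for c in cids])))
    return models
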