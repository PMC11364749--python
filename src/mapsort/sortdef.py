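"""Sort-cluster definition: conjunctions, enrichment, two-ranking selection.

A *sort cluster* is a logical AND of single-channel k-means clusters
from different channels; an event belongs to it only if its
nearest-centroid assignment matches every constituent part.  Candidate
sort clusters are all cross-channel conjunctions (default order 2).

Each candidate is scored against reference population labels by the
enrichment statistic

    x(P, c) = ( N(P,c) / N(·,c) ) / ( N(P,·) / N(·,·) )

— the frequency of population P inside cluster c relative to its
frequency in the whole sample.  A pure-P cluster attains the maximum
achievable value x_max(P) = N(·,·)/N(P,·), the reciprocal prevalence.

Selection uses two rankings per population: (A) the top clusters by
enrichment, and (B) the largest clusters whose enrichment exceeds a
fixed fraction of x_max (default 0.75) — highly enriched clusters can
be tiny and thus unsorbtably dilute, so B guards yield.  The final pick
prefers large above-threshold clusters and falls back to top-enrichment
entries, deduplicated, ``top_n`` per population (default 3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ChannelModel

__all__ = [
    "SortCluster",
    "enumerate_conjunctions",
    "enrichment",
    "max_achievable_enrichment",
    "build_enrichment_table",
    "rank_and_select",
    "SelectionResult",
]


@dataclass(frozen=True)
class SortCluster:
    """A conjunction of (channel id, single-channel cluster id) pairs."""

    parts: tuple[tuple[int, int], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.parts) < 1:
            raise ValueError("a sort cluster needs at least one part")
        channels = [c for c, _ in self.parts]
        if len(set(channels)) != len(channels):
            raise ValueError("at most one part per channel")
        object.__setattr__(self, "parts", tuple(sorted(self.parts)))
        if not self.name:
            label = "&".join(f"ch{c}:{k}" for c, k in self.parts)
            object.__setattr__(self, "name", label)

    def membership(self, assignments: np.ndarray) -> np.ndarray:
        """Boolean mask of events matching every part.

        ``assignments`` is the (n_events, n_channels) per-channel
        cluster-id table.
        """
        mask = np.ones(assignments.shape[0], dtype=bool)
        for ch, cid in self.parts:
            mask &= assignments[:, ch] == cid
        return mask


def enumerate_conjunctions(
    models: list[ChannelModel], assignments: np.ndarray, order: int = 2
) -> list[tuple[SortCluster, np.ndarray]]:
    """All cross-channel conjunction clusters with their memberships.

    For every combination of ``order`` distinct channels and every
    cluster-id tuple, yields the :class:`SortCluster` and the boolean
    membership mask (intersection of the single-channel memberships).
    """
    n_ch = len(models)
    if order > n_ch:
        raise ValueError(f"order {order} exceeds number of channels {n_ch}")
    if assignments.shape[1] != n_ch:
        raise ValueError("assignment table does not match model list")
    out = []
    for chans in itertools.combinations(range(n_ch), order):
        for cids in itertools.product(*(range(models[c].k) for c in chans)):
            sc = SortCluster(tuple(zip(chans, cids)))
            out.append((sc, sc.membership(assignments)))
    return out


def enrichment(
    labels: np.ndarray, membership: np.ndarray
) -> tuple[dict[str, float], dict[str, int], int]:
    """Enrichment x(P, c) of one cluster for every population.

    Returns ``(x, n_in_cluster, cluster_size)`` where ``x[P]`` is the
    enrichment (NaN if the cluster is empty) and ``n_in_cluster[P]`` the
    count N(P, c).
    """
    labels = np.asarray(labels)
    membership = np.asarray(membership)
    if membership.dtype != bool:
        m = np.zeros(labels.shape[0], dtype=bool)
        m[membership] = True
        membership = m
    if membership.shape[0] != labels.shape[0]:
        raise ValueError("membership mask must cover all labelled events")
    n_total = labels.shape[0]
    n_c = int(membership.sum())
    pops = pd.unique(labels)
    x: dict[str, float] = {}
    counts: dict[str, int] = {}
    for p in pops:
        in_pop = labels == p
        n_p = int(in_pop.sum())
        n_pc = int((in_pop & membership).sum())
        counts[p] = n_pc
        if n_c == 0 or n_p == 0:
            x[p] = float("nan")
        else:
            x[p] = (n_pc / n_c) / (n_p / n_total)
    return x, counts, n_c


def max_achievable_enrichment(labels: np.ndarray, population: str) -> float:
    """x_max(P) = N(·,·)/N(P,·): the enrichment of a pure-P cluster."""
    labels = np.asarray(labels)
    n_p = int((labels == population).sum())
    if n_p == 0:
        raise ValueError(f"population {population!r} absent from sample")
    return labels.shape[0] / n_p


def build_enrichment_table(
    conjunctions: list[tuple[SortCluster, np.ndarray]],
    labels: np.ndarray,
    singlet_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-form enrichment table over all candidate clusters.

    One row per (cluster, population): counts N(P,c) and N(·,c), the
    enrichment x, and the cluster size as a fraction of all events
    (``size_frac``) and, when a singlet mask is given, of singlet
    events (``size_frac_singlet``).
    """
    labels = np.asarray(labels)
    n_total = labels.shape[0]
    pop_totals = {p: int((labels == p).sum()) for p in pd.unique(labels)}
    n_singlet = int(singlet_mask.sum()) if singlet_mask is not None else None
    rows = []
    for sc, mask in conjunctions:
        x, counts, n_c = enrichment(labels, mask)
        size_frac = n_c / n_total
        if singlet_mask is not None and n_singlet:
            size_singlet = int((mask & singlet_mask).sum()) / n_singlet
        else:
            size_singlet = size_frac
        for p, xv in x.items():
            rows.append(
                {
                    "cluster": sc.name,
                    "parts": sc.parts,
                    "population": p,
                    "n_pc": counts[p],
                    "n_c": n_c,
                    "n_p_total": pop_totals[p],
                    "n_total": n_total,
                    "x": xv,
                    "size_frac": size_frac,
                    "size_frac_singlet": size_singlet,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SelectionResult:
    """Selected sort clusters for one population, with provenance."""

    population: str
    selected: list[SortCluster]
    ranking_top: pd.DataFrame = field(repr=False, default=None)
    ranking_size: pd.DataFrame = field(repr=False, default=None)
    x_max: float = float("nan")
    underfilled: bool = False


def rank_and_select(
    table: pd.DataFrame,
    threshold_frac: float = 0.75,
    top_n: int = 3,
    min_size_frac: float = 0.01,
) -> dict[str, SelectionResult]:
    """Two-ranking selection of sort clusters per population.

    Ranking A: top-``top_n`` clusters by enrichment x (ties broken by
    larger size).  Ranking B: clusters with x ≥ threshold_frac × x_max,
    ordered by size descending.  The selection draws from the union,
    preferring ranking-B entries of size at least ``min_size_frac``,
    then falling back to ranking A; duplicates collapse.  If fewer than
    ``top_n`` candidates exist the result carries ``underfilled=True``.

    ``threshold_frac`` defaults to 0.75 (the fixed-cell setting; 0.67 is
    the live-cell choice).
    """
    if table.empty:
        raise ValueError("enrichment table is empty")
    valid = table[(table["n_c"] > 0) & table["x"].notna()]
    results: dict[str, SelectionResult] = {}
    for pop, sub in valid.groupby("population", sort=False):
        if "n_p_total" in sub.columns:
            x_max = float(sub["n_total"].iloc[0]) / float(sub["n_p_total"].iloc[0])
        else:  # legacy tables: recover prevalence from any informative row
            ref = sub[(sub["n_pc"] > 0) & (sub["x"] > 0)].iloc[0]
            x_max = ref["x"] * ref["n_c"] / ref["n_pc"]

        rank_a = sub.sort_values(["x", "size_frac"], ascending=[False, False])
        above = sub[sub["x"] >= threshold_frac * x_max]
        rank_b = above.sort_values(["size_frac", "x"], ascending=[False, False])

        chosen: list[tuple] = []
        for _, row in rank_b.iterrows():
            if len(chosen) >= top_n:
                break
            if row["size_frac"] >= min_size_frac and row["parts"] not in chosen:
                chosen.append(row["parts"])
        for _, row in pd.concat([rank_b, rank_a]).iterrows():
            if len(chosen) >= top_n:
                break
            if row["parts"] not in chosen:
                chosen.append(row["parts"])

        results[pop] = SelectionResult(
            population=pop,
            selected=[SortCluster(p) for p in chosen],
            ranking_top=rank_a.head(top_n).reset_index(drop=True),
            ranking_size=rank_b.reset_index(drop=True),
            x_max=x_max,
            underfilled=len(chosen) < top_n,
        )
    return results
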