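"""Novelty scores over acceleration records: NN distance, LOF, RBF kernel.

All scorers share one notion of dissimilarity: the root sum over time
indices of squared per-sample differences, which is exactly the Euclidean
distance in the flattened 3x51 vector space.  Higher score always means
"more anomalous" (more fall-like), so downstream ROC code never needs to
know which scorer produced a value.

Two details of the local outlier factor are configurable because the
field's standard formulation and a common re-statement of it differ:

* ``variant="breunig"`` (default) uses the *neighbor's* k-distance in the
  reachability distance, as in the original LOF formulation;
  ``variant="as_printed"`` uses the query's own k-distance, which collapses
  every in-neighborhood reachability distance to that single value.
* the RBF kernel ``form`` applies gamma either to the distance itself
  (default) or to its square (the common machine-learning convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .records import ADL, Record

LOF_VARIANTS = ("breunig", "as_printed")
KERNEL_FORMS = ("distance", "squared_distance")


class EmptyExemplarSetError(ValueError):
    """Raised when scoring is attempted against an empty exemplar set."""


def record_distance(a: Record, b: Record) -> float:
    """Distance between two records.

    sqrt of the summed squared per-sample (x, y, z) differences over the
    window; symmetric, zero iff the sample matrices are identical.
    """
    if a.samples.shape != b.samples.shape:
        raise ValueError(
            f"records have different shapes: {a.samples.shape} vs "
            f"{b.samples.shape}"
        )
    return float(np.linalg.norm(a.samples - b.samples))


def _stack(records: Sequence[Record]) -> np.ndarray:
    return np.stack([r.flat() for r in records])


def pairwise_distances(records: Sequence[Record]) -> np.ndarray:
    """Symmetric matrix of record distances with a zero diagonal."""
    x = _stack(records)
    d = cdist(x, x)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ExemplarSet:
    """ADL-only training exemplars for novelty scoring.

    The pairwise-distance matrix is computed lazily and cached; LOF needs
    it, plain NN scoring does not.
    """

    exemplars: list[Record]

    def __post_init__(self) -> None:
        bad = [r.label for r in self.exemplars if r.label != ADL]
        if bad:
            raise ValueError(
                f"exemplar set must be ADL-only; got labels {set(bad)}"
            )
        self._matrix: np.ndarray | None = None
        self._x: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.exemplars)

    @property
    def x(self) -> np.ndarray:
        if self._x is None:
            self._x = _stack(self.exemplars)
        return self._x

    @property
    def distance_matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = pairwise_distances(self.exemplars)
        return self._matrix

    def distances_to(self, record: Record) -> np.ndarray:
        if not self.exemplars:
            raise EmptyExemplarSetError("exemplar set is empty")
        return cdist(record.flat()[None, :], self.x)[0]

    def index_of(self, record: Record) -> int | None:
        """Position of ``record`` in the set, else None.

        Membership is by object identity or exact sample equality; at most
        one copy is reported, so scoring a record that coincides with an
        exemplar excludes exactly one zero-distance neighbor.
        """
        fallback = None
        for i, r in enumerate(self.exemplars):
            if r is record:
                return i
            if fallback is None and np.array_equal(r.samples, record.samples):
                fallback = i
        return fallback


@dataclass(frozen=True)
class LOFConfig:
    k: int = 10
    variant: str = "breunig"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.variant not in LOF_VARIANTS:
            raise ValueError(f"variant must be one of {LOF_VARIANTS}")


def nn_score(record: Record, exemplars: ExemplarSet) -> float:
    """Distance to the nearest exemplar; the NN anomaly score.

    No self-exclusion: a record that is a member of the set scores 0.
    """
    return float(np.min(exemplars.distances_to(record)))


def _neighbor_distances(record: Record, exemplars: ExemplarSet) -> np.ndarray:
    """Distances to exemplars, excluding the record itself if a member."""
    d = exemplars.distances_to(record)
    own = exemplars.index_of(record)
    if own is not None:
        d = np.delete(d, own)
    return d


def knn_distance(record: Record, exemplars: ExemplarSet, k: int) -> float:
    """Distance to the k-th nearest exemplar (self excluded if a member)."""
    d = _neighbor_distances(record, exemplars)
    if k < 1 or k > d.size:
        raise ValueError(
            f"k={k} out of range for {d.size} available neighbors"
        )
    return float(np.sort(d)[k - 1])


def _k_distances(dmat: np.ndarray, k: int) -> np.ndarray:
    """Per-row k-th smallest off-diagonal distance."""
    n = dmat.shape[0]
    out = np.empty(n)
    for i in range(n):
        others = np.delete(dmat[i], i)
        out[i] = np.sort(others)[k - 1]
    return out


def _lrd(dist_to_others: np.ndarray, kdist_others: np.ndarray,
         kdist_self: float, k: int, variant: str) -> tuple[float, np.ndarray]:
    """Local reachability density and the neighbor mask for one point.

    Neighborhood = every point within the query's k-distance (ties kept).
    A zero reachability sum (duplicate cluster) yields +inf density.
    """
    kd = np.sort(dist_to_others)[k - 1]
    mask = dist_to_others <= kd + 0.0
    if variant == "breunig":
        reach = np.maximum(kdist_others[mask], dist_to_others[mask])
    else:  # as_printed: the query's own k-distance
        reach = np.maximum(kdist_self, dist_to_others[mask])
    total = float(reach.sum())
    if total == 0.0:
        return np.inf, mask
    return float(mask.sum()) / total, mask


def lof_scores(exemplars: ExemplarSet, cfg: LOFConfig) -> np.ndarray:
    """LOF of every member of the set (leave-self-out neighborhoods)."""
    n = len(exemplars)
    if not 1 <= cfg.k < n:
        raise ValueError(f"need 1 <= k < {n}, got k={cfg.k}")
    dmat = exemplars.distance_matrix
    kdist = _k_distances(dmat, cfg.k)
    lrds = np.empty(n)
    masks = []
    for i in range(n):
        d = np.delete(dmat[i], i)
        kd_others = np.delete(kdist, i)
        lrds[i], mask = _lrd(d, kd_others, kdist[i], cfg.k, cfg.variant)
        masks.append(mask)
    out = np.empty(n)
    for i in range(n):
        if np.isinf(lrds[i]):
            out[i] = 1.0  # duplicate-cluster convention
            continue
        neighbor_lrds = np.delete(lrds, i)[masks[i]]
        out[i] = float(np.mean(neighbor_lrds)) / lrds[i]
    return out


def lof_score(record: Record, exemplars: ExemplarSet, cfg: LOFConfig) -> float:
    """Local outlier factor of one record against an ADL exemplar set.

    ~1 inside a cluster of comparable density, >1 for outliers.  If the
    record is a member of the set it is excluded from its own neighborhood.
    """
    n = len(exemplars)
    own = exemplars.index_of(record)
    n_avail = n - (1 if own is not None else 0)
    if cfg.k < 1 or cfg.k >= n or cfg.k > n_avail:
        raise ValueError(
            f"k={cfg.k} invalid for {n} exemplars "
            f"({n_avail} available neighbors)"
        )
    dmat = exemplars.distance_matrix
    kdist = _k_distances(dmat, cfg.k)
    d = _neighbor_distances(record, exemplars)
    kd_others = kdist if own is None else np.delete(kdist, own)
    lrd_c, mask = _lrd(d, kd_others, np.sort(d)[cfg.k - 1], cfg.k, cfg.variant)
    if np.isinf(lrd_c):
        return 1.0
    member_lrds = _member_lrds(exemplars, cfg)
    neighbor_lrds = (member_lrds if own is None
                     else np.delete(member_lrds, own))[mask]
    return float(np.mean(neighbor_lrds)) / lrd_c


def _member_lrds(exemplars: ExemplarSet, cfg: LOFConfig) -> np.ndarray:
    """Cached local reachability densities of the set members."""
    key = (cfg.k, cfg.variant)
    cache = getattr(exemplars, "_lrd_cache", None)
    if cache is None:
        cache = {}
        exemplars._lrd_cache = cache  # type: ignore[attr-defined]
    if key not in cache:
        n = len(exemplars)
        dmat = exemplars.distance_matrix
        kdist = _k_distances(dmat, cfg.k)
        lrds = np.empty(n)
        for i in range(n):
            d = np.delete(dmat[i], i)
            kd_others = np.delete(kdist, i)
            lrds[i], _ = _lrd(d, kd_others, kdist[i], cfg.k, cfg.variant)
        cache[key] = lrds
    return cache[key]


def rbf_kernel(a: Record, b: Record, gamma: float,
               form: str = "distance") -> float:
    """RBF similarity between two records.

    form="distance" (default) is exp(-gamma * d); form="squared_distance"
    is the usual exp(-gamma * d**2).  Both give k(A, A) = 1.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if form not in KERNEL_FORMS:
        raise ValueError(f"form must be one of {KERNEL_FORMS}")
    d = record_distance(a, b)
    return float(np.exp(-gamma * (d if form == "distance" else d * d)))


def kernel_matrix(rows: Sequence[Record], cols: Sequence[Record],
                  gamma: float, form: str = "distance") -> np.ndarray:
    """Gram matrix of the record RBF kernel (rows x cols)."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if form not in KERNEL_FORMS:
        raise ValueError(f"form must be one of {KERNEL_FORMS}")
    d = cdist(_stack(rows), _stack(cols))
    return np.exp(-gamma * (d if form == "distance" else d * d))


def median_pairwise_distance(records: Sequence[Record]) -> float:
    """Median off-diagonal record distance; the kernel length scale."""
    d = pairwise_distances(records)
    iu = np.triu_indices_from(d, k=1)
    vals = d[iu]
    if vals.size == 0:
        return 1.0
    med = float(np.median(vals))
    return med if med > 0 else 1.0
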