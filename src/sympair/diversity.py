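"""Entropy-based diversity measures and cluster-based species detection.

The "true diversity" (Hill number) of order q of an abundance distribution
p_1..p_S is

    D_q = (sum_i p_i^q) ** (1 / (1 - q)),

the effective number of equally common species: it equals S for S equally
common species, doubles when every species is split in two equal halves, and
is non-increasing in q.  At q = 1 the defining expression is a limit, the
exponential of Shannon entropy (natural log).  Orders 0, 0.5, 1 and 2 are the
ones reported by the simulator: richness, rare-weighted, Shannon-based and
common-weighted diversity.

Species are detected in genetic space (the genotype x-coordinates only) by
k-medoids (PAM, BUILD + SWAP) over a range of k, selecting the k with the
largest mean silhouette width and falling back to a single species when no
clustering is convincing.  Centroid-distance diversity — the mean Euclidean
distance of genotypes from the population centroid — is the scalar diversity
series used in the pair-age sweep analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .errors import DomainError

__all__ = [
    "AbundanceDistribution",
    "SpeciesPartition",
    "DiversityReport",
    "shannon_entropy",
    "hill_number",
    "centroid_distance",
    "pam_cluster",
    "detect_species",
    "abundances_from_labels",
    "diversity_report",
]

#: minimum mean silhouette width for accepting a multi-cluster partition.
#: A single Gaussian or uniform cloud scores ~0.35-0.45 under k-medoids, so
#: the floor sits above that; genuinely separated clusters score 0.6+.
SILHOUETTE_FLOOR = 0.5


@dataclass(frozen=True)
class AbundanceDistribution:
    """Relative species abundances p_i (nonnegative, summing to one)."""

    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        p = tuple(float(v) for v in self.proportions)
        object.__setattr__(self, "proportions", p)
        if any(v < 0.0 for v in p):
            raise DomainError("proportions must be nonnegative")
        if abs(sum(p) - 1.0) > 1e-9:
            raise DomainError(f"proportions must sum to 1, got {sum(p)!r}")

    @property
    def S(self) -> int:
        """Number of species actually present (p_i > 0)."""
        return sum(1 for v in self.proportions if v > 0.0)

    @classmethod
    def from_counts(cls, counts: Sequence[float]) -> "AbundanceDistribution":
        c = np.asarray(counts, dtype=float)
        if c.sum() <= 0:
            raise DomainError("counts must have a positive total")
        return cls(tuple(c / c.sum()))


def _proportions(dist) -> np.ndarray:
    if isinstance(dist, AbundanceDistribution):
        return np.asarray(dist.proportions)
    return np.asarray(AbundanceDistribution(tuple(dist)).proportions)


def shannon_entropy(dist, base: float = 2.0) -> float:
    """Shannon entropy -sum p_i log_base(p_i), with 0 log 0 = 0.

    With base 2, eight equally common species give 3.0 bits and sixteen give
    4.0 — an index of sampling uncertainty, not yet an effective species
    number (that is what Hill numbers are for).
    """
    if not base > 1.0:
        raise DomainError(f"log base must be > 1, got {base}")
    p = _proportions(dist)
    p = p[p > 0.0]
    return float(-(p * (np.log(p) / math.log(base))).sum())


def hill_number(dist, q: float) -> float:
    """True diversity of order q (see module docstring).

    q = 0 counts species; q = 1 is the exp-Shannon limit (also used within
    |q - 1| < 1e-9); larger q discounts rare species more strongly.
    """
    if q < 0.0:
        raise DomainError(f"order q must be >= 0, got {q}")
    p = _proportions(dist)
    p = p[p > 0.0]
    if q == 0.0:
        return float(len(p))
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p ** q).sum() ** (1.0 / (1.0 - q)))


def centroid_distance(points) -> float:
    """Mean Euclidean distance of points from their arithmetic mean."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise DomainError("centroid_distance needs a nonempty (n, d) array")
    centroid = pts.mean(axis=0)
    return float(np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean())


@dataclass(frozen=True)
class SpeciesPartition:
    """A clustering of agents into species."""

    labels: np.ndarray          # per-point cluster id, 0..k-1 (0 = largest)
    medoid_indices: tuple[int, ...]
    k: int
    silhouette: float

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


# ---------------------------------------------------------------------------
# PAM (k-medoids): BUILD then best-improvement SWAP, fully deterministic.
# Vectorized over the distance matrix so snapshot-sized populations cluster in
# milliseconds; ties always resolve to the lowest index.
# ---------------------------------------------------------------------------

def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = len(D)
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        reduction = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        reduction[medoids] = -np.inf
        c = int(np.argmax(reduction))
        medoids.append(c)
        np.minimum(d_near, D[c], out=d_near)
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], max_iter: int) -> tuple[list[int], float]:
    n = len(D)
    for _ in range(max_iter):
        M = np.asarray(medoids)
        dm = D[M]                                    # (k, n)
        order = np.argsort(dm, axis=0, kind="stable")
        nearest = order[0]                           # index into medoid list
        d1 = dm[nearest, np.arange(n)]
        d2 = dm[order[1], np.arange(n)] if len(M) > 1 else np.full(n, np.inf)
        cost = d1.sum()
        best = (0.0, None, None)
        for mi in range(len(M)):
            d_excl = np.where(nearest == mi, d2, d1)
            new_costs = np.minimum(d_excl[None, :], D).sum(axis=1)
            new_costs[M] = np.inf
            h = int(np.argmin(new_costs))
            delta = new_costs[h] - cost
            if delta < best[0] - 1e-12:
                best = (delta, mi, h)
        if best[1] is None:
            return medoids, float(cost)
        medoids[best[1]] = best[2]
    M = np.asarray(medoids)
    return medoids, float(D[M].min(axis=0).sum())


def _canonical(labels: np.ndarray, medoids: Sequence[int], points: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Relabel clusters by (size desc, medoid coordinates) so that the labels
    are invariant to the input order of the points."""
    k = len(medoids)
    counts = np.bincount(labels, minlength=k)
    keys = sorted(range(k), key=lambda c: (-counts[c],) + tuple(points[medoids[c]]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(keys):
        remap[old] = new
    return remap[labels], tuple(int(medoids[c]) for c in keys)


def pam_cluster(points, k: int, max_iter: int = 100) -> SpeciesPartition:
    """Partition points into k clusters around medoids (PAM).

    Medoids are always members of the data set; the total within-cluster
    distance is non-increasing across SWAP iterations.  Deterministic.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise DomainError("pam_cluster needs a nonempty (n, d) array")
    n_distinct = len(np.unique(pts, axis=0))
    if k < 1 or k > n_distinct:
        raise DomainError(f"k must lie in [1, {n_distinct} (distinct points)], got {k}")
    D = cdist(pts, pts)
    medoids = _pam_build(D, k)
    medoids, _ = _pam_swap(D, medoids, max_iter)
    labels = np.argmin(D[np.asarray(medoids)], axis=0)
    labels, medoids_out = _canonical(labels, medoids, pts)
    sil = float("nan")
    if 2 <= k <= len(pts) - 1:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    return SpeciesPartition(labels=labels, medoid_indices=medoids_out, k=k, silhouette=sil)


def pam_total_cost(points, partition: SpeciesPartition) -> float:
    """Total distance of every point to its cluster medoid."""
    pts = np.asarray(points, dtype=float)
    med = np.asarray(partition.medoid_indices)
    D = cdist(pts, pts[med])
    return float(D[np.arange(len(pts)), partition.labels].sum())


def _trivial_partition(points: np.ndarray) -> SpeciesPartition:
    D = cdist(points, points)
    medoid = int(np.argmin(D.sum(axis=1)))
    return SpeciesPartition(
        labels=np.zeros(len(points), dtype=int),
        medoid_indices=(medoid,),
        k=1,
        silhouette=float("nan"),
    )


def detect_species(points, kmax: int = 10, silhouette_floor: float = SILHOUETTE_FLOOR) -> SpeciesPartition:
    """Pick the best k in 2..kmax by mean silhouette width; k = 1 fallback.

    Mirrors the pamk-style procedure: PAM is run for each candidate k and the
    partition with the largest mean silhouette wins.  A single species is
    reported when the winning silhouette stays below ``silhouette_floor`` —
    one homogeneous cloud, however noisy, is one species — or when there are
    fewer than two distinct points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise DomainError("detect_species needs a nonempty (n, d) array")
    n = len(pts)
    n_distinct = len(np.unique(pts, axis=0))
    upper = min(kmax, n_distinct, n - 1)
    if n < 2 or upper < 2:
        return _trivial_partition(pts)
    best: Optional[SpeciesPartition] = None
    for k in range(2, upper + 1):
        part = pam_cluster(pts, k)
        if best is None or part.silhouette > best.silhouette + 1e-12:
            best = part
    if best is None or not best.silhouette > silhouette_floor:
        return _trivial_partition(pts)
    return best


def abundances_from_labels(labels) -> AbundanceDistribution:
    counts = np.bincount(np.asarray(labels, dtype=int))
    return AbundanceDistribution.from_counts(counts[counts > 0])


@dataclass(frozen=True)
class DiversityReport:
    """Species labels, abundances, the four Hill numbers and centroid diversity."""

    n: int
    labels: np.ndarray
    abundances: AbundanceDistribution
    d0: float
    d05: float
    d1: float
    d2: float
    centroid_distance: float
    k: int
    silhouette: float


def diversity_report(points, kmax: int = 10) -> DiversityReport:
    """Full diversity analysis of a set of genotype coordinates.

    Detects species, converts the label counts to abundances, and evaluates
    D0, D0.5, D1, D2 plus centroid-distance diversity.  An empty population
    yields a zero report; a single agent is one species.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        empty = AbundanceDistribution((1.0,))
        return DiversityReport(
            n=0, labels=np.zeros(0, dtype=int), abundances=empty,
            d0=0.0, d05=0.0, d1=0.0, d2=0.0,
            centroid_distance=0.0, k=0, silhouette=float("nan"),
        )
    part = detect_species(pts, kmax=kmax)
    dist = abundances_from_labels(part.labels)
    return DiversityReport(
        n=len(pts),
        labels=part.labels,
        abundances=dist,
        d0=hill_number(dist, 0.0),
        d05=hill_number(dist, 0.5),
        d1=hill_number(dist, 1.0),
        d2=hill_number(dist, 2.0),
        centroid_distance=centroid_distance(pts),
        k=part.k,
        silhouette=part.silhouette,
    )
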