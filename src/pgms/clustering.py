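"""Glucose-range clustering.

Two schemes are provided:

* the six *domain-knowledge* clinical ranges (hypoglycemia through
  critically diabetic) used by the personalized monitoring workflow, and
* a 1-D K-means baseline (Lloyd's algorithm with k-means++ seeding).

The clinical ranges are half-open real intervals so that every positive
glucose value belongs to exactly one cluster; the hypoglycemia range is
extended down to 0 because reference values as low as 37 mg/dl occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

CLUSTER_NAMES = (
    "Hypoglycemia",
    "No diabetic",
    "Pre-diabetic",
    "Diabetic",
    "Highly diabetic",
    "Critically diabetic",
)

# Upper edges of the first five intervals; the sixth is open-ended.
DEFAULT_BOUNDARIES = (80.0, 115.0, 150.0, 180.0, 250.0)


class DomainError(ValueError):
    pass


class UsageError(ValueError):
    pass


@dataclass(frozen=True)
class DomainClusterScheme:
    """Partition of (0, inf) into six clinical glucose ranges.

    ``boundaries`` are the five inner edges; interval j is
    ``(boundaries[j-1], boundaries[j]]`` with the conventions
    ``boundaries[-1] = 0`` and ``boundaries[5] = inf``.
    """

    boundaries: Tuple[float, ...] = DEFAULT_BOUNDARIES
    names: Tuple[str, ...] = CLUSTER_NAMES

    def __post_init__(self) -> None:
        if len(self.boundaries) + 1 != len(self.names):
            raise UsageError("need one more name than boundary")
        if any(b <= a for a, b in zip(self.boundaries, self.boundaries[1:])):
            raise UsageError("boundaries must be strictly increasing")

    @property
    def n_clusters(self) -> int:
        return len(self.names)

    def assign(self, glucose: float) -> int:
        return assign_domain_cluster(glucose, self)

    def assign_many(self, glucose: Sequence[float]) -> np.ndarray:
        values = np.asarray(glucose, dtype=float)
        if values.size and np.any(values <= 0):
            raise DomainError("glucose values must be positive")
        # searchsorted with side='left' puts a value equal to a boundary
        # into the lower interval: (0,80], (80,115], ...
        return np.searchsorted(np.asarray(self.boundaries), values, side="left")

    def interval(self, cluster_id: int) -> Tuple[float, float]:
        lo = 0.0 if cluster_id == 0 else self.boundaries[cluster_id - 1]
        hi = (
            float("inf")
            if cluster_id == len(self.boundaries)
            else self.boundaries[cluster_id]
        )
        return lo, hi

    def to_dict(self) -> dict:
        return {"boundaries": list(self.boundaries), "names": list(self.names)}


def assign_domain_cluster(
    glucose: float, scheme: DomainClusterScheme | None = None
) -> int:
    """Index of the clinical range containing ``glucose`` (mg/dl)."""
    if scheme is None:
        scheme = DomainClusterScheme()
    g = float(glucose)
    if g <= 0:
        raise DomainError(f"glucose must be positive, got {g}")
    return int(np.searchsorted(np.asarray(scheme.boundaries), g, side="left"))


@dataclass
class KMeansResult:
    k: int
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    inertia_history: List[float] = field(default_factory=list)
    seed: int = 0

    def assign(self, value: float) -> int:
        return int(np.argmin(np.abs(self.centroids - float(value))))

    def assign_many(self, values: Sequence[float]) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return np.argmin(np.abs(v[:, None] - self.centroids[None, :]), axis=1)


def _inertia(values: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(np.sum((values - centroids[labels]) ** 2))


def kmeans_1d(
    values: Sequence[float], k: int, seed: int = 0, max_iter: int = 300
) -> KMeansResult:
    """Lloyd's algorithm on 1-D glucose values with k-means++ seeding.

    Deterministic given ``seed``; iteration stops when assignments
    stabilize or after ``max_iter`` sweeps.  Inertia is recorded after
    every update step and is non-increasing.
    """
    v = np.asarray(values, dtype=float)
    if k < 1:
        raise UsageError("k must be >= 1")
    if k > np.unique(v).size:
        raise UsageError(f"k={k} exceeds the number of distinct values")
    rng = np.random.RandomState(seed)

    # k-means++ initialization
    centroids = np.empty(k)
    centroids[0] = v[rng.randint(v.size)]
    closest = (v - centroids[0]) ** 2
    for j in range(1, k):
        probs = closest / closest.sum() if closest.sum() > 0 else None
        if probs is None:
            centroids[j] = v[rng.randint(v.size)]
        else:
            centroids[j] = v[rng.choice(v.size, p=probs)]
        closest = np.minimum(closest, (v - centroids[j]) ** 2)

    labels = np.argmin(np.abs(v[:, None] - centroids[None, :]), axis=1)
    history = [_inertia(v, centroids, labels)]
    for _ in range(max_iter):
        for j in range(k):
            mask = labels == j
            if mask.any():
                centroids[j] = v[mask].mean()
        new_labels = np.argmin(np.abs(v[:, None] - centroids[None, :]), axis=1)
        history.append(_inertia(v, centroids, new_labels))
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    return KMeansResult(
        k=k,
        centroids=centroids,
        labels=labels,
        inertia=history[-1],
        inertia_history=history,
        seed=seed,
    )
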