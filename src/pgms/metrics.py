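"""Device-accuracy statistics for paired glucose readings.

Conventions
-----------
* Signed relative error of a value ``v`` against reference ``y`` is
  ``(y - v) / y * 100`` percent.  A non-invasive reading far above the
  reference therefore yields a large *negative* error (the -221 %
  extreme of the GlucoTrack-like data is only expressible this way).
* MARD (mean absolute relative difference) takes the absolute value
  before averaging, so it is always >= 0.
* RMSE is computed on the additive differences ``d = y - x`` against
  their predictions, in mg/dl.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np


class UsageError(ValueError):
    """Empty or misaligned metric inputs."""


def signed_error(y: float, v: float) -> float:
    """Signed relative error (y - v)/y * 100, in percent.

    ``y`` is the reference invasive value and must be positive; ``v`` is
    the value under assessment (measured or predicted).
    """
    y = float(y)
    if y <= 0:
        raise UsageError(f"reference glucose must be positive, got {y}")
    return (y - float(v)) / y * 100.0


def signed_errors(ref: Sequence[float], vals: Sequence[float]) -> np.ndarray:
    """Vectorized :func:`signed_error` over aligned sequences."""
    ref = np.asarray(ref, dtype=float)
    vals = np.asarray(vals, dtype=float)
    if ref.shape != vals.shape or ref.size == 0:
        raise UsageError("ref and vals must be non-empty and aligned")
    if np.any(ref <= 0):
        raise UsageError("all reference values must be positive")
    return (ref - vals) / ref * 100.0


def mard(ref: Sequence[float], vals: Sequence[float]) -> float:
    """Mean absolute relative difference in percent."""
    return float(np.mean(np.abs(signed_errors(ref, vals))))


def rmse_of_differences(d: Sequence[float], d_pred: Sequence[float]) -> float:
    """Root mean square error of predicted additive differences, mg/dl."""
    d = np.asarray(d, dtype=float)
    d_pred = np.asarray(d_pred, dtype=float)
    if d.shape != d_pred.shape or d.size == 0:
        raise UsageError("d and d_pred must be non-empty and aligned")
    return float(np.sqrt(np.mean((d - d_pred) ** 2)))


def overall_weighted_mard(clusters: Iterable[Tuple[float, float]]) -> float:
    """Pair-count-weighted average of per-cluster MARDs, in percent.

    ``clusters`` yields ``(m_j, mard_j)`` tuples.  When the clusters
    partition a dataset this equals the pooled MARD exactly.
    """
    pairs = list(clusters)
    if not pairs:
        raise UsageError("no clusters given")
    m = np.array([p[0] for p in pairs], dtype=float)
    v = np.array([p[1] for p in pairs], dtype=float)
    if np.any(m < 0):
        raise UsageError("cluster sizes must be non-negative")
    total = m.sum()
    if total <= 0:
        raise UsageError("cluster sizes sum to zero")
    return float(np.sum(m * v) / total)


def overall_weighted_rmse(clusters: Iterable[Tuple[float, float]]) -> float:
    """Pooled RMSE from per-cluster RMSEs: sqrt(sum m_j rmse_j^2 / sum m_j)."""
    pairs = list(clusters)
    if not pairs:
        raise UsageError("no clusters given")
    m = np.array([p[0] for p in pairs], dtype=float)
    v = np.array([p[1] for p in pairs], dtype=float)
    if np.any(m < 0):
        raise UsageError("cluster sizes must be non-negative")
    total = m.sum()
    if total <= 0:
        raise UsageError("cluster sizes sum to zero")
    return float(np.sqrt(np.sum(m * v**2) / total))


@dataclass
class ErrorSummary:
    """Accuracy summary of one set of values against the reference.

    Fields mirror the per-range result rows this method reports:
    minimum/maximum signed error and MARD in percent, RMSE of the
    additive differences in mg/dl, and the pair count.
    """

    mard: float
    min_error: float
    max_error: float
    rmse: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mard_pct": self.mard,
            "min_error_pct": self.min_error,
            "max_error_pct": self.max_error,
            "rmse_mgdl": self.rmse,
            "n": self.n,
        }


def summarize_errors(ref: Sequence[float], vals: Sequence[float]) -> ErrorSummary:
    """Full :class:`ErrorSummary` of ``vals`` against reference ``ref``."""
    e = signed_errors(ref, vals)
    ref = np.asarray(ref, dtype=float)
    vals = np.asarray(vals, dtype=float)
    return ErrorSummary(
        mard=float(np.mean(np.abs(e))),
        min_error=float(np.min(e)),
        max_error=float(np.max(e)),
        rmse=rmse_of_differences(ref - vals, np.zeros_like(ref)),
        n=int(ref.size),
    )


@dataclass
class ClusterSummary:
    """One cluster's row of an evaluation report.

    ``initial`` summarizes the measured values x against y; ``final``
    summarizes the corrected predictions z against y.  Both are absent
    when the cluster holds no test pairs.
    """

    cluster_id: int
    name: str
    m: int
    initial: Optional[ErrorSummary]
    final: Optional[ErrorSummary]

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "name": self.name,
            "n_pairs": self.m,
            "initial": self.initial.to_dict() if self.initial else None,
            "final": self.final.to_dict() if self.final else None,
        }
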