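"""Clarke Error Grid Analysis (CEGA).

Classifies each (reference, estimate) glucose pair into one of the five
clinical-risk zones of Clarke's 1987 grid:

* **A** — clinically accurate (within 20 % of the reference, or both
  values in the hypoglycemic range <= 70 mg/dl);
* **B** — benign deviation;
* **C** — overcorrection zone (would trigger unnecessary treatment);
* **D** — dangerous failure to detect hypo-/hyperglycemia;
* **E** — erroneous treatment (hypoglycemia confused for hyperglycemia
  or vice versa).

The boundary inequalities below are the canonical published geometry,
evaluated in the fixed order A, E, C, D, B with ties on a boundary going
to the earlier zone.  Sloped boundaries are compared in multiplied-out
form (integer coefficients), so a pair lying exactly on a boundary line
is classified exactly rather than at the mercy of float rounding of
ratios like 0.2 or 7/5.  Units are mg/dl throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

ZONES = ("A", "B", "C", "D", "E")


class DomainError(ValueError):
    """Non-positive glucose value passed to the classifier."""


def classify_zone(ref: float, pred: float) -> str:
    """Return the Clarke zone label for one (reference, estimate) pair."""
    ref = float(ref)
    pred = float(pred)
    if ref <= 0 or pred <= 0:
        raise DomainError(f"glucose values must be positive, got ({ref}, {pred})")
    # A: both hypoglycemic, or within 20 % of the reference
    if (ref <= 70 and pred <= 70) or 5.0 * abs(ref - pred) <= ref:
        return "A"
    # E: hypoglycemia read as hyperglycemia or vice versa
    if (ref >= 180 and pred <= 70) or (ref <= 70 and pred >= 180):
        return "E"
    # C: overcorrection wedges (pred >= ref + 110; 5*pred <= 7*ref - 910)
    if (70 <= ref <= 290 and pred >= ref + 110) or (
        130 <= ref <= 180 and 5.0 * pred <= 7.0 * ref - 910.0
    ):
        return "C"
    # D: failure to detect (ref <= 175/3 <=> 3*ref <= 175; pred >= 6/5*ref
    # <=> 5*pred >= 6*ref)
    if (
        (ref >= 240 and 70 <= pred <= 180)
        or (3.0 * ref <= 175.0 and 70 <= pred <= 180)
        or (3.0 * ref >= 175.0 and ref <= 70 and 5.0 * pred >= 6.0 * ref)
    ):
        return "D"
    return "B"


@dataclass
class ZoneSummary:
    """Zone occupancy counts and percentages for a set of pairs."""

    counts: Dict[str, int]
    total: int

    @property
    def percents(self) -> Dict[str, float]:
        return {z: self.counts[z] / self.total * 100.0 for z in ZONES}

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "percents": self.percents,
            "total": self.total,
        }


def zone_summary(pairs: Sequence[Tuple[float, float]]) -> ZoneSummary:
    """Tally Clarke zones over ``(ref, estimate)`` pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("zone_summary requires at least one pair")
    counts = {z: 0 for z in ZONES}
    for ref, pred in pairs:
        counts[classify_zone(ref, pred)] += 1
    return ZoneSummary(counts=counts, total=len(pairs))


def zone_summary_arrays(ref: np.ndarray, pred: np.ndarray) -> ZoneSummary:
    return zone_summary(list(zip(np.asarray(ref, float), np.asarray(pred, float))))


def plot_error_grid(ref, pred, ax=None, title: str = "Clarke error grid"):
    """Scatter ``pred`` vs ``ref`` with zone boundaries overlaid.

    Returns the matplotlib axes.  Import of matplotlib is deferred so the
    numeric API stays usable in plot-free environments.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(ref, pred, s=8, c="tab:blue", alpha=0.6, zorder=3)
    lim = 420
    ax.plot([0, lim], [0, lim], "k:", lw=0.8)
    # zone A envelope
    ax.plot([0, lim], [0, 1.2 * lim], "k-", lw=0.8)
    ax.plot([0, lim], [0, 0.8 * lim], "k-", lw=0.8)
    ax.axvline(70, color="k", lw=0.5, ls="--")
    ax.axhline(70, color="k", lw=0.5, ls="--")
    ax.axhline(180, color="k", lw=0.5, ls="--")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("reference glucose (mg/dl)")
    ax.set_ylabel("estimated glucose (mg/dl)")
    ax.set_title(title)
    return ax
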