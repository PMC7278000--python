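"""Synthetic paired invasive/non-invasive glucose datasets.

No public clinical dataset of paired (invasive reference, non-invasive
measured) readings exists for the devices this method targets; published
studies report only marginal statistics (pair counts, value ranges,
signed-error extremes, MARD).  This module generates datasets that
reproduce those marginals *exactly where they are exact* (counts,
ranges, extremes) and to within +/-1 % absolute where they are averages
(MARD), while giving the measurement error a systematic component that
is learnable from the measured value — the property every downstream
correction stage depends on.

Construction, given a :class:`DatasetSpec` and :class:`GeneratorConfig`:

1. reference values ``y`` are sampled from a mixture over the six
   clinical glucose ranges intersected with the invasive range;
2. a smooth monotone systematic map ``g(y)`` (a pchip spline through the
   knots implied by ``bias_knots``) plus relative Gaussian noise gives
   ``x = y * (1 - c*(b(y) + eps))`` with ``b(y) = 1 - g(y)/y``;
3. the single scale ``c`` is solved in closed form so the realized MARD
   hits ``target_mard`` (one corrective pass after range clipping);
4. designated records are overwritten with anchor pairs that realize the
   range endpoints and the signed-error extremes exactly.

Everything is driven by one ``numpy.random.RandomState(seed)``, so equal
spec+config+seed yields byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .clustering import DomainClusterScheme
from .data import PairedDataset
from .metrics import signed_errors


class InfeasibleSpecError(ValueError):
    """The requested marginal statistics cannot be realized."""


@dataclass
class DatasetSpec:
    """Target marginal statistics for a generated dataset.

    Signed errors follow the convention e = (y - x)/y * 100, so a
    measured value far above the reference gives a large negative error.
    """

    n_pairs: int
    invasive_min: float
    invasive_max: float
    noninvasive_min: float
    noninvasive_max: float
    target_mard: float
    signed_error_min: float
    signed_error_max: float

    def validate(self) -> None:
        if self.n_pairs < 10:
            raise InfeasibleSpecError("n_pairs must be >= 10")
        if not 0 < self.invasive_min < self.invasive_max:
            raise InfeasibleSpecError("invasive range must satisfy 0 < min < max")
        if not 0 < self.noninvasive_min < self.noninvasive_max:
            raise InfeasibleSpecError("noninvasive range must satisfy 0 < min < max")
        if not self.signed_error_min < 0 < self.signed_error_max:
            raise InfeasibleSpecError("signed-error extremes must straddle zero")
        if not 0 < self.target_mard < abs(self.signed_error_min):
            raise InfeasibleSpecError(
                "target MARD must be positive and below |signed_error_min|"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "DatasetSpec":
        return cls(**payload)


@dataclass
class GeneratorConfig:
    """Error-structure and sampling knobs for the generator.

    ``bias_knots`` are (reference glucose mg/dl, relative bias) pairs;
    the bias is interpolated through the induced measured-value knots
    ``(y, y*(1 - bias))`` so the noise-free measured value is a monotone
    function of the reference — the property that makes the additive
    error learnable from the measured value alone.  ``anchor_pairs`` of
    ``None`` means "derive the four default anchors from the spec";
    pass ``[]`` to disable anchoring.
    """

    bias_knots: List[Tuple[float, float]]
    bias_amplitude: float = 1.0
    noise_sigma: float = 0.06
    seed: int = 0
    anchor_pairs: Optional[List[Tuple[float, float]]] = None
    mixture_weights: Optional[Sequence[float]] = None
    top_cluster_tail: float = 1.0
    scheme: DomainClusterScheme = field(default_factory=DomainClusterScheme)

    def validate(self, spec: DatasetSpec) -> None:
        if self.noise_sigma < 0:
            raise InfeasibleSpecError("noise_sigma must be >= 0")
        ys = [k[0] for k in self.bias_knots]
        if len(ys) < 2 or any(b <= a for a, b in zip(ys, ys[1:])):
            raise InfeasibleSpecError("bias_knots must have increasing glucose values")
        if ys[0] > spec.invasive_min or ys[-1] < spec.invasive_max:
            raise InfeasibleSpecError("bias curve must cover the invasive range")
        for y_a, x_a in self.anchor_pairs or []:
            if not spec.invasive_min <= y_a <= spec.invasive_max:
                raise InfeasibleSpecError(
                    f"anchor reference {y_a} outside invasive range"
                )
            if not spec.noninvasive_min <= x_a <= spec.noninvasive_max:
                raise InfeasibleSpecError(
                    f"anchor measured value {x_a} outside noninvasive range"
                )


@dataclass
class GeneratorTruth:
    """The generating mechanism behind a dataset, for oracle checks."""

    curve: PchipInterpolator
    scale: float
    spec: DatasetSpec
    config: GeneratorConfig

    def systematic_difference(self, y) -> np.ndarray:
        """True systematic additive error c*(y - g(y)) at reference y."""
        y = np.asarray(y, dtype=float)
        return self.scale * (y - self.curve(y))

    def corrected(self, data: PairedDataset) -> np.ndarray:
        """Measured values corrected by the true systematic component."""
        return data.noninvasive + self.systematic_difference(data.invasive)


def _systematic_curve(config: GeneratorConfig) -> PchipInterpolator:
    ys = np.array([k[0] for k in config.bias_knots], dtype=float)
    bs = np.array([k[1] for k in config.bias_knots], dtype=float)
    gx = ys * (1.0 - config.bias_amplitude * bs)
    if np.any(np.diff(gx) <= 0):
        raise InfeasibleSpecError(
            "bias knots imply a non-monotone measured value; the additive "
            "error would not be learnable from the measured value"
        )
    if np.any(gx <= 0):
        raise InfeasibleSpecError("bias knots imply non-positive measured values")
    return PchipInterpolator(ys, gx, extrapolate=True)


def default_anchor_pairs(spec: DatasetSpec) -> List[Tuple[float, float]]:
    """Four anchors: both range corners plus both signed-error extremes.

    Range corners (inv_min, ni_min) and (inv_max, ni_max) pin all four
    range endpoints exactly; the extreme anchors are placed at the
    midpoint of the feasible reference interval for each extreme.
    """
    anchors = [
        (spec.invasive_min, spec.noninvasive_min),
        (spec.invasive_max, spec.noninvasive_max),
    ]
    for y_a, x_a in anchors:
        e = (y_a - x_a) / y_a * 100.0
        if not spec.signed_error_min <= e <= spec.signed_error_max:
            raise InfeasibleSpecError(
                f"range corner ({y_a}, {x_a}) has signed error {e:.1f}% outside "
                f"[{spec.signed_error_min}, {spec.signed_error_max}]"
            )
    for extreme in (spec.signed_error_min, spec.signed_error_max):
        f = 1.0 - extreme / 100.0  # x = f * y
        lo = max(spec.invasive_min, spec.noninvasive_min / f)
        hi = min(spec.invasive_max, spec.noninvasive_max / f)
        if lo > hi:
            raise InfeasibleSpecError(
                f"signed-error extreme {extreme}% unreachable inside both ranges"
            )
        y_a = 0.5 * (lo + hi)
        anchors.append((y_a, y_a * f))
    return anchors


def _sample_reference(
    spec: DatasetSpec, config: GeneratorConfig, rng: np.random.RandomState
) -> np.ndarray:
    scheme = config.scheme
    intervals = []
    for j in range(scheme.n_clusters):
        lo, hi = scheme.interval(j)
        lo = max(lo, spec.invasive_min)
        hi = min(hi, spec.invasive_max)
        intervals.append((lo, hi))
    if config.mixture_weights is None:
        weights = np.array([max(hi - lo, 0.0) for lo, hi in intervals])
    else:
        weights = np.asarray(config.mixture_weights, dtype=float).copy()
        if weights.size != scheme.n_clusters or np.any(weights < 0):
            raise InfeasibleSpecError("mixture_weights must be six non-negatives")
        weights[[hi <= lo for lo, hi in intervals]] = 0.0
    if weights.sum() <= 0:
        raise InfeasibleSpecError("no clinical range overlaps the invasive range")
    weights = weights / weights.sum()
    counts = rng.multinomial(spec.n_pairs, weights)
    parts = []
    top = scheme.n_clusters - 1
    for j, ((lo, hi), cnt) in enumerate(zip(intervals, counts)):
        if cnt == 0:
            continue
        if j == top and config.top_cluster_tail != 1.0:
            # skew the open-ended top range toward its lower edge
            u = rng.beta(1.0, config.top_cluster_tail, size=cnt)
        else:
            u = rng.uniform(size=cnt)
        parts.append(lo + (hi - lo) * u)
    y = np.concatenate(parts)
    return rng.permutation(y)


def generate_with_truth(
    spec: DatasetSpec, config: GeneratorConfig
) -> Tuple[PairedDataset, GeneratorTruth]:
    """Generate a dataset and return the generating mechanism with it."""
    spec.validate()
    config.validate(spec)
    anchors = (
        default_anchor_pairs(spec)
        if config.anchor_pairs is None
        else list(config.anchor_pairs)
    )
    for y_a, x_a in anchors:
        if not (
            spec.invasive_min <= y_a <= spec.invasive_max
            and spec.noninvasive_min <= x_a <= spec.noninvasive_max
        ):
            raise InfeasibleSpecError(f"anchor ({y_a}, {x_a}) outside the ranges")
    k = len(anchors)
    n = spec.n_pairs
    if k > n:
        raise InfeasibleSpecError("more anchors than records")

    rng = np.random.RandomState(config.seed)
    y = _sample_reference(spec, config, rng)
    curve = _systematic_curve(config)
    eps = rng.normal(0.0, config.noise_sigma, size=n) if config.noise_sigma else (
        np.zeros(n)
    )
    s = (1.0 - np.asarray(curve(y)) / y) + eps

    anchor_idx = (
        rng.choice(n, size=k, replace=False) if k else np.empty(0, dtype=int)
    )
    non = np.ones(n, dtype=bool)
    non[anchor_idx] = False
    anchor_e = np.array([(ya - xa) / ya for ya, xa in anchors])

    target_sum = spec.target_mard / 100.0 * n
    need = target_sum - np.abs(anchor_e).sum()
    if need < 0:
        raise InfeasibleSpecError(
            "anchor pairs alone already exceed the target MARD"
        )
    s_non_abs = np.abs(s[non]).sum()

    def realize(scale: float):
        x = y * (1.0 - scale * s)
        clip_mask = (x < spec.noninvasive_min) | (x > spec.noninvasive_max)
        return np.clip(x, spec.noninvasive_min, spec.noninvasive_max), clip_mask

    c = need / s_non_abs if s_non_abs > 0 else 1.0
    x, clipped = realize(c)
    realized_non = np.abs((y[non] - x[non]) / y[non]).sum()
    if realized_non > 0 and s_non_abs > 0 and need > 0:
        c *= need / realized_non  # one corrective pass after clipping
        x, clipped = realize(c)

    if k:
        y = y.copy()
        y[anchor_idx] = [a[0] for a in anchors]
        x[anchor_idx] = [a[1] for a in anchors]
        clipped[anchor_idx] = False

    realized_mard = float(np.mean(np.abs((y - x) / y))) * 100.0
    data = PairedDataset(
        y,
        x,
        provenance={
            "spec": spec.to_dict(),
            "seed": config.seed,
            "noise_sigma": config.noise_sigma,
            "systematic_scale": c,
            "n_clipped": int(clipped.sum()),
            "clipped_rows": np.nonzero(clipped)[0].tolist(),
            "anchor_rows": anchor_idx.tolist(),
            "realized_mard": realized_mard,
        },
    )
    return data, GeneratorTruth(curve=curve, scale=c, spec=spec, config=config)


def generate_dataset(spec: DatasetSpec, config: GeneratorConfig) -> PairedDataset:
    """Generate a paired dataset matching the spec's marginals."""
    data, _ = generate_with_truth(spec, config)
    return data


@dataclass
class ValidationReport:
    """Per-statistic pass/fail of a dataset against its spec."""

    checks: dict

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks.values())

    def to_dict(self) -> dict:
        return {"passed": self.passed, "checks": self.checks}


def validate_against_spec(
    data: PairedDataset, spec: DatasetSpec, mard_tolerance: float = 1.0
) -> ValidationReport:
    """Check realized marginals: count and ranges exact, extremes exact,
    MARD within ``mard_tolerance`` percent absolute."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    e = signed_errors(data.invasive, data.noninvasive)
    realized = {
        "count": len(data),
        "invasive_min": float(data.invasive.min()),
        "invasive_max": float(data.invasive.max()),
        "noninvasive_min": float(data.noninvasive.min()),
        "noninvasive_max": float(data.noninvasive.max()),
        "mard": float(np.mean(np.abs(e))),
        "signed_error_min": float(e.min()),
        "signed_error_max": float(e.max()),
    }
    tol = 1e-9

    def check(name, value, expect, band):
        return {
            "realized": value,
            "expected": expect,
            "passed": bool(abs(value - expect) <= band),
        }

    checks = {
        "count": check("count", realized["count"], spec.n_pairs, 0),
        "invasive_min": check("", realized["invasive_min"], spec.invasive_min, tol),
        "invasive_max": check("", realized["invasive_max"], spec.invasive_max, tol),
        "noninvasive_min": check(
            "", realized["noninvasive_min"], spec.noninvasive_min, tol
        ),
        "noninvasive_max": check(
            "", realized["noninvasive_max"], spec.noninvasive_max, tol
        ),
        "mard": check("", realized["mard"], spec.target_mard, mard_tolerance),
        "signed_error_min": check(
            "", realized["signed_error_min"], spec.signed_error_min, tol
        ),
        "signed_error_max": check(
            "", realized["signed_error_max"], spec.signed_error_max, tol
        ),
    }
    return ValidationReport(checks=checks)


# ---------------------------------------------------------------------------
# Presets emulating the two published device studies
# ---------------------------------------------------------------------------

def dataset1_spec() -> DatasetSpec:
    """Marginals of the GlucoTrack-like paired study (918 pairs)."""
    return DatasetSpec(
        n_pairs=918,
        invasive_min=65.0,
        invasive_max=492.0,
        noninvasive_min=80.0,
        noninvasive_max=352.0,
        target_mard=23.9,
        signed_error_min=-221.0,
        signed_error_max=61.0,
    )


# Systematic-map knots: strong over-reading at low glucose (large negative
# signed error), under-reading at high glucose, with the measured value
# monotone in the reference throughout.
_DATASET1_KNOTS = [
    (65.0, 1.0 - 150.0 / 65.0),
    (80.0, 1.0 - 155.0 / 80.0),
    (115.0, 1.0 - 177.0 / 115.0),
    (150.0, 1.0 - 205.0 / 150.0),
    (180.0, 1.0 - 229.0 / 180.0),
    (250.0, 1.0 - 282.0 / 250.0),
    (380.0, 1.0 - 336.0 / 380.0),
    (492.0, 1.0 - 348.0 / 492.0),
]

# Range-occupancy weights mirroring the six clinical-range populations
# reported for each study.
_DATASET1_WEIGHTS = (4, 32, 51, 42, 93, 54)
_DATASET2_WEIGHTS = (12, 26, 39, 30, 27, 9)


def dataset1_config(seed: int = 1) -> GeneratorConfig:
    return GeneratorConfig(
        bias_knots=list(_DATASET1_KNOTS),
        noise_sigma=0.06,
        seed=seed,
        mixture_weights=_DATASET1_WEIGHTS,
        top_cluster_tail=3.0,
    )


def dataset2_spec() -> DatasetSpec:
    """Marginals of the CoG-like paired study (470 pairs)."""
    return DatasetSpec(
        n_pairs=470,
        invasive_min=37.0,
        invasive_max=458.0,
        noninvasive_min=40.0,
        noninvasive_max=428.0,
        target_mard=17.4,
        signed_error_min=-131.0,
        signed_error_max=65.0,
    )


_DATASET2_KNOTS = [
    (37.0, 1.0 - 45.0 / 37.0),
    (80.0, 1.0 - 104.0 / 80.0),
    (115.0, 1.0 - 140.0 / 115.0),
    (150.0, 1.0 - 172.0 / 150.0),
    (180.0, 1.0 - 200.0 / 180.0),
    (250.0, 1.0 - 262.0 / 250.0),
    (360.0, 1.0 - 340.0 / 360.0),
    (458.0, 1.0 - 420.0 / 458.0),
]


def dataset2_config(seed: int = 1) -> GeneratorConfig:
    return GeneratorConfig(
        bias_knots=list(_DATASET2_KNOTS),
        noise_sigma=0.06,
        seed=seed,
        mixture_weights=_DATASET2_WEIGHTS,
    )


def variant_study_spec() -> DatasetSpec:
    """Smaller dataset for comparing clustering variants.

    Range-dependent bias plus gross low-glucose outliers (the documented
    failure mode of these sensors) — the regime in which stratifying by
    clinical range should pay off.
    """
    return DatasetSpec(
        n_pairs=450,
        invasive_min=60.0,
        invasive_max=400.0,
        noninvasive_min=40.0,
        noninvasive_max=430.0,
        target_mard=16.0,
        signed_error_min=-200.0,
        signed_error_max=45.0,
    )


_VARIANT_KNOTS = [
    (60.0, 1.0 - 78.0 / 60.0),
    (80.0, 1.0 - 96.0 / 80.0),
    (115.0, 1.0 - 126.0 / 115.0),
    (150.0, 1.0 - 158.0 / 150.0),
    (180.0, 1.0 - 190.0 / 180.0),
    (250.0, 1.0 - 252.0 / 250.0),
    (400.0, 1.0 - 372.0 / 400.0),
]


def variant_study_config(seed: int = 1) -> GeneratorConfig:
    spec = variant_study_spec()
    anchors = default_anchor_pairs(spec)
    # gross over-reading outliers concentrated in the 80-115 mg/dl range
    outlier_y = np.linspace(84.0, 112.0, 10)
    outlier_e = np.linspace(-190.0, -95.0, 10)  # percent
    anchors += [
        (float(ya), float(ya * (1.0 - ea / 100.0)))
        for ya, ea in zip(outlier_y, outlier_e)
    ]
    return GeneratorConfig(
        bias_knots=list(_VARIANT_KNOTS),
        noise_sigma=0.05,
        seed=seed,
        anchor_pairs=anchors,
        mixture_weights=(0.05, 0.20, 0.20, 0.20, 0.20, 0.15),
    )
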