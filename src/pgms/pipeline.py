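"""The personalized-monitoring workflow: split, per-range training with
grid search, prediction, evaluation reports, baseline variants, and the
calibration/recalibration decision logic.

Cluster-assignment conventions
------------------------------
Training and evaluation assign pairs to clinical ranges by the
*reference* value y — the range names describe the patient's true state,
and per-range result tables group by it.  Deployment-time prediction has
no reference value, so :func:`predict_pgms` routes by the measured value
x.  Both behaviors are explicit.

Grid search uses an inner validation split of each cluster's training
data by default.  Re-tuning hyperparameters against the final test split
(as the original optimization protocol effectively did) leaks test
information; pass ``search="holdout"`` with an explicit holdout to
reproduce that protocol deliberately.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import boosting, cega, metrics
from .boosting import EnsembleModel, TrainingSet, fit_adaboost_r2, predict_glucose
from .clustering import DomainClusterScheme, KMeansResult, kmeans_1d
from .data import PairedDataset
from .metrics import ClusterSummary, ErrorSummary, summarize_errors


class UsageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Hyperparameter grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperparamGrid:
    """Cartesian hyperparameter grid for the boosted error model.

    Ranges mirror the search space of the original optimization:
    depth 1-100, 10-500 estimators, learning rate 0.0001-1, the three
    loss laws, boosting seeds 1-5.
    """

    max_depth: Tuple[int, ...] = (5, 10)
    n_estimators: Tuple[int, ...] = (50, 150)
    alpha: Tuple[float, ...] = (0.008, 0.7)
    loss_kind: Tuple[str, ...] = ("linear", "exponential")
    seed: Tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if not all(
            [self.max_depth, self.n_estimators, self.alpha, self.loss_kind, self.seed]
        ):
            raise UsageError("grid sets must be non-empty")
        if not all(1 <= d <= 100 for d in self.max_depth):
            raise UsageError("max_depth values must lie in 1..100")
        if not all(10 <= t <= 500 for t in self.n_estimators):
            raise UsageError("n_estimators values must lie in 10..500")
        if not all(0.0001 <= a <= 1 for a in self.alpha):
            raise UsageError("alpha values must lie in 0.0001..1")
        if not all(1 <= s <= 5 for s in self.seed):
            raise UsageError("grid seeds must lie in 1..5")

    def configurations(self) -> List[dict]:
        return [
            {
                "max_depth": d,
                "n_estimators": t,
                "alpha": a,
                "loss_kind": l,
                "seed": s,
            }
            for d, t, a, l, s in itertools.product(
                self.max_depth, self.n_estimators, self.alpha, self.loss_kind,
                self.seed,
            )
        ]


def default_grid() -> HyperparamGrid:
    """Desk-scale default grid (see the methods note for sizing)."""
    return HyperparamGrid()


def comparison_grid() -> HyperparamGrid:
    """Compact grid used for clustering-variant comparisons."""
    return HyperparamGrid(
        max_depth=(2, 4),
        n_estimators=(30, 80),
        alpha=(0.008, 0.7),
        loss_kind=("linear",),
        seed=(1,),
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_train_test(
    data: PairedDataset, train_fraction: float = 0.7, seed: int = 0
) -> Tuple[PairedDataset, PairedDataset]:
    """Seeded uniform shuffle; train gets floor(fraction * n) pairs."""
    if not 0 < train_fraction < 1:
        raise UsageError("train_fraction must be in (0, 1)")
    n = len(data)
    if n < 2:
        raise UsageError("need at least two pairs to split")
    order = np.random.RandomState(seed).permutation(n)
    # tiny epsilon so e.g. floor(0.7 * 470) is 329, not a float-rounding 328
    n_train = int(np.floor(train_fraction * n + 1e-9))
    return data.subset(order[:n_train]), data.subset(order[n_train:])


# ---------------------------------------------------------------------------
# Cluster partitioners
# ---------------------------------------------------------------------------

class _Partitioner:
    kind = "abstract"

    @property
    def n_clusters(self) -> int:  # pragma: no cover - interface
        raise NotImplementedError

    def assign_many(self, values) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def name(self, j: int) -> str:  # pragma: no cover
        raise NotImplementedError


class DomainPartitioner(_Partitioner):
    kind = "domain"

    def __init__(self, scheme: Optional[DomainClusterScheme] = None):
        self.scheme = scheme or DomainClusterScheme()

    @property
    def n_clusters(self) -> int:
        return self.scheme.n_clusters

    def assign_many(self, values) -> np.ndarray:
        return self.scheme.assign_many(values)

    def name(self, j: int) -> str:
        return self.scheme.names[j]


class KMeansPartitioner(_Partitioner):
    kind = "kmeans"

    def __init__(self, result: KMeansResult):
        self.result = result

    @property
    def n_clusters(self) -> int:
        return self.result.k

    def assign_many(self, values) -> np.ndarray:
        return self.result.assign_many(values)

    def name(self, j: int) -> str:
        return f"kmeans-{j} (centroid {self.result.centroids[j]:.0f})"


class GlobalPartitioner(_Partitioner):
    kind = "none"

    @property
    def n_clusters(self) -> int:
        return 1

    def assign_many(self, values) -> np.ndarray:
        return np.zeros(np.asarray(values).shape[0], dtype=int)

    def name(self, j: int) -> str:
        return "all"


# ---------------------------------------------------------------------------
# Grid search and training
# ---------------------------------------------------------------------------

FALLBACK_HYPER = {
    "max_depth": 10,
    "n_estimators": 100,
    "alpha": 0.7,
    "loss_kind": "linear",
    "seed": 1,
}


def _fit(x, d, hyper: dict) -> EnsembleModel:
    return fit_adaboost_r2(TrainingSet(x, d), **hyper)


def grid_search_cluster(
    x: np.ndarray,
    d: np.ndarray,
    grid: HyperparamGrid,
    validation_fraction: float = 0.2,
    seed: int = 0,
    holdout: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tuple[dict, EnsembleModel, float]:
    """Exhaustive grid search for one cluster's error model.

    Objective: MARD of the corrected readings on the validation pairs;
    ties break on lower validation RMSE of the difference predictions,
    then on fewer estimators, then on grid order.  The winning
    configuration is refit on the cluster's full training data.
    Returns (best hyper, refit model, best validation MARD).
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    configs = grid.configurations()
    if holdout is not None:
        x_tr, d_tr = x, d
        x_val, d_val = (np.asarray(a, dtype=float) for a in holdout)
    else:
        order = np.random.RandomState(seed).permutation(x.size)
        n_val = max(1, int(round(validation_fraction * x.size)))
        if x.size - n_val < 2:
            raise UsageError("cluster too small for an inner validation split")
        val_idx, tr_idx = order[:n_val], order[n_val:]
        x_tr, d_tr = x[tr_idx], d[tr_idx]
        x_val, d_val = x[val_idx], d[val_idx]
    y_val = x_val + d_val
    best = None
    for conf in configs:
        model = _fit(x_tr, d_tr, conf)
        d_pred = boosting.predict_difference(model, x_val)
        z_val = np.clip(x_val + d_pred, *boosting.GLUCOSE_CLIP)
        score = (
            metrics.mard(y_val, z_val),
            metrics.rmse_of_differences(d_val, d_pred),
            conf["n_estimators"],
        )
        if best is None or score < best[0]:
            best = (score, conf)
    best_conf = best[1]
    return best_conf, _fit(x, d, best_conf), best[0][0]


@dataclass
class TrainedPGMS:
    """Per-cluster boosted error models plus a global fallback."""

    partitioner: _Partitioner
    models: Dict[int, EnsembleModel]
    chosen: Dict[int, dict]
    fallback: EnsembleModel
    min_cluster_size: int
    grid: HyperparamGrid
    seed: int
    train: PairedDataset
    warning: Optional[str] = None

    def model_for_cluster(self, j: int) -> EnsembleModel:
        return self.models.get(j, self.fallback)


def train_pgms(
    train: PairedDataset,
    partitioner: Optional[_Partitioner] = None,
    grid: Optional[HyperparamGrid] = None,
    seed: int = 0,
    min_cluster_size: int = 10,
    holdout: Optional[PairedDataset] = None,
) -> TrainedPGMS:
    """Partition the training pairs by reference value and fit one
    grid-searched error model per sufficiently populated cluster.

    Clusters with fewer than ``min_cluster_size`` training pairs route to
    a global fallback model fit on all pairs.  Passing ``holdout``
    switches grid search to holdout scoring (the leakage-reproduction
    protocol) instead of the inner validation split.
    """
    if len(train) == 0:
        raise UsageError("empty training data")
    partitioner = partitioner or DomainPartitioner()
    grid = grid or default_grid()
    labels = partitioner.assign_many(train.invasive)
    x, d = train.noninvasive, train.difference
    fallback = _fit(x, d, FALLBACK_HYPER)
    models: Dict[int, EnsembleModel] = {}
    chosen: Dict[int, dict] = {}
    for j in range(partitioner.n_clusters):
        mask = labels == j
        if mask.sum() < min_cluster_size:
            continue
        hold = None
        if holdout is not None:
            hmask = partitioner.assign_many(holdout.invasive) == j
            if hmask.sum() == 0:
                continue
            hold = (holdout.noninvasive[hmask], holdout.difference[hmask])
        conf, model, _ = grid_search_cluster(
            x[mask], d[mask], grid, seed=seed + j, holdout=hold
        )
        models[j] = model
        chosen[j] = conf
    return TrainedPGMS(
        partitioner=partitioner,
        models=models,
        chosen=chosen,
        fallback=fallback,
        min_cluster_size=min_cluster_size,
        grid=grid,
        seed=seed,
        train=train,
    )


def predict_pgms(model: TrainedPGMS, x) -> Union[float, np.ndarray]:
    """Deployment prediction: route each measured value x to a cluster by
    its own value and apply that cluster's corrected-reading model."""
    scalar = np.isscalar(x) or np.ndim(x) == 0
    xq = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xq <= 0):
        raise UsageError("measured glucose must be positive")
    labels = model.partitioner.assign_many(xq)
    z = np.empty_like(xq)
    for j in np.unique(labels):
        mask = labels == j
        z[mask] = predict_glucose(model.model_for_cluster(int(j)), xq[mask])
    return float(z[0]) if scalar else z


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-cluster and overall accuracy, before and after correction."""

    variant: str
    clusters: List[ClusterSummary]
    overall_initial: ErrorSummary
    overall_final: ErrorSummary
    cega_measured: cega.ZoneSummary
    cega_predicted: cega.ZoneSummary
    test_size: int
    seed: int
    chosen: Dict[int, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "seed": self.seed,
            "test_size": self.test_size,
            "clusters": [c.to_dict() for c in self.clusters],
            "overall_initial": self.overall_initial.to_dict(),
            "overall_final": self.overall_final.to_dict(),
            "cega_measured": self.cega_measured.to_dict(),
            "cega_predicted": self.cega_predicted.to_dict(),
            "chosen_hyperparameters": {
                str(k): v for k, v in self.chosen.items()
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    def cluster_table(self) -> pd.DataFrame:
        """Per-range rows: initial and final min/max error and MARD."""
        rows = []
        for c in self.clusters:
            row = {"cluster": c.name, "paired_data": c.m}
            for tag, summ in (("initial", c.initial), ("final", c.final)):
                row[f"{tag}_min_pct"] = summ.min_error if summ else np.nan
                row[f"{tag}_max_pct"] = summ.max_error if summ else np.nan
                row[f"{tag}_mard_pct"] = summ.mard if summ else np.nan
            rows.append(row)
        rows.append(
            {
                "cluster": "Total",
                "paired_data": self.test_size,
                "initial_min_pct": self.overall_initial.min_error,
                "initial_max_pct": self.overall_initial.max_error,
                "initial_mard_pct": self.overall_initial.mard,
                "final_min_pct": self.overall_final.min_error,
                "final_max_pct": self.overall_final.max_error,
                "final_mard_pct": self.overall_final.mard,
            }
        )
        return pd.DataFrame(rows)

    def zone_table(self) -> pd.DataFrame:
        """Zone counts/percents for measured and predicted values."""
        rows = []
        for z in cega.ZONES:
            rows.append(
                {
                    "zone": z,
                    "measured_n": self.cega_measured.counts[z],
                    "measured_pct": self.cega_measured.percents[z],
                    "predicted_n": self.cega_predicted.counts[z],
                    "predicted_pct": self.cega_predicted.percents[z],
                }
            )
        return pd.DataFrame(rows)


def evaluate(model: TrainedPGMS, test: PairedDataset) -> EvaluationReport:
    """Per-cluster initial (x vs y) and final (z vs y) accuracy.

    Test pairs are grouped by reference value; each group is corrected by
    its own cluster's model (the fallback where no model exists).
    Overall MARD/RMSE are the pair-count-weighted aggregates of the
    cluster rows, which for a full partition equal the pooled values.
    """
    if len(test) == 0:
        raise UsageError("empty test data")
    part = model.partitioner
    labels = part.assign_many(test.invasive)
    y, x = test.invasive, test.noninvasive
    z = np.empty_like(x)
    rows: List[ClusterSummary] = []
    for j in range(part.n_clusters):
        mask = labels == j
        m = int(mask.sum())
        if m == 0:
            rows.append(
                ClusterSummary(
                    cluster_id=j, name=part.name(j), m=0, initial=None, final=None
                )
            )
            continue
        z[mask] = predict_glucose(model.model_for_cluster(j), x[mask])
        rows.append(
            ClusterSummary(
                cluster_id=j,
                name=part.name(j),
                m=m,
                initial=summarize_errors(y[mask], x[mask]),
                final=summarize_errors(y[mask], z[mask]),
            )
        )
    populated = [c for c in rows if c.m > 0]

    def overall(tag: str) -> ErrorSummary:
        summ = [getattr(c, tag) for c in populated]
        return ErrorSummary(
            mard=metrics.overall_weighted_mard(
                [(c.m, s.mard) for c, s in zip(populated, summ)]
            ),
            min_error=min(s.min_error for s in summ),
            max_error=max(s.max_error for s in summ),
            rmse=metrics.overall_weighted_rmse(
                [(c.m, s.rmse) for c, s in zip(populated, summ)]
            ),
            n=len(test),
        )

    return EvaluationReport(
        variant=part.kind,
        clusters=rows,
        overall_initial=overall("initial"),
        overall_final=overall("final"),
        cega_measured=cega.zone_summary_arrays(y, x),
        cega_predicted=cega.zone_summary_arrays(y, z),
        test_size=len(test),
        seed=model.seed,
        chosen=model.chosen,
    )


# ---------------------------------------------------------------------------
# Variants, recalibration, personalization
# ---------------------------------------------------------------------------

def run_variant(
    data: PairedDataset,
    variant: str = "domain",
    grid: Optional[HyperparamGrid] = None,
    seed: int = 0,
    train_fraction: float = 0.7,
    k: int = 4,
    min_cluster_size: int = 10,
) -> EvaluationReport:
    """Full split/train/evaluate cycle for one clustering variant.

    ``variant`` is ``"domain"`` (six clinical ranges), ``"kmeans"``
    (K-means on the training reference values, ``k`` clusters), or
    ``"none"`` (one global model).
    """
    train, test = split_train_test(data, train_fraction, seed)
    if variant == "domain":
        part: _Partitioner = DomainPartitioner()
    elif variant == "kmeans":
        part = KMeansPartitioner(kmeans_1d(train.invasive, k=k, seed=seed))
    elif variant == "none":
        part = GlobalPartitioner()
    else:
        raise UsageError(f"unknown variant {variant!r}")
    trained = train_pgms(
        train, part, grid=grid, seed=seed, min_cluster_size=min_cluster_size
    )
    return evaluate(trained, test)


def check_recalibration(
    recent_pairs: PairedDataset, model: TrainedPGMS, threshold_mard: float = 15.0
) -> str:
    """Decide whether recent paired readings warrant recalibration.

    Computes the MARD of the corrected readings over the recent window
    and returns ``"continue"`` iff it is <= ``threshold_mard`` percent
    (ties continue).  The default threshold follows the regulatory
    +/-15 % error band.
    """
    if len(recent_pairs) < 1:
        raise UsageError("need at least one recent pair")
    labels = model.partitioner.assign_many(recent_pairs.invasive)
    z = np.empty(len(recent_pairs))
    for j in np.unique(labels):
        mask = labels == j
        z[mask] = predict_glucose(
            model.model_for_cluster(int(j)), recent_pairs.noninvasive[mask]
        )
    current = metrics.mard(recent_pairs.invasive, z)
    return "continue" if current <= threshold_mard else "recalibrate"


def personalize(
    model: TrainedPGMS,
    patient_pairs: PairedDataset,
    grid: Optional[HyperparamGrid] = None,
) -> TrainedPGMS:
    """Refit the models for the clusters a patient's readings fall in.

    The patient's pairs are appended to the population training pairs of
    their clusters and the per-cluster grid search is rerun; clusters the
    patient never visits keep their population models.  Returns the
    original model (with a warning) when no visited cluster reaches the
    minimum training size.
    """
    grid = grid or model.grid
    part = model.partitioner
    if len(patient_pairs) == 0:
        return model
    visited = np.unique(part.assign_many(patient_pairs.invasive))
    pop_labels = part.assign_many(model.train.invasive)
    pat_labels = part.assign_many(patient_pairs.invasive)
    models = dict(model.models)
    chosen = dict(model.chosen)
    refit_any = False
    for j in visited:
        pop_mask = pop_labels == j
        pat_mask = pat_labels == j
        x = np.concatenate(
            [model.train.noninvasive[pop_mask], patient_pairs.noninvasive[pat_mask]]
        )
        d = np.concatenate(
            [model.train.difference[pop_mask], patient_pairs.difference[pat_mask]]
        )
        if x.size < model.min_cluster_size:
            continue
        conf, refit, _ = grid_search_cluster(x, d, grid, seed=model.seed + int(j))
        models[int(j)] = refit
        chosen[int(j)] = conf
        refit_any = True
    return TrainedPGMS(
        partitioner=part,
        models=models,
        chosen=chosen,
        fallback=model.fallback,
        min_cluster_size=model.min_cluster_size,
        grid=grid,
        seed=model.seed,
        train=model.train,
        warning=None if refit_any else "no cluster reached the minimum size",
    )
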