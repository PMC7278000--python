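"""AdaBoost.R2 regression boosting with a learning rate, used as an
additive *error-prediction* model for non-invasive glucose readings.

The ensemble regresses the additive difference ``d = y - x`` (reference
minus measured, mg/dl) on the measured value ``x``.  A corrected reading
is then ``z = x + d_pred``.

Algorithm (Drucker's AdaBoost.R2, with a learning rate ``alpha``):

1. start from the uniform weight distribution ``D_1(i) = 1/m``;
2. each round draws a bootstrap sample of size ``m`` from ``D_t`` and
   fits the weak learner (a regression tree) on it;
3. per-example losses ``l_t(i) = |h_t(x_i) - d_i|`` are normalized by
   ``den_t = sup_i l_t(i)`` and mapped through a linear, square or
   exponential law into ``L_t(i) in [0, 1]``;
4. the average loss ``Lavg = sum_i L_t(i) D_t(i)`` gives the confidence
   ``beta_t = Lavg / (1 - Lavg)``; rounds with ``Lavg >= 0.5`` stop the
   boosting (the offending round is discarded unless it is the only one);
5. weights update multiplicatively, ``D_{t+1}(i) ∝ D_t(i) *
   beta_t**(alpha * (1 - L_t(i)))``, and are renormalized to sum to 1;
6. the final prediction is the weighted median of the per-round
   predictions under the weights ``w_t = alpha * log(1/beta_t)``.

With ``alpha = 1`` this reduces exactly to the classical AdaBoost.R2
update, which the test suite cross-checks against an independent
reference implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .tree import RegressionTree

LOSS_KINDS = ("linear", "square", "exponential")
BETA_MIN = 1e-10
BETA_MAX = 1.0 - 1e-10
GLUCOSE_CLIP = (20.0, 600.0)


class BoostingStop(Exception):
    """Raised internally when the average loss reaches 0.5."""


@dataclass
class TrainingSet:
    """Features x (measured reading) and targets d = y - x, mg/dl."""

    x: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.d = np.asarray(self.d, dtype=float).ravel()
        if self.x.size != self.d.size:
            raise ValueError("x and d must be aligned")
        if self.x.size < 2:
            raise ValueError("need at least two training examples")

    @property
    def m(self) -> int:
        return int(self.x.size)

    @property
    def y(self) -> np.ndarray:
        """Implied reference values y = x + d."""
        return self.x + self.d


@dataclass
class BoostRound:
    tree: RegressionTree
    beta: float
    avg_loss: float
    den: float


@dataclass
class EnsembleModel:
    """Trained boosted error predictor."""

    rounds: List[BoostRound]
    alpha: float
    loss_kind: str
    seed: int
    warning: Optional[str] = None
    hyper: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return len(self.rounds)

    @property
    def betas(self) -> np.ndarray:
        return np.array([r.beta for r in self.rounds])

    def round_predictions(self, x) -> np.ndarray:
        """(T, n) matrix of per-round weak predictions."""
        xq = np.atleast_1d(np.asarray(x, dtype=float))
        return np.stack([r.tree.predict(xq) for r in self.rounds])

    def to_json(self) -> str:
        payload = {
            "alpha": self.alpha,
            "loss_kind": self.loss_kind,
            "seed": self.seed,
            "warning": self.warning,
            "hyper": self.hyper,
            "rounds": [
                {
                    "beta": r.beta,
                    "avg_loss": r.avg_loss,
                    "den": r.den,
                    "tree": r.tree.to_dict(),
                }
                for r in self.rounds
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        payload = json.loads(text)
        rounds = [
            BoostRound(
                tree=RegressionTree.from_dict(r["tree"]),
                beta=r["beta"],
                avg_loss=r["avg_loss"],
                den=r["den"],
            )
            for r in payload["rounds"]
        ]
        return cls(
            rounds=rounds,
            alpha=payload["alpha"],
            loss_kind=payload["loss_kind"],
            seed=payload["seed"],
            warning=payload.get("warning"),
            hyper=payload.get("hyper", {}),
        )


def fit_weighted_tree(
    data: TrainingSet,
    weights: Optional[np.ndarray] = None,
    max_depth: int = 10,
    seed: int = 0,
) -> RegressionTree:
    """Fit the weak learner directly on weighted data.

    The boosting loop itself trains on bootstrap resamples, but the
    explicitly weighted criterion is exposed for direct use and for the
    exhaustive-split oracle tests.  ``seed`` is accepted for interface
    symmetry; the tree fit is deterministic.
    """
    del seed
    return RegressionTree(max_depth=max_depth).fit(data.x, data.d, weights)


def loss_function(raw_losses: Sequence[float], den: float, kind: str) -> np.ndarray:
    """Map raw absolute losses into [0, 1] by the chosen law.

    ``den`` is the supremum of the raw losses over the training set; a
    zero ``den`` (perfect weak model) yields all-zero losses and the
    caller handles the early stop.
    """
    if kind not in LOSS_KINDS:
        raise ValueError(f"unknown loss kind {kind!r}")
    l = np.abs(np.asarray(raw_losses, dtype=float))
    if den == 0:
        return np.zeros_like(l)
    if den < 0:
        raise ValueError("den must be non-negative")
    ratio = l / den
    if kind == "linear":
        return ratio
    if kind == "square":
        return ratio**2
    return 1.0 - np.exp(-ratio)


def average_loss(losses: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted average loss  sum_i L_t(i) D_t(i)."""
    losses = np.asarray(losses, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if losses.shape != weights.shape:
        raise ValueError("losses and weights must be aligned")
    return float(np.sum(losses * weights))


def confidence_beta(avg: float) -> float:
    """beta_t = Lavg / (1 - Lavg), clamped into (0, 1).

    Raises :class:`BoostingStop` for ``Lavg >= 0.5`` so the caller can end
    the boosting rather than propagate an exception to users.
    """
    if avg < 0:
        raise ValueError("average loss cannot be negative")
    if avg >= 0.5:
        raise BoostingStop(f"average loss {avg:.4f} >= 0.5")
    return float(min(max(avg / (1.0 - avg), BETA_MIN), BETA_MAX))


def update_weights(
    weights: np.ndarray, beta: float, losses: np.ndarray, alpha: float
) -> np.ndarray:
    """Multiplicative reweighting followed by renormalization to sum 1."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    weights = np.asarray(weights, dtype=float)
    losses = np.asarray(losses, dtype=float)
    updated = weights * beta ** (alpha * (1.0 - losses))
    return updated / updated.sum()


def weighted_median_predict(model: EnsembleModel, x) -> np.ndarray:
    """Weighted median of the round predictions at ``x``.

    Round t carries weight ``alpha * log(1/beta_t)``; the prediction is
    the smallest round prediction at which the cumulative weight (in
    sorted prediction order) reaches half the total.
    """
    if model.T < 1:
        raise ValueError("model has no rounds")
    scalar = np.isscalar(x) or np.ndim(x) == 0
    preds = model.round_predictions(x)  # (T, n)
    w = model.alpha * np.log(1.0 / model.betas)
    order = np.argsort(preds, axis=0, kind="mergesort")
    sorted_preds = np.take_along_axis(preds, order, axis=0)
    cum = np.cumsum(w[order], axis=0)
    half = 0.5 * cum[-1, :]
    idx = np.argmax(cum >= half[None, :], axis=0)
    out = sorted_preds[idx, np.arange(preds.shape[1])]
    return float(out[0]) if scalar else out


def fit_adaboost_r2(
    data: TrainingSet,
    max_depth: int = 10,
    n_estimators: int = 50,
    alpha: float = 1.0,
    loss_kind: str = "linear",
    seed: int = 0,
) -> EnsembleModel:
    """Train the boosted error-prediction ensemble.

    Weak learners are fit on bootstrap resamples drawn from the current
    weight distribution (Drucker's resampling scheme).  One master seed
    drives a single random stream; a per-round sub-seed is drawn first so
    a stochastic weak learner could be plugged in without disturbing the
    resampling stream.
    """
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    if loss_kind not in LOSS_KINDS:
        raise ValueError(f"unknown loss kind {loss_kind!r}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.RandomState(seed)
    m = data.m
    D = np.full(m, 1.0 / m)
    rounds: List[BoostRound] = []
    warning = None
    for _ in range(n_estimators):
        tree_seed = rng.randint(np.iinfo(np.int32).max)
        idx = rng.choice(m, size=m, replace=True, p=D)
        tree = RegressionTree(max_depth=max_depth).fit(data.x[idx], data.d[idx])
        del tree_seed  # deterministic weak learner
        raw = np.abs(tree.predict(data.x) - data.d)
        den = float(raw.max())
        if den == 0:
            # perfect weak model: keep it with maximal confidence and stop
            rounds.append(
                BoostRound(tree=tree, beta=BETA_MIN, avg_loss=0.0, den=0.0)
            )
            break
        L = loss_function(raw, den, loss_kind)
        avg = average_loss(L, D)
        try:
            beta = confidence_beta(avg)
        except BoostingStop:
            if not rounds:
                beta = BETA_MAX
                rounds.append(
                    BoostRound(tree=tree, beta=beta, avg_loss=avg, den=den)
                )
                warning = "first round already had average loss >= 0.5"
            break
        rounds.append(BoostRound(tree=tree, beta=beta, avg_loss=avg, den=den))
        D = update_weights(D, beta, L, alpha)
    return EnsembleModel(
        rounds=rounds,
        alpha=alpha,
        loss_kind=loss_kind,
        seed=seed,
        warning=warning,
        hyper={
            "max_depth": max_depth,
            "n_estimators": n_estimators,
            "alpha": alpha,
            "loss_kind": loss_kind,
            "seed": seed,
        },
    )


def predict_difference(model: EnsembleModel, x) -> np.ndarray:
    """Predicted additive difference d_pred at measured value(s) x."""
    return weighted_median_predict(model, x)


def predict_glucose(model: EnsembleModel, x) -> np.ndarray:
    """Corrected reading z = x + d_pred, clipped to a physiological range."""
    scalar = np.isscalar(x) or np.ndim(x) == 0
    xq = np.atleast_1d(np.asarray(x, dtype=float))
    z = xq + weighted_median_predict(model, xq)
    z = np.clip(z, *GLUCOSE_CLIP)
    return float(z[0]) if scalar else z
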