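"""Neural-network summaries of cSFS vectors plus rejection ABC on the
network outputs: model choice, Bayes factors, goodness of fit, and
parameter estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from demosmc.demography import PriorBox
from demosmc.nn import MLP, TrainingLog

__all__ = [
    "NetSpec",
    "ReferenceTable",
    "TrainedPredictor",
    "ModelPosterior",
    "ParamPosterior",
    "train_network",
    "abc_model_choice",
    "bayes_factor",
    "goodness_of_fit",
    "abc_parameters",
]

DEFAULT_TOLERANCE = 0.05


@dataclass(frozen=True)
class NetSpec:
    """Architecture and training schedule of the summarizing network.

    Defaults follow the published setup: hidden widths 256/128/64/32 with
    ReLU, 1% inter-layer dropout, input Gaussian noise (sd 0.05) followed
    by rectification, Adam (classification) or Nadam (regression) at
    initial learning rate 1e-3 halved on a 10-epoch validation plateau,
    early stop after 100 flat epochs, best-checkpoint retention, batch
    size 32, per-epoch shuffling.  ``max_epochs`` bounds desk runs.
    """

    hidden: Tuple[int, ...] = (256, 128, 64, 32)
    dropout: float = 0.01
    noise_sd: float = 0.05
    learning_rate: float = 1e-3
    lr_patience: int = 10
    early_stop_patience: int = 100
    batch_size: int = 32
    max_epochs: int = 1000


@dataclass
class ReferenceTable:
    """cSFS feature rows with either model labels or parameter vectors.

    ``labels`` is an integer model index per row (classification) or a
    (rows × n_params) array in original units (regression, scaled to
    [0, 1] by ``prior_box`` before training).  ``n_train`` rows train,
    the rest validate.
    """

    features: np.ndarray
    labels: np.ndarray
    n_train: int
    model_ids: Optional[Tuple[str, ...]] = None
    prior_box: Optional[PriorBox] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features/labels row mismatch")
        if not 0 < self.n_train < self.features.shape[0]:
            raise ValueError("n_train must leave a nonempty validation set")

    @property
    def kind(self) -> str:
        return "classification" if self.labels.ndim == 1 else "regression"

    def train_split(self):
        return self.features[: self.n_train], self.labels[: self.n_train]

    def validation_split(self):
        return self.features[self.n_train:], self.labels[self.n_train:]


@dataclass
class TrainedPredictor:
    """A trained network plus everything needed to interpret its output."""

    net: MLP
    kind: str
    log: TrainingLog
    model_ids: Optional[Tuple[str, ...]] = None
    prior_box: Optional[PriorBox] = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.net.predict(features)

    def predict_parameters(self, features: np.ndarray) -> np.ndarray:
        """Regression output mapped back to original parameter units."""
        if self.kind != "regression" or self.prior_box is None:
            raise ValueError("not a regression predictor with a prior box")
        out = self.net.predict(features)
        return np.vstack([self.prior_box.unscale(row) for row in out])


@dataclass
class ModelPosterior:
    """ABC posterior over model identities."""

    model_ids: Tuple[str, ...]
    probabilities: np.ndarray
    n_accepted: int
    tolerance: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be a simplex")
        self.probabilities = p

    def probability(self, model_id: str) -> float:
        return float(self.probabilities[self.model_ids.index(model_id)])

    def best_model(self) -> str:
        return self.model_ids[int(np.argmax(self.probabilities))]


@dataclass
class ParamPosterior:
    """ABC posterior sample over parameters (original units)."""

    names: Tuple[str, ...]
    accepted: np.ndarray           # (draws × params), pooled over replicates
    point_estimate: np.ndarray     # median-of-medians across replicates
    interval_low: np.ndarray       # 2.5th percentile
    interval_high: np.ndarray      # 97.5th percentile
    tolerance: float

    def __post_init__(self) -> None:
        if not (np.all(self.interval_low <= self.point_estimate + 1e-9)
                and np.all(self.point_estimate <= self.interval_high + 1e-9)):
            raise ValueError("credible interval must contain the point estimate")

    def summary(self) -> Dict[str, Tuple[float, float, float]]:
        return {
            n: (float(self.point_estimate[i]),
                float(self.interval_low[i]),
                float(self.interval_high[i]))
            for i, n in enumerate(self.names)
        }


def train_network(table: ReferenceTable, spec: NetSpec, seed: int) -> TrainedPredictor:
    """Train a classifier (5-way softmax / cross-entropy / Adam) or
    regressor (linear head / log-cosh / Nadam, labels scaled to [0, 1] by
    the prior box) on the reference table."""
    x_train, y_train = table.train_split()
    x_val, y_val = table.validation_split()
    if not np.isfinite(table.features).all():
        raise ValueError("non-finite features in reference table")
    if table.kind == "classification":
        if table.model_ids is None:
            raise ValueError("classification table needs model_ids")
        n_out = len(table.model_ids)
        onehot = np.eye(n_out)
        y_train_m = onehot[y_train.astype(int)]
        y_val_m = onehot[y_val.astype(int)]
        head, optimizer = "softmax", "adam"
    else:
        if table.prior_box is None:
            raise ValueError("regression table needs a prior_box")
        n_out = table.labels.shape[1]
        y_train_m = np.vstack([table.prior_box.scale(r) for r in y_train])
        y_val_m = np.vstack([table.prior_box.scale(r) for r in y_val])
        head, optimizer = "linear", "nadam"
    net = MLP(
        n_in=table.features.shape[1],
        n_out=n_out,
        head=head,
        hidden=spec.hidden,
        dropout=spec.dropout,
        noise_sd=spec.noise_sd,
        seed=seed,
    )
    log = net.fit(
        x_train, y_train_m, x_val, y_val_m,
        optimizer=optimizer,
        learning_rate=spec.learning_rate,
        batch_size=spec.batch_size,
        max_epochs=spec.max_epochs,
        lr_patience=spec.lr_patience,
        early_stop_patience=spec.early_stop_patience,
    )
    return TrainedPredictor(
        net=net, kind=table.kind, log=log,
        model_ids=table.model_ids, prior_box=table.prior_box,
    )


def _accepted_indices(
    reference: np.ndarray, observed: np.ndarray, tolerance: float
) -> np.ndarray:
    """Indices of the tolerance-fraction of reference rows nearest
    (Euclidean) to the observed row."""
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    d = np.linalg.norm(reference - observed[None, :], axis=1)
    n_keep = max(1, int(round(tolerance * reference.shape[0])))
    return np.argsort(d, kind="stable")[:n_keep]


def abc_model_choice(
    predictions: np.ndarray,
    labels: np.ndarray,
    observed: np.ndarray,
    model_ids: Sequence[str],
    tolerance: float = DEFAULT_TOLERANCE,
) -> ModelPosterior:
    """Rejection ABC in network-output space.

    Keeps the tolerance-fraction of validation predictions nearest each
    observed prediction; posterior probabilities are label frequencies
    among kept rows, averaged over observed replicates.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=int)
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    n_models = len(model_ids)
    probs = np.zeros(n_models)
    total_accepted = 0
    for obs in observed:
        idx = _accepted_indices(predictions, obs, tolerance)
        if idx.size == 0:
            raise ValueError("no accepted rows at this tolerance")
        if idx.size < 10:
            import warnings

            warnings.warn(f"only {idx.size} accepted rows", stacklevel=2)
        freq = np.bincount(labels[idx], minlength=n_models) / idx.size
        probs += freq
        total_accepted += idx.size
    probs /= observed.shape[0]
    return ModelPosterior(
        model_ids=tuple(model_ids),
        probabilities=probs,
        n_accepted=total_accepted,
        tolerance=tolerance,
    )


def bayes_factor(post: ModelPosterior, m1: str, m2: str) -> float:
    """P(m1)/P(m2) under equal model priors (inf when P(m2)=0)."""
    p1, p2 = post.probability(m1), post.probability(m2)
    if p2 == 0:
        import warnings

        warnings.warn(f"P({m2}) = 0; Bayes factor reported as inf", stacklevel=2)
        return float("inf")
    return p1 / p2


def _gfit_statistic(
    point: np.ndarray, reference: np.ndarray, n_neighbors: int
) -> float:
    d = np.linalg.norm(reference - point[None, :], axis=1)
    k = min(n_neighbors, d.size)
    return float(np.sort(d)[:k].mean())


def goodness_of_fit(
    reference_predictions: np.ndarray,
    null_predictions: np.ndarray,
    observed: np.ndarray,
    n_neighbors: int = 10,
) -> float:
    """Nearest-neighbor-distance goodness-of-fit p-value.

    The statistic is the mean distance to the ``n_neighbors`` nearest
    reference predictions; the null distribution evaluates it on
    held-out rows simulated under the fitted model.  ``p`` is the
    fraction of null statistics ≥ the observed statistic.
    """
    reference_predictions = np.asarray(reference_predictions, dtype=float)
    null_predictions = np.atleast_2d(np.asarray(null_predictions, dtype=float))
    if null_predictions.shape[0] < 100:
        import warnings

        warnings.warn(
            f"only {null_predictions.shape[0]} null rows; p-value is coarse",
            stacklevel=2,
        )
    obs_stat = _gfit_statistic(
        np.asarray(observed, dtype=float), reference_predictions, n_neighbors
    )
    null_stats = np.array([
        _gfit_statistic(row, reference_predictions, n_neighbors)
        for row in null_predictions
    ])
    return float((null_stats >= obs_stat).mean())


def abc_parameters(
    predictions: np.ndarray,
    true_parameters: np.ndarray,
    observed: np.ndarray,
    names: Sequence[str],
    tolerance: float = DEFAULT_TOLERANCE,
    prior_box: Optional[PriorBox] = None,
) -> ParamPosterior:
    """Rejection ABC for parameters.

    Accepted rows' *true* generating parameters form the posterior
    sample.  With several observed replicates the per-replicate medians
    are combined by a final median; the credible interval is the 2.5–97.5
    percentile range of the pooled accepted draws.
    """
    predictions = np.asarray(predictions, dtype=float)
    true_parameters = np.asarray(true_parameters, dtype=float)
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    medians = []
    pooled = []
    for obs in observed:
        idx = _accepted_indices(predictions, obs, tolerance)
        if idx.size < 10:
            import warnings

            warnings.warn(f"only {idx.size} accepted rows", stacklevel=2)
        draws = true_parameters[idx]
        pooled.append(draws)
        medians.append(np.median(draws, axis=0))
    pooled_arr = np.vstack(pooled)
    point = np.median(np.vstack(medians), axis=0)
    lo = np.percentile(pooled_arr, 2.5, axis=0)
    hi = np.percentile(pooled_arr, 97.5, axis=0)
    # the cross-replicate median can sit marginally outside the pooled
    # percentile band in tiny-acceptance regimes; widen to contain it
    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    if prior_box is not None and not prior_box.contains(point):
        raise ValueError("posterior point estimate escaped the prior box")
    return ParamPosterior(
        names=tuple(names),
        accepted=pooled_arr,
        point_estimate=point,
        interval_low=lo,
        interval_high=hi,
        tolerance=tolerance,
    )
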