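"""Neural-network clustering: competitive learning plus the threshold neuron.

Two models live here.  `ThresholdNeuron` is the classical binary unit whose
activation is 1 when the weighted input sum exceeds a threshold and 0
otherwise — the textbook building block of artificial neural networks, kept
as a separately tested reference model.  The clustering itself is
`CompetitiveLearningClusterer`: seeded winner-take-all competitive learning
(a one-dimensional Kohonen network without a neighborhood function), the
canonical unsupervised "neural network clustering".  Binary threshold units
cannot represent distance-based cluster membership directly, which is why
the two models are separate.

Training standardizes every feature to zero mean and unit standard
deviation first — assay descriptors span orders of magnitude (catalase
activity ~140 u/mg vs. lipid-peroxidation MDA ~1 nmol/mg), so unscaled
Euclidean distance would be dominated by a single descriptor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .table import feature_columns, feature_matrix

__all__ = [
    "ThresholdNeuron",
    "neuron_output",
    "CompetitiveLearningClusterer",
    "train_nnc",
    "assign",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ThresholdNeuron:
    """A binary neuron: output 1 iff w . x > threshold."""

    weights: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=np.float64))

    def output(self, x) -> int:
        return neuron_output(self, x)


def neuron_output(neuron: ThresholdNeuron, x) -> int:
    """Activation of the threshold neuron: 1 iff net = w . x exceeds the threshold.

    The boundary case net == threshold yields 0 (strict inequality).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != neuron.weights.shape:
        raise ValueError(
            f"input dimension {x.shape} does not match weights {neuron.weights.shape}"
        )
    net = float(neuron.weights @ x)
    return 1 if net > neuron.threshold else 0


class CompetitiveLearningClusterer(ClusterMixin, BaseEstimator):
    """Winner-take-all competitive-learning clustering.

    ``fit`` standardizes the features, initializes one unit per cluster at a
    randomly chosen (distinct) training sample, then for each epoch visits
    the samples in a fresh seeded random order and moves the nearest unit
    toward each sample by a linearly decaying learning rate
    ``eta(t) = eta_0 * (1 - t / epochs)``.  Ties in the distance go to the
    lowest unit index.  Given the same data and ``random_state`` the
    trained model is bit-reproducible.

    Parameters
    ----------
    n_clusters : int, default 2
        Number of competitive units.
    epochs : int, default 100
        Full passes over the training samples.
    learning_rate : float, default 0.5
        Initial learning rate ``eta_0``.
    random_state : int or None
        Seed for unit initialization and sample-visit order.

    Attributes
    ----------
    unit_weights_ : ndarray (n_clusters, n_features)
        Trained unit weight vectors in standardized feature space.
    scale_mean_, scale_std_ : ndarray (n_features,)
        Per-feature standardization; zero-spread features get std 1 and are
        excluded from distances (with a warning).
    labels_ : ndarray (n_samples,)
        Cluster index of each training sample under the final units.
    distances_ : ndarray (n_samples,)
        Euclidean distance of each training sample to its winning unit.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        epochs: int = 100,
        learning_rate: float = 0.5,
        random_state: int | None = None,
    ) -> None:
        self.n_clusters = n_clusters
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- internal helpers -------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.scale_mean_) / self.scale_std_
        return Z[:, self.active_mask_]

    @staticmethod
    def _nearest(units: np.ndarray, z: np.ndarray) -> tuple[int, float]:
        d2 = ((units - z) ** 2).sum(axis=1)
        j = int(np.argmin(d2))  # argmin takes the lowest index on ties
        return j, float(np.sqrt(d2[j]))

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y=None) -> "CompetitiveLearningClusterer":
        X = validate_data(self, X, ensure_min_samples=1)
        n, _ = X.shape
        if self.n_clusters > n:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the {n} available samples"
            )
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be at least 1")

        self.scale_mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.active_mask_ = std > 0
        if not self.active_mask_.all():
            dead = int((~self.active_mask_).sum())
            warnings.warn(
                f"{dead} zero-spread feature(s) excluded from clustering distances",
                UserWarning,
                stacklevel=2,
            )
        if not self.active_mask_.any():
            raise ValueError("all features have zero spread; nothing to cluster on")
        self.scale_std_ = np.where(self.active_mask_, std, 1.0)

        Z = self._standardize(X)
        rng = np.random.default_rng(self.random_state)

        # units start at distinct randomly chosen samples; prefer rows with
        # pairwise-distinct coordinates so units do not collapse at birth
        perm = rng.permutation(n)
        chosen: list[int] = []
        seen: set[bytes] = set()
        for idx in perm:
            key = Z[idx].tobytes()
            if key not in seen:
                chosen.append(int(idx))
                seen.add(key)
            if len(chosen) == self.n_clusters:
                break
        while len(chosen) < self.n_clusters:  # duplicates unavoidable
            chosen.append(int(perm[len(chosen) - 1]))
        units = Z[chosen].copy()

        for t in range(self.epochs):
            eta = self.learning_rate * (1.0 - t / self.epochs)
            for i in rng.permutation(n):
                j, _ = self._nearest(units, Z[i])
                units[j] += eta * (Z[i] - units[j])

        self.unit_weights_ = units
        labels = np.empty(n, dtype=np.int64)
        dists = np.empty(n, dtype=np.float64)
        for i in range(n):
            labels[i], dists[i] = self._nearest(units, Z[i])
        self.labels_ = labels
        self.distances_ = dists
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        Z = self._standardize(X)
        return np.array([self._nearest(self.unit_weights_, z)[0] for z in Z])

    def transform(self, X) -> np.ndarray:
        """Distance of each sample to every unit (standardized space)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        Z = self._standardize(X)
        return np.sqrt(((Z[:, None, :] - self.unit_weights_[None]) ** 2).sum(axis=2))


def train_nnc(
    table: pd.DataFrame,
    n_clusters: int = 2,
    seed: int | None = 0,
    epochs: int = 100,
    learning_rate: float = 0.5,
) -> tuple[CompetitiveLearningClusterer, pd.DataFrame]:
    """Cluster a feature table; returns the model and the assignment.

    The assignment is a DataFrame with columns ``sample_id``, ``group``,
    ``cluster`` and ``distance`` (to the winning unit).
    """
    model = CompetitiveLearningClusterer(
        n_clusters=n_clusters,
        epochs=epochs,
        learning_rate=learning_rate,
        random_state=seed,
    )
    X = table[feature_columns(table)]
    feature_matrix(table)  # finiteness check with the table's own error text
    model.fit(X)
    assignment = pd.DataFrame(
        {
            "sample_id": table["sample_id"].to_numpy(),
            "group": table["group"].to_numpy(),
            "cluster": model.labels_,
            "distance": model.distances_,
        }
    )
    return model, assignment


def assign(model: CompetitiveLearningClusterer, table: pd.DataFrame) -> pd.DataFrame:
    """Assign new samples to the trained units using the stored scaling."""
    check_is_fitted(model)
    feats = feature_columns(table)
    expected = list(getattr(model, "feature_names_in_", []))
    if expected and feats != expected:
        raise ValueError(
            f"feature mismatch: model was trained on {expected}, table has {feats}"
        )
    X = table[feats]
    labels = model.predict(X)
    dists = model.transform(X).min(axis=1)
    return pd.DataFrame(
        {
            "sample_id": table["sample_id"].to_numpy(),
            "group": table["group"].to_numpy(),
            "cluster": labels,
            "distance": dists,
        }
    )


def save_model(model: CompetitiveLearningClusterer, path: str | Path) -> None:
    """Serialize a fitted model (units, scaling, config) as JSON."""
    check_is_fitted(model)
    payload = {
        "params": model.get_params(),
        "unit_weights": model.unit_weights_.tolist(),
        "scale_mean": model.scale_mean_.tolist(),
        "scale_std": model.scale_std_.tolist(),
        "active_mask": model.active_mask_.astype(int).tolist(),
        "feature_names": list(getattr(model, "feature_names_in_", [])),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> CompetitiveLearningClusterer:
    payload = json.loads(Path(path).read_text())
    model = CompetitiveLearningClusterer(**payload["params"])
    model.unit_weights_ = np.asarray(payload["unit_weights"], dtype=np.float64)
    model.scale_mean_ = np.asarray(payload["scale_mean"], dtype=np.float64)
    model.scale_std_ = np.asarray(payload["scale_std"], dtype=np.float64)
    model.active_mask_ = np.asarray(payload["active_mask"], dtype=bool)
    model.n_features_in_ = model.scale_mean_.shape[0]
    if payload["feature_names"]:
        model.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
    return model
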