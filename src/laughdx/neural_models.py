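"""From-scratch MLP and hybrid RBF network classifiers.

All networks use hyperbolic-tangent units throughout and are trained by
batch ("static") backpropagation with a momentum term and per-layer step
sizes:

    dw(t) = -eta_layer * dMSE/dw + mu * dw(t-1)

The three perceptrons (ANN p=40, EANN p=5, 5PANN p=6) share the 16- and
9-unit hidden layers with step sizes 1.0 / 0.1 / 0.01 and momentum 0.7,
trained for at most 10,000 epochs with MSE as the stop criterion.  The
hybrid RBFN puts an unsupervised Gaussian prototype layer (8 k-means
centers, Euclidean distance, 100 unsupervised epochs) in front of a 4-unit
tanh layer and a tanh output, the dense part trained with steps 1.0 / 0.1.

Targets are coded +1 (depression) / -1 (control); the {1, 2} file coding is
converted only at this boundary.  Inputs are expected standardized
(z-score, parameters fit on the training split only) — tanh units saturate
on raw Hz scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .acoustic_features import FeatureMatrix

__all__ = [
    "MLPConfig",
    "RBFNConfig",
    "SplitSpec",
    "MLPModel",
    "RBFNModel",
    "Standardizer",
    "holdout_split",
    "mlp_forward",
    "mlp_train",
    "kmeans_centers",
    "rbfn_train",
    "predict_class",
    "tanh_forward",
    "tanh_backprop",
]

DIVERGENCE_MSE = 1e6


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPConfig:
    layer_sizes: Tuple[int, ...] = (40, 16, 9, 1)
    step_sizes: Tuple[float, ...] = (1.0, 0.1, 0.01)
    momentum: float = 0.7
    max_epochs: int = 10_000
    mse_stop_threshold: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if len(self.step_sizes) != len(self.layer_sizes) - 1:
            raise ValueError("one step size per weight layer required")
        if any(s <= 0 for s in self.step_sizes):
            raise ValueError("step sizes must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass(frozen=True)
class RBFNConfig:
    input_size: int = 40
    n_centers: int = 8
    hidden_size: int = 4
    step_sizes: Tuple[float, float] = (1.0, 0.1)
    momentum: float = 0.7
    unsupervised_epochs: int = 100
    supervised_epochs: int = 10_000
    mse_stop_threshold: float = 1e-4
    seed: int = 0


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    unit: str = "subject"  # "subject" | "laugh"
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.unit not in ("subject", "laugh"):
            raise ValueError("unit must be 'subject' or 'laugh'")


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-column z-scoring with parameters fit on the training split only.

    Constant columns (sd = 0, e.g. the placement channel of a fixed layout)
    map to 0 rather than dividing by zero.
    """

    mean_: Optional[np.ndarray] = None
    sd_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer must be fit before transform")
        return (np.asarray(X, dtype=np.float64) - self.mean_) / self.sd_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# Shared tanh-net machinery
# ---------------------------------------------------------------------------

def tanh_forward(weights: Sequence[np.ndarray], biases: Sequence[np.ndarray],
                 X: np.ndarray) -> List[np.ndarray]:
    """Activations of every layer (input first) for a tanh network."""
    acts = [np.asarray(X, dtype=np.float64)]
    for W, b in zip(weights, biases):
        acts.append(np.tanh(acts[-1] @ W + b))
    return acts


def tanh_backprop(weights: Sequence[np.ndarray], biases: Sequence[np.ndarray],
                  X: np.ndarray, targets: np.ndarray
                  ) -> Tuple[List[np.ndarray], List[np.ndarray], float]:
    """Analytic MSE gradients for a tanh network (batch, mean over exemplars).

    MSE = mean over exemplars and outputs of (y - t)^2.
    Returns (dW per layer, db per layer, mse).
    """
    t = np.asarray(targets, dtype=np.float64)
    if t.ndim == 1:
        t = t[:, None]
    acts = tanh_forward(weights, biases, X)
    y = acts[-1]
    n, m = y.shape
    mse = float(np.mean((y - t) ** 2))
    delta = 2.0 * (y - t) / (n * m) * (1.0 - y ** 2)
    dWs: List[np.ndarray] = [np.empty(0)] * len(weights)
    dbs: List[np.ndarray] = [np.empty(0)] * len(weights)
    for l in range(len(weights) - 1, -1, -1):
        dWs[l] = acts[l].T @ delta
        dbs[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ weights[l].T) * (1.0 - acts[l] ** 2)
    return dWs, dbs, mse


def _init_layers(sizes: Sequence[int], rng: np.random.Generator
                 ) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    # uniform in [-0.5, 0.5]: the era-typical scale for tanh units on
    # standardized inputs
    Ws = [rng.uniform(-0.5, 0.5, size=(a, b)) for a, b in zip(sizes, sizes[1:])]
    bs = [rng.uniform(-0.5, 0.5, size=b) for b in sizes[1:]]
    return Ws, bs


def _train_tanh_layers(Ws: List[np.ndarray], bs: List[np.ndarray],
                       X: np.ndarray, t: np.ndarray,
                       step_sizes: Sequence[float], momentum: float,
                       max_epochs: int, mse_stop: float
                       ) -> Tuple[List[np.ndarray], List[np.ndarray], List[float]]:
    vW = [np.zeros_like(W) for W in Ws]
    vb = [np.zeros_like(b) for b in bs]
    history: List[float] = []
    for _ in range(max_epochs):
        dWs, dbs, mse = tanh_backprop(Ws, bs, X, t)
        history.append(mse)
        if mse > DIVERGENCE_MSE or not np.isfinite(mse):
            raise RuntimeError(
                f"training diverged (MSE={mse:.3g}); try smaller step sizes")
        if mse <= mse_stop:
            break
        for l, eta in enumerate(step_sizes):
            vW[l] = -eta * dWs[l] + momentum * vW[l]
            vb[l] = -eta * dbs[l] + momentum * vb[l]
            Ws[l] = Ws[l] + vW[l]
            bs[l] = bs[l] + vb[l]
    return Ws, bs, history


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

@dataclass
class MLPModel:
    config: MLPConfig
    weights: List[np.ndarray]
    biases: List[np.ndarray]
    history: List[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return int(sum(W.size for W in self.weights) + sum(b.size for b in self.biases))

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.config.layer_sizes[0]:
            raise ValueError(
                f"input has {X.shape[1]} features, network expects "
                f"{self.config.layer_sizes[0]}")
        return tanh_forward(self.weights, self.biases, X)[-1][:, 0]

    def get_state(self) -> dict:
        return {
            "config": {
                "layer_sizes": list(self.config.layer_sizes),
                "step_sizes": list(self.config.step_sizes),
                "momentum": self.config.momentum,
                "max_epochs": self.config.max_epochs,
                "mse_stop_threshold": self.config.mse_stop_threshold,
                "seed": self.config.seed,
            },
            "weights": self.weights,
            "biases": self.biases,
            "history": list(self.history),
        }

    @classmethod
    def from_state(cls, state: dict) -> "MLPModel":
        cfg = state["config"]
        config = MLPConfig(layer_sizes=tuple(cfg["layer_sizes"]),
                           step_sizes=tuple(cfg["step_sizes"]),
                           momentum=cfg["momentum"], max_epochs=int(cfg["max_epochs"]),
                           mse_stop_threshold=cfg["mse_stop_threshold"],
                           seed=int(cfg["seed"]))
        return cls(config=config, weights=list(state["weights"]),
                   biases=list(state["biases"]), history=list(state["history"]))


def mlp_forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Score(s) in (-1, 1) for standardized input row(s)."""
    return model.forward(X)


def mlp_train(config: MLPConfig, X: np.ndarray, targets: np.ndarray) -> MLPModel:
    """Train an MLP by batch gradient descent with momentum.

    ``X`` is (n, p) standardized, ``targets`` +1/-1.  Training stops at
    ``max_epochs`` or when the epoch MSE drops to ``mse_stop_threshold``;
    the per-epoch MSE history is recorded on the model.
    """
    X = np.asarray(X, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != config.layer_sizes[0]:
        raise ValueError(
            f"training matrix must be (n, {config.layer_sizes[0]}), got {X.shape}")
    if X.shape[0] < 2 or len(np.unique(t)) < 2:
        raise ValueError("training needs >= 2 exemplars with both classes present")
    rng = np.random.default_rng(config.seed)
    Ws, bs = _init_layers(config.layer_sizes, rng)
    Ws, bs, history = _train_tanh_layers(
        Ws, bs, X, t, config.step_sizes, config.momentum,
        config.max_epochs, config.mse_stop_threshold)
    return MLPModel(config=config, weights=Ws, biases=bs, history=history)


# ---------------------------------------------------------------------------
# k-means (unsupervised phase of the RBFN)
# ---------------------------------------------------------------------------

def kmeans_centers(X: np.ndarray, n_centers: int = 8, max_epochs: int = 100,
                   seed: int = 0) -> np.ndarray:
    """Lloyd iterations under squared Euclidean distance.

    Stops when assignments converge or after ``max_epochs``; an emptied
    cluster is reseeded from the point farthest from its assigned center.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < n_centers:
        raise ValueError(f"need >= {n_centers} exemplars, got {n}")
    distinct = np.unique(X, axis=0)
    if distinct.shape[0] < n_centers:
        warnings.warn(
            f"only {distinct.shape[0]} distinct exemplars for {n_centers} "
            "clusters; effective center count will be lower")
    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=n_centers, replace=False)].copy()
    assign = np.full(n, -1)
    for _ in range(max_epochs):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        for j in range(n_centers):
            members = X[new_assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                far = int(d2[np.arange(n), new_assign].argmax())
                centers[j] = X[far]
                new_assign[far] = j
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return centers


def _rbf_widths(centers: np.ndarray) -> np.ndarray:
    """sigma_j = mean Euclidean distance from c_j to its 2 nearest centers."""
    k = centers.shape[0]
    if k == 1:
        return np.ones(1)
    d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    widths = np.empty(k)
    for j in range(k):
        nearest = np.sort(d[j])[: min(2, k - 1)]
        widths[j] = nearest.mean()
    return np.where(widths > 0, widths, 1.0)


# ---------------------------------------------------------------------------
# RBFN
# ---------------------------------------------------------------------------

@dataclass
class RBFNModel:
    config: RBFNConfig
    centers: np.ndarray
    widths: np.ndarray
    weights: List[np.ndarray]   # dense part: [n_centers->hidden, hidden->1]
    biases: List[np.ndarray]
    history: List[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        dense = sum(W.size for W in self.weights) + sum(b.size for b in self.biases)
        return int(self.centers.size + self.widths.size + dense)

    def rbf_layer(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.config.input_size:
            raise ValueError(
                f"input has {X.shape[1]} features, network expects "
                f"{self.config.input_size}")
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.widths ** 2))

    def forward(self, X: np.ndarray) -> np.ndarray:
        phi = self.rbf_layer(X)
        return tanh_forward(self.weights, self.biases, phi)[-1][:, 0]

    def get_state(self) -> dict:
        return {
            "config": {
                "input_size": self.config.input_size,
                "n_centers": self.config.n_centers,
                "hidden_size": self.config.hidden_size,
                "step_sizes": list(self.config.step_sizes),
                "momentum": self.config.momentum,
                "unsupervised_epochs": self.config.unsupervised_epochs,
                "supervised_epochs": self.config.supervised_epochs,
                "mse_stop_threshold": self.config.mse_stop_threshold,
                "seed": self.config.seed,
            },
            "centers": self.centers,
            "widths": self.widths,
            "weights": self.weights,
            "biases": self.biases,
            "history": list(self.history),
        }

    @classmethod
    def from_state(cls, state: dict) -> "RBFNModel":
        cfg = state["config"]
        config = RBFNConfig(input_size=int(cfg["input_size"]),
                            n_centers=int(cfg["n_centers"]),
                            hidden_size=int(cfg["hidden_size"]),
                            step_sizes=tuple(cfg["step_sizes"]),
                            momentum=cfg["momentum"],
                            unsupervised_epochs=int(cfg["unsupervised_epochs"]),
                            supervised_epochs=int(cfg["supervised_epochs"]),
                            mse_stop_threshold=cfg["mse_stop_threshold"],
                            seed=int(cfg["seed"]))
        return cls(config=config, centers=np.asarray(state["centers"]),
                   widths=np.asarray(state["widths"]),
                   weights=list(state["weights"]), biases=list(state["biases"]),
                   history=list(state["history"]))


def rbfn_train(config: RBFNConfig, X: np.ndarray, targets: np.ndarray) -> RBFNModel:
    """Two-phase hybrid training.

    Phase 1 (unsupervised): k-means centers under Euclidean distance and
    the two-nearest-centers width heuristic.  Phase 2 (supervised): the
    Gaussian layer outputs feed a tanh hidden layer and a tanh output
    trained by momentum backpropagation with the centers frozen.
    """
    X = np.asarray(X, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != config.input_size:
        raise ValueError(f"training matrix must be (n, {config.input_size}), got {X.shape}")
    if X.shape[0] < 2 or len(np.unique(t)) < 2:
        raise ValueError("training needs >= 2 exemplars with both classes present")
    centers = kmeans_centers(X, n_centers=config.n_centers,
                             max_epochs=config.unsupervised_epochs, seed=config.seed)
    widths = _rbf_widths(centers)
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    phi = np.exp(-d2 / (2.0 * widths ** 2))
    rng = np.random.default_rng(config.seed)
    Ws, bs = _init_layers((config.n_centers, config.hidden_size, 1), rng)
    Ws, bs, history = _train_tanh_layers(
        Ws, bs, phi, t, config.step_sizes, config.momentum,
        config.supervised_epochs, config.mse_stop_threshold)
    return RBFNModel(config=config, centers=centers, widths=widths,
                     weights=Ws, biases=bs, history=history)


# ---------------------------------------------------------------------------
# Prediction and splitting
# ---------------------------------------------------------------------------

def predict_class(model, X: np.ndarray, threshold: float = 0.0
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Labels {+1 depression, -1 control} and raw scores.

    A score exactly at the threshold is classed -1 (strict inequality).
    """
    scores = model.forward(X)
    labels = np.where(scores > threshold, 1.0, -1.0)
    return labels, scores


def holdout_split(fm: FeatureMatrix, spec: SplitSpec = SplitSpec()
                  ) -> Tuple[FeatureMatrix, FeatureMatrix]:
    """80/20 holdout at subject or laugh granularity.

    With ``unit='subject'`` no subject's laughs straddle the split (the
    leakage-safe default); stratification splits each class's units
    separately so class proportions carry over.  If a side ends up missing
    a class the split is redrawn (warned), erroring after 100 attempts.
    """
    if len(fm) == 0:
        raise ValueError("cannot split an empty feature matrix")
    if len(np.unique(fm.y)) < 2:
        raise ValueError("both classes must be present before splitting")
    units = fm.subject_ids if spec.unit == "subject" else fm.laugh_ids
    rng = np.random.default_rng(spec.seed)
    unit_ids = np.array(sorted(set(units)))
    unit_label = {u: fm.y[units == u][0] for u in unit_ids}

    for attempt in range(100):
        train_units: set = set()
        if spec.stratified:
            for cls in (1.0, -1.0):
                members = np.array([u for u in unit_ids if unit_label[u] == cls])
                n_train = int(round(spec.train_fraction * len(members)))
                n_train = min(max(n_train, 1), max(len(members) - 1, 1))
                picked = rng.permutation(members)[:n_train]
                train_units.update(picked.tolist())
        else:
            n_train = int(round(spec.train_fraction * len(unit_ids)))
            n_train = min(max(n_train, 1), len(unit_ids) - 1)
            train_units.update(rng.permutation(unit_ids)[:n_train].tolist())
        in_train = np.array([u in train_units for u in units])
        tr, te = fm.subset(in_train), fm.subset(~in_train)
        if len(np.unique(tr.y)) == 2 and len(np.unique(te.y)) == 2:
            return tr, te
        warnings.warn(f"holdout redraw {attempt + 1}: a class was absent from one side")
    raise RuntimeError("could not produce a split with both classes on both sides "
                       "after 100 attempts")


def kfold_split(fm: FeatureMatrix, k: int = 5, unit: str = "subject",
                seed: int = 0) -> List[Tuple[FeatureMatrix, FeatureMatrix]]:
    """k disjoint stratified holdouts (each fold an 80/20-style split at k=5).

    Units (subjects by default) of each class are permuted once and dealt
    round-robin into k folds, so every unit is held out exactly once and
    class proportions carry over.  Folds lacking a class on either side
    are skipped with a warning (possible only for tiny cohorts).
    """
    units = fm.subject_ids if unit == "subject" else fm.laugh_ids
    unit_ids = np.array(sorted(set(units)))
    unit_label = {u: fm.y[units == u][0] for u in unit_ids}
    rng = np.random.default_rng(seed)
    fold_of = {}
    for cls in (1.0, -1.0):
        members = rng.permutation([u for u in unit_ids if unit_label[u] == cls])
        for i, u in enumerate(members):
            fold_of[u] = i % k
    folds = []
    for f in range(k):
        in_test = np.array([fold_of[u] == f for u in units])
        tr, te = fm.subset(~in_test), fm.subset(in_test)
        if len(te) == 0 or len(np.unique(tr.y)) < 2 or len(np.unique(te.y)) < 2:
            warnings.warn(f"fold {f} lacks a class on one side; skipped")
            continue
        folds.append((tr, te))
    return folds
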