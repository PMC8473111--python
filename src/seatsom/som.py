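"""Self-organizing map classifier on a 2x3 hexagonal lattice.

The map has six output nodes — one per posture class — laid out in two offset
rows of three, so lattice neighbours sit exactly one unit apart. Training is
classic online competitive learning on L2-normalized 256-element feature
vectors: find the best-matching unit (BMU) by Euclidean distance, then pull
every node in the shrinking winner neighbourhood toward the sample,

    w_j <- w_j + eta(t) * h_cj(t) * (x - w_j),

with Gaussian neighbourhood ``h_cj = exp(-D_cj^2 / (2 sigma(t)^2))`` and
exponentially decaying schedules ``sigma(t) = sigma0 exp(-t/tau_sigma)`` and
``eta(t) = eta0 exp(-t/tau_eta)``; ``t`` counts individual sample
presentations. Weights are renormalized to unit length after every update so
the distance computation stays consistent with the normalization step. After
training, each node is labeled by majority vote of the training samples it
wins, which turns the unsupervised map into a six-class posture classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .sensor import POSTURE_CLASSES

__all__ = [
    "HexGrid",
    "TrainConfig",
    "SomModel",
    "normalize",
    "find_bmu",
    "neighborhood",
    "sigma_at",
    "eta_at",
    "update_weights",
    "train",
    "assign_labels",
    "predict_features",
    "SomPostureClassifier",
]


class HexGrid:
    """Hexagonal output lattice: ``n_rows`` offset rows of ``n_cols`` nodes.

    Node ``i`` of row ``r`` sits at ``x = i + 0.5*(r % 2)``,
    ``y = r * sqrt(3)/2``, so all lattice neighbours (within-row and
    across-row) are exactly distance 1 apart. Nodes are indexed row-major.
    The default 2x3 grid is the six-posture output layer.
    """

    def __init__(self, n_rows: int = 2, n_cols: int = 3):
        if n_rows < 1 or n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        self.n_rows = n_rows
        self.n_cols = n_cols
        pos = [(c + 0.5 * (r % 2), r * np.sqrt(3.0) / 2.0)
               for r in range(n_rows) for c in range(n_cols)]
        self.positions = np.asarray(pos, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean lattice distances, shape (n_nodes, n_nodes)."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    def adjacency(self, tol: float = 1e-9) -> np.ndarray:
        """Boolean matrix of lattice neighbours (distance exactly 1)."""
        d = self.distances()
        return np.abs(d - 1.0) < tol

    def neighbors(self, j: int) -> np.ndarray:
        """Indices of the hex-adjacent nodes of node ``j``."""
        return np.flatnonzero(self.adjacency()[j])


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule parameters (defaults are the method's tuned values).

    eta0 : initial learning rate (0.6), decaying as ``eta0 * exp(-t/tau_eta)``.
    tau_eta : learning-rate time constant in sample presentations (1000).
    sigma0 : initial neighbourhood width / learning gain (10).
    tau_sigma : neighbourhood time constant (2) — the winner neighbourhood
        collapses to the BMU alone within a few presentations.
    nc0 : initial neighbourhood radius cap (3 lattice units); node ``j``
        belongs to the winner neighbourhood when
        ``D_cj <= min(nc0, sigma(t))``.
    r_min : differentiation threshold of the sample filter (0.15).
    max_iters : presentation budget; training also stops once
        ``eta(t) < eta_stop``.
    init : "maximin" (farthest-point draw from the data, default), "sample"
        (uniform draw), or "random" unit vectors.
    n_restarts : independent fits (seeds ``seed .. seed+n_restarts-1``); the
        one with the lowest quantization error (mean BMU distance) is kept.
        With one node per posture and the fast neighbourhood collapse of the
        default schedule, single runs can leave two postures sharing a node;
        restart selection is the standard unsupervised remedy.
    """

    eta0: float = 0.6
    tau_eta: float = 1000.0
    sigma0: float = 10.0
    tau_sigma: float = 2.0
    nc0: float = 3.0
    r_min: float = 0.15
    max_iters: int = 5000
    eta_stop: float = 1e-3
    seed: int = 0
    init: str = "maximin"
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.eta0 <= 1:
            raise ValueError("eta0 must be in (0, 1]")
        if min(self.tau_eta, self.tau_sigma, self.sigma0) <= 0:
            raise ValueError("time constants and sigma0 must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.init not in ("random", "sample", "maximin"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class SomModel:
    """A (possibly trained) map: lattice, unit-norm weights, node labels."""

    grid: HexGrid
    weights: np.ndarray                       # (n_nodes, dim), rows unit-norm
    node_labels: Optional[list[str]] = None   # len n_nodes, set post-training

    def to_json(self) -> str:
        payload = {
            "grid": {"n_rows": self.grid.n_rows, "n_cols": self.grid.n_cols},
            "weights": self.weights.tolist(),
            "node_labels": self.node_labels,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SomModel":
        payload = json.loads(text)
        grid = HexGrid(payload["grid"]["n_rows"], payload["grid"]["n_cols"])
        return cls(grid, np.asarray(payload["weights"], float),
                   payload["node_labels"])


def normalize(v: np.ndarray) -> np.ndarray:
    """L2-normalize a vector (or each row of a matrix); zero norm is an error."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v, axis=-1, keepdims=v.ndim > 1)
    if np.any(norm == 0):
        raise ValueError("cannot normalize a zero vector")
    return v / norm


def find_bmu(x: np.ndarray, weights: np.ndarray) -> tuple[int, float]:
    """Best-matching unit: ``argmin_j ||x - w_j||`` with its distance.

    Ties go to the lowest node index (np.argmin's convention).
    """
    d = np.linalg.norm(weights - x, axis=1)
    c = int(np.argmin(d))
    return c, float(d[c])


def sigma_at(t: float, cfg: TrainConfig) -> float:
    """Neighbourhood width ``sigma0 * exp(-t / tau_sigma)``."""
    return cfg.sigma0 * float(np.exp(-t / cfg.tau_sigma))


def eta_at(t: float, cfg: TrainConfig) -> float:
    """Learning rate ``eta0 * exp(-t / tau_eta)``."""
    return cfg.eta0 * float(np.exp(-t / cfg.tau_eta))


def neighborhood(c: int, j: int, sigma_t: float, grid: HexGrid) -> float:
    """Gaussian lattice kernel ``exp(-D_cj^2 / (2 sigma_t^2))`` in (0, 1]."""
    if sigma_t <= 0:
        raise ValueError("sigma_t must be positive")
    d = np.linalg.norm(grid.positions[c] - grid.positions[j])
    return float(np.exp(-(d ** 2) / (2.0 * sigma_t ** 2)))


def update_weights(model: SomModel, x: np.ndarray, c: int, t: float,
                   cfg: TrainConfig) -> SomModel:
    """One competitive-learning step centred on winner ``c`` (in place).

    Nodes within lattice distance ``min(nc0, sigma(t))`` of the winner move
    toward ``x`` by ``eta(t) * h_cj``; all moved weights are renormalized.
    """
    sigma_t = sigma_at(t, cfg)
    eta_t = eta_at(t, cfg)
    d_lattice = np.linalg.norm(model.grid.positions - model.grid.positions[c], axis=1)
    in_hood = d_lattice <= min(cfg.nc0, sigma_t) + 1e-12
    d_h = d_lattice[in_hood]
    # sigma(t) underflows to 0 for large t; the winner (d=0) keeps h=1 and
    # any other node's kernel flushes to 0
    with np.errstate(invalid="ignore", divide="ignore", under="ignore"):
        h = np.exp(-(d_h ** 2) / (2.0 * sigma_t ** 2))
    h = np.where(d_h == 0, 1.0, np.nan_to_num(h, nan=0.0))
    w = model.weights[in_hood]
    w = w + eta_t * h[:, None] * (x - w)
    model.weights[in_hood] = normalize(w)
    return model


def _init_weights(n_nodes: int, dim: int, X: np.ndarray, cfg: TrainConfig,
                  rng: np.random.Generator) -> np.ndarray:
    if cfg.init == "sample":
        idx = rng.choice(len(X), size=n_nodes, replace=len(X) < n_nodes)
        w = X[idx].copy()
    elif cfg.init == "maximin":
        # farthest-point draw: a random seed sample, then greedily the
        # sample farthest from the chosen set — spreads the 6 nodes over
        # distinct data modes so none starts dead
        chosen = [int(rng.integers(len(X)))]
        d_min = np.linalg.norm(X - X[chosen[0]], axis=1)
        while len(chosen) < min(n_nodes, len(X)):
            nxt = int(np.argmax(d_min))
            chosen.append(nxt)
            d_min = np.minimum(d_min, np.linalg.norm(X - X[nxt], axis=1))
        w = X[(chosen * n_nodes)[:n_nodes]].copy()
    else:
        w = rng.normal(size=(n_nodes, dim))
    return normalize(w)


def train(samples: np.ndarray, cfg: TrainConfig = TrainConfig(),
          grid: Optional[HexGrid] = None,
          init_weights: Optional[np.ndarray] = None) -> SomModel:
    """Fit the map to an ``(n, dim)`` array of feature vectors.

    Samples are L2-normalized, then presented in seeded per-epoch shuffles
    until ``max_iters`` presentations or ``eta(t) < eta_stop``. Of
    ``cfg.n_restarts`` independent runs (consecutive seeds), the fit with the
    lowest quantization error — mean distance from each sample to its BMU —
    is returned; the whole procedure is deterministic given ``cfg.seed``.
    ``init_weights`` (e.g. a previous model's weights for a warm start)
    overrides the configured initialization and disables restarts.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("samples must be a non-empty 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("samples must be finite")
    X = normalize(X)
    grid = grid or HexGrid()

    def one_run(seed: int, w0: Optional[np.ndarray]) -> SomModel:
        rng = np.random.default_rng(seed)
        if w0 is None:
            w0 = _init_weights(grid.n_nodes, X.shape[1], X, cfg, rng)
        model = SomModel(grid, w0)
        t = 0
        while t < cfg.max_iters and eta_at(t, cfg) >= cfg.eta_stop:
            for i in rng.permutation(len(X)):
                if t >= cfg.max_iters or eta_at(t, cfg) < cfg.eta_stop:
                    break
                c, _ = find_bmu(X[i], model.weights)
                update_weights(model, X[i], c, t, cfg)
                t += 1
        return model

    if init_weights is not None:
        w0 = normalize(np.asarray(init_weights, dtype=float).copy())
        if w0.shape != (grid.n_nodes, X.shape[1]):
            raise ValueError("init_weights shape mismatch")
        return one_run(cfg.seed, w0)

    best, best_qe = None, np.inf
    for r in range(cfg.n_restarts):
        model = one_run((cfg.seed + r) % 2**31, None)
        qe = float(np.min(np.linalg.norm(X[:, None] - model.weights[None], axis=2),
                          axis=1).mean())
        if qe < best_qe - 1e-12:
            best, best_qe = model, qe
    return best


def assign_labels(model: SomModel, samples: np.ndarray,
                  labels: Sequence[str],
                  class_order: Sequence[str] = POSTURE_CLASSES) -> SomModel:
    """Label each node by majority vote of the training samples it wins.

    Vote ties break toward the earlier class in ``class_order``; a node that
    wins no samples inherits the label of the nearest (lattice distance,
    lowest index on ties) labeled node.
    """
    X = normalize(np.asarray(samples, dtype=float))
    labels = list(labels)
    if len(labels) != len(X) or not labels:
        raise ValueError("need one label per sample")
    rank = {c: i for i, c in enumerate(class_order)}
    counts = [dict.fromkeys(class_order, 0) for _ in range(model.grid.n_nodes)]
    for x, lab in zip(X, labels):
        c, _ = find_bmu(x, model.weights)
        counts[c][lab] += 1
    node_labels: list[Optional[str]] = [None] * model.grid.n_nodes
    for j, cnt in enumerate(counts):
        total = sum(cnt.values())
        if total:
            node_labels[j] = max(class_order, key=lambda c: (cnt[c], -rank[c]))
    hit = [j for j, lab in enumerate(node_labels) if lab is not None]
    if not hit:
        raise ValueError("no node won any labeled sample")
    d = model.grid.distances()
    for j, lab in enumerate(node_labels):
        if lab is None:
            node_labels[j] = node_labels[min(hit, key=lambda h: (d[j, h], h))]
    model.node_labels = node_labels  # type: ignore[assignment]
    return model


def predict_features(model: SomModel, features: np.ndarray) -> list[str]:
    """Posture class of each feature vector: label of its BMU."""
    if model.node_labels is None:
        raise ValueError("model has no node labels; call assign_labels first")
    X = normalize(np.atleast_2d(np.asarray(features, dtype=float)))
    return [model.node_labels[find_bmu(x, model.weights)[0]] for x in X]


class SomPostureClassifier(ClassifierMixin, BaseEstimator):
    """Sitting-posture classifier backed by the hexagonal self-organizing map.

    A scikit-learn style estimator: ``fit(X, y)`` takes 256-element feature
    vectors (rows of ``X``) with posture labels ``y``, trains the map
    unsupervised, then labels nodes by majority vote; ``predict`` maps each
    sample to its best-matching node's label.

    Parameters mirror :class:`TrainConfig`; see there for meanings.

    Attributes
    ----------
    model_ : SomModel
        Trained lattice with unit-norm weights and node labels.
    classes_ : ndarray
        Classes seen during fit, in the fixed posture order.
    """

    def __init__(self, eta0: float = 0.6, tau_eta: float = 1000.0,
                 sigma0: float = 10.0, tau_sigma: float = 2.0,
                 nc0: float = 3.0, max_iters: int = 5000,
                 eta_stop: float = 1e-3, init: str = "maximin",
                 n_restarts: int = 5, n_rows: int = 2, n_cols: int = 3,
                 random_state: int = 0):
        self.eta0 = eta0
        self.tau_eta = tau_eta
        self.sigma0 = sigma0
        self.tau_sigma = tau_sigma
        self.nc0 = nc0
        self.max_iters = max_iters
        self.eta_stop = eta_stop
        self.init = init
        self.n_restarts = n_restarts
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.random_state = random_state

    def _config(self, **overrides) -> TrainConfig:
        kw = dict(eta0=self.eta0, tau_eta=self.tau_eta, sigma0=self.sigma0,
                  tau_sigma=self.tau_sigma, nc0=self.nc0,
                  max_iters=self.max_iters, eta_stop=self.eta_stop,
                  seed=self.random_state, init=self.init,
                  n_restarts=self.n_restarts)
        kw.update(overrides)
        return TrainConfig(**kw)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        grid = HexGrid(self.n_rows, self.n_cols)
        self.model_ = train(X, self._config(), grid)
        assign_labels(self.model_, X, [str(c) for c in y])
        present = set(str(c) for c in y)
        self.classes_ = np.asarray([c for c in POSTURE_CLASSES if c in present]
                                   or sorted(present))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise ValueError("classifier is not fitted")
        return np.asarray(predict_features(self.model_, np.asarray(X, float)))

    def bmu_distances(self, X) -> np.ndarray:
        """Distance from each (normalized) sample to every node weight."""
        X = normalize(np.atleast_2d(np.asarray(X, dtype=float)))
        return np.linalg.norm(X[:, None, :] - self.model_.weights[None], axis=2)
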