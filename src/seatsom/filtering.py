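"""Differentiation-based sample filtering and the improved-map classifier.

After a first unsupervised fit the node weights are frozen and every training
sample is scored by how decisively it prefers its best-matching node ``j``
over the strongest hex-adjacent rival ``k``:

    e_jk = d_ij - d_ik,      r_jk = |e_jk| / (d_ij + d_ik),

where ``d_ij`` and ``d_ik`` are the Euclidean distances from the normalized
sample to the two frozen weights. ``r_jk`` is scale-free and lies in [0, 1]:
0 when the sample is equidistant from the two nodes (maximally ambiguous) and
1 when it coincides with its winner. Samples with ``r_jk`` below a threshold
``r_min`` sit on cluster boundaries, blur the map during training, and are
removed; the map is then retrained from scratch on the retained samples,
which drives the node weights further apart and sharpens the clustering.
The filter touches training data only — test samples are never filtered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .sensor import POSTURE_CLASSES
from .som import (
    HexGrid,
    SomModel,
    SomPostureClassifier,
    TrainConfig,
    assign_labels,
    normalize,
    train,
)

__all__ = [
    "DifferentiationRecord",
    "recompute_distances",
    "differentiation",
    "differentiation_records",
    "filter_samples",
    "isom_train",
    "IsomPostureClassifier",
]


@dataclass(frozen=True)
class DifferentiationRecord:
    """Per-sample ambiguity score between the BMU and its strongest rival."""

    sample_index: int
    bmu: int
    rival: int
    d_ij: float
    d_ik: float
    e_jk: float
    r_jk: float


def recompute_distances(model: SomModel, samples: np.ndarray) -> np.ndarray:
    """Distances from each normalized sample to every frozen node weight.

    Entry ``(i, j)`` is ``||x_i - w_j||``; shape ``(n_samples, n_nodes)``.
    """
    X = normalize(np.atleast_2d(np.asarray(samples, dtype=float)))
    return np.linalg.norm(X[:, None, :] - model.weights[None], axis=2)


def differentiation(model: SomModel, distances: np.ndarray, i: int,
                    rival: str = "nearest") -> DifferentiationRecord:
    """Score sample ``i``'s differentiation between its BMU and a rival node.

    ``rival="nearest"`` (default) picks the hex-adjacent node of the BMU with
    the smallest distance — the neighbour most likely to steal the sample.
    ``rival="all"`` evaluates every adjacent pair and keeps the one with the
    smallest ``r_jk`` (the worst case). ``e_jk`` is signed (negative when the
    BMU is genuinely closer); ``r_jk`` uses its magnitude. A sample lying on
    both nodes at once (``d_ij + d_ik = 0``) gets ``r_jk = 0``.
    """
    row = distances[i]
    j = int(np.argmin(row))
    adjacent = model.grid.neighbors(j)
    if adjacent.size == 0:
        raise ValueError(f"node {j} has no lattice neighbours")

    def record(k: int) -> DifferentiationRecord:
        d_ij, d_ik = float(row[j]), float(row[k])
        e_jk = d_ij - d_ik
        denom = d_ij + d_ik
        r_jk = abs(e_jk) / denom if denom > 0 else 0.0
        return DifferentiationRecord(i, j, int(k), d_ij, d_ik, e_jk, r_jk)

    if rival == "nearest":
        k = adjacent[int(np.argmin(row[adjacent]))]
        return record(k)
    if rival == "all":
        return min((record(k) for k in adjacent), key=lambda r: (r.r_jk, r.rival))
    raise ValueError(f"unknown rival mode {rival!r}")


def differentiation_records(model: SomModel, samples: np.ndarray,
                            rival: str = "nearest") -> list[DifferentiationRecord]:
    """Differentiation record for every sample (distances computed once)."""
    distances = recompute_distances(model, samples)
    return [differentiation(model, distances, i, rival)
            for i in range(len(distances))]


def filter_samples(records: Sequence[DifferentiationRecord], r_min: float
                   ) -> tuple[list[int], list[int]]:
    """Partition sample indices into (kept, removed) by ``r_jk < r_min``."""
    kept = [r.sample_index for r in records if r.r_jk >= r_min]
    removed = [r.sample_index for r in records if r.r_jk < r_min]
    return kept, removed


def _guard_classes(records: Sequence[DifferentiationRecord], kept: list[int],
                   removed: list[int], labels: Sequence[str],
                   keep_fraction: float = 0.1) -> tuple[list[int], list[int]]:
    """Re-admit the top-r samples of any class the filter emptied.

    Keeps ``max(1, keep_fraction * class size)`` best-differentiated samples
    so every class can still claim a node in the retrain.
    """
    kept_set = set(kept)
    kept_classes = {labels[i] for i in kept}
    by_class: dict[str, list[DifferentiationRecord]] = {}
    for rec in records:
        by_class.setdefault(labels[rec.sample_index], []).append(rec)
    for cls, recs in by_class.items():
        if cls in kept_classes:
            continue
        n_keep = max(1, int(round(keep_fraction * len(recs))))
        best = sorted(recs, key=lambda r: (-r.r_jk, r.sample_index))[:n_keep]
        kept_set.update(r.sample_index for r in best)
    kept = sorted(kept_set)
    removed = [i for i in removed if i not in kept_set]
    return kept, removed


def isom_train(samples: np.ndarray, labels: Sequence[str],
               cfg: TrainConfig = TrainConfig(),
               grid: Optional[HexGrid] = None,
               rival: str = "nearest",
               strict_paper_mode: bool = False,
               warm_start: bool = False,
               ) -> tuple[SomModel, list[DifferentiationRecord], list[int], list[int]]:
    """Full improved pipeline: fit, score, filter, refit, label.

    Returns ``(model, records, kept, removed)``. The retrain restarts with
    fresh schedules and the same seed unless ``warm_start`` continues from
    the first model's weights. ``strict_paper_mode`` disables the
    class-extinction guard (a class may then lose all its samples).
    """
    X = np.asarray(samples, dtype=float)
    labels = [str(c) for c in labels]
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("samples must be a non-empty 2-D array")
    if len(labels) != len(X):
        raise ValueError("need one label per sample")
    grid = grid or HexGrid()
    first = train(X, cfg, grid)
    records = differentiation_records(first, X, rival)
    kept, removed = filter_samples(records, cfg.r_min)
    if not strict_paper_mode:
        kept, removed = _guard_classes(records, kept, removed, labels)
    if not kept:
        raise ValueError("filter removed every sample; lower r_min")
    model = train(X[kept], cfg, grid,
                  init_weights=first.weights if warm_start else None)
    assign_labels(model, X[kept], [labels[i] for i in kept])
    return model, records, kept, removed


class IsomPostureClassifier(SomPostureClassifier):
    """Posture classifier with differentiation filtering and retraining.

    Fits a first map, removes training samples whose differentiation degree
    ``r_jk`` falls below ``r_min``, and refits on the retained samples. The
    extra parameters:

    r_min : float, default=0.15
        Filtering threshold on the differentiation degree.
    rival : {"nearest", "all"}, default="nearest"
        How the rival node of each sample's BMU is chosen.
    strict_paper_mode : bool, default=False
        Disable the guard that re-admits the best samples of a class the
        filter would empty.
    warm_start_retrain : bool, default=False
        Continue the retrain from the first map's weights instead of a fresh
        restart.

    Extra fitted attributes: ``filter_records_`` (per-sample
    :class:`DifferentiationRecord`), ``kept_idx_``, ``removed_idx_``.
    """

    def __init__(self, eta0: float = 0.6, tau_eta: float = 1000.0,
                 sigma0: float = 10.0, tau_sigma: float = 2.0,
                 nc0: float = 3.0, max_iters: int = 5000,
                 eta_stop: float = 1e-3, init: str = "maximin",
                 n_restarts: int = 5, n_rows: int = 2, n_cols: int = 3,
                 random_state: int = 0,
                 r_min: float = 0.15, rival: str = "nearest",
                 strict_paper_mode: bool = False,
                 warm_start_retrain: bool = False):
        super().__init__(eta0=eta0, tau_eta=tau_eta, sigma0=sigma0,
                         tau_sigma=tau_sigma, nc0=nc0, max_iters=max_iters,
                         eta_stop=eta_stop, init=init, n_restarts=n_restarts,
                         n_rows=n_rows, n_cols=n_cols,
                         random_state=random_state)
        self.r_min = r_min
        self.rival = rival
        self.strict_paper_mode = strict_paper_mode
        self.warm_start_retrain = warm_start_retrain

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = [str(c) for c in np.asarray(y)]
        grid = HexGrid(self.n_rows, self.n_cols)
        cfg = self._config(r_min=self.r_min)
        model, records, kept, removed = isom_train(
            X, y, cfg, grid, rival=self.rival,
            strict_paper_mode=self.strict_paper_mode,
            warm_start=self.warm_start_retrain)
        self.model_ = model
        self.filter_records_ = records
        self.kept_idx_ = np.asarray(kept, dtype=int)
        self.removed_idx_ = np.asarray(removed, dtype=int)
        present = set(y)
        self.classes_ = np.asarray([c for c in POSTURE_CLASSES if c in present]
                                   or sorted(present))
        self.n_features_in_ = X.shape[1]
        return self
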