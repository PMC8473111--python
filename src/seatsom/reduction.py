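"""Per-frame PCA reduction of 32x32 pressure maps to 256-element vectors.

Each frame's 32 columns are treated as variables observed over its 32 rows;
the top 8 eigenvectors of the resulting 32x32 column covariance matrix form a
projection ``A``, and ``P_r = P A`` is the 32x8 reduced frame. Flattening
``P_r`` row-major (head to tail) yields the 256-element feature vector the
map classifier consumes — a 4x compression of the original 1024 cells.

By default every frame is reduced in its own eigenbasis (the reduction is
defined frame by frame); a pooled mode that fits one shared basis on a
training set is available through :class:`PressureMapReducer`. Eigenvector
sign is fixed by forcing each column's largest-magnitude entry positive, so
identical frames always map to identical feature vectors.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .sensor import PressureFrame

__all__ = [
    "column_covariance",
    "top_eigenvectors",
    "reduce_frame",
    "flatten_to_vector",
    "frame_features",
    "PressureMapReducer",
]

FrameLike = Union[PressureFrame, np.ndarray]


def _frame_values(frame: FrameLike, rows: int = 32, cols: int = 32) -> np.ndarray:
    values = frame.values if isinstance(frame, PressureFrame) else np.asarray(frame, float)
    if values.shape != (rows, cols):
        raise ValueError(f"expected a {rows}x{cols} frame, got shape {values.shape}")
    return values


def column_covariance(frame: FrameLike) -> np.ndarray:
    """Sample covariance (divisor n-1) between the 32 columns of a frame.

    Entry ``(m, n)`` is the covariance between columns ``m`` and ``n``
    observed over the 32 rows; the result is symmetric 32x32.
    """
    values = _frame_values(frame)
    return np.cov(values, rowvar=False, ddof=1)


def top_eigenvectors(cov: np.ndarray, k: int = 8, *, tol: float = 1e-8) -> np.ndarray:
    """Orthonormal eigenvectors of a symmetric matrix, top-``k`` by eigenvalue.

    Columns are ordered by decreasing eigenvalue (ties broken by original
    index order) with each column's largest-magnitude entry forced positive.
    A rank-deficient covariance (fewer than ``k`` nonzero eigenvalues) still
    yields ``k`` orthonormal columns — the eigensolver completes the basis —
    but a warning flags the degeneracy.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got shape {cov.shape}")
    if not 1 <= k <= cov.shape[0]:
        raise ValueError(f"k must be in [1, {cov.shape[0]}], got {k}")
    asym = np.abs(cov - cov.T).max() if cov.size else 0.0
    if asym > 100 * tol * max(1.0, np.abs(cov).max()):
        raise ValueError(f"covariance is asymmetric (max deviation {asym:.3g})")
    evals, evecs = np.linalg.eigh((cov + cov.T) / 2.0)
    # eigh returns ascending eigenvalues; stable flip keeps index order on ties
    order = np.argsort(-evals, kind="stable")
    evals, evecs = evals[order], evecs[:, order]
    scale = max(np.abs(evals).max(), 1.0)
    if np.sum(evals > tol * scale) < k:
        warnings.warn(
            "covariance has rank < k; trailing eigenvectors are an arbitrary "
            "(but deterministic) orthonormal completion", RuntimeWarning,
            stacklevel=2)
    top = evecs[:, :k].copy()
    # sign convention: largest-|entry| of each eigenvector made positive
    anchor = np.abs(top).argmax(axis=0)
    signs = np.sign(top[anchor, np.arange(k)])
    signs[signs == 0] = 1.0
    return top * signs


def reduce_frame(frame: FrameLike, k: int = 8,
                 basis: Optional[np.ndarray] = None) -> np.ndarray:
    """Project a 32x32 frame to 32x``k``: ``P_r = P A``.

    ``A`` is the frame's own top-``k`` column-covariance eigenbasis unless an
    explicit ``basis`` (e.g. a pooled one) is supplied.
    """
    values = _frame_values(frame)
    if basis is None:
        basis = top_eigenvectors(column_covariance(values), k)
    return values @ basis


def flatten_to_vector(reduced: np.ndarray) -> np.ndarray:
    """Concatenate the rows of a 32x8 reduced frame head-to-tail (length 256).

    Element ``(m, n)`` (0-based) lands at index ``8*m + n``.
    """
    reduced = np.asarray(reduced, dtype=float)
    if reduced.ndim != 2 or reduced.shape != (32, 8):
        raise ValueError(f"expected a 32x8 reduced frame, got shape {reduced.shape}")
    return reduced.reshape(-1)


def frame_features(frame: FrameLike, basis: Optional[np.ndarray] = None) -> np.ndarray:
    """Full reduction of one frame: project to 32x8, flatten to length 256."""
    return flatten_to_vector(reduce_frame(frame, 8, basis))


class PressureMapReducer(TransformerMixin, BaseEstimator):
    """Transformer turning pressure frames into 256-element feature vectors.

    Parameters
    ----------
    mode : {"per-frame", "pooled"}, default="per-frame"
        ``"per-frame"`` reduces each frame in its own eigenbasis (the
        method's definition); ``"pooled"`` fits one basis on the column
        covariance pooled over the training frames, making feature axes
        directly comparable across frames.
    n_components : int, default=8
        Number of leading eigenvectors retained.

    Accepts input as a sequence of :class:`PressureFrame`, an array of shape
    ``(n, 32, 32)``, or flattened rows ``(n, 1024)``.
    """

    def __init__(self, mode: str = "per-frame", n_components: int = 8):
        self.mode = mode
        self.n_components = n_components

    @staticmethod
    def _as_stack(X) -> np.ndarray:
        if isinstance(X, PressureFrame):
            X = [X]
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], PressureFrame):
            return np.stack([f.values for f in X])
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape == (32, 32):
            arr = arr[None]
        elif arr.ndim == 2 and arr.shape[1] == 1024:
            arr = arr.reshape(-1, 32, 32)
        if arr.ndim != 3 or arr.shape[1:] != (32, 32):
            raise ValueError(f"cannot interpret input of shape {np.shape(X)} as 32x32 frames")
        return arr

    def fit(self, X, y=None):
        if self.mode not in ("per-frame", "pooled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "pooled":
            stack = self._as_stack(X)
            # pool by averaging per-frame column covariances
            cov = np.mean([np.cov(f, rowvar=False, ddof=1) for f in stack], axis=0)
            self.basis_ = top_eigenvectors(cov, self.n_components)
        else:
            self.basis_ = None
        self.n_features_in_ = 1024
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_features_in_"):
            # per-frame mode needs no fitting; allow transform-only use
            self.fit(X)
        stack = self._as_stack(X)
        basis = getattr(self, "basis_", None)
        out = np.empty((stack.shape[0], 32 * self.n_components))
        for i, values in enumerate(stack):
            if basis is None:
                b = top_eigenvectors(column_covariance(values), self.n_components)
            else:
                b = basis
            out[i] = (values @ b).reshape(-1)
        return out
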