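"""Windowed functional network connectivity: Pearson r per window, Fisher z,
vectorized upper triangle, and a low-variability quality-control screen."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .paradigm import Window
from .signal_prep import ComponentTimeSeries

logger = logging.getLogger(__name__)


def n_links(n_components: int) -> int:
    return n_components * (n_components - 1) // 2


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle (row-major, i < j) of a symmetric matrix."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 components")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu].copy()


def devectorize(vector: np.ndarray, n_components: int) -> np.ndarray:
    """Inverse of :func:`vectorize`; diagonal restored as 0."""
    vector = np.asarray(vector)
    if vector.shape != (n_links(n_components),):
        raise ValueError(
            f"expected length {n_links(n_components)} for C={n_components}, "
            f"got {vector.shape}")
    mat = np.zeros((n_components, n_components), dtype=vector.dtype)
    iu = np.triu_indices(n_components, k=1)
    mat[iu] = vector
    return mat + mat.T


def link_index_pairs(n_components: int) -> np.ndarray:
    """(n_links, 2) array of (i, j) component indices in vectorization order."""
    iu = np.triu_indices(n_components, k=1)
    return np.column_stack(iu)


@dataclass(frozen=True)
class DFCStack:
    """Per-subject stack of vectorized Fisher-z connectivity windows."""

    z: np.ndarray                    # windows x links
    windows: list[Window]
    n_components: int

    def __post_init__(self) -> None:
        if self.z.shape != (len(self.windows), n_links(self.n_components)):
            raise ValueError("z must be (n_windows, C(C-1)/2)")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]

    @property
    def tasks(self) -> list[str]:
        return [w.task for w in self.windows]

    def matrix(self, window_idx: int) -> np.ndarray:
        return devectorize(self.z[window_idx], self.n_components)


def windowed_connectivity(
    ts: ComponentTimeSeries,
    windows: list[Window],
    clip_eps: float = 1e-6,
) -> DFCStack:
    """Pearson correlation of each window's time series, Fisher transformed.

    r is clipped to [-1 + clip_eps, 1 - clip_eps] before atanh so z stays
    finite; a component with zero variance inside a window contributes r = 0
    for all its pairs (keeping the link dimension constant).
    """
    if not (0 < clip_eps <= 0.01):
        raise ValueError("clip_eps must be in (0, 0.01]")
    if any(w.length_tr < 3 for w in windows):
        raise ValueError("windows must span at least 3 TRs")
    C = ts.n_components
    iu = np.triu_indices(C, k=1)
    rows = np.empty((len(windows), n_links(C)))
    for k, w in enumerate(windows):
        seg = ts.data[w.start_tr:w.end_tr]
        dead = seg.std(axis=0) == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(seg, rowvar=False)
        if dead.any():
            logger.warning("window %d: %d zero-variance components, r set to 0",
                           w.index, int(dead.sum()))
            r[dead, :] = 0.0
            r[:, dead] = 0.0
        r = np.clip(r[iu], -1 + clip_eps, 1 - clip_eps)
        rows[k] = np.arctanh(r)
    return DFCStack(z=rows, windows=list(windows), n_components=C)


def qc_low_variability(stack: DFCStack, threshold_r: float = 0.95) -> tuple[bool, dict]:
    """Flag a subject whose windowed connectivity barely varies.

    Computes the mean pairwise Pearson correlation among all window vectors;
    a subject with mean >= threshold_r carries almost no dynamic information
    and should be excluded (the screen the original analysis applied
    qualitatively).
    """
    if stack.n_windows < 2:
        raise ValueError("need at least 2 windows")
    r = np.corrcoef(stack.z)
    iu = np.triu_indices(stack.n_windows, k=1)
    mean_r = float(r[iu].mean())
    flagged = mean_r >= threshold_r
    if flagged:
        logger.warning("low-variability QC: mean pairwise r=%.3f >= %.3f",
                       mean_r, threshold_r)
    return flagged, {"mean_pairwise_r": mean_r, "threshold_r": threshold_r,
                     "n_windows": stack.n_windows}
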