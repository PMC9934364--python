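"""Window-averaged cell-shape ground truth from label images.

A label image is an integer raster in which each cell carries one positive ID
and boundary/background pixels are 0.  For each 128x128 window the per-cell
second central moment (inertia) matrices are averaged, the averaged matrix is
eigendecomposed, and the window is summarized by the full axes of the
equivalent ellipse, L = 4*sqrt(lambda_1) and l = 4*sqrt(lambda_2), plus the
major-axis orientation alpha in [0, pi).

Coordinate conventions: 0-based (row, col) pixel indices; x is the column
axis, y the row axis; angles are measured from +x toward +y and reported
modulo pi.  A uniform ellipse with semi-axes (a, b) has second moments
(a^2/4, b^2/4), hence the factor 4 mapping eigenvalues back to full axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "CellMoments",
    "ShapeTargets",
    "Window",
    "EmptyWindowError",
    "cell_moments",
    "window_shape",
    "tile_image",
    "anisotropy",
    "targets_table",
]

#: relative eigenvalue gap below which the orientation is flagged degenerate
DEGENERACY_RTOL = 1e-12


class EmptyWindowError(ValueError):
    """Raised when a window contains no cell pixels."""


@dataclass(frozen=True)
class Window:
    """A square window fully inside an image; 0-based, half-open."""

    row: int
    col: int
    size: int = 128


@dataclass(frozen=True)
class CellMoments:
    """Area, centroid and 2x2 second central moment matrix of one cell."""

    area: int
    centroid: tuple[float, float]  # (x, y) = (col, row)
    M: np.ndarray  # [[var_x, cov_xy], [cov_xy, var_y]]


@dataclass(frozen=True)
class ShapeTargets:
    """Averaged-cell ellipse of one window: full axes (px) and orientation."""

    L: float
    l: float
    alpha: float
    n_cells: int = 0
    degenerate: bool = False


def anisotropy(targets) -> float:
    """Anisotropy of an averaged cell, defined as L/l - 1 (0 for a disc)."""
    L, l = (targets.L, targets.l) if isinstance(targets, ShapeTargets) else targets
    if l == 0:
        raise ValueError("anisotropy undefined for zero short axis")
    return L / l - 1.0


def cell_moments(labels: np.ndarray, cell_id: int) -> CellMoments:
    """Pixel count, centroid and second central moments of one labelled cell.

    Moments are population moments over the cell's pixel coordinates: the
    (x, x) entry is the variance of the column indices, etc.  A single-pixel
    cell has a zero matrix.
    """
    if cell_id <= 0:
        raise LookupError(f"cell IDs are positive integers, got {cell_id}")
    rows, cols = np.nonzero(labels == cell_id)
    if rows.size == 0:
        raise LookupError(f"cell ID {cell_id} absent from label image")
    x = cols.astype(float)
    y = rows.astype(float)
    cx, cy = x.mean(), y.mean()
    dx, dy = x - cx, y - cy
    M = np.array(
        [[np.mean(dx * dx), np.mean(dx * dy)], [np.mean(dx * dy), np.mean(dy * dy)]]
    )
    return CellMoments(area=int(rows.size), centroid=(cx, cy), M=M)


def _moments_per_label(sub: np.ndarray):
    """Vectorized per-label (count, M) over all positive labels of a window."""
    rows, cols = np.nonzero(sub > 0)
    ids = sub[rows, cols]
    uniq, inv = np.unique(ids, return_inverse=True)
    n = uniq.size
    cnt = np.bincount(inv, minlength=n).astype(float)
    x = cols.astype(float)
    y = rows.astype(float)
    sx = np.bincount(inv, weights=x, minlength=n)
    sy = np.bincount(inv, weights=y, minlength=n)
    sxx = np.bincount(inv, weights=x * x, minlength=n)
    syy = np.bincount(inv, weights=y * y, minlength=n)
    sxy = np.bincount(inv, weights=x * y, minlength=n)
    mx, my = sx / cnt, sy / cnt
    var_x = sxx / cnt - mx * mx
    var_y = syy / cnt - my * my
    cov = sxy / cnt - mx * my
    M = np.empty((n, 2, 2))
    M[:, 0, 0] = var_x
    M[:, 1, 1] = var_y
    M[:, 0, 1] = M[:, 1, 0] = cov
    return uniq, cnt, M


def _shape_from_matrix(M: np.ndarray, n_cells: int) -> ShapeTargets:
    evals, evecs = np.linalg.eigh(M)  # ascending
    lam2, lam1 = float(max(evals[0], 0.0)), float(max(evals[1], 0.0))
    degenerate = (lam1 - lam2) < DEGENERACY_RTOL * max(lam1 + lam2, 1e-300)
    if degenerate:
        alpha = 0.0
    else:
        vx, vy = evecs[0, 1], evecs[1, 1]
        alpha = float(np.mod(np.arctan2(vy, vx), np.pi))
    return ShapeTargets(
        L=4.0 * np.sqrt(lam1),
        l=4.0 * np.sqrt(lam2),
        alpha=alpha,
        n_cells=n_cells,
        degenerate=degenerate,
    )


def window_shape(
    labels: np.ndarray,
    window: Window | None = None,
    *,
    weighting: Literal["per_cell", "area"] = "per_cell",
    min_inside_frac: float = 0.5,
    full_counts: np.ndarray | None = None,
) -> ShapeTargets:
    """Average cell shape of one window of a label image.

    Cells are clipped to the window.  A cell participates if at least
    ``min_inside_frac`` of its total pixels (counted over the whole label
    image) fall inside the window; moments are then computed from the clipped
    pixels.  Matrices are averaged with equal weight per cell by default
    (``weighting="area"`` weights each cell by its clipped pixel count).

    Parameters
    ----------
    labels : ndarray of int
        Full label image (0 = boundary/background).
    window : Window, optional
        Defaults to the whole image.
    full_counts : ndarray, optional
        Precomputed ``np.bincount(labels.ravel())``, to amortize repeated
        calls on the same image.
    """
    if window is None:
        window = Window(0, 0, size=max(labels.shape))
        sub = labels
    else:
        if (
            window.row < 0
            or window.col < 0
            or window.row + window.size > labels.shape[0]
            or window.col + window.size > labels.shape[1]
        ):
            raise ValueError(f"{window} not fully inside image {labels.shape}")
        sub = labels[
            window.row : window.row + window.size,
            window.col : window.col + window.size,
        ]
    uniq, cnt, M = _moments_per_label(sub)
    if uniq.size == 0:
        raise EmptyWindowError(f"no cell pixels in {window}")
    if min_inside_frac > 0.0:
        if full_counts is None:
            full_counts = np.bincount(labels.ravel().astype(np.int64))
        total = full_counts[uniq].astype(float)
        keep = cnt >= min_inside_frac * total
        if not np.any(keep):  # fall back to everything rather than fail
            keep = np.ones_like(keep)
        uniq, cnt, M = uniq[keep], cnt[keep], M[keep]
    if weighting == "per_cell":
        Mbar = M.mean(axis=0)
    elif weighting == "area":
        Mbar = np.einsum("i,ijk->jk", cnt, M) / cnt.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return _shape_from_matrix(Mbar, n_cells=int(uniq.size))


def tile_image(image_shape, tile: int = 128, overlap: float = 0.25):
    """Regular grid of windows covering an image, with clamped trailing row/col.

    The stride is ``round(tile * (1 - overlap))``.  Whenever the last regular
    window does not end exactly at the image edge, an extra window clamped to
    the edge is appended, so the whole image is always covered.  Windows are
    returned in row-major order.
    """
    H, W = image_shape[:2]
    if tile > H or tile > W:
        raise ValueError(f"tile {tile} exceeds image {image_shape}")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    stride = max(1, round(tile * (1.0 - overlap)))

    def origins(extent):
        ks = list(range(0, extent - tile + 1, stride))
        if ks[-1] != extent - tile:
            ks.append(extent - tile)
        return ks

    return [
        Window(r, c, tile) for r in origins(H) for c in origins(W)
    ]


def targets_table(labels: np.ndarray, tile: int = 128, overlap: float = 0.25,
                  **kwargs):
    """Per-window ShapeTargets over a full label image, as a DataFrame.

    Columns: ``tile_id,row,col,L,l,alpha,anisotropy,n_cells``.
    """
    import pandas as pd

    full_counts = np.bincount(labels.ravel().astype(np.int64))
    rows = []
    for i, w in enumerate(tile_image(labels.shape, tile, overlap)):
        t = window_shape(labels, w, full_counts=full_counts, **kwargs)
        rows.append(
            dict(tile_id=i, row=w.row, col=w.col, L=t.L, l=t.l, alpha=t.alpha,
                 anisotropy=anisotropy(t), n_cells=t.n_cells)
        )
    return pd.DataFrame(rows)
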