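"""Seeded synthetic confluent-tissue images with known per-cell shape.

Emulates membrane-labelled epithelium micrographs: confluent polygonal cells
produced by a Voronoi-type tessellation, rendered as thin bright membranes on
a dark background (or inverted), with optional blur and additive noise.  Every
tissue ships with its own label image, so the downstream ground-truth,
training and mapping stages are testable without any experimental data.

Anisotropy control: each Voronoi seed carries an orientation angle, and pixels
are assigned to the seed that is nearest in a metric compressed by
``sqrt(stretch)`` along that orientation and expanded by the same factor
across it.  The metric ball is then an area-preserving ellipse of axis ratio
``stretch`` aligned with the seed's orientation, so rendered cells are
elongated by approximately that ratio while mean cell area stays fixed.

All randomness derives from a single root seed through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .ground_truth import ShapeTargets, window_shape

__all__ = ["TissueSpec", "SyntheticTissue", "generate_tissue", "make_dataset"]

# fly regime: "a few tens" of cells per 128x128 tile
DEFAULT_MEAN_CELL_AREA = 450.0


@dataclass(frozen=True)
class TissueSpec:
    """Parameters of one synthetic tissue.

    ``orientation_mode`` is one of ``"constant"`` (all cells at ``alpha0``),
    ``"smooth"`` (a slowly varying sinusoidal orientation field around
    ``alpha0``) or ``"random"`` (i.i.d. per-cell orientations).
    """

    height: int = 128
    width: int = 128
    mean_cell_area: float = DEFAULT_MEAN_CELL_AREA
    stretch_factor: float = 1.0
    orientation_mode: Literal["constant", "smooth", "random"] = "constant"
    alpha0: float = 0.0
    membrane_thickness: int = 1
    noise_sigma: float = 0.02  # gray-level fraction of full scale
    blur_sigma: float = 0.6  # pixels
    invert: bool = False
    seed: int = 0

    def validate(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        if self.mean_cell_area <= 0:
            raise ValueError("mean_cell_area must be positive")
        if self.stretch_factor < 1.0:
            raise ValueError("stretch_factor must be >= 1")
        if self.membrane_thickness < 1:
            raise ValueError("membrane_thickness must be >= 1")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise/blur sigmas must be >= 0")
        n = self.height * self.width / self.mean_cell_area
        if n < 4:
            raise ValueError(
                f"image too small: {self.height}x{self.width} holds only "
                f"{n:.1f} cells of mean area {self.mean_cell_area}"
            )


@dataclass(frozen=True)
class SyntheticTissue:
    """A rendered tissue: 8-bit image, label image and per-cell parameters."""

    image: np.ndarray  # uint8, (H, W)
    labels: np.ndarray  # int32, (H, W); 0 = membrane/boundary
    cells: list  # of (id, (x, y) seed point, nominal orientation)
    spec: TissueSpec = None


def _orientation_field(spec: TissueSpec, xs, ys, rng):
    """Per-seed nominal orientations according to the spec's mode."""
    if spec.orientation_mode == "constant":
        return np.full(xs.shape, spec.alpha0 % np.pi)
    if spec.orientation_mode == "random":
        return rng.uniform(0.0, np.pi, size=xs.shape)
    if spec.orientation_mode == "smooth":
        phx, phy = rng.uniform(0, 2 * np.pi, size=2)
        a = spec.alpha0 + 0.35 * (
            np.sin(2 * np.pi * xs / spec.width + phx)
            + np.cos(2 * np.pi * ys / spec.height + phy)
        )
        return np.mod(a, np.pi)
    raise ValueError(f"unknown orientation_mode {spec.orientation_mode!r}")


def _anisotropic_labels(spec, seeds_xy, alphas):
    """Assign every pixel to its nearest seed in the seed's stretched metric."""
    H, W = spec.height, spec.width
    yy, xx = np.mgrid[0:H, 0:W]
    px = xx.ravel().astype(np.float64)
    py = yy.ravel().astype(np.float64)
    s = np.sqrt(spec.stretch_factor)
    cos_a, sin_a = np.cos(alphas), np.sin(alphas)
    n_seeds = seeds_xy.shape[0]

    if n_seeds <= 64:
        cand = np.arange(n_seeds)[None, :].repeat(px.size, axis=0)
    else:
        # prune with an isotropic KD-tree; the anisotropic winner is among the
        # nearest isotropic neighbours for the stretch range used here
        k = min(n_seeds, 24)
        tree = cKDTree(seeds_xy)
        _, cand = tree.query(np.column_stack([px, py]), k=k)
        if cand.ndim == 1:
            cand = cand[:, None]

    dx = px[:, None] - seeds_xy[cand, 0]
    dy = py[:, None] - seeds_xy[cand, 1]
    u = dx * cos_a[cand] + dy * sin_a[cand]  # along the seed's orientation
    v = -dx * sin_a[cand] + dy * cos_a[cand]
    d2 = (u / s) ** 2 + (v * s) ** 2
    winner = cand[np.arange(px.size), np.argmin(d2, axis=1)]
    return (winner + 1).astype(np.int32).reshape(H, W)


def _membrane_mask(labels, thickness):
    right = np.zeros(labels.shape, bool)
    down = np.zeros(labels.shape, bool)
    right[:, :-1] = labels[:, :-1] != labels[:, 1:]
    down[:-1, :] = labels[:-1, :] != labels[1:, :]
    mask = right | down
    if thickness > 1:
        mask = ndimage.binary_dilation(mask, iterations=thickness - 1)
    return mask


def generate_tissue(spec: TissueSpec) -> SyntheticTissue:
    """Render one tissue deterministically from its spec.

    Seed points are a uniform (binomial) point process; labels come from the
    per-seed anisotropic nearest-seed rule; membranes (pixels whose right or
    down neighbour belongs to a different cell, dilated to
    ``membrane_thickness``) are set to label 0 and rendered bright on dark
    cells unless ``invert`` is set.  Blur then additive Gaussian noise are
    applied and the image clipped to [0, 255].
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_pts, rng_alpha, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    H, W = spec.height, spec.width
    n_cells = max(4, round(H * W / spec.mean_cell_area))
    xs = rng_pts.uniform(0, W, size=n_cells)
    ys = rng_pts.uniform(0, H, size=n_cells)
    alphas = _orientation_field(spec, xs, ys, rng_alpha)

    labels = _anisotropic_labels(spec, np.column_stack([xs, ys]), alphas)
    mask = _membrane_mask(labels, spec.membrane_thickness)
    labels = np.where(mask, 0, labels).astype(np.int32)

    img = np.where(mask, 255.0, 0.0)
    if spec.invert:
        img = 255.0 - img
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng_noise.normal(0.0, spec.noise_sigma * 255.0, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    cells = [
        (int(i + 1), (float(xs[i]), float(ys[i])), float(alphas[i]))
        for i in range(n_cells)
    ]
    return SyntheticTissue(image=img, labels=labels, cells=cells, spec=spec)


def make_dataset(
    spec: TissueSpec,
    n_tiles: int,
    tile_size: int = 128,
    *,
    stretch_range=(1.0, 2.5),
    min_cells: int = 3,
):
    """Generate ``n_tiles`` independent tiles with their shape targets.

    Each tile is one freshly rendered ``tile_size`` x ``tile_size`` tissue with
    its orientation drawn uniformly on [0, pi) and its stretch factor drawn
    uniformly from ``stretch_range`` (pass a degenerate range to pin it), so a
    dataset covers the whole target space.  Targets are the window-averaged
    (L, l, alpha) of each tile computed from its own label image.  Tiles with
    fewer than ``min_cells`` cells are regenerated.

    Returns
    -------
    images : uint8 array (n_tiles, tile_size, tile_size)
    targets : DataFrame with columns tile_id, row, col, L, l, alpha
    """
    import pandas as pd

    if n_tiles < 0:
        raise ValueError("n_tiles must be >= 0")
    images = np.empty((n_tiles, tile_size, tile_size), dtype=np.uint8)
    rows = []
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.generate_state(2 * max(n_tiles, 1) + 16) % (2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])
    k = 0
    for i in range(n_tiles):
        for attempt in range(20):
            alpha = rng.uniform(0.0, np.pi)
            stretch = rng.uniform(*stretch_range)
            tile_spec = replace(
                spec,
                height=tile_size,
                width=tile_size,
                alpha0=alpha,
                stretch_factor=stretch,
                seed=int(child_seeds[(k + attempt) % child_seeds.size]),
            )
            tissue = generate_tissue(tile_spec)
            n_cells_present = int(np.max(tissue.labels))
            if n_cells_present >= min_cells:
                break
        k += attempt + 1
        t = window_shape(tissue.labels)
        images[i] = tissue.image
        rows.append(
            dict(tile_id=i, row=0, col=0, L=t.L, l=t.l, alpha=t.alpha)
        )
    targets = pd.DataFrame(
        rows, columns=["tile_id", "row", "col", "L", "l", "alpha"]
    )
    return images, targets
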