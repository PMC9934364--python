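"""Coarse-grained shape maps over large tissue images.

A large image is tiled into 128x128 windows with 25% overlap; a trained model
predicts each window's averaged-cell shape; one map pixel per window, in
window-grid order, gives coarse-grained rasters of L, l, alpha and anisotropy
(L/l - 1).  The same machinery covers the axes-only workflow used for
embryo-scale anisotropy maps: train a 2-output model on the top half of an
annotated image and predict the map of the unseen bottom half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ground_truth import Window, anisotropy, tile_image, window_shape
from .model_zoo import ArchSpec
from .train_eval import ShapeDataset, TrainConfig, final_retrain

__all__ = ["ShapeMap", "LabelOracle", "predict_map", "ground_truth_map",
           "chicken_workflow"]

CHICKEN_ARCH = ArchSpec([(64, 5), (64, 5), (64, 5)], n_outputs=2)


@dataclass
class ShapeMap:
    """Per-window shape grids plus provenance.

    ``L``, ``l``, ``alpha`` and ``anisotropy`` are (map_rows, map_cols)
    arrays; ``alpha`` is NaN for axes-only models.  ``origin_rows`` /
    ``origin_cols`` give each map pixel's window origin in image coordinates.
    """

    L: np.ndarray
    l: np.ndarray
    alpha: np.ndarray
    anisotropy: np.ndarray
    origin_rows: np.ndarray
    origin_cols: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.L.shape

    def to_frame(self):
        rr, cc = np.meshgrid(self.origin_rows, self.origin_cols, indexing="ij")
        return pd.DataFrame(
            dict(
                row=rr.ravel(),
                col=cc.ravel(),
                L=self.L.ravel(),
                l=self.l.ravel(),
                alpha=self.alpha.ravel(),
                anisotropy=self.anisotropy.ravel(),
            )
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def render(self, path, quantity="anisotropy", upsample=None):
        """Write a heatmap PNG of one quantity (visualization only)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        grid = getattr(self, quantity)
        if upsample:
            from scipy.ndimage import zoom

            grid = zoom(grid, upsample, order=1)
        fig, ax = plt.subplots(figsize=(6, 6 * grid.shape[0] / grid.shape[1]))
        im = ax.imshow(grid, cmap="viridis")
        fig.colorbar(im, ax=ax, label=quantity)
        ax.set_title(quantity)
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


class LabelOracle:
    """A perfect predictor backed by the segmentation itself.

    Implements the same ``predict_shapes`` interface as a trained model but
    reads the ground truth from label-image windows; used to validate map
    assembly and as a reference in comparisons.
    """

    def __init__(self, full_labels: np.ndarray):
        self._counts = np.bincount(full_labels.ravel().astype(np.int64))

    def predict_shapes(self, label_tiles):
        L, l, a = [], [], []
        for t in label_tiles:
            st = window_shape(np.asarray(t), full_counts=self._counts,
                              min_inside_frac=0.0)
            L.append(st.L)
            l.append(st.l)
            a.append(st.alpha)
        return np.array(L), np.array(l), np.array(a)


def _window_grid(image_shape, tile, overlap):
    windows = tile_image(image_shape, tile, overlap)
    rows = np.unique([w.row for w in windows])
    cols = np.unique([w.col for w in windows])
    return windows, rows, cols


def predict_map(image, model, *, tile=128, overlap=0.25, scaler=None) -> ShapeMap:
    """Tile an image and assemble per-window model predictions into a map.

    ``model`` is a ``TrainedModel`` (or any object with ``predict_shapes``).
    When both the model's bundled scaler and an explicit ``scaler`` are given
    they must be the same object or share the fingerprint — a mismatch means
    predictions would be inverted on the wrong scale.
    """
    if scaler is not None and getattr(model, "scaler", None) is not None:
        if model.scaler.fingerprint != scaler.fingerprint:
            raise ValueError(
                "scaler fingerprint mismatch: model was trained with a "
                "different axis scaler"
            )
    image = np.asarray(image)
    if image.shape[0] < tile or image.shape[1] < tile:
        raise ValueError(f"image {image.shape} smaller than tile {tile}")
    windows, rows, cols = _window_grid(image.shape, tile, overlap)
    tiles = np.stack(
        [image[w.row : w.row + w.size, w.col : w.col + w.size] for w in windows]
    )
    L, l, alpha = model.predict_shapes(tiles)
    shape = (len(rows), len(cols))
    row_of = {r: i for i, r in enumerate(rows)}
    col_of = {c: i for i, c in enumerate(cols)}
    Lg = np.full(shape, np.nan)
    lg = np.full(shape, np.nan)
    ag = np.full(shape, np.nan)
    for i, w in enumerate(windows):
        Lg[row_of[w.row], col_of[w.col]] = L[i]
        lg[row_of[w.row], col_of[w.col]] = l[i]
        if alpha is not None:
            ag[row_of[w.row], col_of[w.col]] = alpha[i]
    return ShapeMap(
        L=Lg,
        l=lg,
        alpha=ag,
        anisotropy=Lg / lg - 1.0,
        origin_rows=rows,
        origin_cols=cols,
        provenance=dict(
            tile=tile,
            overlap=overlap,
            model=getattr(getattr(model, "arch", None), "to_json", lambda: "oracle")(),
            scaler=getattr(getattr(model, "scaler", None), "fingerprint", None),
        ),
    )


def ground_truth_map(labels, *, tile=128, overlap=0.25, **kwargs) -> ShapeMap:
    """The reference map: window_shape evaluated on every window."""
    windows, rows, cols = _window_grid(labels.shape, tile, overlap)
    full_counts = np.bincount(labels.ravel().astype(np.int64))
    shape = (len(rows), len(cols))
    row_of = {r: i for i, r in enumerate(rows)}
    col_of = {c: i for i, c in enumerate(cols)}
    Lg = np.full(shape, np.nan)
    lg = np.full(shape, np.nan)
    ag = np.full(shape, np.nan)
    for w in windows:
        st = window_shape(labels, w, full_counts=full_counts, **kwargs)
        Lg[row_of[w.row], col_of[w.col]] = st.L
        lg[row_of[w.row], col_of[w.col]] = st.l
        ag[row_of[w.row], col_of[w.col]] = st.alpha
    return ShapeMap(L=Lg, l=lg, alpha=ag, anisotropy=Lg / lg - 1.0,
                    origin_rows=rows, origin_cols=cols,
                    provenance=dict(tile=tile, overlap=overlap, model="ground_truth"))


def split_top_bottom(image, labels, tile=128):
    """Split an annotated image into spatially disjoint halves at mid-height.

    The split line is placed at H//2; windows are taken inside each half
    separately, so no window crosses the line.
    """
    H = image.shape[0]
    h2 = H // 2
    return (image[:h2], labels[:h2]), (image[h2:], labels[h2:])


def chicken_workflow(
    image,
    labels,
    *,
    arch: ArchSpec = CHICKEN_ARCH,
    tile=128,
    overlap=0.25,
    config: TrainConfig | None = None,
    val_fraction=0.2,
):
    """Axes-only mapping: train on the top half, map the unseen bottom half.

    Builds the 2-output variant (no orientation head), computes ground truth
    for every training window from the segmentation, trains once with
    ``val_fraction`` held out for early stopping, then predicts the bottom
    half's anisotropy map.  Returns (map, trained model, report dict).
    """
    config = config or TrainConfig()
    (img_top, lab_top), (img_bot, lab_bot) = split_top_bottom(image, labels, tile)
    windows, _, _ = _window_grid(lab_top.shape, tile, overlap)
    full_counts = np.bincount(lab_top.ravel().astype(np.int64))
    tiles, rows = [], []
    for w in windows:
        st = window_shape(lab_top, w, full_counts=full_counts)
        tiles.append(img_top[w.row : w.row + w.size, w.col : w.col + w.size])
        rows.append(dict(L=st.L, l=st.l))
    train = ShapeDataset(np.stack(tiles), pd.DataFrame(rows))
    model = final_retrain(arch, train, config, val_fraction=val_fraction)
    shape_map = predict_map(img_bot, model, tile=tile, overlap=overlap)
    truth = ground_truth_map(lab_bot, tile=tile, overlap=overlap)
    report = dict(
        n_train_windows=len(train),
        map_shape=shape_map.shape,
        mae_anisotropy=float(
            np.nanmean(np.abs(shape_map.anisotropy - truth.anisotropy))
        ),
    )
    return shape_map, model, report
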