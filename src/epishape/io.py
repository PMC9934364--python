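"""Reading and writing images, labels, targets and trained models.

Images are 8-bit grayscale PNG/TIFF; label images 16-bit TIFF; targets CSV
with the header ``tile_id,row,col,L,l,alpha``.  A trained model is a
directory of three text/array files: the architecture JSON, the axis-scaler
JSON and the weight arrays (NPZ).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .encoding import AxisScaler
from .model_zoo import ArchSpec, build_cnn
from .train_eval import TrainedModel

__all__ = [
    "write_image",
    "read_image",
    "write_labels",
    "read_labels",
    "save_model",
    "load_model",
]


def write_image(path, image):
    import imageio.v3 as iio

    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise TypeError("images are written as 8-bit grayscale")
    iio.imwrite(path, image)


def read_image(path):
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:  # collapse accidental RGB
        img = img[..., 0]
    return img.astype(np.uint8)


def write_labels(path, labels):
    import tifffile

    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label IDs must fit in uint16")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels(path):
    import tifffile

    return tifffile.imread(path).astype(np.int32)


def save_model(directory, model: TrainedModel):
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    model.arch.to_json(d / "arch.json")
    model.scaler.to_json(d / "scaler.json")
    np.savez(d / "weights.npz",
             **{f"p{i}": p for i, p in enumerate(model.net.params())})


def load_model(directory) -> TrainedModel:
    d = Path(directory)
    arch = ArchSpec.from_json(d / "arch.json")
    scaler = AxisScaler.from_json(d / "scaler.json")
    net = build_cnn(arch, seed=0)
    with np.load(d / "weights.npz") as z:
        net.set_weights([z[f"p{i}"] for i in range(len(net.params()))])
    return TrainedModel(net=net, arch=arch, scaler=scaler)
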