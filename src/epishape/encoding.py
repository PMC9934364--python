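"""Target and image transforms between physical and network space.

Cell orientation is defined modulo pi: alpha = 0 and alpha = pi are the same
measurement.  A plain squared error on alpha would heavily penalize a
prediction of pi for a ground truth of 0, so the orientation is encoded on the
doubled circle as the pair (cos 2*alpha, sin 2*alpha), which is continuous in
the underlying physical quantity.  The inverse transform is a two-argument
arctangent divided by two.

Axis lengths (long axis L, short axis l, in pixels) are standardized with a
scaler fitted on training data only; the encoded (cos, sin) pair is already
bounded in [-1, 1] and is left untouched.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "encode_orientation",
    "decode_orientation",
    "AxisScaler",
    "normalize_image",
    "circular_squared_error",
    "fold_angle_difference",
]


def encode_orientation(alpha):
    """Encode an orientation (radians, modulo pi) as (cos 2a, sin 2a).

    Parameters
    ----------
    alpha : float or array-like
        Orientation(s) in radians.  Reduced modulo pi before doubling.

    Returns
    -------
    (c, s) : ndarray or float pair with c**2 + s**2 == 1 up to rounding.
    """
    a = np.mod(np.asarray(alpha, dtype=float), np.pi)
    return np.cos(2.0 * a), np.sin(2.0 * a)


def decode_orientation(c, s):
    """Invert the doubled-angle encoding: alpha = atan2(s, c) / 2 in [0, pi).

    The decoding is invariant under positive rescaling of (c, s), so model
    predictions need not lie exactly on the unit circle.

    Raises
    ------
    ValueError
        If any (c, s) pair is exactly (0, 0) — the orientation is undefined.
    """
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any((c == 0.0) & (s == 0.0)):
        raise ValueError("orientation undefined for (c, s) == (0, 0)")
    alpha = 0.5 * np.arctan2(s, c)
    alpha = np.mod(alpha, np.pi)
    if alpha.ndim == 0:
        return float(alpha)
    return alpha


def fold_angle_difference(alpha_pred, alpha_true):
    """Signed orientation difference folded into [-pi/2, pi/2).

    This is the natural distance on orientations defined modulo pi; its
    absolute value is the orientation error used in all MAE reports.
    """
    d = np.asarray(alpha_pred, dtype=float) - np.asarray(alpha_true, dtype=float)
    return np.mod(d + np.pi / 2.0, np.pi) - np.pi / 2.0


def circular_squared_error(alpha_pred, alpha_true):
    """Squared orientation error modulo pi, bounded by (pi/2)**2.

    Used by the alternative "mixed" training strategy that regresses the raw
    angle with a periodic loss instead of the (cos, sin) encoding.
    """
    d = fold_angle_difference(alpha_pred, alpha_true)
    return d * d


@dataclass
class AxisScaler:
    """Standard scaler for the two axis targets, fitted on training data only.

    Stores a fingerprint of the data it was fitted on so that leakage (refits
    on validation/test folds) can be asserted downstream.
    """

    mean_L: float = 0.0
    std_L: float = 1.0
    mean_l: float = 0.0
    std_l: float = 1.0
    fingerprint: str = ""

    def fit(self, L, l):
        L = np.asarray(L, dtype=float)
        l = np.asarray(l, dtype=float)
        if L.size < 2:
            raise ValueError("need at least 2 training samples to fit the scaler")
        sL, sl = float(np.std(L)), float(np.std(l))
        if sL == 0.0 or sl == 0.0:
            raise ValueError("zero variance in axis targets; scaler undefined")
        self.mean_L, self.std_L = float(np.mean(L)), sL
        self.mean_l, self.std_l = float(np.mean(l)), sl
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(L).tobytes())
        h.update(np.ascontiguousarray(l).tobytes())
        self.fingerprint = h.hexdigest()[:16]
        return self

    def transform(self, L, l):
        L = np.asarray(L, dtype=float)
        l = np.asarray(l, dtype=float)
        return (L - self.mean_L) / self.std_L, (l - self.mean_l) / self.std_l

    def inverse_transform(self, zL, zl):
        zL = np.asarray(zL, dtype=float)
        zl = np.asarray(zl, dtype=float)
        return zL * self.std_L + self.mean_L, zl * self.std_l + self.mean_l

    # -- serialization -----------------------------------------------------
    def to_json(self, path):
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path):
        return cls(**json.loads(Path(path).read_text()))


def normalize_image(tile, *, allow_cast=False):
    """Map an 8-bit grayscale tile to floats in [0, 1] by dividing by 255.

    The divisor is the fixed 8-bit maximum, never the per-image maximum, so
    that absolute gray levels remain comparable across tiles.
    """
    tile = np.asarray(tile)
    if tile.dtype != np.uint8:
        if not allow_cast:
            raise TypeError(
                f"expected an 8-bit image, got dtype {tile.dtype}; "
                "pass allow_cast=True to cast explicitly"
            )
        tile = tile.astype(np.uint8)
    return tile.astype(np.float32) / np.float32(255.0)
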