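"""Independent brute-force oracles used to validate the vectorized code."""

import numpy as np

from epishape.ground_truth import Window


def naive_window_shape(labels, window=None, min_inside_frac=0.5):
    """Double-loop pixel implementation of the window-averaged cell shape.

    Equal per-cell weighting; cells clipped to the window and included when
    at least ``min_inside_frac`` of their pixels (counted over the whole
    image) fall inside.  Returns (L, l, alpha).
    """
    if window is None:
        window = Window(0, 0, max(labels.shape))
        sub = labels
    else:
        sub = labels[window.row : window.row + window.size,
                     window.col : window.col + window.size]
    totals = {}
    H, W = labels.shape
    for i in range(H):
        for j in range(W):
            v = int(labels[i, j])
            if v > 0:
                totals[v] = totals.get(v, 0) + 1
    pix = {}
    for i in range(sub.shape[0]):
        for j in range(sub.shape[1]):
            v = int(sub[i, j])
            if v > 0:
                pix.setdefault(v, []).append((j, i))  # (x, y)

    def moment(pts):
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        cx, cy = sum(xs) / len(xs), sum(ys) / len(ys)
        mxx = sum((x - cx) ** 2 for x in xs) / len(xs)
        myy = sum((y - cy) ** 2 for y in ys) / len(ys)
        mxy = sum((x - cx) * (y - cy) for x, y in pts) / len(pts)
        return np.array([[mxx, mxy], [mxy, myy]])

    mats = [
        moment(pts)
        for v, pts in sorted(pix.items())
        if len(pts) >= min_inside_frac * totals[v]
    ]
    if not mats:  # all cells mostly outside: fall back to every clipped cell
        mats = [moment(pts) for _, pts in sorted(pix.items())]
    M = sum(mats) / len(mats)
    evals, evecs = np.linalg.eigh(M)
    alpha = float(np.mod(np.arctan2(evecs[1, 1], evecs[0, 1]), np.pi))
    return 4 * np.sqrt(evals[1]), 4 * np.sqrt(max(evals[0], 0)), alpha
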