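"""Self-contained brute-force oracles used by the acceptance suite.

Everything here is written as direct loops/enumeration over voxels so it is
independent of the library implementations it checks.
"""

import numpy as np

_NEIGHBOR_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def voxel_tallies(gt, pr):
    """(tp, fp, tn, fn) by per-voxel enumeration."""
    tp = fp = tn = fn = 0
    for g, p in zip(np.asarray(gt, bool).ravel(), np.asarray(pr, bool).ravel()):
        if g and p:
            tp += 1
        elif p:
            fp += 1
        elif g:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def _boundary_points(mask):
    """Foreground voxels with a 6-connected background or out-of-volume neighbor."""
    mask = np.asarray(mask, bool)
    pts = []
    for idx in np.argwhere(mask):
        for off in _NEIGHBOR_OFFSETS:
            nb = idx + off
            if np.any(nb < 0) or np.any(nb >= mask.shape) or not mask[tuple(nb)]:
                pts.append(idx)
                break
    return np.array(pts, dtype=float)


def all_pairs_hd95(gt, pr, spacing):
    """95th percentile (linear interpolation) of pooled directed distances
    between boundary voxels, from the full O(n^2) distance matrix; None when
    either mask is empty."""
    gt, pr = np.asarray(gt, bool), np.asarray(pr, bool)
    if not gt.any() or not pr.any():
        return None
    spacing = np.asarray(spacing, float)
    a = _boundary_points(gt) * spacing
    b = _boundary_points(pr) * spacing
    dmat = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([dmat.min(axis=1), dmat.min(axis=0)])
    return float(np.percentile(pooled, 95))
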