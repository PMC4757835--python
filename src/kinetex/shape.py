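"""Lesion shape and margin features from the binary mask.

Six radial-distance morphology features quantify roundness, smoothness and
spiculation of the lesion margin.  With d(i) the distances from the mask
centroid to the N traced boundary points and rho(i) = d(i)/max(d):

* area overlap ratio        = area / (pi * max(d)^2)
* variance of distance ratio = var(rho)
* compactness               = -perimeter^2 / (4 * pi * area)
* smoothness                = mean |d(i) - (d(i-1)+d(i+1))/2| / max(d)
* normalized average radial distance ratio = mean(rho)
* standard deviation of normalized distance ratio = std(rho)

Compactness carries a negative sign so that more spiculated margins give
lower (more negative) values, matching the reporting convention in the
breast-MRI radiomics literature this feature set comes from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RoiMask, ValidationError


@dataclass(frozen=True)
class BoundaryProfile:
    """Traced boundary plus its radial-distance signature.

    ``distances`` is the radial-distance signature: the centroid-to-boundary
    distance resampled at N evenly spaced polar angles (outermost boundary
    point per angular bin, circularly interpolated across empty bins).
    Resampling at fixed angles decouples the signature from pixel-level
    staircase jitter, which would otherwise dominate the smoothness and
    variance measures and make them resolution-dependent.
    """

    centroid: tuple[float, float]
    boundary: np.ndarray          # (M, 2) ordered boundary pixel coords
    distances: np.ndarray         # (N,) radial-distance signature, px
    perimeter: float              # px
    area: float                   # px^2 (foreground pixel count)


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered boundary pixel coordinates via Moore neighbourhood tracing."""
    rows, cols = np.nonzero(mask)
    start = (rows[0], cols[0])  # topmost, then leftmost foreground pixel
    # Moore neighbours in clockwise order starting from the west
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1),
            (0, 1), (1, 1), (1, 0), (1, -1)]
    h, w = mask.shape

    def is_fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    boundary = [start]
    # backtrack point: the neighbour we entered from (west of start)
    prev = (start[0], start[1] - 1)
    cur = start
    while True:
        # index of prev among cur's neighbours
        d = (prev[0] - cur[0], prev[1] - cur[1])
        k = nbrs.index(d)
        nxt = None
        for step in range(1, 9):
            cand_off = nbrs[(k + step) % 8]
            cand = (cur[0] + cand_off[0], cur[1] + cand_off[1])
            if is_fg(cand):
                nxt = cand
                prev = (cur[0] + nbrs[(k + step - 1) % 8][0],
                        cur[1] + nbrs[(k + step - 1) % 8][1])
                break
        if nxt is None:     # isolated pixel (cannot happen: >= 16 px masks)
            break
        cur = nxt
        if cur == start:
            break
        boundary.append(cur)
    return np.array(boundary, dtype=float)


def _radial_signature(boundary: np.ndarray, centroid: np.ndarray,
                      n_samples: int) -> np.ndarray:
    """Outer boundary distance at n_samples evenly spaced polar angles."""
    dy = boundary[:, 0] - centroid[0]
    dx = boundary[:, 1] - centroid[1]
    dist = np.hypot(dy, dx)
    ang = np.arctan2(dy, dx) % (2 * np.pi)
    bins = np.floor(ang / (2 * np.pi) * n_samples).astype(int) % n_samples
    sig = np.full(n_samples, -np.inf)
    np.maximum.at(sig, bins, dist)
    sig[np.isinf(sig)] = np.nan
    if np.isnan(sig).any():
        # circular linear interpolation across empty angular bins
        idx = np.arange(n_samples)
        good = ~np.isnan(sig)
        sig = np.interp((idx + 0.5), np.concatenate([
            idx[good] + 0.5, idx[good][:1] + 0.5 + n_samples]),
            np.concatenate([sig[good], sig[good][:1]]),
            period=n_samples)
    return sig


def boundary_profile(mask: RoiMask, n_samples: int = 128) -> BoundaryProfile:
    """Trace the lesion boundary and build its radial-distance signature.

    Raises if the mask touches the image edge, where the boundary would be
    ill-defined.
    """
    m = mask.mask
    if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
        raise ValidationError("mask touches the image edge; boundary "
                              "ill-defined")
    boundary = _trace_boundary(m)
    if len(boundary) < 8:
        raise ValidationError("boundary too short (< 8 points)")
    centroid = np.array(np.nonzero(m), dtype=float).mean(axis=1)
    d_trace = np.hypot(boundary[:, 0] - centroid[0],
                       boundary[:, 1] - centroid[1])
    if np.any(d_trace <= 0):
        raise ValidationError("degenerate boundary: centroid on boundary")
    d = _radial_signature(boundary, centroid, n_samples)
    steps = np.diff(np.vstack([boundary, boundary[:1]]), axis=0)
    perimeter = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    return BoundaryProfile(centroid=(float(centroid[0]), float(centroid[1])),
                           boundary=boundary, distances=d,
                           perimeter=perimeter, area=float(m.sum()))


def shape_features(mask: RoiMask) -> dict[str, float]:
    """The six radial-distance shape features (see module docstring)."""
    prof = boundary_profile(mask)
    d = prof.distances
    dmax = float(d.max())
    rho = d / dmax
    prev_ = np.roll(d, 1)
    next_ = np.roll(d, -1)
    smoothness = float(np.mean(np.abs(d - (prev_ + next_) / 2)) / dmax)
    return {
        "shape.area_overlap_ratio": prof.area / (np.pi * dmax ** 2),
        "shape.var_distance_ratio": float(np.var(rho)),
        "shape.compactness": -prof.perimeter ** 2 / (4 * np.pi * prof.area),
        "shape.smoothness": smoothness,
        "shape.norm_avg_radial_distance": float(np.mean(rho)),
        "shape.std_norm_distance_ratio": float(np.std(rho)),
    }
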