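"""Sliding-window grey-level co-occurrence (Haralick) feature maps.

Per pixel, a GLCM is accumulated over a small centred window (clipped at
the image edge) from distance-1 pixel pairs in 4 directions, symmetrized,
and reduced to 13 classical statistics.  The contrast-* statistics are
moments/entropy of the |i-j| marginal, the intensity-* statistics of the
(i+j)/2 marginal; entropies are base 2 with the 0*log0 = 0 convention.

The kernel is numba-compiled: a lesion bounding box holds a few thousand
pixels and each needs its own few-thousand-entry GLCM, which is far too
slow in pure Python.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_FEATURES = 13

# feature order; must match registry.HARALICK_FEATURES
# 0 contrast_energy       1 contrast_inverse_moment  2 contrast_average
# 3 contrast_variance     4 contrast_entropy         5 intensity_average
# 6 intensity_variance    7 intensity_entropy        8 entropy
# 9 energy               10 correlation             11 info_measure1
# 12 info_measure2

_OFFSETS = np.array([[0, 1], [1, 0], [1, 1], [1, -1]], dtype=np.int64)
_LOG2 = np.log(2.0)


@njit(cache=False)
def _features_from_glcm(glcm, levels, out, pix):
    total = 0.0
    for a in range(levels):
        for b in range(levels):
            total += glcm[a, b]
    if total <= 0:
        for f in range(N_FEATURES):
            out[pix, f] = 0.0
        return

    px = np.zeros(levels)
    pd = np.zeros(levels)
    ps = np.zeros(2 * levels - 1)
    entropy = 0.0
    energy = 0.0
    inv_moment = 0.0
    mean_x = 0.0
    corr_num = 0.0
    for a in range(levels):
        for b in range(levels):
            p = glcm[a, b] / total
            if p > 0:
                px[a] += p
                pd[abs(a - b)] += p
                ps[a + b] += p
                entropy -= p * np.log(p) / _LOG2
                energy += p * p
                inv_moment += p / (1.0 + (a - b) * (a - b))
                corr_num += a * b * p
    for a in range(levels):
        mean_x += a * px[a]
    var_x = 0.0
    hx = 0.0
    for a in range(levels):
        var_x += (a - mean_x) ** 2 * px[a]
        if px[a] > 0:
            hx -= px[a] * np.log(px[a]) / _LOG2

    contrast_energy = 0.0
    contrast_avg = 0.0
    for k in range(levels):
        contrast_energy += k * k * pd[k]
        contrast_avg += k * pd[k]
    contrast_var = 0.0
    contrast_ent = 0.0
    for k in range(levels):
        contrast_var += (k - contrast_avg) ** 2 * pd[k]
        if pd[k] > 0:
            contrast_ent -= pd[k] * np.log(pd[k]) / _LOG2

    intensity_avg = 0.0
    for k in range(2 * levels - 1):
        intensity_avg += 0.5 * k * ps[k]
    intensity_var = 0.0
    intensity_ent = 0.0
    for k in range(2 * levels - 1):
        intensity_var += (0.5 * k - intensity_avg) ** 2 * ps[k]
        if ps[k] > 0:
            intensity_ent -= ps[k] * np.log(ps[k]) / _LOG2

    if var_x > 1e-300:
        correlation = (corr_num - mean_x * mean_x) / var_x
    else:
        correlation = 0.0

    # information measures of correlation (symmetric GLCM: py = px, hy = hx)
    hxy1 = 0.0
    hxy2 = 0.0
    for a in range(levels):
        if px[a] <= 0:
            continue
        for b in range(levels):
            if px[b] <= 0:
                continue
            q = px[a] * px[b]
            lq = np.log(q) / _LOG2
            hxy2 -= q * lq
            p = glcm[a, b] / total
            if p > 0:
                hxy1 -= p * lq
    if hx > 0:
        im1 = (entropy - hxy1) / hx
    else:
        im1 = 0.0
    arg = 2.0 * (hxy2 - entropy)
    if arg < 0:
        arg = 0.0
    im2 = np.sqrt(1.0 - np.exp(-arg))

    out[pix, 0] = contrast_energy
    out[pix, 1] = inv_moment
    out[pix, 2] = contrast_avg
    out[pix, 3] = contrast_var
    out[pix, 4] = contrast_ent
    out[pix, 5] = intensity_avg
    out[pix, 6] = intensity_var
    out[pix, 7] = intensity_ent
    out[pix, 8] = entropy
    out[pix, 9] = energy
    out[pix, 10] = correlation
    out[pix, 11] = im1
    out[pix, 12] = im2


@njit(cache=False)
def _haralick_maps_kernel(q, levels, radius, rows, cols, offsets):
    h, w = q.shape
    n = rows.shape[0]
    out = np.zeros((n, N_FEATURES))
    glcm = np.zeros((levels, levels))
    for pix in range(n):
        r = rows[pix]
        c = cols[pix]
        r0 = max(r - radius, 0)
        r1 = min(r + radius, h - 1)
        c0 = max(c - radius, 0)
        c1 = min(c + radius, w - 1)
        glcm[:, :] = 0.0
        for o in range(offsets.shape[0]):
            dr = offsets[o, 0]
            dc = offsets[o, 1]
            for i in range(r0, r1 + 1):
                ii = i + dr
                if ii < r0 or ii > r1:
                    continue
                for j in range(c0, c1 + 1):
                    jj = j + dc
                    if jj < c0 or jj > c1:
                        continue
                    a = q[i, j]
                    b = q[ii, jj]
                    glcm[a, b] += 1.0
                    glcm[b, a] += 1.0
        _features_from_glcm(glcm, levels, out, pix)
    return out


def quantize(image: np.ndarray, roi: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantize an image to ``levels`` grey levels over the ROI range.

    Values outside the ROI range are clipped into [0, levels-1]; a flat ROI
    maps everything to level 0.
    """
    vals = image[roi]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.int64)
    q = np.floor((image - lo) / (hi - lo) * levels)
    return np.clip(q, 0, levels - 1).astype(np.int64)


def haralick_maps(image: np.ndarray, roi: np.ndarray, levels: int = 64,
                  window: int = 5) -> np.ndarray:
    """13 windowed Haralick features at each ROI pixel, shape (n_roi, 13).

    ``image`` is the (already cropped) lesion bounding box; ``roi`` the
    same-shape boolean ROI membership.  Windows use all box pixels so
    border ROI pixels keep their context.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    q = quantize(image, roi, levels)
    rows, cols = np.nonzero(roi)
    return _haralick_maps_kernel(q, levels, window // 2,
                                 rows.astype(np.int64),
                                 cols.astype(np.int64), _OFFSETS)
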