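"""Dynamic texture descriptors: DHoG and DLBP.

These descriptors summarize how the *spatial pattern* of lesion intensity
evolves over the contrast phases, rather than how its mean evolves.

DHoG (dynamic histogram of oriented gradients): per phase, gradient
orientations of ROI pixels are histogrammed into B even bins over
[0, 360) within the cells of a spatial grid pyramid (1x1, 2x2, 4x4 by
default); cell histograms are aggregated and the per-phase aggregates are
averaged over phases.  One scalar is emitted per bin count B in
{2, 4, 6, 8, 10}.

DLBP (dynamic local binary patterns): per phase, each ROI pixel is encoded
by comparing it with its 8 neighbours into an 8-bit code; per grid cell the
codes are histogrammed into B even bins over 0..255 and normalized; cell
histograms are averaged over phases and concatenated across cells.  One
scalar per B in {8, 16, 32, 64, 128, 256}.

The histogram-to-scalar reduction is Shannon entropy (base 2) of the final
normalized histogram: both descriptors are read as lesion-heterogeneity
measures, and entropy is maximal for lesions whose textural patterns are
spread evenly over many orientation/code channels.  Raw histograms are kept
on the descriptor objects for inspection or alternative reductions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import registry
from .core import DceSeries, RoiMask, ValidationError


@dataclass(frozen=True)
class OrientationField:
    """Per-pixel gradient magnitude and orientation on the bounding box."""

    magnitude: np.ndarray      # >= 0
    orientation: np.ndarray    # degrees in [0, 360); undefined where mag 0
    valid: np.ndarray          # in-ROI and magnitude > 0


@dataclass(frozen=True)
class DhogDescriptor:
    bins: int
    per_phase: np.ndarray      # (T, B) aggregated counts per phase
    averaged: np.ndarray       # (B,) phase-averaged histogram
    scalar: float


@dataclass(frozen=True)
class DlbpDescriptor:
    bins: int
    per_cell: np.ndarray       # (n_cells, B) phase-averaged cell histograms
    concatenated: np.ndarray   # (n_cells * B,)
    scalar: float


def shannon_entropy(hist: np.ndarray) -> float:
    """Base-2 entropy of a non-negative histogram normalized to sum 1."""
    h = np.asarray(hist, dtype=np.float64)
    total = h.sum()
    if total <= 0:
        return 0.0
    p = h[h > 0] / total
    return float(-(p * np.log2(p)).sum())


def orientation_field(image: np.ndarray, roi: np.ndarray) -> OrientationField:
    """Central-difference gradient orientation over the bounding box.

    ``image``/``roi`` are the cropped lesion box and its ROI membership.
    Orientation is atan2(gy, gx) mapped to [0, 360) degrees; pixels with
    zero gradient magnitude have no orientation and are marked invalid.
    """
    img = np.asarray(image, dtype=np.float64)
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    orient = np.degrees(np.arctan2(gy, gx)) % 360.0
    valid = roi & (mag > 0)
    return OrientationField(magnitude=mag, orientation=orient, valid=valid)


def _cell_slices(n_rows: int, n_cols: int, divisions: int):
    """Partition a box into divisions x divisions cells tiling it exactly."""
    r_edges = np.linspace(0, n_rows, divisions + 1).astype(int)
    c_edges = np.linspace(0, n_cols, divisions + 1).astype(int)
    for i in range(divisions):
        for j in range(divisions):
            yield (slice(r_edges[i], r_edges[i + 1]),
                   slice(c_edges[j], c_edges[j + 1]))


def dhog_descriptor(series: DceSeries, mask: RoiMask, bins: int,
                    levels: int = 3,
                    magnitude_weighted: bool = False) -> DhogDescriptor:
    """Multi-grid orientation histogram, phase-averaged.

    Per phase and pyramid level l (2^l x 2^l cells over the bounding box),
    valid-pixel orientations in each cell are counted into ``bins`` even
    channels over [0, 360); the aggregate over all cells and levels totals
    valid_pixels * levels.  Aggregates are averaged over phases and reduced
    to their Shannon entropy.
    """
    if bins < 1:
        raise ValidationError("DHoG bin count must be >= 1")
    if levels < 1:
        raise ValidationError("need at least one pyramid level")
    mask.check_grid(series)
    rs, cs = mask.bounding_box()
    roi = mask.mask[rs, cs]
    edges = np.linspace(0.0, 360.0, bins + 1)
    per_phase = np.zeros((series.n_phases, bins))
    for ti in range(series.n_phases):
        box = series.frames[ti][rs, cs]
        fld = orientation_field(box, roi)
        for lev in range(levels):
            div = 2 ** lev
            for rsl, csl in _cell_slices(*roi.shape, div):
                v = fld.valid[rsl, csl]
                if not v.any():
                    continue
                ori = fld.orientation[rsl, csl][v]
                if magnitude_weighted:
                    wts = fld.magnitude[rsl, csl][v]
                else:
                    wts = None
                hist, _ = np.histogram(ori, bins=edges, weights=wts)
                per_phase[ti] += hist
    averaged = per_phase.mean(axis=0)
    return DhogDescriptor(bins=bins, per_phase=per_phase, averaged=averaged,
                          scalar=shannon_entropy(averaged))


def dhog_features(series: DceSeries, mask: RoiMask,
                  bin_set=tuple(registry.DHOG_BINS),
                  levels: int = 3) -> dict[str, float]:
    """One DHoG entropy scalar per bin configuration (default 5 values)."""
    return {f"dhog.b{b}": dhog_descriptor(series, mask, b, levels).scalar
            for b in bin_set}


def lbp_codes(image: np.ndarray, roi: np.ndarray):
    """8-neighbour local binary pattern codes on the bounding box.

    Bit k is set iff neighbour k >= centre, neighbours ordered clockwise
    from the top-left with the top-left as the most significant bit.
    Codes are valid where the pixel is in the ROI and all 8 neighbours lie
    inside the box.

    Returns (codes, valid), both with the box shape; invalid entries are 0.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    codes = np.zeros((h, w), dtype=np.int64)
    # clockwise from top-left: TL, T, TR, R, BR, B, BL, L
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
               (1, 1), (1, 0), (1, -1), (0, -1)]
    inner = np.zeros((h, w), dtype=bool)
    if h > 2 and w > 2:
        inner[1:-1, 1:-1] = True
    for bit, (dr, dc) in enumerate(offsets):
        nb = np.roll(np.roll(img, -dr, axis=0), -dc, axis=1)
        ge = nb >= img
        codes[inner] |= (ge[inner].astype(np.int64) << (7 - bit))
    valid = roi & inner
    codes[~valid] = 0
    return codes, valid


def dlbp_descriptor(series: DceSeries, mask: RoiMask, bins: int,
                    grid: int = 4) -> DlbpDescriptor:
    """Grid-cell LBP histograms, phase-averaged and concatenated.

    Codes are binned into ``bins`` equal-width channels over 0..255 (256
    bins = one channel per code); per phase each cell histogram is
    normalized to sum 1 (empty cells contribute zeros), cell histograms are
    averaged across phases and concatenated over the fixed ``grid`` x
    ``grid`` cells; the scalar is the Shannon entropy of the renormalized
    concatenation.
    """
    if bins < 1 or bins > 256 or 256 % bins != 0:
        raise ValidationError("DLBP bin count must divide 256")
    mask.check_grid(series)
    rs, cs = mask.bounding_box()
    roi = mask.mask[rs, cs]
    cells = list(_cell_slices(*roi.shape, grid))
    per_cell = np.zeros((len(cells), bins))
    n_nonempty = np.zeros(len(cells))
    width = 256 // bins
    for ti in range(series.n_phases):
        box = series.frames[ti][rs, cs]
        codes, valid = lbp_codes(box, roi)
        binned = codes // width
        for ci, (rsl, csl) in enumerate(cells):
            v = valid[rsl, csl]
            if not v.any():
                continue
            hist = np.bincount(binned[rsl, csl][v], minlength=bins)
            per_cell[ci] += hist / hist.sum()
            n_nonempty[ci] += 1
    # average over the phases in which the cell actually had valid pixels,
    # so every non-empty averaged cell histogram sums to exactly 1
    per_cell = np.where(n_nonempty[:, None] > 0,
                        per_cell / np.maximum(n_nonempty, 1)[:, None], 0.0)
    concatenated = per_cell.reshape(-1)
    return DlbpDescriptor(bins=bins, per_cell=per_cell,
                          concatenated=concatenated,
                          scalar=shannon_entropy(concatenated))


def dlbp_features(series: DceSeries, mask: RoiMask,
                  bin_set=tuple(registry.DLBP_BINS),
                  grid: int = 4) -> dict[str, float]:
    """One DLBP entropy scalar per bin configuration (default 6 values)."""
    return {f"dlbp.b{b}": dlbp_descriptor(series, mask, b, grid).scalar
            for b in bin_set}
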