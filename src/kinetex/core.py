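"""Core data model for 2-D DCE-MRI lesion analysis.

A lesion is represented by a single representative section imaged at T
contrast phases (a ``DceSeries``) together with a binary lesion mask on the
same pixel grid (a ``RoiMask``).  All feature extractors consume these two
objects and emit named scalar features collected into a ``FeatureVector``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class DceSeries:
    """A T x H x W dynamic contrast-enhanced intensity stack.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative signal intensities, one frame per contrast phase.
    times : ndarray, shape (T,)
        Acquisition times in minutes, strictly increasing.  The first frame
        is the pre-contrast baseline and its time is 0 by convention.
    pixel_spacing : tuple of float
        (row, col) in-plane spacing in mm.
    meta : dict
        Free-form provenance strings.
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_spacing: tuple[float, float] = (0.5, 0.5)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=np.float64)
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)
        if frames.ndim != 3:
            raise ValidationError("frames must be a T x H x W array")
        if frames.shape[0] < 4:
            raise ValidationError("need at least 4 contrast phases")
        if times.shape != (frames.shape[0],):
            raise ValidationError("times length must equal number of frames")
        if not np.all(np.isfinite(frames)) or np.any(frames < 0):
            raise ValidationError("intensities must be finite and non-negative")
        if not np.all(np.diff(times) > 0):
            raise ValidationError("acquisition times must be strictly increasing")

    @property
    def n_phases(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def sorted_by_time(self) -> "DceSeries":
        """Return a copy with phases ordered by acquisition time."""
        order = np.argsort(self.times, kind="stable")
        return DceSeries(self.frames[order], self.times[order],
                         self.pixel_spacing, dict(self.meta))


@dataclass(frozen=True)
class RoiMask:
    """Binary H x W lesion mask sharing the grid of its series.

    Invariants: at least 16 foreground pixels and exactly one 8-connected
    component.  Masks touching the image edge are rejected by the boundary
    tracer (shape features) but are legal here.
    """

    mask: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.mask).astype(bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 2:
            raise ValidationError("mask must be 2-D")
        n_fg = int(mask.sum())
        if n_fg < 16:
            raise ValidationError(
                f"mask has {n_fg} foreground pixels; at least 16 required")
        _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n_comp != 1:
            raise ValidationError(
                f"mask has {n_comp} connected components; exactly 1 required")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def bounding_box(self) -> tuple[slice, slice]:
        """Minimal axis-aligned box containing the mask (row/col slices)."""
        rows = np.any(self.mask, axis=1)
        cols = np.any(self.mask, axis=0)
        r0, r1 = np.where(rows)[0][[0, -1]]
        c0, c1 = np.where(cols)[0][[0, -1]]
        return slice(int(r0), int(r1) + 1), slice(int(c0), int(c1) + 1)

    def check_grid(self, series: DceSeries) -> None:
        if self.mask.shape != series.grid_shape:
            raise ValidationError(
                f"mask grid {self.mask.shape} != series grid {series.grid_shape}")


@dataclass
class FeatureVector:
    """Ordered mapping of canonical feature name -> finite scalar value."""

    values: dict[str, float]
    label: str | None = None

    def __post_init__(self):
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValidationError(f"feature {name!r} is not finite: {v}")
        if self.label is not None and self.label not in ("low", "high"):
            raise ValidationError("label must be 'low' or 'high'")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=np.float64)
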