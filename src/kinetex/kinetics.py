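"""Enhancement, intensity and textural kinetics.

Three feature families live here:

EK — four classical enhancement-curve descriptors (maximal uptake, time to
peak, uptake rate, washout rate) of the ROI-mean relative enhancement.

IK — the four coefficients of a third-order polynomial fitted to the
enhancement curve on normalized time u in [0, 1].

TK — 37 per-phase texture statistics of the lesion ROI (first-order window
statistics, Sobel and Kirsch edge responses, windowed Haralick features),
each tracked over the contrast phases and reduced to 4 cubic coefficients:
148 textural-kinetic features in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import registry
from ._haralick import haralick_maps
from .core import DceSeries, RoiMask, ValidationError


@dataclass(frozen=True)
class KineticCurve:
    """One scalar statistic tracked over the contrast phases."""

    name: str
    values: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        t = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", t)
        if v.shape != t.shape:
            raise ValidationError("curve values/times length mismatch")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"curve {self.name!r} has non-finite values")


@dataclass(frozen=True)
class CubicFit:
    """Coefficients of c0 + c1 u + c2 u^2 + c3 u^3 on u in [0, 1]."""

    c0: float
    c1: float
    c2: float
    c3: float

    def as_tuple(self):
        return (self.c0, self.c1, self.c2, self.c3)

    def __call__(self, u):
        return self.c0 + self.c1 * u + self.c2 * u ** 2 + self.c3 * u ** 3


@dataclass(frozen=True)
class TextureConfig:
    """Knobs for the per-phase texture statistics."""

    first_order_windows: tuple[int, ...] = (3, 5, 7)
    glcm_levels: int = 64
    glcm_window: int = 5


KIRSCH_KERNELS = {}


def _build_kirsch():
    base = np.array([[5, 5, 5],
                     [-3, 0, -3],
                     [-3, -3, -3]], dtype=np.float64)
    ring = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    vals = [base[r, c] for r, c in ring]
    for k, label in enumerate(registry.KIRSCH_CHANNELS[:8]):
        kern = np.zeros((3, 3))
        for j, (r, c) in enumerate(ring):
            kern[r, c] = vals[(j - k) % 8]
        KIRSCH_KERNELS[label] = kern


_build_kirsch()


def enhancement_curve(series: DceSeries, mask: RoiMask) -> KineticCurve:
    """ROI-mean relative enhancement E(t) = (m(t) - m(0)) / m(0)."""
    mask.check_grid(series)
    m = series.frames[:, mask.mask].mean(axis=1)
    if m[0] <= 0:
        raise ValidationError("zero baseline mean inside ROI")
    return KineticCurve("enhancement", (m - m[0]) / m[0], series.times)


def ek_features(curve: KineticCurve) -> dict[str, float]:
    """Maximal uptake, time to peak, uptake rate and washout rate.

    Uptake rate is maximal uptake divided by time-to-peak (0 when the peak
    is the baseline); washout rate is the mean decline per minute from the
    peak to the final phase (0 when the peak is the final phase).
    """
    e = curve.values
    t = curve.times
    peak_idx = int(np.argmax(e))
    max_uptake = float(e[peak_idx])
    time_to_peak = float(t[peak_idx] - t[0])
    uptake_rate = max_uptake / time_to_peak if time_to_peak > 0 else 0.0
    if peak_idx < len(e) - 1:
        washout = float((e[peak_idx] - e[-1]) / (t[-1] - t[peak_idx]))
    else:
        washout = 0.0
    return {
        "ek.max_uptake": max_uptake,
        "ek.time_to_peak": time_to_peak,
        "ek.uptake_rate": uptake_rate,
        "ek.washout_rate": washout,
    }


def fit_cubic(curve: KineticCurve) -> CubicFit:
    """Least-squares cubic on normalized time u = (t - t0)/(tN - t0).

    Exactly interpolates when T = 4; times must span a nonzero interval.
    """
    t = curve.times
    if t.size < 4:
        raise ValidationError("cubic fit needs at least 4 phases")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValidationError("degenerate times for cubic fit")
    u = (t - t[0]) / span
    design = np.vander(u, 4, increasing=True)
    coef, *_ = np.linalg.lstsq(design, curve.values, rcond=None)
    return CubicFit(*map(float, coef))


def _first_order_maps(box: np.ndarray, w: int) -> dict[str, np.ndarray]:
    mean = ndimage.uniform_filter(box, size=w, mode="reflect")
    sq = ndimage.uniform_filter(box ** 2, size=w, mode="reflect")
    std = np.sqrt(np.clip(sq - mean ** 2, 0, None))
    rng = (ndimage.maximum_filter(box, size=w, mode="reflect")
           - ndimage.minimum_filter(box, size=w, mode="reflect"))
    med = ndimage.median_filter(box, size=w, mode="reflect")
    return {"mean": mean, "median": med, "range": rng, "std": std}


def texture_per_phase(series: DceSeries, mask: RoiMask,
                      cfg: TextureConfig = TextureConfig()) -> list[KineticCurve]:
    """The 37 per-phase texture curves, in canonical registry order.

    Per phase, per-pixel feature maps are computed on the lesion bounding
    box (so border ROI pixels have neighbours) and averaged over ROI
    pixels.  Families: first-order window statistics (4 stats x 3 window
    sizes), Sobel (|gx|, |gy|, magnitude), Kirsch (8 compass directions +
    magnitude), and 13 windowed Haralick features.
    """
    mask.check_grid(series)
    rs, cs = mask.bounding_box()
    box_h, box_w = rs.stop - rs.start, cs.stop - cs.start
    w_max = max(max(cfg.first_order_windows), cfg.glcm_window)
    if min(box_h, box_w) < w_max:
        raise ValidationError(
            f"ROI bounding box {box_h}x{box_w} smaller than largest texture "
            f"window ({w_max})")
    roi = mask.mask[rs, cs]
    t_n = series.n_phases
    values = {name: np.zeros(t_n) for name in registry.TEXTURE_CURVE_NAMES}

    for ti in range(t_n):
        box = series.frames[ti][rs, cs].astype(np.float64)
        for w in cfg.first_order_windows:
            maps = _first_order_maps(box, w)
            for stat in registry.FIRST_ORDER_STATS:
                values[f"first_order.{stat}.w{w}"][ti] = maps[stat][roi].mean()
        gx = ndimage.sobel(box, axis=1, mode="reflect")
        gy = ndimage.sobel(box, axis=0, mode="reflect")
        values["sobel.gx"][ti] = np.abs(gx)[roi].mean()
        values["sobel.gy"][ti] = np.abs(gy)[roi].mean()
        values["sobel.magnitude"][ti] = np.hypot(gx, gy)[roi].mean()
        responses = []
        for label in registry.KIRSCH_CHANNELS[:8]:
            resp = ndimage.convolve(box, KIRSCH_KERNELS[label], mode="reflect")
            responses.append(resp)
            values[f"kirsch.{label}"][ti] = np.abs(resp)[roi].mean()
        kmag = np.max(np.abs(np.stack(responses)), axis=0)
        values["kirsch.magnitude"][ti] = kmag[roi].mean()
        hara = haralick_maps(box, roi, cfg.glcm_levels, cfg.glcm_window)
        for fi, feat in enumerate(registry.HARALICK_FEATURES):
            values[f"haralick.{feat}"][ti] = hara[:, fi].mean()

    return [KineticCurve(name, values[name], series.times)
            for name in registry.TEXTURE_CURVE_NAMES]


def ik_features(series: DceSeries, mask: RoiMask) -> dict[str, float]:
    """Cubic coefficients of the enhancement curve (IK, 4 values)."""
    fit = fit_cubic(enhancement_curve(series, mask))
    return {f"ik.c{i}": c for i, c in enumerate(fit.as_tuple())}


def tk_features(series: DceSeries, mask: RoiMask,
                cfg: TextureConfig = TextureConfig()) -> dict[str, float]:
    """Cubic coefficients of all 37 texture curves (TK, 148 values)."""
    out: dict[str, float] = {}
    for curve in texture_per_phase(series, mask, cfg):
        fit = fit_cubic(curve)
        for i, c in enumerate(fit.as_tuple()):
            out[f"tk.{curve.name}.c{i}"] = c
    return out


def ik_tk_features(series: DceSeries, mask: RoiMask,
                   cfg: TextureConfig = TextureConfig()):
    """Convenience wrapper returning (IK dict of 4, TK dict of 148)."""
    return ik_features(series, mask), tk_features(series, mask, cfg)
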