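"""Tofts pharmacokinetic modelling of contrast enhancement.

The standard (two-parameter) Tofts model describes the tissue contrast
concentration as

    C(t) = Ktrans * int_0^t Cp(tau) * exp(-kep * (t - tau)) dtau,

with ``Ktrans`` the plasma-to-tissue transfer constant (1/min), ``ve`` the
extravascular-extracellular volume fraction and ``kep = Ktrans / ve``.  The
arterial input function Cp is the Tofts-Kermode biexponential population
curve; with that form the convolution above has a closed form which this
module evaluates exactly (no numerical quadrature error on the time grid).

Relative signal enhancement (S(t) - S(0)) / S(0) is treated as proportional
to C(t), so curves are fitted directly without T1 mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import DceSeries, RoiMask, ValidationError

KTRANS_BOUNDS = (1e-4, 5.0)
VE_BOUNDS = (0.01, 1.0)


@dataclass(frozen=True)
class Aif:
    """Tofts-Kermode biexponential population arterial input function.

    Cp(t) = dose * (a1 * exp(-m1 t) + a2 * exp(-m2 t)), with the dose in
    mmol/kg, amplitudes in kg/L and decay rates in 1/min.  Defaults follow
    the classic population parameterization at a 0.1 mmol/kg gadolinium
    dose.
    """

    dose: float = 0.1
    a1: float = 3.99
    a2: float = 4.78
    m1: float = 0.144
    m2: float = 0.0111

    def __post_init__(self):
        if min(self.dose, self.a1, self.a2, self.m1, self.m2) <= 0:
            raise ValidationError("all AIF parameters must be positive")


@dataclass(frozen=True)
class PkParams:
    """Fitted Tofts parameters; kep is always Ktrans/ve, never fit freely."""

    ktrans: float
    ve: float
    residual: float = 0.0
    flagged: bool = False

    @property
    def kep(self) -> float:
        return self.ktrans / self.ve


def population_aif(t, aif: Aif = Aif()) -> np.ndarray:
    """Plasma concentration Cp(t) of the biexponential population AIF."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValidationError("AIF requires non-negative times")
    return aif.dose * (aif.a1 * np.exp(-aif.m1 * t)
                       + aif.a2 * np.exp(-aif.m2 * t))


def _exp_conv(t, kep, m):
    """int_0^t exp(-m tau) exp(-kep (t-tau)) dtau, elementwise in t.

    Equals (exp(-m t) - exp(-kep t)) / (kep - m), with the t*exp(-m t)
    limit when kep ~ m.
    """
    t = np.asarray(t, dtype=np.float64)
    kep = np.asarray(kep, dtype=np.float64)
    d = kep - m
    small = np.abs(d) < 1e-10
    d_safe = np.where(small, 1.0, d)
    out = (np.exp(-m * t) - np.exp(-kep * t)) / d_safe
    return np.where(small, t * np.exp(-m * t), out)


def tofts_concentration(t, ktrans, ve, aif: Aif = Aif()) -> np.ndarray:
    """Closed-form Tofts tissue concentration for the biexponential AIF."""
    kep = ktrans / ve
    return ktrans * aif.dose * (aif.a1 * _exp_conv(t, kep, aif.m1)
                                + aif.a2 * _exp_conv(t, kep, aif.m2))


def _kep_basis(t, kep_grid, aif: Aif) -> np.ndarray:
    """Unit-Ktrans model curves for a grid of kep values, shape (K, T)."""
    kep = np.asarray(kep_grid)[:, None]
    return aif.dose * (aif.a1 * _exp_conv(t[None, :], kep, aif.m1)
                       + aif.a2 * _exp_conv(t[None, :], kep, aif.m2))


def fit_tofts(curve, times, aif: Aif = Aif(), n_starts: int = 4) -> PkParams:
    """Fit (Ktrans, ve) to a single relative-enhancement curve.

    Bounded nonlinear least squares with ``n_starts`` multi-starts spread
    over the parameter box; the best-residual solution is returned.  A
    near-zero curve cannot constrain the model and is returned flagged with
    Ktrans at its lower bound.
    """
    curve = np.asarray(curve, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if curve.shape != times.shape or curve.size < 4:
        raise ValidationError("curve and times must match, length >= 4")

    scale = float(np.max(np.abs(curve)))
    if scale < 1e-12:
        return PkParams(KTRANS_BOUNDS[0], VE_BOUNDS[1], residual=0.0,
                        flagged=True)

    def resid(p):
        return tofts_concentration(times, p[0], p[1], aif) - curve

    rng_starts = _multi_starts(n_starts)
    best = None
    for x0 in rng_starts:
        try:
            sol = least_squares(resid, x0,
                                bounds=([KTRANS_BOUNDS[0], VE_BOUNDS[0]],
                                        [KTRANS_BOUNDS[1], VE_BOUNDS[1]]),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return PkParams(KTRANS_BOUNDS[0], VE_BOUNDS[1],
                        residual=float("inf"), flagged=True)
    res = float(np.sqrt(2 * best.cost))
    return PkParams(float(best.x[0]), float(best.x[1]), residual=res,
                    flagged=not best.success)


def _multi_starts(n_starts):
    grid = [(0.2, 0.3), (0.05, 0.1), (1.0, 0.5), (0.5, 0.8),
            (0.02, 0.6), (2.0, 0.2), (0.1, 0.9), (0.8, 0.15)]
    return [np.array(g) for g in grid[:max(1, n_starts)]]


def fit_tofts_map(curves, times, aif: Aif = Aif(), n_refine: int = 6,
                  grid_size: int = 25):
    """Vectorized per-pixel Tofts fit via separable kep search.

    For fixed kep the model is linear in Ktrans, so the optimal Ktrans has a
    closed form; the remaining 1-D kep problem is solved by an iteratively
    refined log-spaced grid, vectorized over all pixels.

    Parameters
    ----------
    curves : ndarray, shape (N, T)
        Relative-enhancement curves, one per pixel.
    times : ndarray, shape (T,)

    Returns
    -------
    ktrans, ve, residual, flagged : ndarrays of shape (N,)
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=np.float64))
    times = np.asarray(times, dtype=np.float64)
    n = curves.shape[0]

    kep_lo = np.full(n, KTRANS_BOUNDS[0] / VE_BOUNDS[1])  # 1e-4
    kep_hi = np.full(n, KTRANS_BOUNDS[1] / VE_BOUNDS[0])  # 500
    kep_lo = np.maximum(kep_lo, 1e-4)
    best_kep = np.full(n, 1.0)

    for _ in range(n_refine):
        # per-pixel log grids between current brackets
        frac = np.linspace(0.0, 1.0, grid_size)
        kep_grid = np.exp(np.log(kep_lo)[:, None]
                          + frac[None, :] * (np.log(kep_hi / kep_lo))[:, None])
        # basis for every (pixel, grid point): (N, K, T)
        kep_flat = kep_grid.reshape(-1)
        basis = _kep_basis(times, kep_flat, aif).reshape(n, grid_size, -1)
        bb = np.einsum("nkt,nkt->nk", basis, basis)
        bc = np.einsum("nkt,nt->nk", basis, curves)
        ktr = np.where(bb > 0, bc / np.maximum(bb, 1e-300), 0.0)
        ktr = np.clip(ktr, KTRANS_BOUNDS[0], KTRANS_BOUNDS[1])
        # enforce ve bound: ve = ktrans/kep in [0.01, 1]
        ve_grid = ktr / kep_grid
        ktr = np.where(ve_grid > VE_BOUNDS[1], kep_grid * VE_BOUNDS[1], ktr)
        ktr = np.where(ktr / kep_grid < VE_BOUNDS[0],
                       np.minimum(kep_grid * VE_BOUNDS[0], KTRANS_BOUNDS[1]),
                       ktr)
        sse = np.einsum("nkt->nk", (ktr[:, :, None] * basis
                                    - curves[:, None, :]) ** 2)
        idx = np.argmin(sse, axis=1)
        rows = np.arange(n)
        best_kep = kep_grid[rows, idx]
        lo_idx = np.maximum(idx - 1, 0)
        hi_idx = np.minimum(idx + 1, grid_size - 1)
        kep_lo = kep_grid[rows, lo_idx]
        kep_hi = kep_grid[rows, hi_idx]

    # final closed-form Ktrans at the refined kep
    basis = _kep_basis(times, best_kep, aif)
    bb = np.einsum("nt,nt->n", basis, basis)
    bc = np.einsum("nt,nt->n", basis, curves)
    ktrans = np.where(bb > 0, bc / np.maximum(bb, 1e-300), KTRANS_BOUNDS[0])
    ktrans = np.clip(ktrans, *KTRANS_BOUNDS)
    ve = np.clip(ktrans / best_kep, *VE_BOUNDS)
    ktrans = np.clip(ve * best_kep, *KTRANS_BOUNDS)
    resid = np.sqrt(np.sum((ktrans[:, None] * basis - curves) ** 2, axis=1))
    scale = np.max(np.abs(curves), axis=1)
    flagged = scale < 1e-12
    return ktrans, ve, resid, flagged


def relative_enhancement(series: DceSeries, mask: RoiMask) -> np.ndarray:
    """Per-pixel relative enhancement curves over ROI pixels, shape (N, T)."""
    mask.check_grid(series)
    sig = series.frames[:, mask.mask].T  # (N, T)
    s0 = sig[:, 0]
    if np.any(s0 <= 0):
        raise ValidationError("non-positive baseline signal inside ROI")
    return (sig - s0[:, None]) / s0[:, None]


def pk_features(series: DceSeries, mask: RoiMask, aif: Aif = Aif(),
                return_maps: bool = False):
    """ROI-mean Tofts parameters (Ktrans, ve, kep) from per-pixel fits.

    Each ROI pixel's relative-enhancement curve is fitted independently and
    features are the means over pixels with successful fits.  If more than
    half the pixels fail (flat curves), the series is deemed unusable.
    """
    curves = relative_enhancement(series, mask)
    ktrans, ve, resid, flagged = fit_tofts_map(curves, series.times, aif)
    ok = ~flagged
    if ok.sum() <= 0.5 * len(flagged):
        raise ValidationError(
            f"{int(flagged.sum())}/{len(flagged)} pixel fits failed; "
            "series unusable for PK features")
    feats = {
        "pk.ktrans": float(np.mean(ktrans[ok])),
        "pk.ve": float(np.mean(ve[ok])),
        "pk.kep": float(np.mean(ktrans[ok] / ve[ok])),
    }
    if not return_maps:
        return feats
    maps = {}
    for name, vals in (("ktrans", ktrans), ("ve", ve), ("kep", ktrans / ve)):
        m = np.full(mask.mask.shape, np.nan)
        m[mask.mask] = vals
        maps[name] = m
    return feats, maps
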