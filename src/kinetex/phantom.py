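"""Synthetic DCE-MRI lesion and cohort generator with known ground truth.

Emulates the acquisition envelope of 1.5 T breast DCE-MRI protocols: 5-10
contrast phases roughly a minute apart, in-plane spacing 0.2-0.8 mm, lesion
diameters 5-50 mm, and contrast wash-in/wash-out governed by the Tofts
model driven by a population AIF.  Lesions are star-convex masks with a
controllable spiculation amplitude; the Ktrans field inside the lesion is a
log-normal random field with a controllable spatial coefficient of
variation (heterogeneity).  Two-class cohorts separate low- from high-risk
lesions through effect sizes on heterogeneity, spiculation and mean Ktrans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DceSeries, RoiMask, ValidationError
from .pk import Aif, tofts_concentration


@dataclass(frozen=True)
class LesionShapeParams:
    """Star-convex lesion outline: r(theta) = R * (1 + s * perturbation)."""

    mean_radius_mm: float = 6.0
    spiculation: float = 0.0
    n_lobes: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.mean_radius_mm <= 0 or self.spiculation < 0 or self.n_lobes < 0:
            raise ValidationError("invalid lesion shape parameters")


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner-side simulation knobs (all inside the printed site envelopes)."""

    n_phases: int = 7
    dt_min: float = 1.0
    pixel_spacing_mm: float = 0.5
    s0: float = 100.0
    noise_sd: float = 2.0          # absolute, default 2% of s0
    gamma: float = 1.0             # signal units per mmol/L of contrast
    rician: bool = False

    def __post_init__(self):
        if self.n_phases < 5:
            raise ValidationError("need at least 5 phases")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.dt_min


@dataclass(frozen=True)
class PkField:
    """Ground-truth per-pixel Tofts parameter maps."""

    ktrans_map: np.ndarray
    ve_map: np.ndarray

    @property
    def kep_map(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.ve_map > 0,
                            self.ktrans_map / np.where(self.ve_map > 0,
                                                       self.ve_map, 1.0),
                            0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Two-class cohort description.

    The low-risk class uses the ``base_*`` parameters; the high-risk class
    shifts them by the corresponding ``effect_*`` deltas.  Lesion radii are
    drawn uniformly from ``radius_range_mm`` for both classes.
    """

    n_low: int = 20
    n_high: int = 20
    base_heterogeneity: float = 0.10
    base_spiculation: float = 0.08
    base_ktrans: float = 0.15
    effect_heterogeneity: float = 0.0
    effect_spiculation: float = 0.0
    effect_ktrans: float = 0.0
    radius_range_mm: tuple[float, float] = (3.5, 7.5)
    ve_range: tuple[float, float] = (0.25, 0.55)
    within_class_jitter: float = 0.15   # relative sd of per-lesion params
    # acquisition nuisances shared by both classes: per-lesion receiver
    # gain (arbitrary MRI signal units) and phase-count variability
    gain_range: tuple[float, float] = (0.6, 1.6)
    phase_range: tuple[int, int] = (6, 8)
    spacing_range_mm: tuple[float, float] = (0.4, 0.8)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_low < 2 or self.n_high < 2:
            raise ValidationError("need at least 2 lesions per class")


def strong_effects(seed: int = 0, n_low: int = 30, n_high: int = 30,
                   **kw) -> CohortSpec:
    """A cohort with pronounced class differences in heterogeneity,
    spiculation and mean Ktrans (high class: CV 0.5 vs 0.05, etc.)."""
    return CohortSpec(n_low=n_low, n_high=n_high,
                      base_heterogeneity=0.05, effect_heterogeneity=0.45,
                      base_spiculation=0.08, effect_spiculation=0.08,
                      base_ktrans=0.15, effect_ktrans=0.0,
                      seed=seed, **kw)


def make_lesion_mask(p: LesionShapeParams, grid_shape=None,
                     pixel_spacing_mm: float = 0.5) -> RoiMask:
    """Rasterize a star-convex lesion outline onto a pixel grid.

    The boundary radius is r(theta) = R * (1 + s * f(theta)) where f is a
    seeded random sum of ``n_lobes`` sine harmonics with unit RMS amplitude,
    clipped so r stays positive; a pixel belongs to the mask iff its centre
    lies within r(theta) of the lesion centre.
    """
    r_px = p.mean_radius_mm / pixel_spacing_mm
    if r_px < 4:
        raise ValidationError(
            f"mean radius {r_px:.1f} px too small; need >= 4 px on this grid")
    rng = np.random.default_rng(p.seed)
    amps = rng.standard_normal(max(p.n_lobes, 1))
    phases = rng.uniform(0, 2 * np.pi, max(p.n_lobes, 1))
    if p.n_lobes == 0 or p.spiculation == 0:
        amps = np.zeros_like(amps)
    rms = np.sqrt(np.mean(amps ** 2)) if np.any(amps) else 1.0
    amps = amps / rms if rms > 0 else amps

    theta_fine = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    pert_fine = np.zeros_like(theta_fine)
    for k in range(1, p.n_lobes + 1):
        pert_fine += amps[k - 1] * np.sin(k * theta_fine + phases[k - 1])
    r_max = r_px * max(1.0, 1 + p.spiculation * pert_fine.max())
    margin = int(np.ceil(r_max)) + 3
    if grid_shape is None:
        n = 2 * margin + 1
        grid_shape = (n, n)
    cy, cx = (grid_shape[0] - 1) / 2.0, (grid_shape[1] - 1) / 2.0
    yy, xx = np.mgrid[0:grid_shape[0], 0:grid_shape[1]]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    perturb = np.zeros_like(theta)
    for k in range(1, p.n_lobes + 1):
        perturb += amps[k - 1] * np.sin(k * theta + phases[k - 1])
    r_theta = r_px * np.clip(1 + p.spiculation * perturb, 0.3, None)
    mask = np.hypot(dy, dx) <= r_theta
    # star-convexity about the centre guarantees a single 8-connected blob,
    # but rasterization of thin spicules can pinch one off; keep the core
    lab, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp > 1:
        mask = lab == lab[int(round(cy)), int(round(cx))]
    return RoiMask(mask)


def make_pk_field(mask: RoiMask, mean_ktrans: float, heterogeneity: float,
                  ve: float, seed: int = 0,
                  correlation_px: float = 3.0) -> PkField:
    # correlation_px is the physical texture scale expressed on this grid;
    # callers with a known pixel spacing should pass correlation_mm/spacing
    """Log-normal Ktrans random field inside the lesion.

    White Gaussian noise is smoothed to the given correlation length,
    standardized, and exponentiated so that the field has the requested
    mean and spatial coefficient of variation.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(mask.mask.shape)
    z = ndimage.gaussian_filter(z, correlation_px)
    inside = mask.mask
    if heterogeneity > 0:
        zin = z[inside]
        z = (z - zin.mean()) / max(zin.std(), 1e-12)
        sigma = np.sqrt(np.log(1 + heterogeneity ** 2))
        field = mean_ktrans * np.exp(sigma * z - sigma ** 2 / 2)
    else:
        field = np.full(mask.mask.shape, mean_ktrans)
    ktrans = np.where(inside, field, 0.0)
    ve_map = np.where(inside, ve, 0.0)
    return PkField(ktrans, ve_map)


def simulate_dce(mask: RoiMask, pk_field: PkField, acq: AcquisitionParams,
                 seed: int = 0, aif: Aif = Aif()):
    """Forward-simulate a DCE series from ground-truth parameter maps.

    Inside the lesion, S(t) = S0 * (1 + gamma * C(t)) with C(t) the exact
    Tofts concentration; background pixels keep a flat baseline.  Gaussian
    noise of sd ``acq.noise_sd`` is added everywhere (Rician optional).

    Returns (series, pk_field) so downstream fits can be checked against
    the truth.
    """
    times = acq.times
    h, w = mask.mask.shape
    frames = np.full((acq.n_phases, h, w), acq.s0, dtype=np.float64)
    inside = mask.mask
    kt = pk_field.ktrans_map[inside]
    ve = pk_field.ve_map[inside]
    conc = np.zeros((inside.sum(), acq.n_phases))
    active = kt > 0
    if np.any(active):
        # closed-form Tofts curves, vectorized over lesion pixels
        kep = kt[active] / ve[active]
        from .pk import _exp_conv
        c = (kt[active, None] * aif.dose
             * (aif.a1 * _exp_conv(times[None, :], kep[:, None], aif.m1)
                + aif.a2 * _exp_conv(times[None, :], kep[:, None], aif.m2)))
        conc[active] = c
    sig = acq.s0 * (1 + acq.gamma * conc)  # (N, T)
    for t_idx in range(acq.n_phases):
        fr = frames[t_idx]
        fr[inside] = sig[:, t_idx]
    if acq.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, acq.noise_sd, frames.shape)
        if acq.rician:
            noise2 = rng.normal(0, acq.noise_sd, frames.shape)
            frames = np.hypot(frames + noise, noise2)
        else:
            frames = frames + noise
    frames = np.clip(frames, 0, None)
    series = DceSeries(frames, times,
                       (acq.pixel_spacing_mm, acq.pixel_spacing_mm),
                       {"source": "kinetex.phantom", "seed": str(seed)})
    return series, pk_field


def make_lesion(seed: int, radius_mm: float, spiculation: float,
                heterogeneity: float, mean_ktrans: float, ve: float,
                acq: AcquisitionParams, correlation_mm: float = 1.5):
    """Convenience: mask + PK field + simulated series for one lesion."""
    shape_p = LesionShapeParams(mean_radius_mm=radius_mm,
                                spiculation=spiculation,
                                n_lobes=8, seed=seed)
    mask = make_lesion_mask(shape_p, pixel_spacing_mm=acq.pixel_spacing_mm)
    corr_px = correlation_mm / acq.pixel_spacing_mm
    pkf = make_pk_field(mask, mean_ktrans, heterogeneity, ve, seed=seed + 1,
                        correlation_px=corr_px)
    series, _ = simulate_dce(mask, pkf, acq, seed=seed + 2)
    return series, mask, pkf


def make_cohort(spec: CohortSpec):
    """Generate a seeded two-class cohort.

    Returns
    -------
    lesions : list of (DceSeries, RoiMask, label)
    truth : pandas.DataFrame
        Per-lesion ground-truth parameters.
    """
    rng = np.random.default_rng(spec.seed)
    lesions, rows = [], []
    classes = [("low", spec.n_low, 0.0)] + [("high", spec.n_high, 1.0)]
    for label, n, shift in classes:
        for i in range(n):
            lesion_seed = int(rng.integers(0, 2 ** 31 - 1))
            radius = rng.uniform(*spec.radius_range_mm)
            ve = rng.uniform(*spec.ve_range)
            jit = spec.within_class_jitter
            het = (spec.base_heterogeneity + shift * spec.effect_heterogeneity)
            spic = (spec.base_spiculation + shift * spec.effect_spiculation)
            kt = (spec.base_ktrans + shift * spec.effect_ktrans)
            if jit > 0:
                het = het * float(np.clip(rng.normal(1.0, jit), 0.3, 2.0))
                spic = spic * float(np.clip(rng.normal(1.0, jit), 0.3, 2.0))
                kt = kt * float(np.clip(rng.normal(1.0, jit), 0.3, 2.0))
            gain = rng.uniform(*spec.gain_range)
            t_n = int(rng.integers(spec.phase_range[0],
                                   spec.phase_range[1] + 1))
            spacing = rng.uniform(*spec.spacing_range_mm)
            acq = replace(spec.acquisition, s0=spec.acquisition.s0 * gain,
                          n_phases=t_n, pixel_spacing_mm=spacing)
            series, mask, pkf = make_lesion(lesion_seed, radius, spic, het,
                                            kt, ve, acq)
            lesions.append((series, mask, label))
            rows.append({"label": label, "seed": lesion_seed,
                         "radius_mm": radius, "spiculation": spic,
                         "heterogeneity": het, "mean_ktrans": kt, "ve": ve,
                         "gain": gain, "n_phases": t_n,
                         "n_pixels": mask.n_pixels})
    truth = pd.DataFrame(rows)
    return lesions, truth
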