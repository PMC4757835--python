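"""Canonical feature registry.

Seven feature classes are extracted per lesion: shape (6), pharmacokinetic
(PK, 3), enhancement kinetics (EK, 4), intensity kinetics (IK, 4), textural
kinetics (TK, 148 = 37 per-phase texture statistics x 4 cubic coefficients),
dynamic histogram of oriented gradients (DHoG, 5 bin configurations) and
dynamic local binary patterns (DLBP, 6 bin configurations) -- 176 features
in total.  Names are frozen here so CSV feature tables are stable.
"""

from __future__ import annotations

SHAPE_FEATURES = [
    "shape.area_overlap_ratio",
    "shape.var_distance_ratio",
    "shape.compactness",
    "shape.smoothness",
    "shape.norm_avg_radial_distance",
    "shape.std_norm_distance_ratio",
]

PK_FEATURES = ["pk.ktrans", "pk.ve", "pk.kep"]

EK_FEATURES = ["ek.max_uptake", "ek.time_to_peak", "ek.uptake_rate",
               "ek.washout_rate"]

IK_FEATURES = [f"ik.c{i}" for i in range(4)]

# 37 per-phase texture curves, each reduced to 4 cubic coefficients.
FIRST_ORDER_STATS = ["mean", "median", "range", "std"]
FIRST_ORDER_WINDOWS = [3, 5, 7]
SOBEL_CHANNELS = ["gx", "gy", "magnitude"]
KIRSCH_CHANNELS = ["d0", "d45", "d90", "d135", "d180", "d225", "d270",
                   "d315", "magnitude"]
HARALICK_FEATURES = [
    "contrast_energy",
    "contrast_inverse_moment",
    "contrast_average",
    "contrast_variance",
    "contrast_entropy",
    "intensity_average",
    "intensity_variance",
    "intensity_entropy",
    "entropy",
    "energy",
    "correlation",
    "info_measure1",
    "info_measure2",
]

TEXTURE_CURVE_NAMES = (
    [f"first_order.{s}.w{w}" for s in FIRST_ORDER_STATS
     for w in FIRST_ORDER_WINDOWS]
    + [f"sobel.{c}" for c in SOBEL_CHANNELS]
    + [f"kirsch.{c}" for c in KIRSCH_CHANNELS]
    + [f"haralick.{h}" for h in HARALICK_FEATURES]
)

TK_FEATURES = [f"tk.{curve}.c{i}" for curve in TEXTURE_CURVE_NAMES
               for i in range(4)]

DHOG_BINS = [2, 4, 6, 8, 10]
DLBP_BINS = [8, 16, 32, 64, 128, 256]

DHOG_FEATURES = [f"dhog.b{b}" for b in DHOG_BINS]
DLBP_FEATURES = [f"dlbp.b{b}" for b in DLBP_BINS]

FEATURE_CLASSES: dict[str, list[str]] = {
    "shape": SHAPE_FEATURES,
    "pk": PK_FEATURES,
    "ek": EK_FEATURES,
    "ik": IK_FEATURES,
    "tk": TK_FEATURES,
    "dhog": DHOG_FEATURES,
    "dlbp": DLBP_FEATURES,
}

ALL_FEATURES: list[str] = [n for names in FEATURE_CLASSES.values()
                           for n in names]


def feature_names(classes=None) -> list[str]:
    """Canonical feature names, optionally restricted to some classes."""
    if classes is None:
        return list(ALL_FEATURES)
    unknown = set(classes) - set(FEATURE_CLASSES)
    if unknown:
        raise KeyError(f"unknown feature classes: {sorted(unknown)}")
    return [n for c in FEATURE_CLASSES if c in classes
            for n in FEATURE_CLASSES[c]]


# structural identities, checked at import time
assert len(TEXTURE_CURVE_NAMES) == 37
assert [len(v) for v in FEATURE_CLASSES.values()] == [6, 3, 4, 4, 148, 5, 6]
assert len(ALL_FEATURES) == 176
assert len(set(ALL_FEATURES)) == 176
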