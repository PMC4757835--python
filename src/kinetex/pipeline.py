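"""Full per-lesion feature extraction.

``extract_all_features`` runs every family extractor (shape, PK, EK, IK,
TK, DHoG, DLBP) on a series/mask pair and returns the canonical 176-entry
feature vector.  Extraction is a pure function of its inputs: repeated
calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dyntex, kinetics, pk, registry, shape
from .core import DceSeries, FeatureVector, RoiMask
from .kinetics import TextureConfig


@dataclass(frozen=True)
class ExtractionConfig:
    """Which feature classes to extract and their knobs."""

    classes: tuple[str, ...] = tuple(registry.FEATURE_CLASSES)
    texture: TextureConfig = field(default_factory=TextureConfig)
    aif: pk.Aif = field(default_factory=pk.Aif)
    dhog_levels: int = 3
    dlbp_grid: int = 4


def extract_all_features(series: DceSeries, mask: RoiMask,
                         cfg: ExtractionConfig = ExtractionConfig(),
                         label: str | None = None) -> FeatureVector:
    """Extract the configured feature classes for one lesion.

    With the default configuration the result has exactly 176 entries in
    canonical registry order.  Phase order is normalized by acquisition
    time first, so a permuted-but-relabelled series yields identical
    features.
    """
    mask.check_grid(series)
    series = series.sorted_by_time()
    values: dict[str, float] = {}
    for cls in cfg.classes:
        if cls == "shape":
            values.update(shape.shape_features(mask))
        elif cls == "pk":
            values.update(pk.pk_features(series, mask, cfg.aif))
        elif cls == "ek":
            curve = kinetics.enhancement_curve(series, mask)
            values.update(kinetics.ek_features(curve))
        elif cls == "ik":
            values.update(kinetics.ik_features(series, mask))
        elif cls == "tk":
            values.update(kinetics.tk_features(series, mask, cfg.texture))
        elif cls == "dhog":
            values.update(dyntex.dhog_features(series, mask,
                                               levels=cfg.dhog_levels))
        elif cls == "dlbp":
            values.update(dyntex.dlbp_features(series, mask,
                                               grid=cfg.dlbp_grid))
        else:
            raise KeyError(f"unknown feature class {cls!r}")
    expected = registry.feature_names(cfg.classes)
    ordered = {name: float(values[name]) for name in expected}
    return FeatureVector(ordered, label=label)


def extract_cohort(lesions, cfg: ExtractionConfig = ExtractionConfig()):
    """Extract features for a list of (series, mask, label) lesions."""
    return [extract_all_features(s, m, cfg, label=lab)
            for s, m, lab in lesions]
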