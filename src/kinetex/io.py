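"""Readers and writers for DCE series, masks and feature tables.

Supported series formats:

* ``nifti`` — a .nii/.nii.gz volume with phases stacked along the last
  axis, plus a JSON sidecar (same stem, ``.json``) carrying acquisition
  times in minutes and the pixel spacing;
* ``image_dir`` — a directory of per-phase 16-bit PNG/TIFF images named
  ``phase_000.png``, ``phase_001.png``, ...; times come from a
  ``times.json`` sidecar or a uniform ``dt`` given explicitly;
* ``bundle`` — a single NPZ file holding ``frames``, ``times``,
  ``pixel_spacing`` (and optionally ``mask``).

Missing timestamps are an error: uniform spacing is never assumed unless
the caller explicitly provides ``dt``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .core import DceSeries, FeatureVector, RoiMask, ValidationError


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def load_series(path, fmt: str | None = None, dt: float | None = None) -> DceSeries:
    """Load a DCE series; ``fmt`` in {nifti, image_dir, bundle} or inferred."""
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "image_dir"
        elif path.suffix == ".npz":
            fmt = "bundle"
        elif path.name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        else:
            raise ValidationError(f"cannot infer format of {path}")
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "nifti":
        return _load_nifti(path, dt)
    if fmt == "image_dir":
        return _load_image_dir(path, dt)
    if fmt == "bundle":
        return _load_bundle(path)
    raise ValidationError(f"unknown series format {fmt!r}")


def _times_from(meta: dict | None, n: int, dt: float | None, where: str):
    if meta and "times_min" in meta:
        times = np.asarray(meta["times_min"], dtype=float)
        if times.shape != (n,):
            raise ValidationError(f"{where}: expected {n} times, "
                                  f"got {times.shape}")
        return times
    if dt is not None:
        return np.arange(n) * float(dt)
    raise ValidationError(
        f"{where}: acquisition times missing; provide a sidecar with "
        "'times_min' or pass dt explicitly")


def _load_nifti(path: Path, dt):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError("NIfTI series must be H x W x T")
    frames = np.transpose(data, (2, 0, 1)).astype(np.float64)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    times = _times_from(meta, frames.shape[0], dt, str(path))
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:2])
    if meta and "pixel_spacing_mm" in meta:
        spacing = tuple(float(s) for s in meta["pixel_spacing_mm"])
    order = np.argsort(times, kind="stable")
    return DceSeries(frames[order], np.sort(times), spacing,
                     {"source": str(path)})


def _load_image_dir(path: Path, dt):
    files = sorted(p for p in path.iterdir()
                   if re.fullmatch(r"phase_\d+\.(png|tif|tiff)", p.name))
    if not files:
        raise ValidationError(f"no phase_NNN images found in {path}")
    frames = np.stack([iio.imread(f).astype(np.float64) for f in files])
    if frames.ndim != 3:
        raise ValidationError("phase images must be single-channel")
    sidecar = path / "times.json"
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    times = _times_from(meta, frames.shape[0], dt, str(path))
    spacing = (0.5, 0.5)
    if meta and "pixel_spacing_mm" in meta:
        spacing = tuple(float(s) for s in meta["pixel_spacing_mm"])
    order = np.argsort(times, kind="stable")
    return DceSeries(frames[order], np.sort(times), spacing,
                     {"source": str(path)})


def _load_bundle(path: Path):
    with np.load(path) as z:
        frames = z["frames"].astype(np.float64)
        times = z["times"].astype(np.float64)
        spacing = tuple(float(s) for s in z["pixel_spacing"]) \
            if "pixel_spacing" in z else (0.5, 0.5)
    order = np.argsort(times, kind="stable")
    return DceSeries(frames[order], np.sort(times), spacing,
                     {"source": str(path)})


def write_series(series: DceSeries, path, fmt: str = "nifti") -> None:
    """Write a series as NIfTI + JSON sidecar or as an NPZ bundle."""
    path = Path(path)
    if fmt == "bundle" or path.suffix == ".npz":
        np.savez_compressed(path, frames=series.frames, times=series.times,
                            pixel_spacing=np.array(series.pixel_spacing))
        return
    data = np.transpose(series.frames, (1, 2, 0))
    affine = np.diag([series.pixel_spacing[0], series.pixel_spacing[1],
                      1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((*series.pixel_spacing, 1.0))
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "times_min": series.times.tolist(),
        "pixel_spacing_mm": list(series.pixel_spacing),
    }, indent=1))


def load_mask(path) -> RoiMask:
    """Load a lesion mask from single-frame NIfTI or PNG (nonzero = lesion)."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
    else:
        data = iio.imread(path)
    if data.ndim != 2:
        raise ValidationError("mask must be a single 2-D frame")
    return RoiMask(data != 0)


def write_mask(mask: RoiMask, path) -> None:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), np.eye(4)),
                 str(path))
    else:
        iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))


def write_feature_table(rows: list[FeatureVector], path,
                        names: list[str] | None = None) -> None:
    """Write feature vectors as CSV (canonical columns + ``label``).

    All rows must share one feature-name set; values are stored at 15
    significant digits so a read-back is lossless for practical purposes.
    """
    path = Path(path)
    if rows:
        if names is None:
            names = rows[0].names
        for fv in rows:
            if fv.names != names:
                raise ValidationError("heterogeneous feature-name sets")
    elif names is None:
        from .registry import ALL_FEATURES
        names = list(ALL_FEATURES)
    records = [{**fv.values, "label": fv.label if fv.label else ""}
               for fv in rows]
    df = pd.DataFrame.from_records(records, columns=[*names, "label"])
    df.to_csv(path, index=False, float_format="%.15g")


def read_feature_table(path) -> list[FeatureVector]:
    df = pd.read_csv(path, keep_default_na=False)
    if "label" not in df.columns:
        raise ValidationError("feature table missing 'label' column")
    names = [c for c in df.columns if c != "label"]
    out = []
    for _, row in df.iterrows():
        label = row["label"] or None
        out.append(FeatureVector({n: float(row[n]) for n in names},
                                 label=label))
    return out


def feature_table_to_matrix(rows: list[FeatureVector]):
    """(X, y, names) arrays from labelled feature vectors; y: high = 1."""
    if not rows:
        raise ValidationError("empty feature table")
    names = rows[0].names
    X = np.vstack([fv.as_array() for fv in rows])
    y = np.array([1 if fv.label == "high" else 0 for fv in rows])
    return X, y, names
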