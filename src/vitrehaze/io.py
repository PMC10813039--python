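"""File formats: volumes as multi-page TIFF + JSON sidecar, surfaces and
tables as CSV, ground truth as JSON/CSV sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import VitrehazeError
from .ilm import IlmSurface
from .phantom import PhantomTruth, RawOctVolume


def write_volume(volume: RawOctVolume, path) -> None:
    """Write a volume as a multi-page 32-bit float TIFF with a JSON
    metadata sidecar (``<path>.json``)."""
    path = Path(path)
    tifffile.imwrite(path, volume.intensities.astype(np.float32), photometric="minisblack")
    meta = {
        "axial_spacing_um": volume.axial_spacing_um,
        "lateral_spacing_um": volume.lateral_spacing_um,
        "bscan_spacing_um": volume.bscan_spacing_um,
        "n_bscans": volume.n_bscans,
        "n_ascans": volume.n_ascans,
        "n_depth": volume.n_depth,
        "is_contrast_adjusted": volume.is_contrast_adjusted,
        "depth_axis": "index 0 = vitreous side (top of image)",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_volume(path) -> RawOctVolume:
    path = Path(path)
    data = tifffile.imread(path).astype(np.float64)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise VitrehazeError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return RawOctVolume(
        data,
        axial_spacing_um=meta["axial_spacing_um"],
        lateral_spacing_um=meta["lateral_spacing_um"],
        bscan_spacing_um=meta["bscan_spacing_um"],
        is_contrast_adjusted=meta.get("is_contrast_adjusted", False),
    )


def write_truth(truth: PhantomTruth, path) -> None:
    """Ground-truth sidecar: boundaries as CSV, scalars as JSON."""
    path = Path(path)
    nb, na, k = truth.layer_boundaries.shape
    b, a = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    frame = {"b_scan": b.ravel(), "a_scan": a.ravel()}
    for i, name in enumerate(truth.boundary_names):
        frame[name] = truth.layer_boundaries[..., i].ravel()
    pd.DataFrame(frame).to_csv(path, index=False)
    meta = {
        "boundary_names": list(truth.boundary_names),
        "layer_intensities": truth.layer_intensities.tolist(),
        "vitreous_baseline": truth.vitreous_baseline,
        "vitreous_haze_level": truth.vitreous_haze_level,
        "noise_sigma": truth.noise_sigma,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_truth(path) -> PhantomTruth:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path)
    names = meta["boundary_names"]
    nb = df["b_scan"].max() + 1
    na = df["a_scan"].max() + 1
    bounds = np.empty((nb, na, len(names)), dtype=np.int64)
    order = df.sort_values(["b_scan", "a_scan"])
    for i, name in enumerate(names):
        bounds[..., i] = order[name].to_numpy().reshape(nb, na)
    return PhantomTruth(
        layer_boundaries=bounds,
        boundary_names=tuple(names),
        layer_intensities=np.asarray(meta["layer_intensities"]),
        vitreous_baseline=meta["vitreous_baseline"],
        vitreous_haze_level=meta["vitreous_haze_level"],
        noise_sigma=meta["noise_sigma"],
    )


def write_surface(surface: IlmSurface, path) -> None:
    nb, na = surface.depth_index.shape
    b, a = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    pd.DataFrame(
        {"b_scan": b.ravel(), "a_scan": a.ravel(), "depth_index": surface.depth_index.ravel()}
    ).to_csv(path, index=False)


def read_surface(path) -> IlmSurface:
    df = pd.read_csv(path)
    nb = df["b_scan"].max() + 1
    na = df["a_scan"].max() + 1
    d = df.sort_values(["b_scan", "a_scan"])["depth_index"].to_numpy().reshape(nb, na)
    return IlmSurface(d)
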