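"""On-disk formats for the per-eye dataset layout.

A dataset directory holds one ``clinical.csv`` (one row per eye) and an
``eyes/<subject>_<eye>/`` directory per eye with whichever modalities
passed acquisition/QC:

* ``artery.png`` / ``vein.png`` + ``landmarks.json`` — vessel rasters
  with optic-disc/fovea landmarks, disc diameter, μm/px scale, laterality;
* ``choroid.tif`` + ``choroid_boundaries.json`` — B-scan stack with
  per-B-scan inner/outer boundary polylines (axial px per A-scan), the
  axial/lateral/slow-axis scales and the fovea location;
* ``angio.tif`` + ``angio_meta.json`` — depth-resolved binary angiogram
  stack plus named en-face slabs (``slab_SVC.png`` ...), lateral scale
  in mm/px, depth pitch and per-depth plexus labels;
* ``width_profiles.csv`` — long-format (vessel_id, vessel_class,
  quadrant, arc_mm, width_um) centerline width samples.

An eye may carry any subset of modalities ("a scan may pass QC for one
modality but fail for another"); readers return None for missing ones.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .types import VesselMap, ChoroidScan, AngioStack, WidthProfile

__all__ = [
    "write_vessel_map",
    "read_vessel_map",
    "write_choroid_scan",
    "read_choroid_scan",
    "write_angio_stack",
    "read_angio_stack",
    "write_width_profiles",
    "read_width_profiles",
]


def _write_mask_png(path: Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def _read_mask_png(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def write_vessel_map(eye_dir: Path, vmap: VesselMap) -> None:
    eye_dir = Path(eye_dir)
    eye_dir.mkdir(parents=True, exist_ok=True)
    _write_mask_png(eye_dir / "artery.png", vmap.artery_mask)
    _write_mask_png(eye_dir / "vein.png", vmap.vein_mask)
    meta = {
        "od_center": list(vmap.od_center),
        "od_diameter": vmap.od_diameter,
        "fovea_center": list(vmap.fovea_center) if vmap.fovea_center else None,
        "pixel_scale_um": vmap.pixel_scale,
        "laterality": vmap.laterality,
    }
    (eye_dir / "landmarks.json").write_text(json.dumps(meta, indent=1))


def read_vessel_map(eye_dir: Path) -> VesselMap | None:
    eye_dir = Path(eye_dir)
    if not (eye_dir / "landmarks.json").exists():
        return None
    meta = json.loads((eye_dir / "landmarks.json").read_text())
    return VesselMap(
        artery_mask=_read_mask_png(eye_dir / "artery.png"),
        vein_mask=_read_mask_png(eye_dir / "vein.png"),
        od_center=tuple(meta["od_center"]),
        od_diameter=meta["od_diameter"],
        fovea_center=tuple(meta["fovea_center"]) if meta.get("fovea_center") else None,
        pixel_scale=meta.get("pixel_scale_um"),
        laterality=meta.get("laterality", "right"),
    )


def write_choroid_scan(eye_dir: Path, scan: ChoroidScan) -> None:
    eye_dir = Path(eye_dir)
    eye_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(eye_dir / "choroid.tif", scan.bscans)
    meta = {
        "axial_scale_um": scan.axial_scale,
        "lateral_scale_um": scan.lateral_scale,
        "bscan_spacing_um": scan.bscan_spacing,
        "fovea": list(scan.fovea),
        "bscans": [
            {"inner": np.round(scan.inner_boundary[i], 3).tolist(),
             "outer": np.round(scan.outer_boundary[i], 3).tolist()}
            for i in range(scan.n_bscans)
        ],
    }
    (eye_dir / "choroid_boundaries.json").write_text(json.dumps(meta))


def read_choroid_scan(eye_dir: Path) -> ChoroidScan | None:
    eye_dir = Path(eye_dir)
    if not (eye_dir / "choroid_boundaries.json").exists():
        return None
    meta = json.loads((eye_dir / "choroid_boundaries.json").read_text())
    return ChoroidScan(
        bscans=tifffile.imread(eye_dir / "choroid.tif"),
        inner_boundary=np.array([b["inner"] for b in meta["bscans"]]),
        outer_boundary=np.array([b["outer"] for b in meta["bscans"]]),
        axial_scale=meta["axial_scale_um"],
        lateral_scale=meta["lateral_scale_um"],
        bscan_spacing=meta["bscan_spacing_um"],
        fovea=tuple(meta["fovea"]),
    )


def write_angio_stack(eye_dir: Path, stack: AngioStack) -> None:
    eye_dir = Path(eye_dir)
    eye_dir.mkdir(parents=True, exist_ok=True)
    if stack.stack is not None:
        tifffile.imwrite(eye_dir / "angio.tif", stack.stack.astype(np.uint8))
    for name, slab in stack.slabs.items():
        _write_mask_png(eye_dir / f"slab_{name}.png", slab)
    meta = {
        "lateral_scale_mm": stack.lateral_scale,
        "fovea_center": list(stack.fovea_center),
        "depth_pitch_um": stack.depth_pitch_um,
        "depth_labels": list(stack.depth_labels) if stack.depth_labels else None,
        "slabs": sorted(stack.slabs),
    }
    (eye_dir / "angio_meta.json").write_text(json.dumps(meta, indent=1))


def read_angio_stack(eye_dir: Path) -> AngioStack | None:
    eye_dir = Path(eye_dir)
    if not (eye_dir / "angio_meta.json").exists():
        return None
    meta = json.loads((eye_dir / "angio_meta.json").read_text())
    stack = None
    if (eye_dir / "angio.tif").exists():
        stack = tifffile.imread(eye_dir / "angio.tif") > 0
    slabs = {name: _read_mask_png(eye_dir / f"slab_{name}.png") for name in meta["slabs"]}
    return AngioStack(
        lateral_scale=meta["lateral_scale_mm"],
        fovea_center=tuple(meta["fovea_center"]),
        slabs=slabs,
        stack=stack,
        depth_pitch_um=meta.get("depth_pitch_um"),
        depth_labels=meta.get("depth_labels"),
    )


def write_width_profiles(eye_dir: Path, profiles: list[WidthProfile]) -> None:
    eye_dir = Path(eye_dir)
    eye_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in profiles:
        for a, w in zip(p.arc_mm, p.width_um):
            rows.append({"vessel_id": p.vessel_id, "vessel_class": p.vessel_class,
                         "quadrant": p.quadrant, "arc_mm": a, "width_um": w})
    pd.DataFrame(rows).to_csv(eye_dir / "width_profiles.csv", index=False, float_format="%.6g")


def read_width_profiles(eye_dir: Path) -> list[WidthProfile] | None:
    path = Path(eye_dir) / "width_profiles.csv"
    if not path.exists():
        return None
    df = pd.read_csv(path)
    profiles = []
    for (vid, cls, quad), sub in df.groupby(["vessel_id", "vessel_class", "quadrant"], sort=True):
        sub = sub.sort_values("arc_mm")
        profiles.append(WidthProfile(str(vid), cls, sub["arc_mm"].to_numpy(),
                                     sub["width_um"].to_numpy(), quad))
    return profiles
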