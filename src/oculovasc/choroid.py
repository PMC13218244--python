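"""Choroidal thickness and vascularity index from OCT B-scan stacks.

The choroid is the slab between Bruch's membrane (inner boundary) and the
choroidal–scleral interface (outer boundary), both supplied as per-A-scan
polylines.  Thickness is the axial boundary separation; vascularity is
quantified by binarizing each B-scan inside the choroid mask — Gaussian
smoothing, 8-bit rescale, local Otsu threshold, one erosion and one
dilation — with dark pixels taken as luminal (vessel lumen) and bright as
stromal.  Binarization runs at several smoothing scales and the luminal
masks are combined by union to capture small and large lumina alike.
Per-B-scan profiles are interpolated into en-face maps and summarised on
the ETDRS grid (central 1 mm circle, 1–3 mm inner ring, 3–6 mm outer
ring, 6 mm global disc).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import interp1d
from scipy.ndimage import gaussian_filter
from skimage.filters import rank, threshold_otsu
from skimage.morphology import dilation, disk, erosion

from .types import ChoroidScan, BinarizationConfig, ChoroidMaps

__all__ = [
    "choroid_mask_and_thickness",
    "binarize_choroid",
    "cvi",
    "bscan_profiles",
    "enface_maps",
    "etdrs_summary",
]

log = logging.getLogger(__name__)

#: ETDRS grid diameters in mm: central circle, inner ring, outer ring.
ETDRS_DIAMETERS = (1.0, 3.0, 6.0)


def choroid_mask_and_thickness(scan: ChoroidScan) -> tuple[np.ndarray, np.ndarray]:
    """Choroid mask per B-scan and thickness per A-scan in μm.

    The mask is true strictly between the boundaries (rows in
    ``[ceil(inner), outer)``); thickness is the axial boundary separation
    times the axial scale, independent of lateral position or tilt.
    """
    n, h, w = scan.bscans.shape
    rows = np.arange(h)[None, :, None]
    inner = scan.inner_boundary[:, None, :]
    outer = scan.outer_boundary[:, None, :]
    mask = (rows >= inner) & (rows < outer)
    ct = (scan.outer_boundary - scan.inner_boundary) * scan.axial_scale
    return mask, ct


def _rescale8(img: np.ndarray, mask: np.ndarray) -> np.ndarray | None:
    """8-bit rescale of ``img`` within ``mask``; None for a flat image."""
    vals = img[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return None
    img8 = np.zeros(img.shape, dtype=np.uint8)
    img8[mask] = np.clip(np.round((img[mask] - lo) / (hi - lo) * 255.0), 0, 255).astype(np.uint8)
    return img8


def _global_dark_gate(
    img8: np.ndarray, mask: np.ndarray, min_separation: float = 4.0
) -> np.ndarray | None:
    """Pixels below the global Otsu cut, or None when the histogram is
    effectively unimodal (class separation under ``min_separation``
    within-class standard deviations), i.e. no lumina present."""
    vals = img8[mask]
    thr = threshold_otsu(vals)
    lo_cls, hi_cls = vals[vals <= thr], vals[vals > thr]
    if len(lo_cls) == 0 or len(hi_cls) == 0:
        return None
    within_sd = np.sqrt(
        (len(lo_cls) * lo_cls.astype(float).var() + len(hi_cls) * hi_cls.astype(float).var())
        / len(vals)
    )
    if within_sd > 0 and (hi_cls.mean() - lo_cls.mean()) < min_separation * within_sd:
        return None
    return mask & (img8 <= thr)


def _binarize_single_scale(
    bscan: np.ndarray, mask: np.ndarray, sigma: float, window: int, morph_radius: int,
    gate: np.ndarray,
) -> np.ndarray:
    img = gaussian_filter(np.asarray(bscan, dtype=float), sigma) if sigma > 0 else np.asarray(bscan, float)
    img8 = _rescale8(img, mask)
    if img8 is None:
        return np.zeros_like(mask)
    thr = rank.otsu(img8, disk(window // 2), mask=mask)
    luminal = mask & (img8 < thr) & gate
    if morph_radius > 0:
        se = disk(morph_radius)
        luminal = dilation(erosion(luminal, se), se)
    return luminal & mask


def binarize_choroid(
    bscan: np.ndarray, mask: np.ndarray, cfg: BinarizationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split the choroid of one B-scan into luminal and stromal masks.

    Dark pixels (below the local Otsu threshold) are luminal; the
    partition is exact: luminal ∪ stromal = mask and the two are
    disjoint.  A global dark gate — pixels must also fall below the
    global Otsu cut of the base-smoothed B-scan — keeps the multi-scale
    union from accreting boundary halos, and a minimum class-separation
    guard declares the choroid lumen-free when its histogram is
    effectively unimodal (local Otsu would otherwise split pure stromal
    noise down the middle).  The local window shrinks with a warning when
    the choroid is thinner than the configured window.
    """
    if cfg is None:
        cfg = BinarizationConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty choroid mask")
    thickness = int(mask.sum(axis=0).max())
    window = cfg.local_window
    if thickness < window:
        window = max(3, thickness | 1)
        log.warning("binarize_choroid: window shrunk to %d (thin choroid)", window)
    base = gaussian_filter(np.asarray(bscan, float), cfg.gaussian_sigma)
    img8 = _rescale8(base, mask)
    gate = _global_dark_gate(img8, mask) if img8 is not None else None
    if gate is None:
        return np.zeros_like(mask), mask.copy()
    sigmas = sorted(set((cfg.gaussian_sigma, *cfg.scales)))
    luminal = np.zeros_like(mask)
    for s in sigmas:
        luminal |= _binarize_single_scale(bscan, mask, s, window, cfg.morph_radius, gate)
    stromal = mask & ~luminal
    return luminal, stromal


def cvi(
    luminal: np.ndarray, choroid_mask: np.ndarray, region: np.ndarray | None = None
) -> float:
    """Choroidal vascularity index: luminal / total choroidal area."""
    sel = choroid_mask if region is None else (choroid_mask & region)
    denom = int(np.count_nonzero(sel))
    if denom == 0:
        raise ValueError("empty choroid region: CVI undefined")
    return float(np.count_nonzero(luminal & sel)) / denom


def bscan_profiles(
    scan: ChoroidScan, cfg: BinarizationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-A-scan CT (μm) and CVI profiles for every B-scan.

    Returns ``(ct, cvi)`` arrays of shape ``(n_bscans, n_ascans)``; CVI is
    NaN where an A-scan column has no choroid pixels.
    """
    mask, ct = choroid_mask_and_thickness(scan)
    n = scan.n_bscans
    cvi_prof = np.full((n, scan.n_ascans), np.nan)
    for i in range(n):
        if not mask[i].any():
            continue
        luminal, _ = binarize_choroid(scan.bscans[i], mask[i], cfg)
        col_choroid = mask[i].sum(axis=0)
        col_luminal = (luminal & mask[i]).sum(axis=0)
        ok = col_choroid > 0
        cvi_prof[i, ok] = col_luminal[ok] / col_choroid[ok]
    return ct, cvi_prof


def enface_maps(scan: ChoroidScan, ct: np.ndarray, cvi_prof: np.ndarray) -> ChoroidMaps:
    """Interpolate per-B-scan profiles into en-face CT and CVI maps.

    Profiles sit at the B-scan slow-axis positions (``bscan_spacing``
    apart) and intermediate rows are filled by linear interpolation, at a
    row pitch close to the lateral pixel pitch so map pixels are roughly
    square.  Rows coinciding with B-scans reproduce the input profiles
    exactly; nothing is extrapolated beyond the first/last B-scan.
    """
    n = ct.shape[0]
    if n < 2:
        log.warning("enface_maps: single B-scan, no slow-axis interpolation")
        return ChoroidMaps(
            ct_map=ct.copy(),
            cvi_map=cvi_prof.copy(),
            row_scale_um=scan.bscan_spacing,
            col_scale_um=scan.lateral_scale,
            fovea_rc=(float(scan.fovea[0]), float(scan.fovea[1])),
            single_bscan=True,
        )
    n_sub = max(1, int(round(scan.bscan_spacing / scan.lateral_scale)))
    rows_in = np.arange(n) * n_sub
    rows_out = np.arange(rows_in[-1] + 1)
    ct_map = interp1d(rows_in, ct, axis=0)(rows_out)
    cvi_map = interp1d(rows_in, cvi_prof, axis=0)(rows_out)
    return ChoroidMaps(
        ct_map=ct_map,
        cvi_map=cvi_map,
        row_scale_um=scan.bscan_spacing / n_sub,
        col_scale_um=scan.lateral_scale,
        fovea_rc=(float(scan.fovea[0] * n_sub), float(scan.fovea[1])),
    )


def etdrs_summary(
    map_arr: np.ndarray,
    fovea_rc: tuple[float, float],
    row_scale_um: float,
    col_scale_um: float,
    diameters_mm: tuple[float, float, float] = ETDRS_DIAMETERS,
) -> dict[str, float]:
    """ETDRS-grid means of an en-face map.

    Regions are the central circle (diameter ``diameters_mm[0]``), inner
    ring (to ``diameters_mm[1]``), outer ring (to ``diameters_mm[2]``) and
    the global disc (full ``diameters_mm[2]``).  Means are over defined
    (non-NaN) pixels; each region also reports its coverage fraction, and
    a fully undefined region is NaN.
    """
    h, w = map_arr.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r_mm = np.hypot(
        (yy - fovea_rc[0]) * row_scale_um / 1000.0,
        (xx - fovea_rc[1]) * col_scale_um / 1000.0,
    )
    d0, d1, d2 = diameters_mm
    regions = {
        "central": r_mm < d0 / 2,
        "inner": (r_mm >= d0 / 2) & (r_mm < d1 / 2),
        "outer": (r_mm >= d1 / 2) & (r_mm < d2 / 2),
        "global": r_mm < d2 / 2,
    }
    # coverage accounts for the part of each region beyond the map edges
    px_area = (row_scale_um / 1000.0) * (col_scale_um / 1000.0)
    full_areas = {
        "central": np.pi * (d0 / 2) ** 2,
        "inner": np.pi * ((d1 / 2) ** 2 - (d0 / 2) ** 2),
        "outer": np.pi * ((d2 / 2) ** 2 - (d1 / 2) ** 2),
        "global": np.pi * (d2 / 2) ** 2,
    }
    out: dict[str, float] = {}
    for name, sel in regions.items():
        vals = map_arr[sel]
        vals = vals[np.isfinite(vals)]
        out[name] = float(np.mean(vals)) if len(vals) else float("nan")
        out[f"{name}_coverage"] = float(len(vals) * px_area / full_areas[name])
        if not len(vals):
            log.warning("etdrs_summary: region %s fully undefined", name)
    return out
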