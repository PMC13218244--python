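"""Posterior-pole vascular parameters from optic-disc-centred vessel maps.

Measurements follow the standard caliber-literature conventions: an annular
zone B (0.5–1.0 disc diameters from the disc margin) for the Knudtson
summary calibers CRAE/CRVE and their ratio AVR, and a wider zone C
(0.5–2.0 diameters) for tortuosity, vessel density and box-count fractal
dimension.  Widths are estimated along skeletonized centerlines with the
Euclidean distance transform.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .types import VesselMap, ZoneSpec, ZONE_B, ZONE_C, CaliberResult

__all__ = [
    "zone_mask",
    "measure_calibers_in_zone",
    "knudtson_equivalent",
    "avr",
    "calibers",
    "centerline_paths",
    "path_tortuosity",
    "tortuosity",
    "tortuosity_in_zone",
    "vessel_density",
    "boxcount_fd",
    "FundusResult",
    "analyze_vessel_map",
]

log = logging.getLogger(__name__)

#: Branching coefficients of the revised Knudtson formulas.
KNUDTSON_K = {"artery": 0.88, "vein": 0.95}


def zone_mask(
    od_center: tuple[float, float],
    od_diameter: float,
    zone: ZoneSpec,
    shape: tuple[int, int],
) -> np.ndarray:
    """Binary annulus for a measurement zone.

    True where the Euclidean distance d from ``od_center`` satisfies
    ``R + inner*D <= d < R + outer*D`` with R = D/2 (offsets measured from
    the disc margin).
    """
    if od_diameter <= 0:
        raise ValueError("od_diameter must be positive")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx - od_center[0], yy - od_center[1])
    r = od_diameter / 2.0
    lo = r + zone.inner_offset * od_diameter
    hi = r + zone.outer_offset * od_diameter
    return (d >= lo) & (d < hi)


def measure_calibers_in_zone(
    vmap: VesselMap, zmask: np.ndarray
) -> dict[str, list[float]]:
    """Per-vessel-segment mean widths (pixels) inside a zone, per class.

    Width at a centerline point is twice its Euclidean distance to the
    nearest background pixel; each connected centerline segment crossing
    the zone contributes the mean of its per-point estimates, and lists
    are sorted descending.  An empty list signals that the caliber is
    undefined downstream.
    """
    out: dict[str, list[float]] = {}
    struct = np.ones((3, 3), bool)
    for cls, mask in (("artery", vmap.artery_mask), ("vein", vmap.vein_mask)):
        skel = skeletonize(mask)
        edt = ndimage.distance_transform_edt(mask)
        inzone = skel & zmask
        labels, n = ndimage.label(inzone, structure=struct)
        widths = []
        for i in range(1, n + 1):
            pts = labels == i
            if pts.sum() < 3:  # too short to call a segment
                continue
            widths.append(float(np.mean(2.0 * edt[pts])))
        out[cls] = sorted(widths, reverse=True)
    return out


def knudtson_equivalent(widths, vessel_class: str) -> float:
    """Combine individual vessel widths into a summary caliber.

    The six largest widths (all, if fewer) are reduced pairwise: the
    current largest w_max and smallest w_min are replaced by
    ``k * sqrt(w_max**2 + w_min**2)`` with k = 0.88 for arterioles and
    0.95 for venules; when an odd number remains the median width carries
    to the next round unchanged.  The procedure is permutation-invariant
    and scale-equivariant.
    """
    if vessel_class not in KNUDTSON_K:
        raise ValueError("vessel_class must be 'artery' or 'vein'")
    w = sorted(float(x) for x in widths)
    if not w:
        raise ValueError("cannot compute an equivalent caliber of no vessels")
    if any(x <= 0 for x in w):
        raise ValueError("widths must be positive")
    k = KNUDTSON_K[vessel_class]
    w = sorted(w, reverse=True)[:6]
    while len(w) > 1:
        nxt = []
        n = len(w)
        for i in range(n // 2):
            nxt.append(k * math.sqrt(w[i] ** 2 + w[n - 1 - i] ** 2))
        if n % 2:
            nxt.append(w[n // 2])  # median carries forward unchanged
        w = sorted(nxt, reverse=True)
    return w[0]


def avr(crae: float, crve: float) -> float:
    """Arteriole-to-venule ratio CRAE/CRVE."""
    if crve == 0:
        raise ZeroDivisionError("AVR undefined for CRVE = 0")
    return crae / crve


def calibers(vmap: VesselMap, zone: ZoneSpec = ZONE_B) -> CaliberResult:
    """CRAE, CRVE and AVR from the widths measured in ``zone``."""
    zmask = zone_mask(vmap.od_center, vmap.od_diameter, zone, vmap.shape)
    widths = measure_calibers_in_zone(vmap, zmask)
    wa, wv = widths["artery"], widths["vein"]
    if not wa or not wv:
        raise ValueError("no measurable vessels in the caliber zone")
    scale = vmap.pixel_scale if vmap.pixel_scale is not None else 1.0
    crae = knudtson_equivalent([w * scale for w in wa], "artery")
    crve = knudtson_equivalent([w * scale for w in wv], "vein")
    return CaliberResult(
        crae=crae,
        crve=crve,
        avr=avr(crae, crve),
        n_arterioles_used=min(len(wa), 6),
        n_venules_used=min(len(wv), 6),
        units="um" if vmap.pixel_scale is not None else "px",
    )


# ---------------------------------------------------------------------------
# centerline paths and tortuosity

_NBR = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace(seg: set[tuple[int, int]], start: tuple[int, int]) -> list[tuple[int, int]]:
    """Walk a branch-free 8-connected pixel chain from one endpoint."""
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = None
        # prefer 4-neighbours so staircase chains are walked in order
        for dy, dx in ((-1, 0), (0, -1), (0, 1), (1, 0), (-1, -1), (-1, 1), (1, -1), (1, 1)):
            cand = (cur[0] + dy, cur[1] + dx)
            if cand in seg and cand not in seen:
                nxt = cand
                break
        if nxt is None:
            return path
        path.append(nxt)
        seen.add(nxt)
        cur = nxt


def centerline_paths(
    mask: np.ndarray,
    region: np.ndarray | None = None,
    min_len: int = 10,
    smooth_window: int = 5,
) -> list[np.ndarray]:
    """Ordered centerline paths (``(n, 2)`` arrays of (y, x)) of a mask.

    The skeleton is cut at branch points into branch-free segments, each
    traced from an endpoint.  Coordinates are smoothed with a short moving
    average so rasterization staircase does not inflate arc length.
    """
    skel = skeletonize(mask)
    if region is not None:
        skel = skel & region
    nbr = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8), mode="constant") - skel
    branch_pts = skel & (nbr >= 3)
    seg_mask = skel & ~branch_pts
    labels, n = ndimage.label(seg_mask, structure=np.ones((3, 3), bool))
    paths = []
    for i in range(1, n + 1):
        pix = np.argwhere(labels == i)
        if len(pix) < min_len:
            continue
        seg = {tuple(p) for p in pix}
        endpoints = []
        for p in seg:
            deg = sum((p[0] + dy, p[1] + dx) in seg for dy, dx in _NBR)
            if deg <= 1:
                endpoints.append(p)
        start = endpoints[0] if endpoints else next(iter(seg))
        chain = _trace(seg, start)
        if len(chain) < min_len:
            continue
        arr = np.asarray(chain, dtype=float)
        if smooth_window > 1 and len(arr) > smooth_window:
            kernel = np.ones(smooth_window) / smooth_window
            sm = np.column_stack(
                [np.convolve(arr[:, j], kernel, mode="valid") for j in range(2)]
            )
            # keep true endpoints so chord length is preserved
            arr = np.vstack([arr[:1], sm, arr[-1:]])
        paths.append(arr)
    return paths


def path_tortuosity(path: np.ndarray) -> tuple[float, float]:
    """(tortuosity, arc length) of one path: arc/chord − 1."""
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        raise ValueError("path needs at least 2 points")
    arc = float(np.sum(np.hypot(*np.diff(path, axis=0).T)))
    chord = float(np.hypot(*(path[-1] - path[0])))
    if chord == 0:
        raise ValueError("closed loop: chord length is zero")
    return arc / chord - 1.0, arc


def tortuosity(paths) -> float:
    """Length-weighted mean tortuosity over centerline paths.

    Closed loops (zero chord) are excluded with a warning.
    """
    vals, lens = [], []
    for p in paths:
        try:
            t, arc = path_tortuosity(p)
        except ValueError:
            warnings.warn("excluding closed-loop path from tortuosity")
            continue
        vals.append(t)
        lens.append(arc)
    if not vals:
        return float("nan")
    return float(np.average(vals, weights=lens))


def tortuosity_in_zone(vmap: VesselMap, zone: ZoneSpec = ZONE_C) -> dict[str, float]:
    """Per-class and combined tortuosity of centerlines inside a zone."""
    zmask = zone_mask(vmap.od_center, vmap.od_diameter, zone, vmap.shape)
    pa = centerline_paths(vmap.artery_mask, zmask)
    pv = centerline_paths(vmap.vein_mask, zmask)
    return {
        "TORTa": tortuosity(pa),
        "TORTv": tortuosity(pv),
        "TORT": tortuosity(pa + pv),
    }


def vessel_density(mask: np.ndarray, zmask: np.ndarray) -> float:
    """Fraction of zone pixels that are vessel."""
    n_zone = int(np.count_nonzero(zmask))
    if n_zone == 0:
        raise ValueError("empty zone")
    return float(np.count_nonzero(mask & zmask)) / n_zone


def boxcount_fd(
    mask: np.ndarray,
    zmask: np.ndarray | None = None,
    min_box: int = 2,
    max_box: int | None = None,
    min_pixels: int = 100,
) -> float:
    """Box-count fractal dimension of the foreground within a zone.

    N(ε) counts grid boxes of side ε intersecting the foreground,
    minimized over a small set of grid origins so an unlucky grid phase
    does not overcount; the dimension is the least-squares slope of
    log N(ε) against log(1/ε) over dyadic ε from ``min_box`` up to
    min(H, W)/8 (boxes coarser than that sit in the saturation plateau
    and flatten the slope for plane-filling patterns).
    """
    fg = mask & zmask if zmask is not None else np.asarray(mask, bool)
    npix = int(np.count_nonzero(fg))
    if npix == 0:
        raise ValueError("no foreground pixels")
    if npix < min_pixels:
        log.warning("boxcount_fd: only %d foreground pixels; estimate unreliable", npix)
    h, w = fg.shape
    if max_box is None:
        max_box = min(h, w) // 8
    sizes = []
    s = min_box
    while s <= max_box:
        sizes.append(s)
        s *= 2
    if len(sizes) < 3:
        raise ValueError("degenerate box-size range: image too small")
    counts = []
    for s in sizes:
        best = None
        for oy in range(0, s, max(1, s // 4)):
            for ox in range(0, s, max(1, s // 4)):
                hb, wb = -(-(h + oy) // s), -(-(w + ox) // s)
                pad = np.zeros((hb * s, wb * s), bool)
                pad[oy:oy + h, ox:ox + w] = fg
                n = int(pad.reshape(hb, s, wb, s).any(axis=(1, 3)).sum())
                best = n if best is None else min(best, n)
        counts.append(best)
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, float)), np.log(counts), 1)
    return float(slope)


@dataclass
class FundusResult:
    """All posterior-pole parameters for one eye."""

    caliber: CaliberResult
    tort: dict[str, float] = field(default_factory=dict)
    vd: dict[str, float] = field(default_factory=dict)
    fd: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {
            "CRAE": self.caliber.crae,
            "CRVE": self.caliber.crve,
            "AVR": self.caliber.avr,
        }
        row.update(self.tort)
        row.update(self.vd)
        row.update(self.fd)
        return row


def analyze_vessel_map(
    vmap: VesselMap,
    caliber_zone: ZoneSpec = ZONE_B,
    geometry_zone: ZoneSpec = ZONE_C,
) -> FundusResult:
    """Full posterior-pole profile: calibers from zone B, geometry from zone C."""
    cal = calibers(vmap, caliber_zone)
    zc = zone_mask(vmap.od_center, vmap.od_diameter, geometry_zone, vmap.shape)
    vd = {
        "VDa": vessel_density(vmap.artery_mask, zc),
        "VDv": vessel_density(vmap.vein_mask, zc),
        "VD": vessel_density(vmap.union_mask, zc),
    }
    fd = {}
    for key, m in (("FDa", vmap.artery_mask), ("FDv", vmap.vein_mask), ("FD", vmap.union_mask)):
        try:
            fd[key] = boxcount_fd(m, zc)
        except ValueError:
            fd[key] = float("nan")
    return FundusResult(caliber=cal, tort=tortuosity_in_zone(vmap, geometry_zone), vd=vd, fd=fd)
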