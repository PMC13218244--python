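"""Peripheral-retina metrics from ultra-widefield vessel maps.

Eyes are first brought into a common frame by mirroring left eyes and
rotating about the image centre until the optic-disc–fovea axis is
horizontal (fovea on the temporal side).  A standardised elliptical
extended zone (≈319 mm² at the nominal field) then bounds the sandbox
fractal dimension, and vessel tapering toward the periphery is summarised
by a Theil–Sen width gradient per quadrant, averaged into a global value
per vessel class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.transform import rotate

from .types import VesselMap, WidthProfile, ExtendedZone

__all__ = [
    "AlignmentTransform",
    "align_to_od_fovea_axis",
    "extended_zone_mask",
    "sandbox_fd",
    "width_gradient",
    "global_width_gradient",
]

log = logging.getLogger(__name__)


@dataclass
class AlignmentTransform:
    """Mirror-then-rotate transform applied during axis alignment.

    The forward transform mirrors left eyes about the vertical midline and
    rotates by ``angle_deg`` (counter-clockwise in image coordinates, i.e.
    the ``skimage`` convention) about the image centre.
    """

    angle_deg: float
    mirrored: bool
    center: tuple[float, float]  # (x, y) rotation centre
    shape: tuple[int, int]

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float)).copy()
        if self.mirrored:
            pts[:, 0] = (self.shape[1] - 1) - pts[:, 0]
        th = np.deg2rad(self.angle_deg)
        # rotate(angle) maps output->input with R(theta); points go input->output
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        c = np.asarray(self.center)
        return (pts - c) @ rot.T + c

    def invert_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        th = np.deg2rad(self.angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(self.center)
        out = (pts - c) @ rot.T + c
        if self.mirrored:
            out = out.copy()
            out[:, 0] = (self.shape[1] - 1) - out[:, 0]
        return out


def align_to_od_fovea_axis(vmap: VesselMap) -> tuple[VesselMap, AlignmentTransform]:
    """Rotate/mirror a vessel map so the OD–fovea axis is horizontal.

    After alignment the fovea sits to the left of the disc and left eyes
    are mirrored, so all eyes share one coordinate frame.  The returned
    transform maps original landmark coordinates to aligned ones and is
    invertible to sub-pixel accuracy.
    """
    if vmap.fovea_center is None:
        raise ValueError("fovea landmark required for axis alignment")
    od = np.asarray(vmap.od_center, dtype=float)
    fov = np.asarray(vmap.fovea_center, dtype=float)
    if np.allclose(od, fov):
        raise ValueError("optic-disc and fovea landmarks coincide")
    h, w = vmap.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    mirrored = vmap.laterality == "left"

    a_mask = vmap.artery_mask
    v_mask = vmap.vein_mask
    if mirrored:
        a_mask = a_mask[:, ::-1]
        v_mask = v_mask[:, ::-1]
        od = od.copy()
        fov = fov.copy()
        od[0] = (w - 1) - od[0]
        fov[0] = (w - 1) - fov[0]

    vec = fov - od
    # rotate so the fovea->disc direction points along +x, fovea leftward
    angle = float(np.degrees(np.arctan2(vec[1], vec[0])) - 180.0)
    angle = (angle + 180.0) % 360.0 - 180.0
    tr = AlignmentTransform(angle_deg=angle, mirrored=mirrored, center=center, shape=(h, w))
    if abs(angle) % 360 < 1e-9:
        a_rot, v_rot = a_mask, v_mask
    else:
        a_rot = rotate(a_mask.astype(float), angle, center=center, order=0).astype(bool)
        v_rot = rotate(v_mask.astype(float), angle, center=center, order=0).astype(bool)
    new_od, new_fov = tr.apply_points(np.vstack([np.asarray(vmap.od_center, float), np.asarray(vmap.fovea_center, float)]))
    aligned = VesselMap(
        artery_mask=a_rot,
        vein_mask=v_rot,
        od_center=tuple(new_od),
        od_diameter=vmap.od_diameter,
        fovea_center=tuple(new_fov),
        pixel_scale=vmap.pixel_scale,
        laterality="right",
    )
    return aligned, tr


def extended_zone_mask(
    shape: tuple[int, int],
    pixel_scale_um: float,
    band_fraction: float = 0.15,
    rotation_deg: float = 0.0,
    mirrored: bool = False,
) -> ExtendedZone:
    """Standardised extended-zone ROI for an aligned ultra-widefield image.

    The template is an axis-aligned ellipse spanning the field width, with
    ``band_fraction`` of the height excluded at top and bottom where
    eyelids and lashes obscure the retina.  At the nominal 24 mm field
    this encloses ≈317 mm², matching the ≈319 mm² standardised region.
    Area is reported in mm² from the supplied scale.
    """
    if pixel_scale_um is None or pixel_scale_um <= 0:
        raise ValueError("pixel_scale_um (μm/pixel) metadata is required")
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a = w / 2.0
    b = (h * (1.0 - 2.0 * band_fraction)) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    area = float(mask.sum()) * (pixel_scale_um / 1000.0) ** 2
    return ExtendedZone(mask=mask, area_mm2=area, rotation_deg=rotation_deg, mirrored=mirrored)


def sandbox_fd(
    mask: np.ndarray,
    zone_mask: np.ndarray | None = None,
    n_seeds: int = 500,
    radii: np.ndarray | None = None,
    seed: int = 0,
) -> float:
    """Sandbox-count fractal dimension.

    For seed points sampled uniformly from the foreground, N(r) is the
    foreground pixel count in the (2r+1)-square window around the seed;
    the dimension is the slope of log⟨N(r)⟩ against log(2r+1) — the
    window side is the proper scale variable, since regressing on log r
    alone biases the slope downward at small radii.  Seeds whose largest
    window would leave the image are excluded so boundary truncation
    does not flatten the scaling.  Deterministic for a fixed ``seed``.
    """
    fg = mask & zone_mask if zone_mask is not None else np.asarray(mask, bool)
    h, w = fg.shape
    if radii is None:
        rmax = min(min(h, w) // 8, 128)
        radii = np.unique(np.round(np.geomspace(4, max(rmax, 8), 8)).astype(int))
    radii = np.asarray(radii, dtype=int)
    rmax_fit = (min(h, w) - 1) // 2
    if radii.max() > rmax_fit:
        log.warning("sandbox_fd: trimming radii beyond the zone extent")
        radii = radii[radii <= rmax_fit]
    if len(radii) < 3:
        raise ValueError("degenerate radius range")
    rmax = int(radii.max())

    ys, xs = np.nonzero(fg)
    inner = (ys >= rmax) & (ys < h - rmax) & (xs >= rmax) & (xs < w - rmax)
    if inner.sum() >= n_seeds // 5:
        ys, xs = ys[inner], xs[inner]
    if len(ys) < n_seeds:
        if len(ys) == 0:
            raise ValueError("no usable seed pixels in zone")
        idx = np.arange(len(ys))
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(ys), size=n_seeds, replace=False)
    sy, sx = ys[idx], xs[idx]

    # summed-area table for O(1) window sums
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(fg, axis=0), axis=1)
    means = []
    for r in radii:
        y0 = np.clip(sy - r, 0, h)
        y1 = np.clip(sy + r + 1, 0, h)
        x0 = np.clip(sx - r, 0, w)
        x1 = np.clip(sx + r + 1, 0, w)
        n = sat[y1, x1] - sat[y0, x1] - sat[y1, x0] + sat[y0, x0]
        means.append(n.mean())
    slope, _ = np.polyfit(np.log(2 * radii + 1), np.log(means), 1)
    return float(slope)


def width_gradient(profile: WidthProfile) -> dict[str, float]:
    """Taper of one vessel: Theil–Sen slope of width (μm) on arc (mm).

    Negative slopes indicate thinning toward the periphery.  The median-of
    -pairwise-slopes estimator tolerates up to ~29% outlying samples, so a
    few artefactual width readings do not move the fit.
    """
    if len(profile.arc_mm) < 5:
        raise ValueError("need at least 5 width samples for a gradient fit")
    res = stats.theilslopes(profile.width_um, profile.arc_mm)
    return {
        "slope_um_per_mm": float(res.slope),
        "intercept_um": float(res.intercept),
        "slope_lo": float(res.low_slope),
        "slope_hi": float(res.high_slope),
        "n_samples": len(profile.arc_mm),
    }


def global_width_gradient(per_quadrant: dict[str, float] | list[float]) -> tuple[float, int]:
    """Global width gradient: arithmetic mean of available quadrant values.

    Returns (mean, number of contributing quadrants); NaN quadrants are
    skipped.  With zero quadrants the value is NaN with n = 0.
    """
    vals = list(per_quadrant.values()) if isinstance(per_quadrant, dict) else list(per_quadrant)
    vals = [v for v in vals if v is not None and np.isfinite(v)]
    if not vals:
        log.warning("global_width_gradient: no quadrant values available")
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)
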