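"""Synthetic inputs with construction-time ground truth.

Every raster the measurement pipeline consumes can be generated here with
known truth, so recovery is testable without any acquisition hardware:

* vessel trees rendered as strokes of known caliber, taper and wave
  tortuosity radiating from an optic disc;
* choroid B-scan phantoms with bright stroma, dark elliptical lumina
  painted until a target luminal fraction is reached (the realized
  painted-pixel fraction is counted directly and returned);
* OCTA angiogram stacks with a known avascular cylinder/cone at the fovea
  inside random capillary texture of stated density;
* two-eyes-per-subject cohorts with exchangeable within-subject residual
  correlation and stated group effects.

Ground truth is always computed by construction (direct counting or
closed form), never by the pipeline under test.  All generators are
bit-reproducible under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import VesselMap, ChoroidScan, AngioStack

__all__ = [
    "VesselTreeParams",
    "gen_vessel_map",
    "ChoroidPhantomParams",
    "gen_choroid_stack",
    "AngioPhantomParams",
    "gen_angio_stack",
    "CohortParams",
    "gen_cohort",
]


# ---------------------------------------------------------------------------
# vessel trees


@dataclass
class VesselTreeParams:
    """Geometry of a synthetic posterior-pole vessel tree.

    Calibers are in μm at the disc and taper linearly with arc length at
    ``taper_slope`` μm/mm (negative = peripheral thinning);
    ``tortuosity_amp`` is the dimensionless amplitude of a sinusoidal
    lateral displacement (0 gives perfectly straight vessels).
    """

    image_size: tuple[int, int] = (512, 512)
    od_center: tuple[float, float] = (256.0, 256.0)
    fovea_center: tuple[float, float] = (100.0, 256.0)
    od_diameter: float = 60.0
    n_arterioles: int = 7
    n_venules: int = 7
    caliber_mean_artery: float = 120.0  # μm
    caliber_mean_vein: float = 150.0
    caliber_jitter: float = 0.15  # relative spread of per-vessel calibers
    taper_slope: float = 0.0  # μm/mm, signed
    tortuosity_amp: float = 0.0
    tortuosity_wavelength: float = 80.0  # px
    pixel_scale: float = 10.0  # μm per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_diameter <= 0 or self.pixel_scale <= 0:
            raise ValueError("od_diameter and pixel_scale must be positive")
        if min(self.caliber_mean_artery, self.caliber_mean_vein) <= 0:
            raise ValueError("calibers must be positive")


def _render_stroke(mask: np.ndarray, pts: np.ndarray, half_w: np.ndarray) -> None:
    """Paint the union of discs of radius ``half_w`` centred on ``pts``
    (round-capped stroke; a pixel is on when its centre lies within the
    local half-width of the centerline)."""
    h, w = mask.shape
    x0 = max(int(np.floor((pts[:, 0] - half_w).min())) - 1, 0)
    x1 = min(int(np.ceil((pts[:, 0] + half_w).max())) + 2, w)
    y0 = max(int(np.floor((pts[:, 1] - half_w).min())) - 1, 0)
    y1 = min(int(np.ceil((pts[:, 1] + half_w).max())) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(pts)
    dist, idx = tree.query(grid, k=1)
    on = dist <= half_w[idx]
    mask[y0:y1, x0:x1] |= on.reshape(yy.shape)


def gen_vessel_map(params: VesselTreeParams) -> tuple[VesselMap, pd.DataFrame]:
    """Render a synthetic vessel map plus a per-vessel ground-truth table.

    Truth columns: class, true caliber at the disc (μm and px), taper
    slope, the analytic arc/chord tortuosity ratio of the centerline, and
    a ``clipped`` flag for vessels trimmed at the canvas edge.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    masks = {"artery": np.zeros((h, w), bool), "vein": np.zeros((h, w), bool)}
    truth_rows = []
    specs = [("artery", params.n_arterioles, params.caliber_mean_artery),
             ("vein", params.n_venules, params.caliber_mean_vein)]
    r_disc = params.od_diameter / 2.0
    for cls, n_vessels, cal_mean in specs:
        base = rng.uniform(0, 2 * np.pi)
        for j in range(n_vessels):
            angle = base + 2 * np.pi * j / n_vessels + rng.normal(0, 0.08)
            u = np.array([np.cos(angle), np.sin(angle)])
            v = np.array([-u[1], u[0]])  # lateral direction
            caliber_um = cal_mean * (1 + params.caliber_jitter * rng.uniform(-1, 1))
            phase = rng.uniform(0, 2 * np.pi)
            # march until the canvas edge
            length = min(h, w)  # generous upper bound, clipped below
            t = np.arange(0.0, length, 0.5)
            origin = np.asarray(params.od_center) + r_disc * u
            lateral = (params.tortuosity_amp * params.tortuosity_wavelength
                       * np.sin(2 * np.pi * t / params.tortuosity_wavelength + phase))
            pts = origin + np.outer(t, u) + np.outer(lateral, v)
            margin = caliber_um / params.pixel_scale / 2 + 1
            inside = ((pts[:, 0] >= margin) & (pts[:, 0] < w - margin)
                      & (pts[:, 1] >= margin) & (pts[:, 1] < h - margin))
            cut = np.argmin(inside) if not inside.all() else len(t)
            clipped = cut < len(t)
            pts, t = pts[:cut], t[:cut]
            if len(pts) < 4:
                continue
            seg = np.hypot(*np.diff(pts, axis=0).T)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            width_um = caliber_um + params.taper_slope * (arc * params.pixel_scale / 1000.0)
            width_um = np.maximum(width_um, params.pixel_scale)  # never thinner than 1 px
            half_w = width_um / params.pixel_scale / 2.0
            _render_stroke(masks[cls], pts, half_w)
            chord = float(np.hypot(*(pts[-1] - pts[0])))
            truth_rows.append({
                "vessel_id": f"{cls[0]}{j}",
                "vessel_class": cls,
                "caliber_um": caliber_um,
                "caliber_px": caliber_um / params.pixel_scale,
                "taper_um_per_mm": params.taper_slope,
                "arc_chord_ratio": float(arc[-1]) / chord if chord > 0 else np.nan,
                "angle_rad": float(angle % (2 * np.pi)),
                "clipped": clipped,
            })
    vmap = VesselMap(
        artery_mask=masks["artery"],
        vein_mask=masks["vein"],
        od_center=params.od_center,
        od_diameter=params.od_diameter,
        fovea_center=params.fovea_center,
        pixel_scale=params.pixel_scale,
        laterality="right",
    )
    return vmap, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# choroid phantoms


@dataclass
class ChoroidPhantomParams:
    """Choroid OCT phantom: bright stroma between smooth boundaries with
    dark elliptical lumina painted to a target areal fraction.

    Defaults mirror the study's EDI volume dialect: 25 B-scans spaced
    240 μm apart.  ``thickness_um`` is the nominal inner-to-outer
    distance; the actual thickness field is a smooth dome peaking at the
    fovea unless ``flat`` is set.
    """

    n_bscans: int = 25
    bscan_spacing: float = 240.0  # μm
    ascans_per_bscan: int = 384
    bscan_height: int = 160  # axial pixels
    axial_scale: float = 3.87  # μm/pixel
    lateral_scale: float = 11.3  # μm/pixel
    thickness_um: float = 300.0
    thickness_dome: float = 0.2  # relative centre-to-edge thickening
    flat: bool = False
    luminal_fraction: float = 0.4
    vessel_radius_range: tuple[float, float] = (2.0, 8.0)  # px
    stroma_level: int = 170
    contrast: float = 120.0  # grey-level separation stroma − lumen
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.luminal_fraction <= 1:
            raise ValueError("luminal_fraction must be in [0, 1]")
        if self.thickness_um < 0:
            raise ValueError("thickness must be non-negative")


def gen_choroid_stack(params: ChoroidPhantomParams) -> tuple[ChoroidScan, dict]:
    """Build a choroid phantom stack and count the realized luminal pixels.

    Lumina are non-overlapping ellipses sampled until the target fraction
    is reached, so the realized dark-pixel fraction inside the choroid
    mask is exactly countable at construction time.  Truth dict carries
    the global realized fraction, per-B-scan luminal/choroid pixel
    counts, and a flag when the target was unreachable.
    """
    rng = np.random.default_rng(params.seed)
    n, h, w = params.n_bscans, params.bscan_height, params.ascans_per_bscan
    inner_px = h * 0.15 + 2.0 * np.sin(np.linspace(0, np.pi, w))[None, :] \
        + np.linspace(0, 1.5, n)[:, None]
    thick_px = np.full((n, w), params.thickness_um / params.axial_scale)
    if not params.flat:
        bb, aa = np.mgrid[0:n, 0:w]
        r2 = (((bb - n / 2) / (n / 2)) ** 2 + ((aa - w / 2) / (w / 2)) ** 2)
        thick_px *= 1 + params.thickness_dome * (1 - np.clip(r2, 0, 1))
    outer_px = np.minimum(inner_px + thick_px, h - 1)

    stack = np.full((n, h, w), 40.0)
    rows = np.arange(h)[None, :, None]
    choroid = (rows >= inner_px[:, None, :]) & (rows < outer_px[:, None, :])
    stack[choroid] = params.stroma_level
    lumen_level = params.stroma_level - params.contrast

    painted = np.zeros((n, h, w), bool)
    n_choroid = int(choroid.sum())
    target_px = int(round(params.luminal_fraction * n_choroid))
    flagged = False
    if target_px > 0:
        r_lo, r_hi = params.vessel_radius_range
        n_painted = 0
        misses = 0
        max_misses = 4000 * n
        while n_painted < target_px and misses < max_misses:
            b = int(rng.integers(0, n))
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            ra = rng.uniform(r_lo, r_hi)
            rb = ra * rng.uniform(0.6, 1.4)
            th = rng.uniform(0, np.pi)
            y0, y1 = int(max(cy - rb - ra, 0)), int(min(cy + rb + ra + 2, h))
            x0, x1 = int(max(cx - rb - ra, 0)), int(min(cx + rb + ra + 2, w))
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dx, dy = xx - cx, yy - cy
            c, s = np.cos(th), np.sin(th)
            ell = ((dx * c + dy * s) / ra) ** 2 + ((-dx * s + dy * c) / rb) ** 2 <= 1
            ell &= choroid[b, y0:y1, x0:x1]
            if not ell.any() or (ell & painted[b, y0:y1, x0:x1]).any():
                misses += 1
                continue
            painted[b, y0:y1, x0:x1] |= ell
            n_painted += int(ell.sum())
        if n_painted < target_px:
            flagged = True
    stack[painted] = lumen_level
    if params.noise_sd > 0:
        stack = stack + rng.normal(0, params.noise_sd, stack.shape)
    stack = np.clip(np.round(stack), 0, 255).astype(np.uint8)

    realized = float(painted.sum()) / n_choroid if n_choroid else 0.0
    scan = ChoroidScan(
        bscans=stack,
        inner_boundary=inner_px,
        outer_boundary=outer_px,
        axial_scale=params.axial_scale,
        lateral_scale=params.lateral_scale,
        bscan_spacing=params.bscan_spacing,
        fovea=(n // 2, w // 2),
    )
    truth = {
        "target_luminal_fraction": params.luminal_fraction,
        "realized_luminal_fraction": realized,
        "luminal_px_per_bscan": painted.sum(axis=(1, 2)),
        "choroid_px_per_bscan": choroid.sum(axis=(1, 2)),
        "luminal_px_per_column": painted.sum(axis=1),
        "choroid_px_per_column": choroid.sum(axis=1),
        "thickness_um": thick_px * params.axial_scale,
        "target_unreachable": flagged,
    }
    return scan, truth


# ---------------------------------------------------------------------------
# angiogram phantoms


@dataclass
class AngioPhantomParams:
    """OCTA phantom: random capillary texture of stated density outside a
    circular avascular core at the fovea, per depth slice.

    ``radius_profile_um`` gives the core radius per depth slice (constant
    → cylinder, linear ramp → cone); the analytic core areas (πr²) and
    their depth integral are the ground truth.
    """

    field_px: int = 640
    lateral_scale: float = 0.01  # mm per pixel
    n_depth: int = 11
    depth_pitch_um: float = 10.0
    radius_profile_um: np.ndarray | float = 300.0
    density: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.density <= 1:
            raise ValueError("density must be in [0, 1]")
        prof = np.broadcast_to(np.asarray(self.radius_profile_um, float),
                               (self.n_depth,)).copy()
        if np.any(prof < 0):
            raise ValueError("radii must be non-negative")
        half_field_um = self.field_px / 2 * self.lateral_scale * 1000
        if np.any(prof >= half_field_um):
            raise ValueError("avascular core larger than the field")
        self.radius_profile_um = prof


def gen_angio_stack(params: AngioPhantomParams) -> tuple[AngioStack, dict]:
    """Depth-resolved angiogram phantom plus closed-form FAZ truth.

    Truth: per-depth analytic core area πr² (mm²), trapezoidal volume
    (mm³), and realized capillary density per ETDRS ring counted at
    construction for the SVC/DVC en-face slabs.
    """
    rng = np.random.default_rng(params.seed)
    npx = params.field_px
    c = (npx - 1) / 2.0
    yy, xx = np.mgrid[0:npx, 0:npx]
    r_px = np.hypot(xx - c, yy - c)
    stack = np.empty((params.n_depth, npx, npx), bool)
    for i, r_um in enumerate(params.radius_profile_um):
        core = r_px <= r_um / (params.lateral_scale * 1000.0)
        texture = rng.random((npx, npx)) < params.density
        stack[i] = texture & ~core
    third = max(params.n_depth // 3, 1)
    labels = ["SVC"] * third + ["ICP"] * third + ["DCP"] * (params.n_depth - 2 * third)
    # device-style en-face slabs with independent texture at the same density
    slabs = {}
    slab_core_um = {"SVC": params.radius_profile_um[:third].mean(),
                    "DVC": params.radius_profile_um[third:].mean()}
    for name in ("SVC", "DVC"):
        core = r_px <= slab_core_um[name] / (params.lateral_scale * 1000.0)
        slabs[name] = (rng.random((npx, npx)) < params.density) & ~core

    area_mm2 = np.pi * (params.radius_profile_um / 1000.0) ** 2
    depth_mm = np.arange(params.n_depth) * params.depth_pitch_um / 1000.0
    volume = float(np.trapezoid(area_mm2, depth_mm))
    ring_density = {}
    scale = params.lateral_scale
    for name, slab in slabs.items():
        for rname, (r0, r1) in {"inner": (1, 2), "outer": (2, 3), "global": (0, 3)}.items():
            ring = (r_px * scale >= r0) & (r_px * scale < r1)
            ring_density[f"{name}_{rname}"] = float((slab & ring).sum() / ring.sum())
    stack_obj = AngioStack(
        lateral_scale=scale,
        fovea_center=(c, c),
        slabs=slabs,
        stack=stack,
        depth_pitch_um=params.depth_pitch_um,
        depth_labels=labels,
    )
    truth = {
        "area_per_depth_mm2": area_mm2,
        "volume_mm3": volume,
        "ring_density": ring_density,
        "radius_profile_um": params.radius_profile_um,
    }
    return stack_obj, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortParams:
    """Two-eyes-per-subject cohort with exchangeable residual correlation.

    Group sizes default to the shape of a small case–control MS imaging
    cohort (controls, MS eyes without optic neuritis history, MS eyes
    with).  ``effect_sizes`` maps outcome name -> {group: offset}; the
    residual of the two eyes of a subject has correlation ``rho``.
    """

    n_ctrl: int = 25
    n_msnon: int = 10
    n_mson: int = 6
    eyes_per_subject: int = 2
    rho: float = 0.6
    outcome_means: dict[str, float] = field(default_factory=lambda: {"CVI": 65.0})
    outcome_sds: dict[str, float] = field(default_factory=lambda: {"CVI": 5.0})
    effect_sizes: dict[str, dict[str, float]] = field(default_factory=dict)
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")


def gen_cohort(params: CohortParams) -> tuple[pd.DataFrame, dict]:
    """Simulate per-eye records and return the true coefficient vectors.

    Outcomes follow ``y = mean + group offset + covariate effects + eps``
    with compound-symmetric Gaussian residuals (equal correlation ``rho``
    between the eyes of one subject).  Covariates echo the study's
    pattern: lower IOP and more hypertension in MS subjects.
    """
    rng = np.random.default_rng(params.seed)
    groups = (["Ctrl"] * params.n_ctrl + ["MSnON"] * params.n_msnon
              + ["MSON"] * params.n_mson)
    rows = []
    for sid, grp in enumerate(groups):
        is_ms = grp != "Ctrl"
        age = float(np.clip(rng.normal(52 if is_ms else 48, 11), 25, 80))
        sex = "F" if rng.random() < (0.48 if is_ms else 0.65) else "M"
        iop = float(np.clip(rng.normal(13.0 if is_ms else 15.7, 3.0), 7, 23))
        htn = int(rng.random() < (0.55 if is_ms else 0.08))
        sph = float(np.clip(rng.normal(0.8 if is_ms else -0.2, 1.8), -6.5, 6.5))
        if is_ms:
            edss_dx = float(rng.integers(2, 9)) / 2.0  # 1.0–4.0 in 0.5 steps
            years = float(rng.integers(3, 35))
            edss_visit = float(np.clip(edss_dx + round(rng.gamma(2.0, 1.0) * 2) / 2.0, 0, 10))
        else:
            edss_dx = edss_visit = 0.0
            years = np.nan
        for e in range(params.eyes_per_subject):
            rows.append({
                "subject_id": f"S{sid:03d}", "eye": "OD" if e == 0 else "OS",
                "group": grp, "age": age, "sex": sex, "iop": iop,
                "hypertension": htn, "spherical_error": sph,
                "edss_dx": edss_dx, "edss_visit": edss_visit,
                "years_since_dx": years,
                "edss_progression": (edss_visit - edss_dx) / years if is_ms else np.nan,
            })
    df = pd.DataFrame(rows)
    true_betas: dict[str, dict[str, float]] = {}
    n_subj = len(groups)
    k = params.eyes_per_subject
    for outcome, mu in params.outcome_means.items():
        sd = params.outcome_sds.get(outcome, 1.0)
        offsets = params.effect_sizes.get(outcome, {})
        cov_eff = params.covariate_effects.get(outcome, {})
        # compound-symmetric residual: shared subject term + eye term
        z_subj = rng.normal(0, 1, n_subj)
        z_eye = rng.normal(0, 1, (n_subj, k))
        eps = sd * (np.sqrt(params.rho) * z_subj[:, None]
                    + np.sqrt(1 - params.rho) * z_eye)
        y = np.empty(len(df))
        for i, (sid, row) in enumerate(zip(np.repeat(np.arange(n_subj), k),
                                           df.itertuples(index=False))):
            val = mu + offsets.get(row.group, 0.0) + eps[sid, i % k]
            for cov, beta in cov_eff.items():
                val += beta * getattr(row, cov)
            y[i] = val
        df[outcome] = y
        true_betas[outcome] = {
            "Intercept": mu,
            **{f"group[{g}]": v for g, v in offsets.items()},
            **cov_eff,
        }
    truth = {"betas": true_betas, "rho": params.rho}
    return df, truth
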