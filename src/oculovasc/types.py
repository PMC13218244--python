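"""Core containers shared across the measurement modules.

Coordinate convention: images are ``ndarray[y, x]`` with the origin at the
top-left pixel centre, x increasing rightward and y downward.  Point-like
fields (``od_center``, ``fovea_center``) are ``(x, y)`` tuples in pixel
units.  Physical scales are carried explicitly (μm/pixel for fundus and OCT
axial/lateral scales, mm/pixel for OCTA en-face slabs) and every distance is
Euclidean in pixels unless a scale is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VesselMap",
    "ZoneSpec",
    "ZONE_B",
    "ZONE_C",
    "CaliberResult",
    "WidthProfile",
    "ExtendedZone",
    "AngioStack",
    "RingSpec",
    "FazResult",
    "ChoroidScan",
    "BinarizationConfig",
    "ChoroidMaps",
]


@dataclass
class VesselMap:
    """Binary artery/vein rasters with optic-disc and fovea landmarks.

    ``artery_mask`` and ``vein_mask`` may overlap at arteriovenous
    crossings; overlaps are counted in both classes downstream.
    """

    artery_mask: np.ndarray
    vein_mask: np.ndarray
    od_center: tuple[float, float]
    od_diameter: float
    fovea_center: Optional[tuple[float, float]] = None
    pixel_scale: Optional[float] = None  # μm per pixel
    laterality: str = "right"

    def __post_init__(self) -> None:
        self.artery_mask = np.asarray(self.artery_mask, dtype=bool)
        self.vein_mask = np.asarray(self.vein_mask, dtype=bool)
        if self.artery_mask.shape != self.vein_mask.shape:
            raise ValueError("artery and vein masks must share a shape")
        if self.od_diameter <= 0:
            raise ValueError("od_diameter must be positive")
        if self.pixel_scale is not None and self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.artery_mask.shape

    @property
    def union_mask(self) -> np.ndarray:
        return self.artery_mask | self.vein_mask


@dataclass(frozen=True)
class ZoneSpec:
    """Annulus bounds in units of optic-disc diameter, measured from the
    disc margin (the Parr–Hubbard/Knudtson convention): a point at distance
    d from the disc centre is inside the zone when
    ``R + inner*D <= d < R + outer*D`` with ``R = D/2``."""

    inner_offset: float
    outer_offset: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.inner_offset < self.outer_offset):
            raise ValueError("require 0 <= inner_offset < outer_offset")


#: Caliber zone: 0.5–1.0 disc diameters from the disc margin.
ZONE_B = ZoneSpec(0.5, 1.0, "B")
#: Geometry zone: 0.5–2.0 disc diameters from the disc margin.
ZONE_C = ZoneSpec(0.5, 2.0, "C")


@dataclass
class CaliberResult:
    """Knudtson summary calibers.  Units are pixels unless the vessel map
    carried a μm/pixel scale, in which case μm."""

    crae: float
    crve: float
    avr: float
    n_arterioles_used: int
    n_venules_used: int
    units: str = "px"


@dataclass
class WidthProfile:
    """Ordered (arc position, width) samples along one vessel path."""

    vessel_id: str
    vessel_class: str  # "artery" | "vein"
    arc_mm: np.ndarray
    width_um: np.ndarray
    quadrant: str = ""  # superotemporal|superonasal|inferotemporal|inferonasal

    def __post_init__(self) -> None:
        self.arc_mm = np.asarray(self.arc_mm, dtype=float)
        self.width_um = np.asarray(self.width_um, dtype=float)
        if self.arc_mm.shape != self.width_um.shape:
            raise ValueError("arc and width must have equal length")
        if np.any(np.diff(self.arc_mm) <= 0):
            raise ValueError("arc positions must be strictly increasing")
        if np.any(self.width_um <= 0):
            raise ValueError("widths must be positive")


@dataclass
class ExtendedZone:
    """Standardised ultra-widefield region of interest."""

    mask: np.ndarray
    area_mm2: float
    rotation_deg: float = 0.0
    mirrored: bool = False


@dataclass
class AngioStack:
    """OCTA en-face slabs and/or a depth-resolved binarized stack.

    ``slabs`` maps slab names (``SVC``/``DVC``) to binary en-face rasters;
    ``stack`` is an optional ``(n_depth, H, W)`` binary array between the
    ILM and OPL surrogates, with ``depth_pitch_um`` the slice spacing.
    ``lateral_scale`` is mm per pixel.
    """

    lateral_scale: float
    fovea_center: tuple[float, float]
    slabs: dict[str, np.ndarray] = field(default_factory=dict)
    stack: Optional[np.ndarray] = None
    depth_pitch_um: Optional[float] = None
    depth_labels: Optional[Sequence[str]] = None  # per-slice SVC/ICP/DCP

    def __post_init__(self) -> None:
        if self.lateral_scale <= 0:
            raise ValueError("lateral_scale must be positive")
        names = list(self.slabs)
        if len(set(names)) != len(names):
            raise ValueError("slab names must be unique")
        for name, arr in self.slabs.items():
            arr = np.asarray(arr)
            if not np.isin(np.unique(arr), [0, 1]).all():
                raise ValueError(f"slab {name!r} must be binary")
            self.slabs[name] = arr.astype(bool)
        if self.stack is not None:
            self.stack = np.asarray(self.stack).astype(bool)


@dataclass(frozen=True)
class RingSpec:
    """Radial annulus bounds in mm around the fovea."""

    r_in: float
    r_out: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.r_in < self.r_out):
            raise ValueError("require 0 <= r_in < r_out")


@dataclass
class FazResult:
    """Foveal avascular zone areas per plexus and integrated volume."""

    area_sup: float
    area_int: float
    area_deep: float
    volume: float
    depth_um: np.ndarray = field(default_factory=lambda: np.array([]))
    area_profile: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class ChoroidScan:
    """B-scan stack with inner/outer choroid boundary polylines.

    Boundaries are axial (row) positions per A-scan, shape ``(n_bscans,
    n_ascans)``; the inner boundary is Bruch's membrane and the outer is
    the choroidal–scleral interface, both taken as supplied.
    """

    bscans: np.ndarray  # (n_bscans, H, W) grayscale
    inner_boundary: np.ndarray  # (n_bscans, W) axial px
    outer_boundary: np.ndarray
    axial_scale: float  # μm per pixel
    lateral_scale: float  # μm per pixel
    bscan_spacing: float  # μm between B-scans
    fovea: tuple[int, int] = (0, 0)  # (bscan index, A-scan index)

    def __post_init__(self) -> None:
        self.bscans = np.asarray(self.bscans)
        self.inner_boundary = np.asarray(self.inner_boundary, dtype=float)
        self.outer_boundary = np.asarray(self.outer_boundary, dtype=float)
        if self.bscans.ndim != 3:
            raise ValueError("bscans must be a (n, H, W) stack")
        n, h, w = self.bscans.shape
        if self.inner_boundary.shape != (n, w) or self.outer_boundary.shape != (n, w):
            raise ValueError("boundaries must be (n_bscans, n_ascans)")
        if np.any(self.outer_boundary < self.inner_boundary):
            bad = np.argwhere(self.outer_boundary < self.inner_boundary)[0]
            raise ValueError(
                f"outer boundary above inner at B-scan {bad[0]}, A-scan {bad[1]}"
            )
        if np.any(self.inner_boundary < 0) or np.any(self.outer_boundary > h):
            raise ValueError("boundaries must lie within the image")
        for name in ("axial_scale", "lateral_scale", "bscan_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_bscans(self) -> int:
        return self.bscans.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.bscans.shape[2]


@dataclass
class BinarizationConfig:
    """Choroid binarization settings.

    The pipeline is: Gaussian smoothing (``gaussian_sigma``), 8-bit
    rescale within the choroid mask, local Otsu thresholding
    (``local_window``), one erosion and one dilation (``morph_radius``);
    dark pixels are luminal.  It is repeated with each extra smoothing
    sigma in ``scales`` and the luminal masks are combined by union so
    both small and large lumina are captured.
    """

    gaussian_sigma: float = 0.5
    local_window: int = 51
    morph_radius: int = 1
    scales: tuple[float, ...] = (0.5, 2.0, 4.0)
    combine: str = "union"

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.local_window < 3 or self.local_window % 2 == 0:
            raise ValueError("local_window must be odd and >= 3")


@dataclass
class ChoroidMaps:
    """En-face choroidal thickness (μm) and vascularity (fraction) maps.

    Rows run along the slow axis at ``row_scale_um`` pitch, columns along
    the B-scan at ``col_scale_um``.  Pixels outside B-scan coverage are
    NaN (masked), never zero-filled.
    """

    ct_map: np.ndarray
    cvi_map: np.ndarray
    row_scale_um: float
    col_scale_um: float
    fovea_rc: tuple[float, float]  # (row, col) of the fovea in map coords
    single_bscan: bool = False
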