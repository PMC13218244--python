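"""Dataset simulation and the per-eye measurement driver.

``simulate_dataset`` writes a complete synthetic cohort to disk in the
layout documented in :mod:`oculovasc.io` — clinical table plus per-eye
vessel maps, width-profile tables, angiogram stacks and choroid stacks —
with a planted group effect on the choroidal vascularity index and
construction-time truth saved alongside.  ``run_pipeline`` walks the
dataset, computes every available vascular parameter per eye, joins the
results to the clinical table on (subject, eye), runs the GEE model
presets, and writes deterministic CSV/JSON artifacts.  A stage failing
for one eye is recorded in the manifest and the pipeline continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import choroid as chor
from . import fundus, octa, widefield
from .io import (
    read_angio_stack,
    read_choroid_scan,
    read_vessel_map,
    read_width_profiles,
    write_angio_stack,
    write_choroid_scan,
    write_vessel_map,
    write_width_profiles,
)
from .stats import fit_models
from .synth import (
    AngioPhantomParams,
    ChoroidPhantomParams,
    CohortParams,
    VesselTreeParams,
    gen_angio_stack,
    gen_choroid_stack,
    gen_cohort,
    gen_vessel_map,
)
from .types import BinarizationConfig, VesselMap, WidthProfile

__all__ = ["SimulationConfig", "simulate_dataset", "PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

_CSV_FMT = "%.8g"


@dataclass
class SimulationConfig:
    """Problem sizes and planted effects for a simulated dataset.

    The planted effect is on CVI (in fraction units): MS eyes get
    ``cvi_effect`` added to the control mean ``cvi_mean``; each eye's
    choroid phantom is painted toward its own simulated target fraction.
    Image sizes are kept modest so a full cohort runs on a laptop; they
    scale the rasters, not the study design.
    """

    cohort: CohortParams = field(default_factory=CohortParams)
    cvi_mean: float = 0.45
    cvi_sd: float = 0.03
    cvi_effect: float = -0.05  # MS offset, fraction units
    taper_slope: float = -2.0  # true peripheral taper, μm/mm
    vessel_image_px: int = 384
    choroid_bscans: int = 7
    choroid_ascans: int = 256
    choroid_height: int = 128
    angio_field_px: int = 640
    angio_depth: int = 7
    seed: int = 0

    def cohort_params(self) -> CohortParams:
        p = self.cohort
        p.seed = self.seed
        p.outcome_means = {"cvi_target": self.cvi_mean}
        p.outcome_sds = {"cvi_target": self.cvi_sd}
        p.effect_sizes = {
            "cvi_target": {"MSnON": self.cvi_effect, "MSON": self.cvi_effect}
        }
        return p


_QUADRANTS = ("superotemporal", "superonasal", "inferotemporal", "inferonasal")


def simulate_dataset(out_dir: Path, cfg: SimulationConfig | None = None) -> pd.DataFrame:
    """Write a full synthetic dataset; returns the clinical table.

    Every modality is generated per eye with an eye-specific seed derived
    from the dataset seed, so the whole dataset is reproducible from one
    integer.  Construction-time truth (per-eye realized CVI fraction,
    true taper, FAZ geometry) is stored in ``truth.csv``.
    """
    cfg = cfg or SimulationConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clinical, truth = gen_cohort(cfg.cohort_params())
    ss = np.random.SeedSequence(cfg.seed)
    truth_rows = []
    for i, row in clinical.iterrows():
        eye_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        eye_dir = out_dir / "eyes" / f"{row.subject_id}_{row.eye}"
        rng = np.random.default_rng(eye_seed)
        n = cfg.vessel_image_px
        vp = VesselTreeParams(
            image_size=(n, n), od_center=(n * 0.5, n * 0.5),
            fovea_center=(n * 0.2, n * 0.5), od_diameter=n / 8.5,
            tortuosity_amp=0.04, seed=eye_seed,
        )
        vmap, vtruth = gen_vessel_map(vp)
        write_vessel_map(eye_dir, vmap)

        profiles = []
        for q, quad in enumerate(_QUADRANTS):
            for cls, cal in (("artery", 110.0), ("vein", 140.0)):
                arc = np.linspace(0, 8, 40)
                width = (cal * (1 + 0.1 * rng.uniform(-1, 1))
                         + cfg.taper_slope * arc + rng.normal(0, 1.5, arc.size))
                width = np.maximum(width, 5.0)
                profiles.append(WidthProfile(f"{cls[0]}{q}", cls, arc, width, quad))
        write_width_profiles(eye_dir, profiles)

        ap = AngioPhantomParams(
            field_px=cfg.angio_field_px, n_depth=cfg.angio_depth,
            radius_profile_um=float(rng.uniform(250, 350)), seed=eye_seed,
        )
        astack, atruth = gen_angio_stack(ap)
        write_angio_stack(eye_dir, astack)

        cvi_target = float(np.clip(row.cvi_target, 0.05, 0.6))
        cp = ChoroidPhantomParams(
            n_bscans=cfg.choroid_bscans, ascans_per_bscan=cfg.choroid_ascans,
            bscan_height=cfg.choroid_height, luminal_fraction=cvi_target,
            thickness_um=float(rng.uniform(260, 340)), seed=eye_seed,
        )
        scan, ctruth = gen_choroid_stack(cp)
        write_choroid_scan(eye_dir, scan)
        truth_rows.append({
            "subject_id": row.subject_id, "eye": row.eye,
            "cvi_target": cvi_target,
            "cvi_realized": ctruth["realized_luminal_fraction"],
            "taper_true_um_per_mm": cfg.taper_slope,
            "faz_volume_true_mm3": atruth["volume_mm3"],
            "eye_seed": eye_seed,
        })
    clinical = clinical.drop(columns=["cvi_target"])
    clinical.to_csv(out_dir / "clinical.csv", index=False, float_format=_CSV_FMT)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False, float_format=_CSV_FMT)
    (out_dir / "simulation.json").write_text(json.dumps(
        {"seed": cfg.seed, "cvi_mean": cfg.cvi_mean, "cvi_effect": cfg.cvi_effect,
         "true_betas": truth["betas"], "rho": truth["rho"]}, indent=1, default=str))
    return clinical


@dataclass
class PipelineConfig:
    """Driver settings: dataset location, stage parameters, model presets."""

    data_dir: Path
    out_dir: Path
    binarization: BinarizationConfig = field(default_factory=BinarizationConfig)
    faz_closing_um: float = 25.0
    sandbox_seed: int = 7
    models: tuple[str, ...] = ("group_unadjusted", "group_adjusted")
    outcomes: tuple[str, ...] = ("CRAE", "CRVE", "AVR", "TORT", "VD", "FD",
                                 "WGa", "WGv", "FD_extended",
                                 "SVC_global", "DVC_global", "FAZ_volume",
                                 "CT_global", "CVI_global")


def _eye_fundus(vmap: VesselMap) -> dict[str, float]:
    # calibers reported in pixels (the vessel-map scale is used only by
    # the widefield stage), matching how fundus calibers are tabulated
    vmap_px = VesselMap(vmap.artery_mask, vmap.vein_mask, vmap.od_center,
                        vmap.od_diameter, vmap.fovea_center, None, vmap.laterality)
    return fundus.analyze_vessel_map(vmap_px).as_row()


def _eye_widefield(vmap: VesselMap, profiles, sandbox_seed: int) -> dict[str, float]:
    out: dict[str, float] = {}
    if profiles:
        for cls, key in (("artery", "WGa"), ("vein", "WGv")):
            per_quadrant: dict[str, float] = {}
            for quad in _QUADRANTS:
                cand = [p for p in profiles if p.vessel_class == cls and p.quadrant == quad]
                if not cand:
                    continue
                # longest profile stands in for the most prominent vessel
                best = max(cand, key=lambda p: p.arc_mm[-1] - p.arc_mm[0])
                per_quadrant[quad] = widefield.width_gradient(best)["slope_um_per_mm"]
            mean, n_q = widefield.global_width_gradient(per_quadrant)
            out[key] = mean
            out[f"{key}_n_quadrants"] = n_q
    if vmap is not None and vmap.fovea_center is not None and vmap.pixel_scale:
        aligned, tr = widefield.align_to_od_fovea_axis(vmap)
        zone = widefield.extended_zone_mask(aligned.shape, vmap.pixel_scale,
                                            rotation_deg=tr.angle_deg, mirrored=tr.mirrored)
        out["FD_extended"] = widefield.sandbox_fd(aligned.union_mask, zone.mask,
                                                  seed=sandbox_seed)
        out["extended_zone_mm2"] = zone.area_mm2
    return out


def _eye_octa(stack, closing_um: float) -> dict[str, float]:
    out = {k: 100.0 * v for k, v in octa.density_table(stack).items()}
    if stack.stack is not None and stack.depth_pitch_um is not None:
        res = octa.faz_volume(stack, closing_radius_um=closing_um)
        out.update({"FAZ_volume": res.volume, "FAZ_area_sup": res.area_sup,
                    "FAZ_area_int": res.area_int, "FAZ_area_deep": res.area_deep})
    return out


def _eye_choroid(scan, cfg: BinarizationConfig) -> dict[str, float]:
    ct, cvi_prof = chor.bscan_profiles(scan, cfg)
    maps = chor.enface_maps(scan, ct, cvi_prof)
    out: dict[str, float] = {}
    for name, arr, scale in (("CT", maps.ct_map, 1.0), ("CVI", maps.cvi_map, 100.0)):
        summ = chor.etdrs_summary(arr, maps.fovea_rc, maps.row_scale_um, maps.col_scale_um)
        for region in ("central", "inner", "outer", "global"):
            out[f"{name}_{region}"] = scale * summ[region]
    return out


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Measure every eye, join to the clinical table, fit the presets.

    Writes ``parameters.csv`` (one row per eye), ``results.csv`` (tidy
    GEE output with BH-FDR per model family) and ``manifest.json``
    (modality availability and per-stage failures) into ``out_dir``.
    Output CSVs are byte-identical across reruns on identical input.
    """
    data_dir, out_dir = Path(cfg.data_dir), Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = {
        "data_dir": str(data_dir), "faz_closing_um": cfg.faz_closing_um,
        "sandbox_seed": cfg.sandbox_seed, "models": list(cfg.models),
        "outcomes": list(cfg.outcomes),
        "binarization": vars(cfg.binarization) | {"scales": list(cfg.binarization.scales)},
    }
    (out_dir / "config.json").write_text(json.dumps(resolved, indent=1, sort_keys=True))
    clinical = pd.read_csv(data_dir / "clinical.csv")
    eye_dirs = sorted((data_dir / "eyes").iterdir()) if (data_dir / "eyes").exists() else []
    rows = []
    manifest: dict = {"eyes": {}, "stages": ["fundus", "widefield", "octa", "choroid"]}
    for eye_dir in eye_dirs:
        subject_id, _, eye = eye_dir.name.rpartition("_")
        row: dict = {"subject_id": subject_id, "eye": eye}
        avail: dict[str, bool] = {}
        vmap = read_vessel_map(eye_dir)
        profiles = read_width_profiles(eye_dir)
        astack = read_angio_stack(eye_dir)
        scan = read_choroid_scan(eye_dir)
        stages = [
            ("fundus", vmap is not None, lambda: _eye_fundus(vmap)),
            ("widefield", vmap is not None or bool(profiles),
             lambda: _eye_widefield(vmap, profiles or [], cfg.sandbox_seed)),
            ("octa", astack is not None, lambda: _eye_octa(astack, cfg.faz_closing_um)),
            ("choroid", scan is not None, lambda: _eye_choroid(scan, cfg.binarization)),
        ]
        for name, present, fn in stages:
            avail[name] = bool(present)
            if not present:
                continue
            try:
                row.update(fn())
            except Exception as exc:  # continue with the other eyes/stages
                avail[name] = False
                manifest.setdefault("failures", []).append(
                    {"eye": eye_dir.name, "stage": name, "error": str(exc)})
                log.warning("stage %s failed for %s: %s", name, eye_dir.name, exc)
        manifest["eyes"][eye_dir.name] = avail
        rows.append(row)
    params = pd.DataFrame(rows)
    if not params.empty:
        dup = params.duplicated(subset=["subject_id", "eye"])
        if dup.any():
            raise ValueError("duplicate (subject_id, eye) rows in parameter table")
        table = clinical.merge(params, on=["subject_id", "eye"], how="left", validate="1:1")
    else:
        table = clinical
    table = table.sort_values(["subject_id", "eye"]).reset_index(drop=True)
    table.to_csv(out_dir / "parameters.csv", index=False, float_format=_CSV_FMT)

    # rename density columns to match the preset outcome names
    results = []
    outcomes = [c for c in cfg.outcomes if c in table.columns]
    for model in cfg.models:
        res = fit_models(table, outcomes, preset=model)
        if not res.empty:
            results.append(res)
    results_df = (pd.concat(results, ignore_index=True)
                  if results else pd.DataFrame())
    results_df.to_csv(out_dir / "results.csv", index=False, float_format=_CSV_FMT)
    counts = {s: sum(1 for a in manifest["eyes"].values() if a.get(s))
              for s in manifest["stages"]}
    manifest["available_counts"] = counts
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"parameters": table, "results": results_df}
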