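"""End-to-end workflow: cluster → genetic metrics → G-value → fire risk.

Each stage is skippable when its inputs are absent (a risk-only run needs no
genotypes), and a run manifest recording the config, seed, package version
and per-stage record counts is written alongside the outputs so a run can be
repeated bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .io_formats import (
    OccurrenceSet, GenotypeMatrix, VegetationMap, BurnLayer,
    read_occurrences, read_genotypes, read_vegetation, read_burn_polygons,
    read_burn_table,
)
from .spatial_units import (
    project_coordinates, dbscan_cluster, split_oversize, units_to_geojson,
    units_to_geojson_file, ManagementUnit, NOISE,
)
from .popgen import filter_genotypes, unit_metrics
from .gvalue import compute_gvalue, multispecies_gvalue
from .fire_risk import buffer_and_trim, ratios_from_layer, unit_risk

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_from_paths"]


@dataclass
class PipelineResult:
    """Everything a run produces, plus the manifest describing it."""

    units: list[ManagementUnit]
    noise_ids: list[str]
    metrics: pd.DataFrame | None
    gvalues: pd.DataFrame | None
    g_multi: pd.Series | None
    ratios: pd.DataFrame | None
    risk: pd.DataFrame | None
    manifest: dict


def run_pipeline(occ: OccurrenceSet,
                 genotypes: dict[str, GenotypeMatrix] | None = None,
                 veg: VegetationMap | None = None,
                 burn: BurnLayer | None = None,
                 cfg: RunConfig | None = None) -> PipelineResult:
    """Run every stage whose inputs are present.

    ``genotypes`` maps species_id → (unfiltered) genotype matrix.  Clustering
    pools the species; metrics and G-values are computed per species within
    the resulting units.
    """
    cfg = cfg or RunConfig()
    manifest: dict = {"config": asdict(cfg), "version": __version__, "stages": {}}

    # --- stage 1: units ---------------------------------------------------
    if not occ.is_projected:
        occ = project_coordinates(occ, cfg.crs_code)
    manifest["config"]["crs_code"] = occ.crs_code
    labeling = dbscan_cluster(occ, eps_m=cfg.eps_m, min_pts=cfg.min_pts)
    units = split_oversize(labeling, occ, perimeter_max_m=cfg.perimeter_max_m,
                           seed=cfg.rng_seed)
    noise_ids = sorted(s for s, c in labeling.labels.items() if c == NOISE)
    manifest["stages"]["cluster"] = {
        "n_samples": len(occ), "n_units": len(units), "n_noise": len(noise_ids),
        "max_perimeter_m": max((u.perimeter_m for u in units), default=0.0),
    }
    logger.info("cluster stage: %s", manifest["stages"]["cluster"])

    sample_unit = {s: u.unit_id for u in units for s in u.member_ids}

    # --- stage 2: per-species metrics --------------------------------------
    metrics = gvalues = g_multi = None
    if genotypes:
        frames = []
        for sp in sorted(genotypes):
            gm, report = filter_genotypes(genotypes[sp], cfg)
            groups = {s: sample_unit[s] for s in gm.sample_ids if s in sample_unit}
            if len(set(groups.values())) == 0:
                logger.warning("species %s: no genotyped samples fall in any unit", sp)
                continue
            gm_u = gm.subset(sample_idx=[i for i, s in enumerate(gm.sample_ids)
                                         if s in groups])
            m = unit_metrics(gm_u, groups, cfg)
            m["species_id"] = sp
            frames.append(m)
            manifest["stages"].setdefault("popgen", {})[sp] = {
                "filter": report.as_dict(),
                "n_samples": gm_u.n_samples, "n_loci": gm_u.n_loci,
                "n_units": m.shape[0],
            }
        if frames:
            metrics = pd.concat(frames)
            gvalues = compute_gvalue(metrics, cfg.gvalue_weights,
                                     normalize_variables=cfg.normalize_variables)
            g_multi = multispecies_gvalue(gvalues)
            manifest["stages"]["gvalue"] = {"n_rows": int(gvalues.shape[0])}
    else:
        logger.info("genotypes absent: G-value stage skipped")

    # --- stage 3: fire risk -------------------------------------------------
    ratios = risk = None
    if veg is not None and burn is not None:
        veg_ref = buffer_and_trim(veg, burn, cfg.buffer_m) if burn.is_polygonal else veg
        ratios = ratios_from_layer(veg_ref, burn)
        geoms, props = units_to_geojson(units, hull_buffer_m=cfg.hull_buffer_m)
        risk = unit_risk(geoms, [p["unit_id"] for p in props], veg, ratios)
        manifest["stages"]["risk"] = {"n_units": int(risk.shape[0])}
    else:
        logger.info("vegetation/burn absent: risk stage skipped")

    return PipelineResult(units=units, noise_ids=noise_ids, metrics=metrics,
                          gvalues=gvalues, g_multi=g_multi, ratios=ratios,
                          risk=risk, manifest=manifest)


def run_pipeline_from_paths(occurrences: str | Path,
                            genotypes: dict[str, tuple[str, str]] | None = None,
                            vegetation: str | Path | None = None,
                            burn: str | Path | None = None,
                            burn_table: str | Path | None = None,
                            cfg: RunConfig | None = None,
                            out_dir: str | Path | None = None) -> PipelineResult:
    """File-path front end; writes all outputs under ``out_dir`` if given."""
    cfg = cfg or RunConfig()
    occ = read_occurrences(occurrences)
    gms = None
    if genotypes:
        gms = {sp: read_genotypes(gp, mp, species_id=sp)
               for sp, (gp, mp) in genotypes.items()}
    veg = read_vegetation(vegetation) if vegetation else None
    bl = None
    if burn:
        bl = read_burn_polygons(burn)
    elif burn_table:
        bl = read_burn_table(burn_table)
    res = run_pipeline(occ, gms, veg, bl, cfg)
    if out_dir is not None:
        write_outputs(res, out_dir, cfg)
    return res


def write_outputs(res: PipelineResult, out_dir: str | Path, cfg: RunConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    units_to_geojson_file(res.units, out / "units.geojson",
                          hull_buffer_m=cfg.hull_buffer_m)
    (out / "noise_samples.txt").write_text("\n".join(res.noise_ids) + "\n")
    if res.metrics is not None:
        res.metrics.to_csv(out / "metrics.csv")
    if res.gvalues is not None:
        res.gvalues.to_csv(out / "gvalues.csv")
        res.g_multi.to_csv(out / "gvalues_multispecies.csv")
    if res.ratios is not None:
        res.ratios.to_csv(out / "burn_ratios.csv")
        res.risk.to_csv(out / "risk.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, default=str)
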