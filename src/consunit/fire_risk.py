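"""Burn-area ratios and overlap-weighted fire risk per management unit.

The burn-area ratio compares the observed burned area of a vegetation class
with the area expected if fire had fallen uniformly over the analysis region:

    expected(v, s) = area_share(v) × total_observed_burn(s)
    ratio(v, s)    = observed(v, s) / expected(v, s)

where area_share(v) is the class's share of the reference region — here the
vegetation map trimmed to a buffer around the fire footprint, so the null
model is "within the fire-affected neighbourhood, every class burns alike".
A ratio of 1 means a class burned exactly as expected, above 1 dispropor-
tionately more.  A management unit's fire risk is the overlap-proportion-
weighted mean of the (total-severity) ratios of the vegetation classes it
intersects, hence on the same scale as the ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.ops import unary_union

from .io_formats import BurnLayer, VegetationMap, SEVERITIES

logger = logging.getLogger(__name__)

__all__ = ["buffer_and_trim", "burn_area_ratio", "observed_areas_from_polygons",
           "unit_risk"]


def buffer_and_trim(veg: VegetationMap, burn: BurnLayer,
                    buffer_m: float = 100.0) -> VegetationMap:
    """Clip the vegetation map to a buffer around the burn footprint.

    Restricting the reference region to burned or near-burned ground keeps
    the expected-burn shares from being diluted by vegetation far from any
    fire.  Classes left with empty geometry are dropped.
    """
    if not burn.is_polygonal:
        raise ValueError("buffer_and_trim requires a polygonal burn layer")
    if not burn.geoms:
        raise ValueError("empty burn layer")
    # mitre joins keep rectangular footprints rectangular under buffering
    footprint = unary_union(burn.geoms).buffer(buffer_m, join_style="mitre")
    geoms, classes = [], []
    for g, c in zip(veg.geoms, veg.classes):
        clipped = g.intersection(footprint)
        if not clipped.is_empty and clipped.area > 0:
            geoms.append(clipped)
            classes.append(c)
    trimmed = VegetationMap(geoms=geoms, classes=classes, crs_code=veg.crs_code)
    logger.info("trimmed vegetation to %.3f of original area",
                trimmed.total_area / veg.total_area if veg.total_area else float("nan"))
    return trimmed


def observed_areas_from_polygons(veg: VegetationMap, burn: BurnLayer) -> pd.DataFrame:
    """Observed burned area (m²) per vegetation class × severity by overlay."""
    if not burn.is_polygonal:
        raise ValueError("need a polygonal burn layer")
    classes = sorted(set(veg.classes))
    out = pd.DataFrame(0.0, index=pd.Index(classes, name="veg_class"),
                       columns=list(SEVERITIES))
    by_class = {c: unary_union([g for g, cc in zip(veg.geoms, veg.classes) if cc == c])
                for c in classes}
    for bg, sev in zip(burn.geoms, burn.severities):
        for c, vg in by_class.items():
            a = vg.intersection(bg).area
            if a > 0:
                out.loc[c, sev] += a
    return out


def burn_area_ratio(observed: pd.DataFrame, reference: pd.Series) -> pd.DataFrame:
    """Observed, expected and ratio per vegetation class and severity.

    ``observed``: class × severity areas (any consistent unit); a ``total``
    column is derived as the severity sum.  ``reference``: per-class areas of
    the reference region from which expected shares are taken.  Severities
    with zero total observed burn get NaN ratios and a warning.
    """
    observed = observed.reindex(columns=list(SEVERITIES)).astype(float)
    reference = reference.astype(float)
    missing_ref = set(observed.index[observed.sum(axis=1) > 0]) - set(reference.index)
    if missing_ref:
        raise ValueError(f"burned classes missing reference areas: {sorted(missing_ref)}")
    if (reference <= 0).any():
        bad = reference.index[reference <= 0].tolist()
        raise ValueError(f"non-positive reference areas: {bad}")
    observed = observed.reindex(reference.index).fillna(0.0)
    observed["total"] = observed[list(SEVERITIES)].sum(axis=1)

    share = reference / reference.sum()
    rows = []
    for sev in list(SEVERITIES) + ["total"]:
        tot = observed[sev].sum()
        if tot <= 0:
            logger.warning("severity %r has zero observed burn; ratios undefined", sev)
        for v in reference.index:
            exp = share[v] * tot
            obs = observed.loc[v, sev]
            rows.append({
                "veg_class": v, "severity": sev,
                "observed": obs, "expected": exp,
                "ratio": obs / exp if tot > 0 else np.nan,
                "defined": tot > 0,
            })
    return pd.DataFrame(rows).set_index(["veg_class", "severity"])


def ratios_from_layer(veg_trimmed: VegetationMap | None, burn: BurnLayer) -> pd.DataFrame:
    """Burn-area ratios from either burn-layer representation."""
    if burn.is_polygonal:
        if veg_trimmed is None:
            raise ValueError("polygonal burn layers require a vegetation map")
        obs = observed_areas_from_polygons(veg_trimmed, burn)
        ref = veg_trimmed.area_by_class()
        return burn_area_ratio(obs, ref)
    return burn_area_ratio(burn.area_table, burn.ref_area_km2)


def unit_risk(unit_geoms: list, unit_ids: list[str], veg: VegetationMap,
              ratios: pd.DataFrame, severity: str = "total") -> pd.DataFrame:
    """Overlap-weighted burn-area-ratio risk per management unit.

    risk(u) = Σ_v (area(u ∩ v) / area(u)) × ratio(v, severity).  Portions of
    a unit outside any mapped vegetation contribute zero risk and lower the
    ``coverage`` diagnostic below 1.
    """
    r = ratios.xs(severity, level="severity")["ratio"]
    by_class = {c: unary_union([g for g, cc in zip(veg.geoms, veg.classes) if cc == c])
                for c in sorted(set(veg.classes))}
    rows = []
    for uid, geom in zip(unit_ids, unit_geoms):
        if geom.area <= 0:
            raise ValueError(f"unit {uid!r} has zero area; buffer hulls before overlay")
        risk, coverage = 0.0, 0.0
        for c, vg in by_class.items():
            prop = geom.intersection(vg).area / geom.area
            if prop <= 0:
                continue
            coverage += prop
            if c in r.index and np.isfinite(r[c]):
                risk += prop * float(r[c])
            else:
                logger.warning("unit %s overlaps class %r with undefined ratio", uid, c)
        rows.append({"unit_id": uid, "risk": risk, "coverage": min(coverage, 1.0)})
    return pd.DataFrame(rows).set_index("unit_id")
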