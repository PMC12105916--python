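"""Readers and writers for all external artifacts.

Canonical interchange formats:

* occurrence CSV — columns ``sample_id, species_id, lon, lat`` (optionally
  ``x, y`` once projected);
* genotype CSV — rows = individuals (index column ``sample_id``), columns =
  loci, cells in {0, 1, 2, NA} counting copies of the alternate allele, with
  a companion locus-metadata CSV (``locus_id, reproducibility, tag_id``);
* GeoJSON (RFC 7946) FeatureCollections for vegetation, burn and unit layers;
* a plain CSV area table for burns reported as printed areas rather than
  polygons.

All geometry lives in a projected metric CRS; areas and lengths are never
computed in degrees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

SEVERITIES = ("low", "medium", "high", "extreme")

__all__ = [
    "OccurrenceSet", "GenotypeMatrix", "VegetationMap", "BurnLayer", "SEVERITIES",
    "read_occurrences", "write_occurrences",
    "read_genotypes", "write_genotypes",
    "read_polygons", "read_vegetation", "read_burn_polygons", "read_burn_table",
    "write_feature_collection", "read_feature_collection",
    "load_nightcap_burn_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSet:
    """Georeferenced samples with species labels.

    ``data`` columns: sample_id, species_id, lon, lat and, after projection,
    x, y in metres of ``crs_code``.
    """

    data: pd.DataFrame
    crs_code: str | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "species_id", "lon", "lat"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
        dup = self.data["sample_id"][self.data["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id values: {sorted(set(dup))}")
        if not np.isfinite(self.data[["lon", "lat"]].to_numpy(float)).all():
            raise ValueError("non-finite lon/lat in occurrence table")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_projected(self) -> bool:
        return self.crs_code is not None and {"x", "y"} <= set(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def xy(self) -> np.ndarray:
        if not self.is_projected:
            raise ValueError("occurrences not projected; call project_coordinates first")
        return self.data[["x", "y"]].to_numpy(float)


@dataclass
class GenotypeMatrix:
    """Individuals × biallelic loci, cells counting alternate-allele copies.

    ``values`` is float with NaN marking missing calls; ``locus_meta`` is
    indexed by locus_id with columns ``reproducibility`` and ``tag_id``.
    """

    values: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    locus_meta: pd.DataFrame
    species_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples × {len(self.locus_ids)} loci"
            )
        ok = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid genotype value {self.values[i, j]!r} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        absent = set(self.locus_ids) - set(self.locus_meta.index)
        if absent:
            raise ValueError(f"loci missing from metadata: {sorted(absent)[:10]}")
        self.locus_meta = self.locus_meta.loc[self.locus_ids]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeMatrix(
            values=self.values[np.ix_(si, li)],
            sample_ids=[self.sample_ids[i] for i in si],
            locus_ids=[self.locus_ids[j] for j in li],
            locus_meta=self.locus_meta.iloc[li].copy(),
            species_id=self.species_id,
        )


@dataclass
class VegetationMap:
    """Classified vegetation polygons in a projected CRS."""

    geoms: list[BaseGeometry]
    classes: list[str]
    crs_code: str | None = None

    def __post_init__(self) -> None:
        if len(self.geoms) != len(self.classes):
            raise ValueError("one class label required per polygon")

    def __len__(self) -> int:
        return len(self.geoms)

    def area_by_class(self) -> pd.Series:
        s = pd.Series(0.0, index=sorted(set(self.classes)), name="area_m2")
        for g, c in zip(self.geoms, self.classes):
            s[c] += g.area
        return s

    @property
    def total_area(self) -> float:
        return float(sum(g.area for g in self.geoms))


@dataclass
class BurnLayer:
    """Fire footprint: severity-classified polygons or a printed area table.

    Exactly one of (``geoms``+``severities``) or (``area_table``+
    ``ref_area_km2``) is populated.  ``area_table`` maps vegetation class ×
    severity to burned km²; ``ref_area_km2`` maps vegetation class to the
    reference area the expected-burn share is taken from.
    """

    geoms: list[BaseGeometry] | None = None
    severities: list[str] | None = None
    area_table: pd.DataFrame | None = None
    ref_area_km2: pd.Series | None = None
    crs_code: str | None = None

    def __post_init__(self) -> None:
        if self.is_polygonal == (self.area_table is not None):
            raise ValueError("burn layer needs polygons or an area table, not both")
        if self.is_polygonal:
            bad = sorted(set(self.severities) - set(SEVERITIES))
            if bad:
                raise ValueError(f"unknown severity labels: {bad}")
        else:
            if self.ref_area_km2 is None:
                raise ValueError("area-table burn layer requires reference areas")
            if (self.area_table.to_numpy(float) < 0).any() or (self.ref_area_km2 < 0).any():
                raise ValueError("burn areas must be >= 0")

    @property
    def is_polygonal(self) -> bool:
        return self.geoms is not None


# ---------------------------------------------------------------------------
# occurrence CSV
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path, species_filter: list[str] | None = None) -> OccurrenceSet:
    """Read an occurrence CSV, dropping (and counting) unparseable rows."""
    df = pd.read_csv(path, dtype={"sample_id": str, "species_id": str})
    if df.empty:
        raise ValueError(f"empty occurrence file: {path}")
    required = {"sample_id", "species_id", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    bad = df["lon"].isna() | df["lat"].isna()
    if bad.any():
        logger.warning("dropped %d occurrence rows with unparseable coordinates", bad.sum())
        df = df[~bad]
    if species_filter is not None:
        df = df[df["species_id"].isin(species_filter)]
    if df.empty:
        raise ValueError("no usable occurrence rows after parsing/filtering")
    crs = None
    if {"x", "y"} <= set(df.columns) and "crs_code" in df.columns:
        crs = df["crs_code"].iloc[0]
    return OccurrenceSet(data=df.reset_index(drop=True), crs_code=crs)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    df = occ.data.copy()
    if occ.crs_code is not None:
        df["crs_code"] = occ.crs_code
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotype CSV + locus metadata
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, meta_path: str | Path,
                   species_id: str | None = None) -> GenotypeMatrix:
    """Read the individuals × loci matrix and its locus metadata (unfiltered)."""
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"empty genotype file: {path}")
    values = np.full(df.shape, np.nan)
    arr = df.to_numpy()
    for j in range(df.shape[1]):
        col = pd.to_numeric(pd.Series(arr[:, j]), errors="coerce").to_numpy(float)
        valid = np.isnan(col) | np.isin(col, (0.0, 1.0, 2.0))
        if not valid.all():
            i = int(np.argwhere(~valid)[0][0])
            raise ValueError(
                f"invalid genotype {arr[i, j]!r} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}"
            )
        values[:, j] = col
    meta = pd.read_csv(meta_path, dtype={"locus_id": str, "tag_id": str})
    if "locus_id" not in meta.columns:
        raise ValueError("locus metadata requires a locus_id column")
    meta = meta.set_index("locus_id")
    for col in ("reproducibility", "tag_id"):
        if col not in meta.columns:
            raise ValueError(f"locus metadata missing column {col!r}")
    if ((meta["reproducibility"] < 0) | (meta["reproducibility"] > 1)).any():
        raise ValueError("reproducibility must lie in [0,1]")
    return GenotypeMatrix(
        values=values,
        sample_ids=[str(s) for s in df.index],
        locus_ids=[str(c) for c in df.columns],
        locus_meta=meta,
        species_id=species_id,
    )


def write_genotypes(gm: GenotypeMatrix, path: str | Path, meta_path: str | Path) -> None:
    df = pd.DataFrame(gm.values, index=gm.sample_ids, columns=gm.locus_ids)
    # keep integer cells in the CSV; NaN renders as empty
    df = df.astype("Int64")
    df.index.name = "sample_id"
    df.to_csv(path)
    meta = gm.locus_meta.copy()
    meta.index.name = "locus_id"
    meta.to_csv(meta_path)


# ---------------------------------------------------------------------------
# GeoJSON layers
# ---------------------------------------------------------------------------

def read_feature_collection(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    """Low-level GeoJSON read: geometries + property dicts, geometry repaired.

    Invalid geometries get one area-preserving repair pass; features still
    invalid afterwards are rejected by id.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    feats = doc.get("features", [])
    if not feats:
        raise ValueError(f"{path}: empty FeatureCollection")
    geoms, props = [], []
    bad_ids = []
    for k, feat in enumerate(feats):
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            # area-preserving repair (keeps both lobes of a bow-tie)
            repaired = make_valid(geom)
            if repaired.geom_type == "GeometryCollection":
                polys = [g for g in repaired.geoms
                         if g.geom_type in ("Polygon", "MultiPolygon")]
                from shapely.ops import unary_union
                repaired = unary_union(polys) if polys else repaired
            geom = repaired
        if not geom.is_valid or geom.is_empty:
            bad_ids.append(feat.get("id", k))
            continue
        geoms.append(geom)
        props.append(feat.get("properties") or {})
    if bad_ids:
        raise ValueError(f"{path}: unrepairable geometries for features {bad_ids}")
    return geoms, props


def read_polygons(path: str | Path, class_field: str) -> tuple[list[BaseGeometry], list[str]]:
    """Read a classified polygon layer, validating the class attribute."""
    geoms, props = read_feature_collection(path)
    missing = [i for i, p in enumerate(props) if p.get(class_field) in (None, "")]
    if missing:
        raise ValueError(f"{path}: features missing {class_field!r}: {missing}")
    return geoms, [str(p[class_field]) for p in props]


def read_vegetation(path: str | Path, class_field: str = "veg_class",
                    crs_code: str | None = None) -> VegetationMap:
    geoms, classes = read_polygons(path, class_field)
    return VegetationMap(geoms=geoms, classes=classes, crs_code=crs_code)


def read_burn_polygons(path: str | Path, class_field: str = "severity",
                       crs_code: str | None = None) -> BurnLayer:
    geoms, sev = read_polygons(path, class_field)
    return BurnLayer(geoms=geoms, severities=[s.lower() for s in sev], crs_code=crs_code)


def write_feature_collection(path: str | Path, geoms: list[BaseGeometry],
                             props: list[dict]) -> None:
    feats = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, props)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# burn area tables
# ---------------------------------------------------------------------------

def read_burn_table(path: str | Path) -> BurnLayer:
    """Read a printed-style burn area table.

    Columns: ``veg_class, ref_area_km2, low, medium, high, extreme``.
    An optional ``total`` column is checked against the severity sum when all
    four severities are present.
    """
    df = pd.read_csv(path)
    required = {"veg_class", "ref_area_km2"} | set(SEVERITIES)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"burn table missing columns: {sorted(missing)}")
    df = df.set_index("veg_class")
    table = df[list(SEVERITIES)].astype(float)
    ref = df["ref_area_km2"].astype(float)
    return BurnLayer(area_table=table, ref_area_km2=ref)


def load_nightcap_burn_table() -> tuple[BurnLayer, pd.Series]:
    """Bundled Nightcap reserves burn-area table (areas in km²).

    Returns the burn layer whose reference areas are the 100 m fire-buffer
    areas, plus the whole-reserve area per vegetation class (used for
    reserve-level summaries such as the fraction of the reserve burned).
    """
    src = resources.files("consunit.data") / "nightcap_burn_table.csv"
    with resources.as_file(src) as p:
        df = pd.read_csv(p).set_index("veg_class")
    layer = BurnLayer(
        area_table=df[list(SEVERITIES)].astype(float),
        ref_area_km2=df["buffer_area_km2"].astype(float),
    )
    return layer, df["reserve_area_km2"].astype(float)
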