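"""Management-unit definition from projected occurrence points.

Two unit-definition methods are provided:

* a grid method — points are binned into square cells by rounding their
  projected coordinates divided by the cell size;
* a density method — DBSCAN (eps in metres, minimum cluster size) pools all
  target species, then clusters whose convex-hull perimeter exceeds a
  management limit are split by recursive 2-means until every unit fits.

The perimeter of a point cluster is the boundary length of its convex hull;
collinear or two-point clusters use twice the maximum pairwise distance and
are flagged degenerate, single points have perimeter zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Point
from shapely.geometry.base import BaseGeometry
from sklearn.cluster import DBSCAN, KMeans

from .io_formats import OccurrenceSet, write_feature_collection, read_feature_collection
from . import projection as proj

logger = logging.getLogger(__name__)

NOISE = "NOISE"

__all__ = [
    "NOISE", "ManagementUnit", "ClusterLabeling",
    "project_coordinates", "assign_grid_cells", "dbscan_cluster",
    "cluster_perimeter", "split_oversize", "units_to_geojson", "units_to_geojson_file",
]


@dataclass
class ManagementUnit:
    """A labeled cluster of samples with its hull geometry."""

    unit_id: str
    member_ids: list[str]
    species_present: set[str]
    hull: BaseGeometry
    perimeter_m: float
    area_m2: float
    provenance: str  # grid | dbscan | kmeans_split
    degenerate_flag: bool

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("management unit must have members")
        if self.perimeter_m < 0:
            raise ValueError("perimeter must be >= 0")

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterLabeling:
    """DBSCAN output: sample_id → cluster id or NOISE."""

    labels: dict[str, str]
    eps_m: float
    min_pts: int

    def cluster_ids(self) -> list[str]:
        return sorted({v for v in self.labels.values() if v != NOISE})

    def members(self, cluster_id: str) -> list[str]:
        return [s for s, c in self.labels.items() if c == cluster_id]

    @property
    def n_noise(self) -> int:
        return sum(1 for v in self.labels.values() if v == NOISE)


# ---------------------------------------------------------------------------

def project_coordinates(occ: OccurrenceSet, crs_code: str | None = None) -> OccurrenceSet:
    """Fill metric x/y by projecting lon/lat into a transverse-Mercator CRS.

    With no ``crs_code`` the MGA/UTM zone containing the mean longitude is
    used.  Points far outside the zone's domain of validity are warned about,
    not rejected.
    """
    df = occ.data.copy()
    if df.empty:
        return OccurrenceSet(data=df, crs_code=crs_code)
    code = crs_code or proj.suggest_crs(float(df["lon"].mean()))
    crs = proj.get_crs(code)
    outside = ~crs.domain_ok(df["lon"].to_numpy())
    for sid in df.loc[outside, "sample_id"]:
        logger.warning("sample %s outside domain of validity of %s", sid, crs.code)
    x, y = crs.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    df["x"], df["y"] = x, y
    return OccurrenceSet(data=df, crs_code=crs.code)


def _unit_from_points(unit_id: str, member_ids: list[str], species: list[str],
                      xy: np.ndarray, provenance: str) -> ManagementUnit:
    perimeter, hull, degenerate = cluster_perimeter(xy)
    return ManagementUnit(
        unit_id=unit_id,
        member_ids=list(member_ids),
        species_present=set(species),
        hull=hull,
        perimeter_m=perimeter,
        area_m2=float(hull.area),
        provenance=provenance,
        degenerate_flag=degenerate,
    )


def assign_grid_cells(occ: OccurrenceSet, cell_size_m: float,
                      binning: str = "round") -> list[ManagementUnit]:
    """Bin projected samples into square grid cells.

    ``round`` binning maps a coordinate v to floor(v/s + 0.5) (nearest
    integer, half-up); ``floor`` binning to floor(v/s).
    """
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be > 0")
    xy = occ.xy()
    if binning == "round":
        ij = np.floor(xy / cell_size_m + 0.5).astype(int)
    elif binning == "floor":
        ij = np.floor(xy / cell_size_m).astype(int)
    else:
        raise ValueError("binning must be 'round' or 'floor'")
    df = occ.data
    units = []
    keys = [tuple(r) for r in ij]
    for key in sorted(set(keys)):
        mask = np.array([k == key for k in keys])
        units.append(_unit_from_points(
            unit_id=f"grid_{key[0]}_{key[1]}",
            member_ids=df.loc[mask, "sample_id"].tolist(),
            species=df.loc[mask, "species_id"].tolist(),
            xy=xy[mask],
            provenance="grid",
        ))
    return units


def dbscan_cluster(occ: OccurrenceSet, eps_m: float = 100.0,
                   min_pts: int = 3) -> ClusterLabeling:
    """Standard DBSCAN on projected coordinates, all species pooled.

    A core point has at least ``min_pts`` points (itself included) within
    ``eps_m``; clusters are density-reachability closures, everything else
    is noise.
    """
    xy = occ.xy()
    if len(xy) < 1:
        raise ValueError("need at least one point to cluster")
    raw = DBSCAN(eps=eps_m, min_samples=min_pts).fit_predict(xy)
    labels = {}
    for sid, lab in zip(occ.sample_ids, raw):
        labels[sid] = NOISE if lab == -1 else f"c{lab:03d}"
    return ClusterLabeling(labels=labels, eps_m=eps_m, min_pts=min_pts)


def cluster_perimeter(points: np.ndarray) -> tuple[float, BaseGeometry, bool]:
    """Perimeter, hull geometry and degeneracy flag of a point set."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need an (n,2) array with n >= 1")
    if pts.shape[0] == 1:
        return 0.0, Point(pts[0]), True
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type == "Polygon":
        return float(hull.exterior.length), hull, False
    if hull.geom_type == "LineString":  # 2 points or collinear
        return 2.0 * float(hull.length), hull, True
    return 0.0, hull, True  # coincident points


def split_oversize(labeling: ClusterLabeling, occ: OccurrenceSet,
                   perimeter_max_m: float = 700.0, seed: int = 0) -> list[ManagementUnit]:
    """Turn a DBSCAN labeling into units obeying the perimeter constraint.

    Clusters over the limit are split by 2-means on projected coordinates
    (10 restarts, seeded) and each side re-examined, recursing until every
    unit's hull perimeter is within the limit or the unit cannot be reduced
    (single point, or coincident points).  Noise samples are excluded and
    reported via the labeling, never attached to a unit.  Splitting may
    produce units below the DBSCAN minimum size; these are kept and show up
    flagged degenerate when too small for a hull.
    """
    if perimeter_max_m <= 0:
        raise ValueError("perimeter_max_m must be > 0")
    df = occ.data.set_index("sample_id")
    xy_all = occ.xy()
    pos = {sid: i for i, sid in enumerate(occ.sample_ids)}

    units: list[ManagementUnit] = []
    rng = np.random.RandomState(seed % (2**31))

    for cid in labeling.cluster_ids():
        members = labeling.members(cid)
        stack = [(cid, members, False)]
        part = 0
        while stack:
            uid, mem, was_split = stack.pop()
            xy = xy_all[[pos[s] for s in mem]]
            perim, _, _ = cluster_perimeter(xy)
            n_distinct = len(np.unique(xy, axis=0))
            if perim <= perimeter_max_m or n_distinct < 2:
                unit = _unit_from_points(
                    unit_id=uid if not was_split else f"{cid}_s{part}",
                    member_ids=mem,
                    species=df.loc[mem, "species_id"].tolist(),
                    xy=xy,
                    provenance="kmeans_split" if was_split else "dbscan",
                )
                if was_split:
                    part += 1
                units.append(unit)
                continue
            km = KMeans(n_clusters=2, n_init=10,
                        random_state=rng.randint(2**31)).fit(xy)
            side = km.labels_
            # deterministic tie-break: equidistant points go to centroid 0
            d = np.linalg.norm(xy[:, None, :] - km.cluster_centers_[None], axis=2)
            tie = np.isclose(d[:, 0], d[:, 1])
            side[tie] = 0
            if side.min() == side.max():  # degenerate k-means outcome
                side = np.zeros(len(mem), dtype=int)
                side[: len(mem) // 2] = 1
            for s_val in (1, 0):  # push so side 0 is processed first
                sub = [m for m, s in zip(mem, side) if s == s_val]
                stack.append((uid, sub, True))
    # stable ordering + unique ids
    units.sort(key=lambda u: (u.unit_id, u.member_ids[0]))
    seen: dict[str, int] = {}
    for u in units:
        k = seen.get(u.unit_id, 0)
        seen[u.unit_id] = k + 1
        if k:
            u.unit_id = f"{u.unit_id}.{k}"
    return units


# ---------------------------------------------------------------------------

def units_to_geojson(units: list[ManagementUnit], hull_buffer_m: float = 0.0):
    """Units → (geometries, property dicts); hulls optionally buffered so
    degenerate units acquire positive area for overlay work."""
    geoms, props = [], []
    for u in units:
        g = u.hull.buffer(hull_buffer_m) if hull_buffer_m > 0 else u.hull
        geoms.append(g)
        props.append({
            "unit_id": u.unit_id,
            "perimeter_m": u.perimeter_m,
            "area_m2": u.area_m2,
            "n_members": u.n_members,
            "species": sorted(u.species_present),
            "members": list(u.member_ids),
            "provenance": u.provenance,
            "degenerate_flag": u.degenerate_flag,
        })
    return geoms, props


def units_to_geojson_file(units: list[ManagementUnit], path,
                          hull_buffer_m: float = 0.0) -> None:
    geoms, props = units_to_geojson(units, hull_buffer_m)
    write_feature_collection(path, geoms, props)


def units_from_geojson_file(path) -> tuple[list, list[dict]]:
    """Read a unit layer back as (geometries, properties)."""
    return read_feature_collection(path)
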