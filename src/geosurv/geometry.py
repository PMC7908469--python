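"""District geometry: map loading, town-to-district assignment, centroid distances.

Polygon maps are read from GeoJSON.  Geographic (longitude/latitude) inputs
are reprojected per region to a local equirectangular metric projection so
that all downstream distances are in metres; inputs that already carry a
projected CRS are taken to be in metres.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

#: Mean Earth radius in metres, used by the local metric projection.
EARTH_RADIUS_M = 6_371_008.8

#: Sentinel district id for towns absent from the lookup.
UNASSIGNED = "<unassigned>"

_GEOGRAPHIC_CRS_TOKENS = ("crs84", "4326", "wgs84", "wgs 84", "longlat")


class GeometryError(ValueError):
    """Raised for unreadable, CRS-less or unrepairable geometry inputs."""


@dataclass(frozen=True)
class DistrictMap:
    """An ordered collection of district polygons for a single region.

    Coordinates are planar metres; ``centroids`` holds the area-weighted
    centroid of each (possibly multi-part) polygon.
    """

    ids: tuple[str, ...]
    names: tuple[str, ...]
    region: str
    polygons: tuple[BaseGeometry, ...]
    centroids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise GeometryError(f"duplicate district ids: {dupes}")
        if not (len(self.ids) == len(self.names) == len(self.polygons)):
            raise GeometryError("ids, names and polygons must align")
        cents = np.asarray(self.centroids, dtype=float)
        if cents.shape != (len(self.ids), 2):
            raise GeometryError("centroids must be an (n, 2) array")
        object.__setattr__(self, "centroids", cents)
        for did, poly, (cx, cy) in zip(self.ids, self.polygons, cents):
            if poly.is_empty or not poly.is_valid:
                raise GeometryError(f"district {did!r}: empty or invalid polygon")
            minx, miny, maxx, maxy = poly.bounds
            if not (minx <= cx <= maxx and miny <= cy <= maxy):
                raise GeometryError(f"district {did!r}: centroid outside bounding box")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, district_id: str) -> int:
        return self.ids.index(district_id)

    @property
    def diameter(self) -> float:
        """Largest inter-centroid distance, metres."""
        d = cdist(self.centroids, self.centroids)
        return float(d.max())


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of inter-centroid Euclidean distances in metres."""

    ids: tuple[str, ...]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape must match id count")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "d", d)


def normalise_town(name: str) -> str:
    """Trim, case-fold and collapse internal whitespace of a town name."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


class TownLookup:
    """Normalised town name -> district id mapping."""

    def __init__(self, mapping: dict[str, str], known_districts: set[str] | None = None):
        self._map = {normalise_town(k): v for k, v in mapping.items()}
        if known_districts is not None:
            bad = sorted(set(self._map.values()) - set(known_districts))
            if bad:
                raise ValueError(f"lookup targets unknown districts: {bad}")
        if not self._map:
            raise ValueError("town lookup is empty")

    @classmethod
    def from_file(cls, path, known_districts: set[str] | None = None,
                  sep: str = "\t") -> "TownLookup":
        """Read a two-column delimited ``town<sep>district_id`` table."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                town, district = line.split(sep)[:2]
                mapping[town] = district
        return cls(mapping, known_districts)

    def __len__(self) -> int:
        return len(self._map)

    def towns(self) -> list[str]:
        return sorted(self._map)


def assign_district(town: str, lookup: TownLookup) -> str:
    """Map a free-text town name to its district id.

    Unmapped towns return the :data:`UNASSIGNED` sentinel — a data condition,
    not an error.
    """
    return lookup._map.get(normalise_town(town), UNASSIGNED)


def assign_districts(towns, lookup: TownLookup) -> tuple[list[str], int]:
    """Vector version of :func:`assign_district`; returns (ids, n_unassigned)."""
    out = [assign_district(t, lookup) for t in towns]
    n_un = sum(1 for x in out if x == UNASSIGNED)
    if n_un:
        logger.warning("%d patients could not be assigned to a district", n_un)
    return out, n_un


def _crs_is_geographic(crs_name: str) -> bool:
    low = crs_name.casefold()
    return any(tok in low for tok in _GEOGRAPHIC_CRS_TOKENS)


def _project_equirectangular(lon: np.ndarray, lat: np.ndarray,
                             lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection centred on (lon0, lat0), metres.

    Adequate (<1% distance error) at regional extents; chosen because the
    range parameter of the spatial correlation is expressed in metres.
    """
    x = EARTH_RADIUS_M * np.cos(np.deg2rad(lat0)) * np.deg2rad(lon - lon0)
    y = EARTH_RADIUS_M * np.deg2rad(lat - lat0)
    return x, y


def _project_geometry(geom: BaseGeometry, lon0: float, lat0: float) -> BaseGeometry:
    import shapely.ops

    def tf(x, y, z=None):
        return _project_equirectangular(np.asarray(x), np.asarray(y), lon0, lat0)

    return shapely.ops.transform(tf, geom)


def _repair(geom: BaseGeometry):
    if geom.is_valid and not geom.is_empty:
        return geom, False
    fixed = make_valid(geom)
    if fixed.geom_type == "GeometryCollection":
        polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if not polys:
            return None, True
        fixed = polys[0] if len(polys) == 1 else shapely_shape(
            {"type": "MultiPolygon",
             "coordinates": [shapely_mapping(p)["coordinates"] for p in polys]})
    if fixed.is_valid and not fixed.is_empty:
        return fixed, True
    return None, True


def load_district_map(vector_file, region_field: str = "region",
                      id_field: str = "district_id", name_field: str = "name",
                      expected_regions=None) -> dict[str, DistrictMap]:
    """Load district polygons from GeoJSON and split them by region label.

    The file must declare a CRS (top-level ``crs`` member).  Geographic
    coordinates are reprojected, per region, to a local metric projection;
    projected inputs are assumed to be in metres already.  Invalid polygons
    are repaired where possible; unrepairable ones abort the load with a
    report naming the offenders.

    Returns a dict mapping each region label to its :class:`DistrictMap`.
    """
    with open(vector_file) as fh:
        gj = json.load(fh)
    crs = gj.get("crs")
    if crs is None:
        raise GeometryError(f"no CRS declared in {vector_file}; refusing to guess units")
    crs_name = str(crs.get("properties", {}).get("name", crs))
    geographic = _crs_is_geographic(crs_name)

    feats = gj.get("features", [])
    by_region: dict[str, list] = {}
    unrepairable: list[str] = []
    for i, feat in enumerate(feats):
        props = feat.get("properties", {})
        if region_field not in props:
            raise GeometryError(
                f"feature {i} lacks region field {region_field!r}; "
                f"fields present: {sorted(props)}")
        did = str(props.get(id_field, f"F{i}"))
        name = str(props.get(name_field, did))
        geom = shapely_shape(feat["geometry"])
        geom, repaired = _repair(geom)
        if geom is None:
            unrepairable.append(did)
            continue
        if repaired:
            logger.warning("repaired invalid geometry for district %s", did)
        by_region.setdefault(str(props[region_field]), []).append((did, name, geom))
    if unrepairable:
        raise GeometryError(f"unrepairable geometries for districts: {unrepairable}")

    if expected_regions is not None:
        unknown = sorted(set(by_region) - set(expected_regions))
        if unknown:
            raise GeometryError(
                f"unknown region value(s) {unknown}; regions found: {sorted(by_region)}")

    out: dict[str, DistrictMap] = {}
    for region, items in by_region.items():
        ids, names, geoms = zip(*items)
        if geographic:
            # Region-local projection centre: mean of geometry centroids.
            cents = np.array([[g.centroid.x, g.centroid.y] for g in geoms])
            lon0, lat0 = cents.mean(axis=0)
            geoms = tuple(_project_geometry(g, lon0, lat0) for g in geoms)
        centroids = np.array([[g.centroid.x, g.centroid.y] for g in geoms])
        out[region] = DistrictMap(ids=tuple(ids), names=tuple(names), region=region,
                                  polygons=tuple(geoms), centroids=centroids)
    return out


def centroid_distances(dmap: DistrictMap) -> DistanceMatrix:
    """Pairwise Euclidean distances between district centroids, metres."""
    if len(dmap) < 1:
        raise ValueError("need at least one district")
    d = cdist(dmap.centroids, dmap.centroids)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(ids=dmap.ids, d=d)


def map_to_geojson(dmap: DistrictMap, path=None) -> dict:
    """Serialise a DistrictMap to GeoJSON (projected metre coordinates)."""
    feats = []
    for did, name, poly, (cx, cy) in zip(dmap.ids, dmap.names, dmap.polygons,
                                         dmap.centroids):
        feats.append({
            "type": "Feature",
            "properties": {"district_id": did, "name": name, "region": dmap.region,
                           "centroid_x": float(cx), "centroid_y": float(cy)},
            "geometry": shapely_mapping(poly),
        })
    gj = {"type": "FeatureCollection",
          "crs": {"type": "name", "properties": {"name": "local-metric-metres"}},
          "features": feats}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(gj, fh, sort_keys=True)
    return gj


def district_summary(dmap: DistrictMap, patient_districts=None, path=None):
    """District summary table: id, region, centroid x/y, patient count."""
    import pandas as pd

    counts = {did: 0 for did in dmap.ids}
    if patient_districts is not None:
        for d in patient_districts:
            if d in counts:
                counts[d] += 1
    df = pd.DataFrame({
        "district_id": dmap.ids,
        "region": dmap.region,
        "centroid_x": dmap.centroids[:, 0],
        "centroid_y": dmap.centroids[:, 1],
        "n_patients": [counts[d] for d in dmap.ids],
    })
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
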