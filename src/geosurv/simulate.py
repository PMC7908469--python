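"""Synthetic registry cohorts with the exact structure the model assumes.

Generates a district grid map per region, a log-Gaussian frailty field on
it, patient covariates with explicit missing levels, right-censored
survival times from the proportional-hazards model, a partially observed
socioeconomic index (to exercise kriging) and hospital point locations.
The simulation truth is kept separate from the data tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geometry import DistrictMap, TownLookup, centroid_distances, map_to_geojson
from .model import BaselineHazard, cumulative_baseline, chol_with_jitter


def make_grid_map(n_districts: int, region: str, cell_km: float = 30.0,
                  n_cols: int | None = None, origin=(0.0, 0.0),
                  id_prefix: str | None = None) -> DistrictMap:
    """Rectangular grid of square districts, filled row-major.

    ``n_districts`` need not be a perfect rectangle; the last row may be
    partial (e.g. 87 districts on a 10-wide grid).
    """
    if n_districts < 1:
        raise ValueError("need at least one district")
    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(n_districts)))
    cell = cell_km * 1000.0
    ox, oy = origin
    prefix = id_prefix if id_prefix is not None else region[:1].upper()
    ids, names, polys, cents = [], [], [], []
    for k in range(n_districts):
        r, c = divmod(k, n_cols)
        x0, y0 = ox + c * cell, oy + r * cell
        polys.append(Polygon([(x0, y0), (x0 + cell, y0),
                              (x0 + cell, y0 + cell), (x0, y0 + cell)]))
        ids.append(f"{prefix}{k:03d}")
        names.append(f"{region} district {k}")
        cents.append((x0 + cell / 2.0, y0 + cell / 2.0))
    return DistrictMap(ids=tuple(ids), names=tuple(names), region=region,
                       polygons=tuple(polys), centroids=np.array(cents))


def sample_frailty_field(dmap: DistrictMap, sigma2: float, phi: float,
                         seed_or_rng) -> np.ndarray:
    """One draw of Y ~ N(-sigma2/2, sigma2 * exp(-d/phi)) via Cholesky."""
    if sigma2 < 0 or phi <= 0:
        raise ValueError("require sigma2 >= 0 and phi > 0")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    m = len(dmap)
    if sigma2 == 0.0:
        return np.zeros(m)
    D = centroid_distances(dmap)
    Sigma = sigma2 * np.exp(-D.d / phi)
    L, _ = chol_with_jitter(Sigma)
    return -0.5 * sigma2 + L @ rng.standard_normal(m)


def simulate_survival(lin_pred, baseline: BaselineHazard, censor_time: float,
                      seed_or_rng) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-transform survival times under the PH hazard, then censor.

    Solves ``H0(T) * exp(lin_pred) = -log(U)`` per patient; B-spline
    baselines invert numerically.  Returns (follow-up time, event flag).
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    lin = np.asarray(lin_pred, dtype=float)
    E = rng.exponential(size=len(lin))          # -log U
    target = E * np.exp(-lin)                   # required H0(T)
    if baseline.family == "exponential":
        T = target / baseline.omega[0]
    elif baseline.family == "weibull":
        shape, scale = baseline.omega
        T = np.power(target / scale, 1.0 / shape)
    else:
        from scipy.optimize import brentq

        def invert(g):
            hi = baseline.t_max or 1.0
            while cumulative_baseline(hi, baseline) < g:
                hi *= 2.0
                if hi > 1e12:
                    return hi
            return brentq(lambda t: cumulative_baseline(t, baseline) - g,
                          0.0, hi, xtol=1e-9 * max(hi, 1.0))
        T = np.array([invert(g) for g in target])
    T = np.maximum(T, 1e-12)
    delta = (T <= censor_time).astype(int)
    t_obs = np.where(delta == 1, T, censor_time)
    return t_obs, delta


DEFAULT_FACTORS = {
    # level lists start with the reference; explicit "missing" levels mirror
    # registry recoding of inconsistent missing-data indicators
    "ethnicity": (["non_malay", "malay", "missing"], [0.55, 0.43, 0.02]),
    "stage": (["stage_1", "stage_2", "stage_3", "stage_4", "not_staged", "missing"],
              [0.05, 0.14, 0.18, 0.15, 0.14, 0.34]),
    "treatment": (["surgery", "surgery_chemo_radio", "chemo_radio", "other",
                   "unknown"], [0.38, 0.33, 0.10, 0.03, 0.16]),
}


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic registry cohort."""

    n_patients: int = 4412
    districts_per_region: dict[str, int] = field(
        default_factory=lambda: {"west": 87, "east": 57})
    cell_km: float = 30.0
    region_gap_km: float = 300.0
    factors: dict = field(default_factory=lambda: dict(DEFAULT_FACTORS))
    numeric: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"age_std": (0.0, 1.0)})
    beta: dict[str, float] = field(default_factory=dict)
    baseline_family: str = "weibull"
    omega: tuple[float, ...] = (1.2, 2e-4)
    sigma2: float = 0.25
    phi: float | None = None          # default: half the west-map diameter
    censor_time: float = 2000.0       # days
    se_missing_frac: float = 0.06
    n_hospitals: int = 25
    towns_per_district: tuple[int, int] = (3, 6)
    seed: int = 0

    def __post_init__(self):
        for name, (levels, probs) in self.factors.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"factor {name!r} probabilities must sum to 1")
        if self.censor_time <= 0:
            raise ValueError("censoring time must be positive")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")

    def design_columns(self) -> list[str]:
        cols = [f"{f}[{lev}]" for f, (levels, _) in self.factors.items()
                for lev in levels[1:]]
        return cols + list(self.numeric)


@dataclass
class SyntheticCohort:
    patients: pd.DataFrame
    truth_districts: pd.DataFrame
    truth_params: dict
    maps: dict[str, DistrictMap]
    se_table: pd.DataFrame
    hospitals: pd.DataFrame
    town_lookup: TownLookup
    spec: CohortSpec

    def baseline(self) -> BaselineHazard:
        return BaselineHazard(self.spec.baseline_family,
                              np.asarray(self.truth_params["omega"]))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    # -- maps, laid out left to right with a sea gap between regions
    maps: dict[str, DistrictMap] = {}
    x_off = 0.0
    for region, n_d in spec.districts_per_region.items():
        dmap = make_grid_map(n_d, region, cell_km=spec.cell_km, origin=(x_off, 0.0))
        maps[region] = dmap
        width = dmap.centroids[:, 0].max() - dmap.centroids[:, 0].min() \
            + spec.cell_km * 1000.0
        x_off += width + spec.region_gap_km * 1000.0

    all_ids = [d for m in maps.values() for d in m.ids]
    first_map = next(iter(maps.values()))
    phi = spec.phi if spec.phi is not None else 0.5 * first_map.diameter

    # -- frailty field per region (regions are physically separate)
    Y_by_district: dict[str, float] = {}
    for region, dmap in maps.items():
        Y = sample_frailty_field(dmap, spec.sigma2, phi, rng)
        for did, y in zip(dmap.ids, Y):
            Y_by_district[did] = float(y)

    # -- towns: 3-6 pseudo-towns per district
    lo, hi = spec.towns_per_district
    town_map: dict[str, str] = {}
    towns_of: dict[str, list[str]] = {}
    for did in all_ids:
        k = int(rng.integers(lo, hi + 1))
        towns_of[did] = [f"{did}_town{j}" for j in range(k)]
        for t in towns_of[did]:
            town_map[t] = did
    lookup = TownLookup(town_map, known_districts=set(all_ids))

    # -- patient-level draws
    n = spec.n_patients
    weights = np.array([spec.districts_per_region[r] for r in maps], dtype=float)
    region_of = rng.choice(list(maps), size=n, p=weights / weights.sum())
    districts = np.empty(n, dtype=object)
    towns = np.empty(n, dtype=object)
    for i, r in enumerate(region_of):
        did = maps[r].ids[int(rng.integers(len(maps[r])))]
        districts[i] = did
        towns[i] = towns_of[did][int(rng.integers(len(towns_of[did])))]

    data = {"patient_id": [f"P{i:05d}" for i in range(n)],
            "region": region_of, "town": towns}
    lin = np.zeros(n)
    for fac, (levels, probs) in spec.factors.items():
        draw = rng.choice(levels, size=n, p=probs)
        data[fac] = draw
        for lev in levels[1:]:
            b = spec.beta.get(f"{fac}[{lev}]", 0.0)
            if b:
                lin += b * (draw == lev)
    for num, (mean, sd) in spec.numeric.items():
        v = mean + sd * rng.standard_normal(n)
        data[num] = v
        lin += spec.beta.get(num, 0.0) * v
    lin += np.array([Y_by_district[d] for d in districts])

    baseline = BaselineHazard(spec.baseline_family, np.asarray(spec.omega))
    t_obs, delta = simulate_survival(lin, baseline, spec.censor_time, rng)
    data["time"] = t_obs
    data["event"] = delta
    patients = pd.DataFrame(data)

    # -- socioeconomic index: smooth spatial gradient + noise, then mask
    se_rows = []
    for region, dmap in maps.items():
        c = dmap.centroids
        span = max(np.ptp(c[:, 0]), 1.0)
        true_se = (np.sin(2.0 * np.pi * (c[:, 0] - c[:, 0].min()) / span)
                   + 0.8 * (c[:, 1] - c[:, 1].mean()) / max(np.ptp(c[:, 1]), 1.0)
                   + 0.3 * rng.standard_normal(len(dmap)))
        for did, v in zip(dmap.ids, true_se):
            se_rows.append({"district_id": did, "se_index_true": float(v)})
    se_truth = pd.DataFrame(se_rows)
    n_mask = int(round(spec.se_missing_frac * len(se_truth)))
    masked = rng.choice(len(se_truth), size=n_mask, replace=False)
    se_table = se_truth.rename(columns={"se_index_true": "se_index"}).copy()
    se_table.loc[masked, "se_index"] = np.nan

    # -- hospitals: uniform points over each region's bounding box
    hosp_rows = []
    for region, dmap in maps.items():
        xs = np.concatenate([np.asarray(p.exterior.coords)[:, 0]
                             for p in _iter_polys(dmap)])
        ys = np.concatenate([np.asarray(p.exterior.coords)[:, 1]
                             for p in _iter_polys(dmap)])
        n_h = max(1, int(round(spec.n_hospitals
                               * len(dmap) / len(all_ids))))
        hx = rng.uniform(xs.min(), xs.max(), n_h)
        hy = rng.uniform(ys.min(), ys.max(), n_h)
        for j, (x, y) in enumerate(zip(hx, hy)):
            hosp_rows.append({"name": f"{region}_hosp{j}", "region": region,
                              "x": float(x), "y": float(y)})
    hospitals = pd.DataFrame(hosp_rows)

    truth_districts = pd.DataFrame({
        "district_id": all_ids,
        "Y": [Y_by_district[d] for d in all_ids],
    }).merge(se_truth, on="district_id")
    truth_params = {"beta": dict(spec.beta), "baseline_family": spec.baseline_family,
                    "omega": list(spec.omega), "sigma2": spec.sigma2, "phi": phi,
                    "censor_time": spec.censor_time, "seed": spec.seed}
    return SyntheticCohort(patients=patients, truth_districts=truth_districts,
                           truth_params=truth_params, maps=maps, se_table=se_table,
                           hospitals=hospitals, town_lookup=lookup, spec=spec)


def _iter_polys(dmap: DistrictMap):
    for poly in dmap.polygons:
        if poly.geom_type == "MultiPolygon":
            yield from poly.geoms
        else:
            yield poly


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write all cohort artifacts as plain text under one directory.

    Data and truth are separate files; they share only ``district_id``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["patients"] = out / "patients.tsv"
    cohort.patients.to_csv(paths["patients"], sep="\t", index=False)
    paths["truth_districts"] = out / "truth_districts.tsv"
    cohort.truth_districts.to_csv(paths["truth_districts"], sep="\t", index=False)
    paths["truth_params"] = out / "truth_params.json"
    with open(paths["truth_params"], "w") as fh:
        json.dump(cohort.truth_params, fh, indent=2, sort_keys=True)
    for region, dmap in cohort.maps.items():
        p = out / f"map_{region}.geojson"
        map_to_geojson(dmap, p)
        paths[f"map_{region}"] = p
    paths["se_index"] = out / "se_index.tsv"
    cohort.se_table.to_csv(paths["se_index"], sep="\t", index=False)
    paths["hospitals"] = out / "hospitals.tsv"
    cohort.hospitals.to_csv(paths["hospitals"], sep="\t", index=False)
    paths["town_lookup"] = out / "town_lookup.tsv"
    with open(paths["town_lookup"], "w") as fh:
        fh.write("town\tdistrict_id\n")
        for town in sorted(cohort.town_lookup.towns()):
            fh.write(f"{town}\t{cohort.town_lookup._map[town]}\n")
    return paths
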