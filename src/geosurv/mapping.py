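"""Posterior post-processing: HR tables, correlation curves, exceedance maps.

All summaries are draw-wise: the statistic is evaluated per retained MCMC
draw and then reduced to a median and equal-tailed 95% credible interval.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DistrictMap
from .mcmc import McmcChain
from .model import baseline_hazard, cumulative_baseline

DEFAULT_THRESHOLDS = (1.1, 1.25, 1.5)
DEFAULT_PROB_BREAKS = (0.25, 0.5, 0.75)


def hazard_ratio_table(chain: McmcChain, covariate_spec=None,
                       counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Median hazard ratios with 95% credible intervals per covariate column.

    ``covariate_spec`` selects and orders columns (default: all); the
    significance flag marks intervals excluding 1.  Reference levels never
    appear because they carry no coefficient.
    """
    if chain.n_draws < 100:
        raise ValueError("need at least 100 retained draws for an HR table")
    names = list(covariate_spec) if covariate_spec is not None else list(chain.beta_names)
    missing = [n for n in names if n not in chain.beta_names]
    if missing:
        raise KeyError(f"covariates absent from chain: {missing}")
    rows = []
    for name in names:
        j = list(chain.beta_names).index(name)
        hr = np.exp(chain.beta[:, j])
        lo, med, hi = np.quantile(hr, [0.025, 0.5, 0.975])
        rows.append({"covariate": name,
                     "n": counts.get(name) if counts else None,
                     "median_hr": float(med), "cri_lower": float(lo),
                     "cri_upper": float(hi),
                     "significant": bool(hi < 1.0 or lo > 1.0)})
    return pd.DataFrame(rows)


def correlation_curve(chain: McmcChain, d_grid) -> pd.DataFrame:
    """Posterior median and 95% band of rho(d) = exp(-d/phi) over a grid."""
    d_grid = np.asarray(d_grid, dtype=float)
    phi = chain.phi  # (S,)
    rho = np.exp(-d_grid[:, None] / phi[None, :])  # (G, S)
    lo, med, hi = np.quantile(rho, [0.025, 0.5, 0.975], axis=1)
    return pd.DataFrame({"distance": d_grid, "rho_median": med,
                         "rho_lower": lo, "rho_upper": hi})


def exceedance_probability(chain: McmcChain,
                           thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Per-district P[exp(Y) > c] for each threshold c, with MC standard error."""
    thresholds = tuple(float(c) for c in thresholds)
    if any(c <= 0 for c in thresholds):
        raise ValueError("exceedance thresholds must be positive")
    expY = np.exp(chain.Y)  # (S, m)
    S = expY.shape[0]
    out = {"district_id": list(chain.district_ids)}
    for c in thresholds:
        p = (expY > c).mean(axis=0)
        out[f"p_exceed_{c:g}"] = p
        out[f"mc_se_{c:g}"] = np.sqrt(p * (1.0 - p) / S)
    return pd.DataFrame(out)


def probability_bin(p, breaks=DEFAULT_PROB_BREAKS) -> np.ndarray:
    """Bin probabilities into reporting classes; break k starts class k+1."""
    return np.digitize(np.asarray(p, dtype=float), breaks, right=False)


def export_risk_map(surface: pd.DataFrame, dmap: DistrictMap, out_dir,
                    breaks=DEFAULT_PROB_BREAKS, image_format: str = "png"):
    """Write GeoJSON + one static choropleth per threshold.

    ``surface`` is the frame from :func:`exceedance_probability`; its
    districts must all exist in ``dmap``.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = sorted(set(surface["district_id"]) - set(dmap.ids))
    if missing:
        raise KeyError(f"districts in surface but not in map: {missing}")
    prob_cols = [c for c in surface.columns if c.startswith("p_exceed_")]
    sur = surface.set_index("district_id")

    from shapely.geometry import mapping as shapely_mapping

    feats = []
    for did, name, poly in zip(dmap.ids, dmap.names, dmap.polygons):
        props = {"district_id": did, "name": name, "region": dmap.region}
        if did in sur.index:
            for c in prob_cols:
                p = float(sur.loc[did, c])
                props[c] = p
                props[c.replace("p_exceed_", "bin_")] = int(
                    probability_bin(p, breaks))
        feats.append({"type": "Feature", "properties": props,
                      "geometry": shapely_mapping(poly)})
    gj = {"type": "FeatureCollection",
          "crs": {"type": "name", "properties": {"name": "local-metric-metres"}},
          "features": feats}
    gj_path = out_dir / f"risk_map_{dmap.region}.geojson"
    with open(gj_path, "w") as fh:
        json.dump(gj, fh, sort_keys=True)

    written = [gj_path]
    for c in prob_cols:
        img = out_dir / f"risk_map_{dmap.region}_{c}.{image_format}"
        _plot_choropleth(dmap, sur, c, breaks, img)
        written.append(img)
    return written


def _plot_choropleth(dmap, sur, col, breaks, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    edges = [0.0, *breaks, 1.0]
    cmap = plt.get_cmap("YlOrRd", len(edges) - 1)
    fig, ax = plt.subplots(figsize=(7, 7))
    for did, poly in zip(dmap.ids, dmap.polygons):
        p = float(sur.loc[did, col]) if did in sur.index else np.nan
        colour = cmap(int(probability_bin(p, breaks))) if np.isfinite(p) else "0.85"
        geoms = poly.geoms if poly.geom_type == "MultiPolygon" else [poly]
        for g in geoms:
            ax.add_patch(MplPolygon(np.asarray(g.exterior.coords),
                                    facecolor=colour, edgecolor="k", linewidth=0.3))
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_title(col.replace("p_exceed_", "P[exp(Y) > ") + "]")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    handles = [plt.Rectangle((0, 0), 1, 1, facecolor=cmap(i))
               for i in range(len(edges) - 1)]
    labels = [f"[{edges[i]:g}, {edges[i+1]:g})" for i in range(len(edges) - 1)]
    ax.legend(handles, labels, title="probability", loc="lower right", fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def baseline_curves(chain: McmcChain, t_grid) -> pd.DataFrame:
    """Posterior median and 95% band of h0(t) and H0(t) on a time grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    S = chain.n_draws
    h0 = np.empty((len(t_grid), S))
    H0 = np.empty((len(t_grid), S))
    for s in range(S):
        bl = chain.baseline_draw(s)
        h0[:, s] = baseline_hazard(t_grid, bl)
        H0[:, s] = cumulative_baseline(t_grid, bl)
    qs = [0.025, 0.5, 0.975]
    h_lo, h_med, h_hi = np.quantile(h0, qs, axis=1)
    H_lo, H_med, H_hi = np.quantile(H0, qs, axis=1)
    return pd.DataFrame({"t": t_grid,
                         "h0_median": h_med, "h0_lower": h_lo, "h0_upper": h_hi,
                         "H0_median": H_med, "H0_lower": H_lo, "H0_upper": H_hi})
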