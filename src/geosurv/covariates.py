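"""District-level area covariates.

Two covariates enter the survival model at the area level: a socioeconomic
index observed for most (not all) districts — missing districts are imputed
by ordinary kriging at their centroids — and a smoothed hospital-density
surface (Gaussian kernel intensity, hospitals per square kilometre)
evaluated at every district centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .geometry import DistrictMap

VARIOGRAM_MODELS = ("exponential", "spherical", "gaussian")


class DegenerateFieldError(ValueError):
    """Raised when the observed field carries no spatial information."""


@dataclass(frozen=True)
class Variogram:
    """A fitted semivariogram model gamma(h)."""

    model: str
    nugget: float
    partial_sill: float
    range_: float  # metres

    def __post_init__(self):
        if self.model not in VARIOGRAM_MODELS:
            raise ValueError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0 or self.partial_sill <= 0 or self.range_ <= 0:
            raise ValueError("require nugget >= 0, partial_sill > 0, range > 0")

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = self.range_
        if self.model == "exponential":
            struct = 1.0 - np.exp(-h / r)
        elif self.model == "gaussian":
            struct = 1.0 - np.exp(-((h / r) ** 2))
        else:  # spherical
            hr = np.clip(h / r, 0.0, 1.0)
            struct = 1.5 * hr - 0.5 * hr ** 3
        gamma = self.nugget + self.partial_sill * struct
        return np.where(h == 0.0, 0.0, gamma)


def empirical_semivariogram(locations, values, n_bins: int = 12,
                            max_dist: float | None = None):
    """Binned method-of-moments semivariogram.

    Returns (bin centres, semivariances, pair counts); empty bins dropped.
    """
    locs = np.asarray(locations, dtype=float)
    vals = np.asarray(values, dtype=float)
    d = cdist(locs, locs)
    iu = np.triu_indices(len(vals), k=1)
    h = d[iu]
    g = 0.5 * (vals[iu[0]] - vals[iu[1]]) ** 2
    if max_dist is None:
        max_dist = 0.5 * h.max()
    keep = h <= max_dist
    h, g = h[keep], g[keep]
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    idx = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    centres, gammas, counts = [], [], []
    for b in range(n_bins):
        m = idx == b
        if m.sum() == 0:
            continue
        centres.append(h[m].mean())
        gammas.append(g[m].mean())
        counts.append(int(m.sum()))
    return np.array(centres), np.array(gammas), np.array(counts)


def _fit_one_model(model, h, gamma, counts):
    sill0 = gamma.max() if gamma.max() > 0 else 1.0
    r0 = max(h.mean(), 1e-6)

    def resid(p):
        nug, psill, rng = p
        v = Variogram(model=model, nugget=max(nug, 0.0),
                      partial_sill=max(psill, 1e-12), range_=max(rng, 1e-12))
        pred = v.semivariance(h)
        # gstat-style N_j / h_j^2 weights: emphasise short lags, where the
        # range is identified.
        w = np.sqrt(counts) / np.maximum(h, 1e-12)
        return w * (gamma - pred)

    best = None
    for r_init in (r0, r0 / 5.0, r0 * 5.0):
        try:
            sol = least_squares(resid, x0=[0.1 * sill0, 0.9 * sill0, r_init],
                                bounds=([0.0, 1e-12, 1e-12],
                                        [np.inf, np.inf, np.inf]),
                                max_nfev=500)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None, np.inf
    nug, psill, rng = best.x
    return Variogram(model=model, nugget=float(nug),
                     partial_sill=float(max(psill, 1e-12)),
                     range_=float(max(rng, 1e-12))), float(best.cost)


def fit_variogram(locations, values, n_bins: int = 12,
                  models=VARIOGRAM_MODELS) -> Variogram:
    """Fit a semivariogram by weighted least squares over candidate models.

    The candidate model with the lowest weighted residual cost wins,
    mirroring automatic variogram selection.
    """
    locs = np.asarray(locations, dtype=float)
    vals = np.asarray(values, dtype=float)
    min_pts = 10
    if len(vals) < min_pts:
        raise ValueError(f"need at least {min_pts} observed locations, got {len(vals)}")
    if np.std(vals) == 0.0:
        raise DegenerateFieldError("constant field: semivariogram is identically zero")
    d_max = float(cdist(locs, locs).max())
    # Regular (e.g. gridded) layouts can leave short-range bins empty;
    # widen the lag window and coarsen bins before giving up.
    for max_dist, nb in ((0.5 * d_max, n_bins), (d_max, n_bins),
                         (d_max, max(4, n_bins // 2))):
        h, gamma, counts = empirical_semivariogram(locs, vals, n_bins=nb,
                                                   max_dist=max_dist)
        if len(h) >= 3:
            break
    else:
        raise ValueError("too few non-empty distance bins to fit a variogram")
    best_v, best_cost = None, np.inf
    for model in models:
        v, cost = _fit_one_model(model, h, gamma, counts)
        if v is not None and cost < best_cost:
            best_v, best_cost = v, cost
    if best_v is None:
        raise RuntimeError("variogram fit failed for all candidate models")
    return best_v


def ordinary_krige(observed_locations, observed_values, targets,
                   variogram: Variogram, return_weights: bool = False):
    """Ordinary kriging prediction at target locations.

    Solves the standard unit-sum-weight system (Lagrange multiplier) built
    from the fitted semivariogram.  Returns ``(predictions, variances)``,
    plus the (n_obs, n_targets) weight matrix when ``return_weights`` is
    set; kriging variances are clipped at zero against round-off.
    """
    locs = np.asarray(observed_locations, dtype=float)
    vals = np.asarray(observed_values, dtype=float)
    tgts = np.asarray(targets, dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 observed points for ordinary kriging")
    d_obs = cdist(locs, locs)
    off_diag = d_obs[np.triu_indices(n, k=1)]
    if np.any(off_diag == 0.0):
        ii, jj = np.where((d_obs == 0.0) & ~np.eye(n, dtype=bool))
        dup = sorted({tuple(sorted((int(a), int(b)))) for a, b in zip(ii, jj)})
        raise ValueError(f"duplicate observed locations at index pairs {dup}")

    A = np.empty((n + 1, n + 1))
    A[:n, :n] = variogram.semivariance(d_obs)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0

    d_t = cdist(tgts, locs)
    B = np.empty((n + 1, tgts.shape[0]))
    B[:n, :] = variogram.semivariance(d_t).T
    B[n, :] = 1.0
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular kriging system: {exc}") from exc
    w = sol[:n, :]
    mu = sol[n, :]
    preds = w.T @ vals
    variances = np.einsum("it,it->t", w, B[:n, :]) + mu
    if return_weights:
        return preds, np.maximum(variances, 0.0), w
    return preds, np.maximum(variances, 0.0)


def rule_of_thumb_bandwidth(points) -> float:
    """Isotropic normal-reference bandwidth for a 2-D point pattern."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    sd = np.sqrt(0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1))) if n > 1 else 1.0
    if sd == 0.0:
        sd = 1.0
    return float(sd * n ** (-1.0 / 6.0))


def hospital_density(points, eval_at, bandwidth: float) -> np.ndarray:
    """Gaussian-kernel intensity of hospital locations, hospitals per km^2.

    ``lambda(s) = sum_k exp(-|s - s_k|^2 / (2 h^2)) / (2 pi h^2)`` with all
    distances in metres, rescaled to per-km^2.  No edge correction.
    """
    pts = np.asarray(points, dtype=float)
    ev = np.asarray(eval_at, dtype=float)
    if len(pts) < 1:
        raise ValueError("need at least one hospital location")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    d2 = cdist(ev, pts, "sqeuclidean")
    dens_per_m2 = np.exp(-d2 / (2.0 * bandwidth ** 2)).sum(axis=1) / (
        2.0 * np.pi * bandwidth ** 2)
    return dens_per_m2 * 1e6  # m^-2 -> km^-2


def build_area_covariates(dmap: DistrictMap, se_observed: dict[str, float],
                          hospitals, bandwidth: float | None = None,
                          n_bins: int = 12) -> pd.DataFrame:
    """Assemble the per-district covariate table.

    Districts missing from ``se_observed`` (or with NaN values) get their
    socioeconomic index kriged from the observed districts' centroids;
    hospital density is evaluated at every centroid.  The returned frame
    carries provenance flags and z-scored columns for model entry.
    """
    obs_ids = [d for d in dmap.ids
               if d in se_observed and np.isfinite(se_observed[d])]
    missing_ids = [d for d in dmap.ids if d not in obs_ids]
    if not obs_ids:
        raise ValueError("all socioeconomic values missing: nothing to krige from")

    se = {d: float(se_observed[d]) for d in obs_ids}
    source = {d: "observed" for d in obs_ids}
    if missing_ids:
        obs_idx = [dmap.index_of(d) for d in obs_ids]
        mis_idx = [dmap.index_of(d) for d in missing_ids]
        obs_locs = dmap.centroids[obs_idx]
        obs_vals = np.array([se[d] for d in obs_ids])
        vgm = fit_variogram(obs_locs, obs_vals, n_bins=n_bins)
        preds, _ = ordinary_krige(obs_locs, obs_vals, dmap.centroids[mis_idx], vgm)
        for d, p in zip(missing_ids, preds):
            se[d] = float(p)
            source[d] = "kriged"

    pts = np.asarray(hospitals, dtype=float)
    h = bandwidth if bandwidth is not None else rule_of_thumb_bandwidth(pts)
    dens = hospital_density(pts, dmap.centroids, h)

    df = pd.DataFrame({
        "district_id": dmap.ids,
        "se_index": [se[d] for d in dmap.ids],
        "se_index_source": [source[d] for d in dmap.ids],
        "hospital_density": dens,
    })
    for col in ("se_index", "hospital_density"):
        sd = df[col].std(ddof=0)
        df[col + "_z"] = (df[col] - df[col].mean()) / (sd if sd > 0 else 1.0)
    return df
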