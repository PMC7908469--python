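"""Parametric proportional-hazards model with log-Gaussian spatial frailties.

The hazard for patient ``i`` in district ``d(i)`` is

    h(t_i) = h0(t_i; omega) * exp(x_i' beta + Y_{d(i)})

with ``h0`` one of three baseline families (exponential, Weibull, cubic
B-spline on the log hazard) and ``Y`` a zero-sum-free Gaussian field over
districts with covariance ``sigma2 * exp(-d / phi)`` on centroid distances.
The frailty prior mean is ``-sigma2 / 2`` so that ``E[exp(Y)] = 1``, which
separates the frailty level from the baseline scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

from .geometry import DistanceMatrix

logger = logging.getLogger(__name__)

BASELINE_FAMILIES = ("exponential", "weibull", "bspline")

_GL_NODES, _GL_WEIGHTS = leggauss(64)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Baseline hazard families
# ---------------------------------------------------------------------------

def make_spline_knots(t_max: float, interior_quantile_times=None,
                      n_interior: int = 3) -> np.ndarray:
    """Clamped cubic knot vector on [0, t_max].

    Interior knots default to equally spaced; pass follow-up-time quantiles
    (e.g. the 25/50/75% points) for data-adaptive placement.
    """
    if interior_quantile_times is None:
        interior = np.linspace(0.0, t_max, n_interior + 2)[1:-1]
    else:
        interior = np.sort(np.asarray(interior_quantile_times, dtype=float))
        interior = np.clip(interior, 1e-9, t_max * (1 - 1e-9))
    return np.concatenate([[0.0] * 4, interior, [t_max] * 4])


@dataclass(frozen=True)
class BaselineHazard:
    """Baseline hazard h0(t; omega) for one of the three supported families.

    Parameters (``omega``) by family:

    - ``exponential``: ``[rate]`` with h0(t) = rate
    - ``weibull``: ``[shape, scale]`` with h0(t) = shape*scale*t^(shape-1)
    - ``bspline``: spline coefficients on log h0; requires ``knots``
    """

    family: str
    omega: np.ndarray
    knots: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.family not in BASELINE_FAMILIES:
            raise ModelError(f"unknown baseline family {self.family!r}")
        om = np.atleast_1d(np.asarray(self.omega, dtype=float))
        object.__setattr__(self, "omega", om)
        if self.family == "exponential":
            if om.shape != (1,) or om[0] <= 0:
                raise ModelError("exponential baseline needs a single rate > 0")
        elif self.family == "weibull":
            if om.shape != (2,) or np.any(om <= 0):
                raise ModelError("weibull baseline needs [shape, scale] > 0")
        else:
            if self.knots is None:
                raise ModelError("bspline baseline requires a knot vector")
            kn = np.asarray(self.knots, dtype=float)
            object.__setattr__(self, "knots", kn)
            ncoef = len(kn) - 4
            if om.shape != (ncoef,):
                raise ModelError(
                    f"bspline baseline needs {ncoef} coefficients, got {om.shape}")

    @property
    def t_max(self) -> float:
        return float(self.knots[-1]) if self.knots is not None else np.inf

    def _spline(self) -> BSpline:
        return BSpline(self.knots, self.omega, 3, extrapolate=False)

    def _log_h0_spline(self, t: np.ndarray) -> np.ndarray:
        # Constant log-hazard extension beyond the knot span.
        sp = self._spline()
        tc = np.clip(t, 0.0, self.t_max)
        return np.nan_to_num(sp(tc), nan=float(sp(self.t_max)))


def baseline_hazard(t, baseline: BaselineHazard) -> np.ndarray:
    """h0(t) evaluated elementwise; t must be nonnegative."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ModelError("negative time passed to baseline_hazard")
    if baseline.family == "exponential":
        return np.full_like(t, baseline.omega[0])
    if baseline.family == "weibull":
        shape, scale = baseline.omega
        with np.errstate(divide="ignore"):
            return shape * scale * np.power(t, shape - 1.0)
    return np.exp(baseline._log_h0_spline(t))


def cumulative_baseline(t, baseline: BaselineHazard) -> np.ndarray:
    """H0(t) = integral of h0 on [0, t]; B-splines use Gauss-Legendre."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ModelError("negative time passed to cumulative_baseline")
    if baseline.family == "exponential":
        return baseline.omega[0] * t
    if baseline.family == "weibull":
        shape, scale = baseline.omega
        return scale * np.power(t, shape)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    tmax = baseline.t_max
    tin = np.minimum(tt, tmax)
    # Map 64 Gauss-Legendre nodes onto [0, t] for each t.
    nodes = 0.5 * tin[:, None] * (_GL_NODES[None, :] + 1.0)
    vals = np.exp(baseline._log_h0_spline(nodes.ravel())).reshape(nodes.shape)
    H = 0.5 * tin * (vals * _GL_WEIGHTS[None, :]).sum(axis=1)
    # Beyond the knot span the log-hazard is held constant.
    over = tt > tmax
    if np.any(over):
        h_end = float(np.exp(baseline._log_h0_spline(np.array([tmax]))[0]))
        H = H + np.where(over, (tt - tmax) * h_end, 0.0)
    return float(H[0]) if scalar else H


# ---------------------------------------------------------------------------
# Spatial correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialCorrelation:
    """Exponential correlation: rho(d) = exp(-d / phi), scaled by sigma2."""

    sigma2: float
    phi: float

    def __post_init__(self):
        if self.sigma2 <= 0 or self.phi <= 0:
            raise ModelError("sigma2 and phi must be positive")


def correlation(d, phi: float) -> np.ndarray:
    """rho(d) = exp(-d/phi); correlation is e^-1 at distance phi."""
    if phi <= 0:
        raise ModelError("phi must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ModelError("distances must be nonnegative")
    return np.exp(-d / phi)


def covariance_matrix(D: DistanceMatrix, corr: SpatialCorrelation) -> np.ndarray:
    """Sigma = sigma2 * exp(-d_ij / phi) over the distance matrix."""
    return corr.sigma2 * correlation(D.d, corr.phi)


def chol_with_jitter(Sigma: np.ndarray, max_tries: int = 6):
    """Cholesky factor, adding logged diagonal jitter only on failure."""
    jitter = 0.0
    base = np.mean(np.diag(Sigma))
    for k in range(max_tries):
        try:
            L = np.linalg.cholesky(Sigma + jitter * np.eye(len(Sigma)))
            if jitter > 0:
                logger.warning("covariance needed diagonal jitter %.3e", jitter)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter = base * 10.0 ** (k - 10)
    raise ModelError("covariance matrix not positive definite even with jitter")


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class SurvivalDataset:
    """Design matrix plus follow-up times, event indicators, district index."""

    t: np.ndarray
    delta: np.ndarray
    X: np.ndarray
    columns: tuple[str, ...]
    district_index: np.ndarray
    district_ids: tuple[str, ...]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.delta = np.asarray(self.delta, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        self.district_index = np.asarray(self.district_index, dtype=int)
        n = len(self.t)
        if not (len(self.delta) == n == self.X.shape[0] == len(self.district_index)):
            raise ModelError("dataset arrays must share the patient dimension")
        if self.X.shape[1] != len(self.columns):
            raise ModelError("X columns must match column names")
        if np.any(self.t <= 0):
            raise ModelError("follow-up times must be positive")
        if not np.isin(self.delta, (0, 1)).all():
            raise ModelError("event indicator must be 0/1")
        m = len(self.district_ids)
        if np.any((self.district_index < 0) | (self.district_index >= m)):
            raise ModelError("district index out of range")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def n_districts(self) -> int:
        return len(self.district_ids)


def dataset_from_dataframe(df, district_ids, time_col: str = "time",
                           event_col: str = "event", district_col: str = "district_id",
                           factors: dict[str, list[str]] | None = None,
                           numeric: list[str] | None = None,
                           standardise_numeric: bool = True) -> SurvivalDataset:
    """Build a SurvivalDataset from a patient table.

    Categorical covariates are dummy-coded against their first listed level
    (the reference); explicit "missing"-style levels are ordinary levels.
    Patients whose district is not in ``district_ids`` are dropped with a
    logged count.
    """
    import pandas as pd

    factors = factors or {}
    numeric = numeric or []
    district_ids = tuple(district_ids)
    pos = {d: i for i, d in enumerate(district_ids)}
    known = df[district_col].map(pos)
    dropped = int(known.isna().sum())
    if dropped:
        logger.warning("dropping %d patients with unassigned/unknown district", dropped)
    df = df.loc[known.notna()].reset_index(drop=True)

    cols: list[str] = []
    mats: list[np.ndarray] = []
    for fac, levels in factors.items():
        vals = df[fac].astype(str)
        unknown = set(vals) - set(levels)
        if unknown:
            raise ModelError(f"factor {fac!r} has undeclared levels {sorted(unknown)}")
        for lev in levels[1:]:  # first level is the reference
            cols.append(f"{fac}[{lev}]")
            mats.append((vals == lev).to_numpy(dtype=float))
    for num in numeric:
        v = df[num].to_numpy(dtype=float)
        if standardise_numeric:
            sd = v.std()
            v = (v - v.mean()) / (sd if sd > 0 else 1.0)
        cols.append(num)
        mats.append(v)
    X = np.column_stack(mats) if mats else np.empty((len(df), 0))
    return SurvivalDataset(
        t=df[time_col].to_numpy(dtype=float),
        delta=df[event_col].to_numpy(dtype=int),
        X=X, columns=tuple(cols),
        district_index=df[district_col].map(pos).to_numpy(dtype=int),
        district_ids=district_ids)


# ---------------------------------------------------------------------------
# Model, likelihood, priors
# ---------------------------------------------------------------------------

@dataclass
class SpatialPHModel:
    """Full parameter state: beta, baseline, spatial correlation, frailties."""

    beta: np.ndarray
    baseline: BaselineHazard
    corr: SpatialCorrelation
    Y: np.ndarray
    distances: DistanceMatrix | None = None

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.Y = np.atleast_1d(np.asarray(self.Y, dtype=float))
        if self.distances is not None and len(self.distances.ids) != len(self.Y):
            raise ModelError("frailty vector length must match district count")


def loglik_pointwise(data: SurvivalDataset, beta, baseline: BaselineHazard,
                     Y) -> np.ndarray:
    """Per-patient censored log-likelihood contributions."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    Y = np.atleast_1d(np.asarray(Y, dtype=float))
    if beta.shape[0] != data.X.shape[1]:
        raise ModelError(
            f"beta has {beta.shape[0]} entries, X has {data.X.shape[1]} columns")
    if Y.shape[0] != data.n_districts:
        raise ModelError(
            f"Y has {Y.shape[0]} entries for {data.n_districts} districts")
    lin = data.X @ beta + Y[data.district_index]
    with np.errstate(divide="ignore"):
        log_h0 = np.log(baseline_hazard(data.t, baseline))
    H0 = cumulative_baseline(data.t, baseline)
    return data.delta * (log_h0 + lin) - H0 * np.exp(lin)


def log_likelihood(data: SurvivalDataset, model: SpatialPHModel) -> float:
    """Censored PH log-likelihood; raises on nonfinite contributions."""
    if data.n == 0:
        raise ModelError("empty dataset")
    terms = loglik_pointwise(data, model.beta, model.baseline, model.Y)
    if not np.all(np.isfinite(terms)):
        bad = int(np.flatnonzero(~np.isfinite(terms))[0])
        raise ModelError(f"nonfinite log-likelihood contribution at patient {bad}")
    return float(terms.sum())


def frailty_log_density(Y, Sigma, mean=None) -> float:
    """Multivariate normal log-density of the frailty field.

    Default mean is ``-diag(Sigma)/2`` (= -sigma2/2 for the stationary
    exponential model) so that exp(Y) has prior unit mean.
    """
    Y = np.atleast_1d(np.asarray(Y, dtype=float))
    Sigma = np.asarray(Sigma, dtype=float)
    if mean is None:
        mean = -0.5 * np.diag(Sigma)
    from scipy.linalg import solve_triangular

    L, _ = chol_with_jitter(Sigma)
    z = solve_triangular(L, Y - mean, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    m = len(Y)
    return float(-0.5 * (m * np.log(2.0 * np.pi) + logdet + z @ z))


class NormalPrior:
    """Independent normal prior; mean/sd may be scalars or vectors."""

    def __init__(self, mean=0.0, sd=1.0):
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        if np.any(self.sd <= 0):
            raise ModelError("prior sd must be positive")

    def logpdf(self, x) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x - self.mean) / self.sd
        return float(np.sum(-0.5 * z * z - np.log(self.sd * np.sqrt(2.0 * np.pi))))

    def sample(self, rng, size):
        return self.mean + self.sd * rng.standard_normal(size)


class GammaRatePrior:
    """Gamma(a, b) prior on exp(theta); logpdf on the theta = log-rate scale.

    Includes the Jacobian of the log transform, so MCMC on theta targets
    the gamma posterior on the rate.  Used for conjugate validation of the
    sampler against the closed-form gamma posterior.
    """

    def __init__(self, a: float, b: float):
        if a <= 0 or b <= 0:
            raise ModelError("gamma prior requires a, b > 0")
        self.a, self.b = float(a), float(b)

    def logpdf(self, theta) -> float:
        from scipy.special import gammaln
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        return float(np.sum(self.a * np.log(self.b) - gammaln(self.a)
                            + self.a * theta - self.b * np.exp(theta)))


@dataclass
class PriorSpec:
    """Priors on beta, log omega, log sigma2 and log phi.

    Default scales follow a weakly-informative convention: sd 10 on the
    log-hazard-ratio coefficients and sd 2 on the log-scale baseline and
    spatial parameters.  Any field left None raises at evaluation time.
    """

    beta: NormalPrior | None = None
    log_omega: object | None = None
    log_sigma2: NormalPrior | None = None
    log_phi: NormalPrior | None = None

    @classmethod
    def default(cls, log_omega_mean=0.0, log_sigma2_mean=np.log(0.1),
                log_phi_mean=0.0) -> "PriorSpec":
        return cls(beta=NormalPrior(0.0, 10.0),
                   log_omega=NormalPrior(log_omega_mean, 2.0),
                   log_sigma2=NormalPrior(log_sigma2_mean, 2.0),
                   log_phi=NormalPrior(log_phi_mean, 2.0))


def log_prior(model: SpatialPHModel, priors: PriorSpec) -> float:
    """Joint log-prior: independent parameter priors + MVN frailty density."""
    for name in ("beta", "log_omega", "log_sigma2", "log_phi"):
        if getattr(priors, name) is None:
            raise ModelError(f"no prior specified for {name}")
    if model.distances is None:
        raise ModelError("model needs a DistanceMatrix to evaluate the frailty prior")
    lp = 0.0
    if len(model.beta):
        lp += priors.beta.logpdf(model.beta)
    lp += priors.log_omega.logpdf(np.log(model.baseline.omega)
                                  if model.baseline.family != "bspline"
                                  else model.baseline.omega)
    lp += priors.log_sigma2.logpdf(np.log(model.corr.sigma2))
    lp += priors.log_phi.logpdf(np.log(model.corr.phi))
    Sigma = covariance_matrix(model.distances, model.corr)
    lp += frailty_log_density(model.Y, Sigma)
    return float(lp)
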