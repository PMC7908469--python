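"""Adaptive MCMC for the spatial proportional-hazards model.

The sampler runs blockwise Metropolis updates on (beta, omega-block,
spatial block, frailties).  Frailties use a non-centred parameterisation
``Y = mu + L v`` with ``v ~ N(0, I)`` and a preconditioned Crank-Nicolson
proposal, so hyperparameter updates remain well mixed and the frailty
update needs no gradient.  Proposal scales adapt during burn-in only
(Robbins-Monro toward 0.234 for multivariate blocks, 0.44 for scalars);
adaptation is frozen afterwards so the retained chain is Markovian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .geometry import DistanceMatrix
from .model import (BaselineHazard, ModelError, NormalPrior, PriorSpec,
                    chol_with_jitter, correlation)

__all__ = ["ModelSpec", "McmcSettings", "McmcChain", "WaicResult", "run_mcmc",
           "diagnostics", "effective_sample_size", "prior_posterior_compare",
           "density_overlap", "compute_waic", "save_chain", "load_chain"]


@dataclass
class ModelSpec:
    """Model structure: baseline family and the district distance matrix."""

    baseline_family: str
    distances: DistanceMatrix
    spline_knots: np.ndarray | None = None

    def n_omega(self) -> int:
        if self.baseline_family == "exponential":
            return 1
        if self.baseline_family == "weibull":
            return 2
        if self.baseline_family == "bspline":
            if self.spline_knots is None:
                raise ModelError("bspline spec requires spline_knots")
            return len(self.spline_knots) - 4
        raise ModelError(f"unknown baseline family {self.baseline_family!r}")

    def baseline_from_theta(self, theta: np.ndarray) -> BaselineHazard:
        """omega block on the sampling scale -> BaselineHazard.

        Exponential/Weibull sample log-parameters; B-spline coefficients are
        already unconstrained.
        """
        if self.baseline_family == "bspline":
            return BaselineHazard("bspline", theta, knots=self.spline_knots)
        return BaselineHazard(self.baseline_family, np.exp(theta))


@dataclass
class McmcSettings:
    n_iter: int = 11_000
    n_burn: int = 1_000
    n_thin: int = 10
    seed: int = 0
    fix_spatial: bool = False
    fix_frailty: np.ndarray | None = None
    likelihood_off: bool = False
    beta0: np.ndarray | None = None
    omega0: np.ndarray | None = None
    sigma2_0: float = 0.1
    phi0: float | None = None
    adapt_batch: int = 50


@dataclass
class McmcChain:
    """Retained posterior draws plus bookkeeping."""

    beta: np.ndarray            # (S, p)
    beta_names: tuple[str, ...]
    omega_theta: np.ndarray     # (S, k) sampling-scale omega block
    log_sigma2: np.ndarray      # (S,)
    log_phi: np.ndarray         # (S,)
    Y: np.ndarray               # (S, m)
    district_ids: tuple[str, ...]
    loglik_pointwise: np.ndarray = field(repr=False)  # (n, S)
    acceptance: dict = field(default_factory=dict)
    settings: McmcSettings | None = None
    model_spec: ModelSpec | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] if self.beta.ndim == 2 else len(self.log_sigma2)

    @property
    def sigma2(self) -> np.ndarray:
        return np.exp(self.log_sigma2)

    @property
    def phi(self) -> np.ndarray:
        return np.exp(self.log_phi)

    def baseline_draw(self, s: int) -> BaselineHazard:
        return self.model_spec.baseline_from_theta(self.omega_theta[s])

    def scalar_series(self) -> dict[str, np.ndarray]:
        """Named scalar traces for diagnostics and identifiability checks."""
        out = {}
        for j, name in enumerate(self.beta_names):
            out[f"beta[{name}]"] = self.beta[:, j]
        for j in range(self.omega_theta.shape[1]):
            out[f"omega_theta[{j}]"] = self.omega_theta[:, j]
        out["log_sigma2"] = self.log_sigma2
        out["log_phi"] = self.log_phi
        return out


@dataclass(frozen=True)
class WaicResult:
    lppd: float
    p_waic: float
    waic: float


# ---------------------------------------------------------------------------
# Likelihood cache
# ---------------------------------------------------------------------------

class _LikCache:
    """Precomputed per-dataset quantities for fast likelihood evaluation."""

    def __init__(self, data, spec: ModelSpec):
        self.X = data.X
        self.t = data.t
        self.delta = data.delta.astype(float)
        self.didx = data.district_index
        self.family = spec.baseline_family
        self.logt = np.log(data.t)
        if self.family == "bspline":
            from numpy.polynomial.legendre import leggauss
            from scipy.interpolate import BSpline

            kn = spec.spline_knots
            ncoef = len(kn) - 4
            nodes, weights = leggauss(32)
            tmax = kn[-1]
            tin = np.minimum(self.t, tmax)
            gl = 0.5 * tin[:, None] * (nodes[None, :] + 1.0)
            eye = np.eye(ncoef)
            def basis(x):
                xc = np.clip(x, 0.0, tmax)
                cols = [BSpline(kn, eye[j], 3, extrapolate=False)(xc)
                        for j in range(ncoef)]
                return np.nan_to_num(np.column_stack(cols))
            self._B_data = basis(self.t)
            self._B_quad = basis(gl.ravel()).reshape(len(self.t), 32, ncoef)
            self._B_end = basis(np.array([tmax]))[0]
            self._gl_w = weights
            self._t_half = 0.5 * tin
            self._t_over = np.maximum(self.t - tmax, 0.0)

    def baseline_parts(self, theta: np.ndarray):
        """(log h0(t_i), H0(t_i)) for the omega block on its sampling scale."""
        if self.family == "exponential":
            lam = np.exp(theta[0])
            return np.full_like(self.t, theta[0]), lam * self.t
        if self.family == "weibull":
            shape, scale = np.exp(theta)
            log_h0 = np.log(shape * scale) + (shape - 1.0) * self.logt
            return log_h0, scale * np.exp(shape * self.logt)
        log_h0 = self._B_data @ theta
        q = np.exp(self._B_quad @ theta)
        H0 = self._t_half * (q @ self._gl_w)
        H0 = H0 + self._t_over * np.exp(self._B_end @ theta)
        return log_h0, H0

    def pointwise(self, xb: np.ndarray, Y: np.ndarray, log_h0, H0) -> np.ndarray:
        lin = xb + Y[self.didx]
        return self.delta * (log_h0 + lin) - H0 * np.exp(lin)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _ml_prefit_theta(data, spec: ModelSpec) -> np.ndarray:
    """Non-spatial maximum-likelihood initial value for the omega block."""
    events = float(data.delta.sum())
    total_t = float(data.t.sum())
    lam = max(events, 0.5) / total_t
    if spec.baseline_family == "exponential":
        return np.array([np.log(lam)])
    if spec.baseline_family == "weibull":
        from scipy.optimize import minimize

        logt = np.log(data.t)
        delta = data.delta.astype(float)

        def nll(th):
            shape, scale = np.exp(th)
            ll = delta * (np.log(shape * scale) + (shape - 1.0) * logt) \
                - scale * np.exp(shape * logt)
            return -np.sum(ll)

        res = minimize(nll, x0=np.array([0.0, np.log(lam)]), method="Nelder-Mead",
                       options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-4})
        return res.x
    return np.full(spec.n_omega(), np.log(lam))


def default_priors(data, spec: ModelSpec) -> PriorSpec:
    """Weakly-informative priors centred on cheap data-driven anchors.

    The log-scale priors are centred at the non-spatial ML prefit for omega
    and the median inter-centroid distance for phi; scales follow the
    package convention (sd 10 for beta, sd 2 for log-scale parameters).
    """
    theta0 = _ml_prefit_theta(data, spec)
    d = spec.distances.d
    med = np.median(d[np.triu_indices(len(d), k=1)]) if len(d) > 1 else 1.0
    return PriorSpec(beta=NormalPrior(0.0, 10.0),
                     log_omega=NormalPrior(theta0, 2.0),
                     log_sigma2=NormalPrior(np.log(0.1), 2.0),
                     log_phi=NormalPrior(np.log(max(med, 1.0)), 2.0))


class _Adapt:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    def __init__(self, scale: float, target: float, batch: int,
                 lo: float = 1e-8, hi: float = 1e8):
        self.log_scale = np.log(scale)
        self.target = target
        self.batch = batch
        self.lo, self.hi = np.log(lo), np.log(hi)
        self.n_acc = 0
        self.n_prop = 0
        self.acc_total = 0
        self.prop_total = 0
        self.n_batches = 0
        self.frozen = False

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def update(self, accepted: bool):
        self.n_prop += 1
        self.prop_total += 1
        if accepted:
            self.n_acc += 1
            self.acc_total += 1
        if not self.frozen and self.n_prop >= self.batch:
            rate = self.n_acc / self.n_prop
            step = min(0.25, 2.0 / np.sqrt(self.n_batches + 1.0))
            self.log_scale += step if rate > self.target else -step
            self.log_scale = float(np.clip(self.log_scale, self.lo, self.hi))
            self.n_acc = self.n_prop = 0
            self.n_batches += 1

    @property
    def overall_rate(self) -> float:
        return self.acc_total / max(self.prop_total, 1)


def run_mcmc(data, model_spec: ModelSpec, priors: PriorSpec,
             settings: McmcSettings) -> McmcChain:
    """Sample the joint posterior of (beta, omega, sigma2, phi, Y).

    Deterministic given ``settings.seed``.  Raises if the posterior is
    nonfinite at initialisation (reporting the offending term) or if the
    burn-in is not shorter than the run.
    """
    if settings.n_burn >= settings.n_iter:
        raise ModelError("n_burn must be smaller than n_iter")
    for name in ("beta", "log_omega", "log_sigma2", "log_phi"):
        if getattr(priors, name) is None:
            raise ModelError(f"no prior specified for {name}")
    if tuple(model_spec.distances.ids) != tuple(data.district_ids):
        raise ModelError("distance matrix districts do not match dataset districts")

    rng = np.random.default_rng(settings.seed)
    cache = _LikCache(data, model_spec)
    p = data.X.shape[1]
    m = data.n_districts
    D = model_spec.distances.d

    # --- initial state -----------------------------------------------------
    beta = (np.zeros(p) if settings.beta0 is None
            else np.asarray(settings.beta0, dtype=float).copy())
    theta = (_ml_prefit_theta(data, model_spec) if settings.omega0 is None
             else np.asarray(settings.omega0, dtype=float).copy())
    sigma2 = float(settings.sigma2_0)
    if settings.phi0 is not None:
        phi = float(settings.phi0)
    else:
        triu = D[np.triu_indices(m, k=1)]
        phi = float(np.median(triu)) if len(triu) else 1.0
    log_sigma2, log_phi = np.log(sigma2), np.log(phi)

    frailty_fixed = settings.fix_frailty is not None
    if frailty_fixed:
        Y = np.asarray(settings.fix_frailty, dtype=float).copy()
        if Y.shape != (m,):
            raise ModelError("fix_frailty must have one value per district")
        v = np.zeros(m)
        L = np.eye(m)
    else:
        Sigma = sigma2 * correlation(D, phi)
        L, _ = chol_with_jitter(Sigma)
        v = np.zeros(m)
        Y = -0.5 * sigma2 + L @ v

    def lik_terms(beta_, theta_, Y_):
        if settings.likelihood_off:
            return np.zeros(data.n)
        log_h0, H0 = cache.baseline_parts(theta_)
        return cache.pointwise(cache.X @ beta_, Y_, log_h0, H0)

    def lp_eta(ls2, lph):
        return priors.log_sigma2.logpdf(ls2) + priors.log_phi.logpdf(lph)

    cur_terms = lik_terms(beta, theta, Y)
    cur_lik = float(cur_terms.sum())
    cur_lp_beta = priors.beta.logpdf(beta) if p else 0.0
    cur_lp_omega = priors.log_omega.logpdf(theta)
    cur_lp_eta = lp_eta(log_sigma2, log_phi)
    for name, val in (("likelihood", cur_lik), ("beta prior", cur_lp_beta),
                      ("omega prior", cur_lp_omega), ("spatial prior", cur_lp_eta)):
        if not np.isfinite(val):
            raise ModelError(f"nonfinite posterior at initialisation: {name} term")

    # --- adaptation state --------------------------------------------------
    batch = settings.adapt_batch
    ad_beta = _Adapt(0.1 / max(np.sqrt(p), 1.0), 0.44 if p == 1 else 0.234, batch)
    k = len(theta)
    ad_omega = _Adapt(0.1 / np.sqrt(k), 0.44 if k == 1 else 0.234, batch)
    ad_eta = _Adapt(0.3, 0.234, batch)
    ad_v = _Adapt(0.2, 0.234, batch, lo=1e-8, hi=0.999)

    S = (settings.n_iter - settings.n_burn) // settings.n_thin
    out_beta = np.empty((S, p))
    out_theta = np.empty((S, k))
    out_ls2 = np.empty(S)
    out_lphi = np.empty(S)
    out_Y = np.empty((S, m))
    out_ll = np.empty((data.n, S))
    s_out = 0

    for it in range(1, settings.n_iter + 1):
        if it == settings.n_burn + 1:
            for ad in (ad_beta, ad_omega, ad_eta, ad_v):
                ad.frozen = True

        # -- beta block
        if p:
            prop = beta + ad_beta.scale * rng.standard_normal(p)
            lp_prop = priors.beta.logpdf(prop)
            terms = lik_terms(prop, theta, Y)
            lik = float(terms.sum())
            logr = lik + lp_prop - cur_lik - cur_lp_beta
            acc = np.isfinite(logr) and np.log(rng.random()) < logr
            if acc:
                beta, cur_terms, cur_lik, cur_lp_beta = prop, terms, lik, lp_prop
            ad_beta.update(acc)

        # -- omega block
        prop = theta + ad_omega.scale * rng.standard_normal(k)
        lp_prop = priors.log_omega.logpdf(prop)
        terms = lik_terms(beta, prop, Y)
        lik = float(terms.sum())
        logr = lik + lp_prop - cur_lik - cur_lp_omega
        acc = np.isfinite(logr) and np.log(rng.random()) < logr
        if acc:
            theta, cur_terms, cur_lik, cur_lp_omega = prop, terms, lik, lp_prop
        ad_omega.update(acc)

        # -- spatial block (log sigma2, log phi): moves Y for fixed v
        if not settings.fix_spatial and not frailty_fixed:
            prop_ls2, prop_lphi = (np.array([log_sigma2, log_phi])
                                   + ad_eta.scale * rng.standard_normal(2))
            prop_s2, prop_phi = np.exp(prop_ls2), np.exp(prop_lphi)
            try:
                L_prop, _ = chol_with_jitter(prop_s2 * correlation(D, prop_phi))
            except ModelError:
                L_prop = None
            if L_prop is not None:
                Y_prop = -0.5 * prop_s2 + L_prop @ v
                lp_prop = lp_eta(prop_ls2, prop_lphi)
                terms = lik_terms(beta, theta, Y_prop)
                lik = float(terms.sum())
                logr = lik + lp_prop - cur_lik - cur_lp_eta
                acc = np.isfinite(logr) and np.log(rng.random()) < logr
            else:
                acc = False
            if acc:
                log_sigma2, log_phi = float(prop_ls2), float(prop_lphi)
                sigma2, phi, L, Y = prop_s2, prop_phi, L_prop, Y_prop
                cur_terms, cur_lik, cur_lp_eta = terms, lik, lp_prop
            ad_eta.update(acc)

        # -- frailty block: preconditioned Crank-Nicolson on whitened v
        if not frailty_fixed:
            s = min(ad_v.scale, 0.999)
            v_prop = np.sqrt(1.0 - s * s) * v + s * rng.standard_normal(m)
            Y_prop = -0.5 * sigma2 + L @ v_prop
            terms = lik_terms(beta, theta, Y_prop)
            lik = float(terms.sum())
            logr = lik - cur_lik  # pCN: prior ratio cancels
            acc = np.isfinite(logr) and np.log(rng.random()) < logr
            if acc:
                v, Y, cur_terms, cur_lik = v_prop, Y_prop, terms, lik
            ad_v.update(acc)

        # -- retain
        if it > settings.n_burn and (it - settings.n_burn) % settings.n_thin == 0:
            out_beta[s_out] = beta
            out_theta[s_out] = theta
            out_ls2[s_out] = log_sigma2
            out_lphi[s_out] = log_phi
            out_Y[s_out] = Y
            out_ll[:, s_out] = cur_terms
            s_out += 1

    acceptance = {"beta": ad_beta.overall_rate if p else np.nan,
                  "omega": ad_omega.overall_rate,
                  "eta": ad_eta.overall_rate if not (settings.fix_spatial
                                                     or frailty_fixed) else np.nan,
                  "frailty": ad_v.overall_rate if not frailty_fixed else np.nan}
    return McmcChain(beta=out_beta, beta_names=tuple(data.columns),
                     omega_theta=out_theta, log_sigma2=out_ls2, log_phi=out_lphi,
                     Y=out_Y, district_ids=tuple(data.district_ids),
                     loglik_pointwise=out_ll, acceptance=acceptance,
                     settings=settings, model_spec=model_spec)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Sample autocorrelation function via FFT."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag is None:
        max_lag = n - 1
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    if acov[0] == 0:
        return np.concatenate([[1.0], np.zeros(max_lag)])
    return acov[:max_lag + 1] / acov[0]


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial positive sequence on paired autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 or np.var(x) == 0:
        return 1.0
    rho = autocorrelation(x)
    tau = 1.0
    for k in range(1, (n - 1) // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(min(n, max(1.0, n / tau)))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Mean-split convergence z-score (first vs last chain segment)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: int(first * n)]
    b = x[int((1.0 - last) * n):]
    va = np.var(a, ddof=1) / effective_sample_size(a)
    vb = np.var(b, ddof=1) / effective_sample_size(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def diagnostics(chain: McmcChain, ess_floor: float = 100.0) -> pd.DataFrame:
    """Per-parameter summary: mean, sd, ESS, Geweke z, low-ESS flag."""
    series = chain.scalar_series()
    if chain.n_draws < 100:
        raise ModelError("need at least 100 retained draws for diagnostics")
    rows = []
    for name, x in series.items():
        ess = effective_sample_size(x)
        rows.append({"parameter": name, "mean": float(np.mean(x)),
                     "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                     "ess": ess, "geweke_z": geweke_z(x),
                     "low_ess": bool(ess < ess_floor)})
    return pd.DataFrame(rows)


def density_overlap(pdf_a, pdf_b, grid: np.ndarray) -> float:
    """Overlap coefficient of two densities on a grid: integral of min."""
    a = np.asarray(pdf_a(grid) if callable(pdf_a) else pdf_a, dtype=float)
    b = np.asarray(pdf_b(grid) if callable(pdf_b) else pdf_b, dtype=float)
    return float(np.trapezoid(np.minimum(a, b), grid))


def _normal_pdf(mean, sd):
    def pdf(x):
        z = (x - mean) / sd
        return np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))
    return pdf


def prior_posterior_compare(chain: McmcChain, priors: PriorSpec) -> pd.DataFrame:
    """Per-parameter prior/posterior overlap in [0, 1].

    Posterior densities are Gaussian KDEs of the retained draws; overlap
    near 1 flags weak identifiability (posterior ~ prior).
    """
    from scipy.stats import gaussian_kde

    records = []
    series = chain.scalar_series()

    def prior_pdf_for(name):
        if name.startswith("beta["):
            pr = priors.beta
        elif name.startswith("omega_theta["):
            pr = priors.log_omega
        elif name == "log_sigma2":
            pr = priors.log_sigma2
        elif name == "log_phi":
            pr = priors.log_phi
        else:
            return None
        if isinstance(pr, NormalPrior):
            mean = np.atleast_1d(pr.mean)
            sd = np.atleast_1d(pr.sd)
            j = 0
            if "[" in name and name.startswith(("beta[", "omega_theta[")):
                key = name[name.index("[") + 1:-1]
                if name.startswith("beta["):
                    j = list(chain.beta_names).index(key)
                else:
                    j = int(key)
            return _normal_pdf(float(mean[j % len(mean)]), float(sd[j % len(sd)])), \
                float(mean[j % len(mean)]), float(sd[j % len(sd)])
        return None

    for name, x in series.items():
        info = prior_pdf_for(name)
        if info is None:
            continue
        pdf, pm, psd = info
        lo = min(x.min(), pm - 4 * psd)
        hi = max(x.max(), pm + 4 * psd)
        grid = np.linspace(lo, hi, 512)
        if np.std(x) == 0:
            overlap = 0.0
        else:
            kde = gaussian_kde(x)
            overlap = density_overlap(pdf, kde, grid)
        records.append({"parameter": name, "overlap": min(overlap, 1.0),
                        "posterior_mean": float(np.mean(x)),
                        "posterior_sd": float(np.std(x, ddof=1)),
                        "weakly_identified": bool(overlap > 0.75)})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# WAIC
# ---------------------------------------------------------------------------

def compute_waic(chain: McmcChain) -> WaicResult:
    """WAIC from the pointwise log-likelihood matrix.

    lppd uses log-sum-exp stabilisation; the effective-parameter term is the
    summed posterior variance of the pointwise log-likelihood.
    """
    ll = np.asarray(chain.loglik_pointwise, dtype=float)
    n, S = ll.shape
    if S < 2:
        raise ModelError("WAIC needs at least 2 retained draws")
    lppd = float(np.sum(logsumexp(ll, axis=1) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=1, ddof=1)))
    return WaicResult(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic))


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def save_chain(chain: McmcChain, path) -> None:
    """Write retained draws as CSV with a JSON metadata header line."""
    meta = {"seed": chain.settings.seed if chain.settings else None,
            "n_iter": chain.settings.n_iter if chain.settings else None,
            "n_burn": chain.settings.n_burn if chain.settings else None,
            "n_thin": chain.settings.n_thin if chain.settings else None,
            "baseline_family": (chain.model_spec.baseline_family
                                if chain.model_spec else None),
            "beta_names": list(chain.beta_names),
            "district_ids": list(chain.district_ids),
            "acceptance": {k: (None if not np.isfinite(v) else round(v, 6))
                           for k, v in chain.acceptance.items()}}
    cols = {}
    for j, name in enumerate(chain.beta_names):
        cols[f"beta.{name}"] = chain.beta[:, j]
    for j in range(chain.omega_theta.shape[1]):
        cols[f"omega_theta.{j}"] = chain.omega_theta[:, j]
    cols["log_sigma2"] = chain.log_sigma2
    cols["log_phi"] = chain.log_phi
    for j, d in enumerate(chain.district_ids):
        cols[f"Y.{d}"] = chain.Y[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def load_chain(path) -> tuple[pd.DataFrame, dict]:
    """Read a saved chain; returns (draws frame, metadata dict)."""
    with open(path) as fh:
        header = fh.readline()
        meta = json.loads(header.lstrip("# ").strip()) if header.startswith("#") else {}
        df = pd.read_csv(fh)
    return df, meta
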