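"""Bayesian hierarchical spatial models for occurrence, cover and bleaching.

Three models are fitted:

* occurrence: ``Y_i ~ Bernoulli(pi_i)`` with
  ``logit(pi_i) = alpha + X_i beta + W_i``,
* conditional cover / bleaching: ``Z_i ~ Lognormal(mu_i, sigma2)``
  (natural-log scale) with ``log(mu_i) = alpha + X_i beta + W_i``,
  fitted to presence records only,

where W is a zero-mean Gaussian spatial random effect with Matérn
covariance between site locations, and the fixed effects carry vague
zero-mean Gaussian priors with variance 100.

Inference is a deterministic Laplace / empirical-Bayes scheme in the
INLA spirit: the Matérn hyperparameters (and the lognormal variance)
live on a small grid; for each grid point the latent field posterior
is obtained exactly (Gaussian likelihood) or by a Newton-optimised
Gaussian approximation (Bernoulli likelihood); grid points are weighted
by their (approximate) marginal likelihood times a weakly-informative
hyperprior; posterior draws are sampled from the resulting mixture.
The model contract is checked by parameter recovery, not by matching
any particular sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit

from .covariates import Standardization, standardize
from .matern import MaternParams, matern_correlation, pairwise_distances
from .observations import ObservationSet
from .stack import CovariateStack

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ModelSpec:
    """What enters one model: response, covariates, spatial effect, priors."""

    response_kind: str
    covariate_names: list[str] = field(default_factory=list)
    include_spatial: bool = True
    matern_prior: dict | None = None  # optional sigma_grid / range_grid / nu
    fixed_effect_prior_variance: float = 100.0

    def __post_init__(self) -> None:
        if self.fixed_effect_prior_variance <= 0:
            raise ValueError("fixed_effect_prior_variance must be > 0")
        self.covariate_names = list(self.covariate_names)

    def with_added(self, covariate: str | None = None, spatial: bool | None = None) -> "ModelSpec":
        return ModelSpec(
            response_kind=self.response_kind,
            covariate_names=self.covariate_names + ([covariate] if covariate else []),
            include_spatial=self.include_spatial if spatial is None else spatial,
            matern_prior=self.matern_prior,
            fixed_effect_prior_variance=self.fixed_effect_prior_variance,
        )

    def label(self) -> str:
        covs = "+".join(self.covariate_names) if self.covariate_names else "1"
        return f"{covs}{'+spatial' if self.include_spatial else ''}"


@dataclass
class InferenceConfig:
    """Engine settings: draw count, seed, hyperparameter grids."""

    n_draws: int = 1000
    seed: int = 0
    sigma_grid: tuple = (0.3, 0.75, 1.5)          # spatial sd grid
    range_fractions: tuple = (0.15, 0.35, 0.7)    # of the site bbox diagonal
    nu: float = 1.0
    sigma2_grid_size: int = 7                     # lognormal variance grid
    sigma2_grid_spread: float = 4.0
    max_iter: int = 50
    tol: float = 1e-8
    metric: str = "planar"
    jitter: float = 1e-8


@dataclass
class PosteriorFit:
    """Posterior summaries, draws and pointwise log-likelihoods."""

    spec: ModelSpec
    params: pd.DataFrame                 # mean/sd/quantiles per parameter
    b_draws: np.ndarray                  # (n_draws, 1+p): intercept then betas
    w_draws: np.ndarray                  # (n_draws, m) spatial field at sites
    sigma2_draws: np.ndarray | None      # conditional models only
    hyper_draws: pd.DataFrame            # spatial sigma/range per draw
    site_coords: np.ndarray              # (m, 2) unique (lat, lon)
    site_index: np.ndarray               # obs -> site map
    X: np.ndarray                        # (n_obs, p) standardized covariates
    response: np.ndarray                 # y (0/1) or log z
    standardization: Standardization
    loglik: np.ndarray                   # (n_obs, n_draws)
    diagnostics: dict = field(default_factory=dict)
    obs_fingerprint: tuple = ()

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_draws(self) -> int:
        return self.b_draws.shape[0]

    def coefficient_mean(self, name: str) -> float:
        return float(self.params.loc[f"beta_{name}", "mean"])


@dataclass
class HurdleFit:
    """Two-step fit: occurrence component and conditional component."""

    occurrence: PosteriorFit
    conditional: PosteriorFit


def unconditional_mean(pi: np.ndarray, mu: np.ndarray, sigma2) -> np.ndarray:
    """Expected response of the hurdle model, pi * exp(mu + sigma2/2)."""
    return pi * np.exp(mu + np.asarray(sigma2) / 2.0)


# ----------------------------------------------------------------- engine

def _factorize_sites(obs: ObservationSet) -> tuple[np.ndarray, np.ndarray]:
    keys = pd.MultiIndex.from_arrays([obs.lat, obs.lon])
    idx, uniques = pd.factorize(keys, sort=True)
    coords = np.array([[la, lo] for la, lo in uniques])
    return idx, coords


def _design(obs: ObservationSet, covariates: CovariateStack, spec: ModelSpec,
            standardization: Standardization | None):
    if standardization is None:
        _, standardization = standardize(covariates)
    if not spec.covariate_names:
        return np.empty((len(obs), 0)), standardization
    raw = covariates.at_sites(obs.lat, obs.lon, spec.covariate_names)
    X = standardization.transform_values(raw).to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = int(np.isnan(X).any(axis=1).sum())
        raise ValueError(f"missing covariate values at {bad} observation row(s)")
    return X, standardization


def _hyper_combos(spec: ModelSpec, config: InferenceConfig, coords: np.ndarray):
    """Spatial hyperparameter grid with log hyperprior weights.

    sigma carries an Exponential(1) prior (shrinks toward no spatial
    effect); range is uniform over a grid scaled to the site bounding
    box diagonal.
    """
    prior = spec.matern_prior or {}
    nu = prior.get("nu", config.nu)
    sigmas = prior.get("sigma_grid", config.sigma_grid)
    if "range_grid" in prior:
        ranges = prior["range_grid"]
    else:
        span = coords.max(axis=0) - coords.min(axis=0)
        diag = float(np.hypot(*span)) or 1.0
        ranges = [f * diag for f in config.range_fractions]
    combos = []
    for rho in ranges:
        for s in sigmas:
            combos.append((MaternParams(s, rho, nu), -float(s)))
    return combos


def _spatial_precisions(coords: np.ndarray, combos, config: InferenceConfig):
    """Per-combo (precision of w, logdet of its covariance).

    K(sigma, rho) = sigma^2 (R(rho) + jitter I), so (R + jI) is
    factorised once per distinct range and rescaled per sigma.
    """
    d = pairwise_distances(coords, metric=config.metric)
    m = len(coords)
    cache: dict[float, tuple[np.ndarray, float]] = {}
    out = []
    for params, logprior in combos:
        if params.range_ not in cache:
            R = matern_correlation(d, MaternParams(1.0, params.range_, params.nu))
            R = R + config.jitter * np.eye(m)
            c, low = cho_factor(R, lower=True)
            Rinv = cho_solve((c, low), np.eye(m))
            logdetR = 2.0 * np.log(np.diag(c)).sum()
            cache[params.range_] = (Rinv, logdetR)
        Rinv, logdetR = cache[params.range_]
        prec = Rinv / params.sigma**2
        logdetK = m * np.log(params.sigma**2) + logdetR
        out.append((params, logprior, prec, logdetK))
    return out


def _assemble_H(A, W, site_index, m, P_bb_diag, P_ww):
    """Hessian of the negative log posterior in (b, w), exploiting the
    incidence structure of the site map (no dense n x (q) product)."""
    pb = A.shape[1]
    AtWA = (A * W[:, None]).T @ A
    AtWZ = np.zeros((pb, m))
    for k in range(pb):
        AtWZ[k] = np.bincount(site_index, weights=A[:, k] * W, minlength=m)
    ZtWZ = np.bincount(site_index, weights=W, minlength=m)
    q = pb + m
    H = np.zeros((q, q))
    H[:pb, :pb] = AtWA + np.diag(P_bb_diag)
    H[:pb, pb:] = AtWZ
    H[pb:, :pb] = AtWZ.T
    H[pb:, pb:] = P_ww + np.diag(ZtWZ)
    return H


def _grad(A, resid, site_index, m, P, u):
    pb = A.shape[1]
    g = np.empty(len(u))
    g[:pb] = A.T @ resid
    g[pb:] = np.bincount(site_index, weights=resid, minlength=m)
    return g - P @ u


def _summaries(names, draws_2d, extra: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = {}
    for j, name in enumerate(names):
        rows[name] = draws_2d[:, j]
    rows.update(extra)
    recs = []
    for name, d in rows.items():
        q = np.quantile(d, [0.025, 0.5, 0.975])
        recs.append(
            {"parameter": name, "mean": d.mean(), "sd": d.std(ddof=1),
             "q025": q[0], "q500": q[1], "q975": q[2]}
        )
    return pd.DataFrame(recs).set_index("parameter")


def _allocate(weights: np.ndarray, n_draws: int, rng) -> np.ndarray:
    return rng.multinomial(n_draws, weights)


def fit_occurrence(
    obs: ObservationSet,
    covariates: CovariateStack,
    spec: ModelSpec,
    config: InferenceConfig | None = None,
    standardization: Standardization | None = None,
) -> PosteriorFit:
    """Fit the Bernoulli-logit occurrence model.

    Raises on complete separation (all-presence or all-absence data)
    and on missing covariate values at observation sites.
    """
    config = config or InferenceConfig()
    y = obs.y.astype(float)
    if y.min() == y.max():
        raise ValueError("occurrence response is all 0 or all 1; model is not identifiable")
    X, standardization = _design(obs, covariates, spec, standardization)
    site_index, coords = _factorize_sites(obs)
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    pb = A.shape[1]
    P_bb = np.full(pb, 1.0 / spec.fixed_effect_prior_variance)
    logdet_Pbb = float(np.sum(np.log(P_bb)))

    if spec.include_spatial:
        combos = _spatial_precisions(coords, _hyper_combos(spec, config, coords), config)
        m = len(coords)
    else:
        combos = [(None, 0.0, None, 0.0)]
        m = 0

    rng = np.random.default_rng(config.seed)
    results = []
    u = np.zeros(pb + m)
    for params, logprior, prec_w, logdetK in combos:
        q = pb + m
        if m:
            P = np.zeros((q, q))
            P[:pb, :pb] = np.diag(P_bb)
            P[pb:, pb:] = prec_w
            logdetP = logdet_Pbb - logdetK
        else:
            P = np.diag(P_bb)
            logdetP = logdet_Pbb

        def logpost(u_):
            eta = A @ u_[:pb] + (u_[pb:][site_index] if m else 0.0)
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            return ll - 0.5 * float(u_ @ P @ u_), eta

        lp, eta = logpost(u)
        converged = False
        iters = 0
        for it in range(config.max_iter):
            iters = it + 1
            p = expit(eta)
            W = np.clip(p * (1 - p), 1e-10, None)
            g = _grad(A, y - p, site_index, m, P, u) if m else (A.T @ (y - p) - P @ u)
            if m:
                H = _assemble_H(A, W, site_index, m, P_bb, prec_w)
            else:
                H = (A * W[:, None]).T @ A + np.diag(P_bb)
            cH = cho_factor(H, lower=True)
            step = cho_solve(cH, g)
            t = 1.0
            for _ in range(12):
                lp_new, eta_new = logpost(u + t * step)
                if lp_new >= lp - 1e-12:
                    break
                t /= 2.0
            u = u + t * step
            if abs(lp_new - lp) < config.tol * (1 + abs(lp)) and float(np.abs(g).max()) < 1e-4:
                lp, eta = lp_new, eta_new
                converged = True
                break
            lp, eta = lp_new, eta_new
        # final curvature at the mode
        p = expit(eta)
        W = np.clip(p * (1 - p), 1e-10, None)
        H = _assemble_H(A, W, site_index, m, P_bb, prec_w) if m else (
            (A * W[:, None]).T @ A + np.diag(P_bb)
        )
        cH = cho_factor(H, lower=True)
        logdetH = 2.0 * float(np.log(np.diag(cH[0])).sum())
        evidence = lp + 0.5 * logdetP - 0.5 * logdetH + logprior
        results.append({"params": params, "u": u.copy(), "cH": cH, "evidence": evidence,
                        "converged": converged, "iters": iters})
        if not converged:
            warnings.warn(f"occurrence Newton did not fully converge for {params}")

    ev = np.array([r["evidence"] for r in results])
    wts = np.exp(ev - ev.max())
    wts /= wts.sum()
    counts = _allocate(wts, config.n_draws, rng)

    draws = np.empty((config.n_draws, pb + m))
    hyper_sigma = np.empty(config.n_draws)
    hyper_range = np.empty(config.n_draws)
    pos = 0
    for r, k in zip(results, counts):
        if k == 0:
            continue
        L = r["cH"][0]
        zdim = pb + m
        zs = rng.standard_normal((zdim, k))
        dev = solve_triangular(L, zs, lower=True, trans="T")
        draws[pos : pos + k] = r["u"][None, :] + dev.T
        if r["params"] is not None:
            hyper_sigma[pos : pos + k] = r["params"].sigma
            hyper_range[pos : pos + k] = r["params"].range_
        else:
            hyper_sigma[pos : pos + k] = 0.0
            hyper_range[pos : pos + k] = np.nan
        pos += k

    b_draws = draws[:, :pb]
    w_draws = draws[:, pb:] if m else np.zeros((config.n_draws, 0))
    eta_draws = A @ b_draws.T + (w_draws[:, site_index].T if m else 0.0)
    loglik = -np.logaddexp(0.0, np.where(y[:, None] == 1, -eta_draws, eta_draws))

    names = ["alpha"] + [f"beta_{c}" for c in spec.covariate_names]
    extra = {}
    if m:
        extra = {"spatial_sigma": hyper_sigma, "spatial_range": hyper_range}
    params_tab = _summaries(names, b_draws, extra)
    return PosteriorFit(
        spec=spec,
        params=params_tab,
        b_draws=b_draws,
        w_draws=w_draws,
        sigma2_draws=None,
        hyper_draws=pd.DataFrame({"sigma": hyper_sigma, "range": hyper_range}),
        site_coords=coords,
        site_index=site_index,
        X=X,
        response=y,
        standardization=standardization,
        loglik=loglik,
        diagnostics={
            "weights": wts.tolist(),
            "converged": [bool(r["converged"]) for r in results],
            "newton_iterations": [r["iters"] for r in results],
        },
        obs_fingerprint=_fingerprint(obs),
    )


def fit_conditional_lognormal(
    obs: ObservationSet,
    covariates: CovariateStack,
    spec: ModelSpec,
    config: InferenceConfig | None = None,
    standardization: Standardization | None = None,
) -> PosteriorFit:
    """Fit the conditional (presence-only) lognormal model on log z.

    ``obs`` must contain only presence records with z > 0 (use
    :meth:`ObservationSet.presence_subset`); at least 10 records are
    required.
    """
    config = config or InferenceConfig()
    z = obs.z
    if np.isnan(z).any() or np.any(z <= 0):
        raise ValueError("conditional model requires z > 0 for every record")
    if len(z) < 10:
        raise ValueError(f"conditional model needs >= 10 records, got {len(z)}")
    t = np.log(z)
    X, standardization = _design(obs, covariates, spec, standardization)
    site_index, coords = _factorize_sites(obs)
    n = len(t)
    A = np.column_stack([np.ones(n), X])
    pb = A.shape[1]
    P_bb = np.full(pb, 1.0 / spec.fixed_effect_prior_variance)
    logdet_Pbb = float(np.sum(np.log(P_bb)))
    m = len(coords) if spec.include_spatial else 0

    # empirical-Bayes sigma^2 grid around the OLS residual variance
    coef, *_ = np.linalg.lstsq(A, t, rcond=None)
    resid = t - A @ coef
    s2_hat = max(float((resid**2).sum() / max(n - pb, 1)), 1e-8)
    g = config.sigma2_grid_size
    s2_grid = s2_hat * config.sigma2_grid_spread ** np.linspace(-1, 1, g)

    if m:
        sp_combos = _spatial_precisions(coords, _hyper_combos(spec, config, coords), config)
    else:
        sp_combos = [(None, 0.0, None, 0.0)]

    # precompute structured C'C blocks
    AtA = A.T @ A
    if m:
        AtZ = np.zeros((pb, m))
        for k in range(pb):
            AtZ[k] = np.bincount(site_index, weights=A[:, k], minlength=m)
        ZtZ = np.bincount(site_index, minlength=m).astype(float)
        Ct_t = np.concatenate([A.T @ t, np.bincount(site_index, weights=t, minlength=m)])
    else:
        Ct_t = A.T @ t
    tt = float(t @ t)

    rng = np.random.default_rng(config.seed)
    results = []
    for params, logprior, prec_w, logdetK in sp_combos:
        for s2 in s2_grid:
            q = pb + m
            H = np.zeros((q, q))
            H[:pb, :pb] = AtA / s2 + np.diag(P_bb)
            if m:
                H[:pb, pb:] = AtZ / s2
                H[pb:, :pb] = AtZ.T / s2
                H[pb:, pb:] = prec_w + np.diag(ZtZ / s2)
                logdetP = logdet_Pbb - logdetK
            else:
                logdetP = logdet_Pbb
            cH = cho_factor(H, lower=True)
            rhs = Ct_t / s2
            u_hat = cho_solve(cH, rhs)
            logdetH = 2.0 * float(np.log(np.diag(cH[0])).sum())
            evidence = (
                -0.5 * n * (LOG2PI + np.log(s2))
                + 0.5 * logdetP
                - 0.5 * logdetH
                - 0.5 * (tt / s2 - float(u_hat @ H @ u_hat))
                + logprior  # flat on log sigma^2 within the grid
            )
            results.append({"params": params, "s2": s2, "u": u_hat, "cH": cH,
                            "evidence": evidence})

    ev = np.array([r["evidence"] for r in results])
    wts = np.exp(ev - ev.max())
    wts /= wts.sum()
    counts = _allocate(wts, config.n_draws, rng)

    q = pb + m
    draws = np.empty((config.n_draws, q))
    s2_draws = np.empty(config.n_draws)
    hyper_sigma = np.empty(config.n_draws)
    hyper_range = np.empty(config.n_draws)
    pos = 0
    for r, k in zip(results, counts):
        if k == 0:
            continue
        L = r["cH"][0]
        dev = solve_triangular(L, rng.standard_normal((q, k)), lower=True, trans="T")
        draws[pos : pos + k] = r["u"][None, :] + dev.T
        s2_draws[pos : pos + k] = r["s2"]
        if r["params"] is not None:
            hyper_sigma[pos : pos + k] = r["params"].sigma
            hyper_range[pos : pos + k] = r["params"].range_
        else:
            hyper_sigma[pos : pos + k] = 0.0
            hyper_range[pos : pos + k] = np.nan
        pos += k

    b_draws = draws[:, :pb]
    w_draws = draws[:, pb:] if m else np.zeros((config.n_draws, 0))
    eta_draws = A @ b_draws.T + (w_draws[:, site_index].T if m else 0.0)
    # refresh sigma^2 from its conditional posterior given each latent
    # draw (Jeffreys prior -> inverse-gamma), so its posterior spread
    # is continuous rather than pinned to the hyper grid
    rss = ((t[:, None] - eta_draws) ** 2).sum(axis=0)
    s2_draws = (rss / 2.0) / rng.gamma(n / 2.0, 1.0, size=config.n_draws)
    # lognormal density of z = normal density of log z minus log z
    loglik = (
        -0.5 * (LOG2PI + np.log(s2_draws)[None, :])
        - 0.5 * (t[:, None] - eta_draws) ** 2 / s2_draws[None, :]
        - t[:, None]
    )

    names = ["alpha"] + [f"beta_{c}" for c in spec.covariate_names]
    extra = {"sigma2": s2_draws}
    if m:
        extra.update({"spatial_sigma": hyper_sigma, "spatial_range": hyper_range})
    params_tab = _summaries(names, b_draws, extra)
    return PosteriorFit(
        spec=spec,
        params=params_tab,
        b_draws=b_draws,
        w_draws=w_draws,
        sigma2_draws=s2_draws,
        hyper_draws=pd.DataFrame({"sigma": hyper_sigma, "range": hyper_range}),
        site_coords=coords,
        site_index=site_index,
        X=X,
        response=t,
        standardization=standardization,
        loglik=loglik,
        diagnostics={"weights": wts.tolist(), "sigma2_grid": s2_grid.tolist()},
        obs_fingerprint=_fingerprint(obs),
    )


def fit_hurdle(
    obs: ObservationSet,
    covariates: CovariateStack,
    spec_occ: ModelSpec,
    spec_cond: ModelSpec,
    config: InferenceConfig | None = None,
    standardization: Standardization | None = None,
) -> HurdleFit:
    """Fit the two-step hurdle: occurrence on all records, conditional
    lognormal on the presence subset.  The two components are fitted
    independently."""
    occ = fit_occurrence(obs, covariates, spec_occ, config, standardization)
    cond = fit_conditional_lognormal(
        obs.presence_subset(), covariates, spec_cond, config, standardization
    )
    return HurdleFit(occurrence=occ, conditional=cond)


def _fingerprint(obs: ObservationSet) -> tuple:
    z = obs.z
    return (
        len(obs),
        float(np.nansum(z)),
        int(obs.y.sum()),
        float(obs.lat.sum()),
        float(obs.lon.sum()),
    )


def pointwise_loglik(fit: PosteriorFit, obs: ObservationSet) -> np.ndarray:
    """(n_obs, n_draws) log-likelihood of each observation under each
    retained posterior draw; errors if ``obs`` is not the fitted set."""
    if _fingerprint(obs) != fit.obs_fingerprint:
        raise ValueError("observation set does not match the one the model was fitted to")
    return fit.loglik
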