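"""NB2 random-intercept count model with exposure offset, AICc model
averaging, and relative variable importance.

The model for the late-season conflict-kill count y_ij in year i and
population unit j is

    y_ij ~ NB2(mu_ij, phi),        Var(y) = mu + mu^2 / phi
    log mu_ij = alpha + alpha_j + X_ij . beta_annual + Z_j . beta_spatial
                + log A_j
    alpha_j ~ Normal(0, sigma_alpha^2)

with A_j the habitable area of unit j (so the modelled rate is per km^2).
The marginal likelihood integrates the population random intercepts out
by adaptive Gauss-Hermite quadrature, one 1-D integral per unit, centred
and scaled at the conditional mode found by Newton iterations.  Gradients
of the marginal log-likelihood are computed by the Fisher identity (the
posterior expectation of the joint score under the same quadrature rule).

Candidate models are all subsets of the annual predictors with the
spatial predictors always retained; they are combined by Akaike weights
on AICc, with full (zero-substitution) coefficient averaging,
Burnham-Anderson unconditional variances, and relative variable
importance (the summed weight of candidates containing a term).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp, roots_hermite

from conflict_ecology.predictors import DesignMatrix

logger = logging.getLogger(__name__)

_ETA_CLIP = 45.0


class LikelihoodError(ValueError):
    """Raised when the linear predictor is non-finite for some row."""


class AveragingError(RuntimeError):
    """Raised when no converged candidate fit is available."""


@dataclass
class FitResult:
    """One fitted candidate: coefficients, dispersion, random-intercept SD."""

    terms: tuple[str, ...]
    beta: dict[str, float]  # includes "intercept"
    phi: float
    sigma_alpha: float
    loglik: float
    aicc: float
    converged: bool
    alpha_j_modes: pd.Series | None = None
    se: dict[str, float] = field(default_factory=dict)
    vcov: np.ndarray | None = None
    n_obs: int = 0
    k_params: int = 0

    def ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        b, s = self.beta[term], self.se[term]
        return (b - z * s, b + z * s)


@dataclass
class AveragedModel:
    """Model-averaged coefficients, unconditional SEs/CIs and RVI."""

    table: pd.DataFrame  # term, estimate, se, ci50/ci95 bounds, rvi
    weights: pd.Series  # Akaike weight per candidate (index: term tuples)
    fits: list[FitResult]

    def rvi(self, term: str) -> float:
        return float(self.table.set_index("term").at[term, "rvi"])

    def estimate(self, term: str) -> float:
        return float(self.table.set_index("term").at[term, "estimate"])


# --------------------------------------------------------------------------
# likelihood internals


class _DesignArrays:
    """Design unpacked to numpy, rows sorted by unit for reduceat sums."""

    def __init__(self, data: pd.DataFrame, terms: list[str] | tuple[str, ...],
                 offset_col: str = "offset_log_area"):
        df = data.sort_values(["unit_id", "year"], kind="stable")
        self.unit_ids = df["unit_id"].drop_duplicates().to_list()
        codes = pd.Categorical(df["unit_id"], categories=self.unit_ids).codes
        self.unit_idx = np.asarray(codes, dtype=np.intp)
        self.n_units = len(self.unit_ids)
        self.starts = np.searchsorted(self.unit_idx, np.arange(self.n_units))
        self.y = df["y"].to_numpy(dtype=float)
        self.offset = df[offset_col].to_numpy(dtype=float)
        self.X = np.column_stack(
            [np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in terms]
        )
        self.terms = tuple(terms)
        self.index = df.index.to_numpy()

    def group_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts, axis=-1)


def _nb2_logpmf_parts(y: np.ndarray, phi: float) -> np.ndarray:
    """mu-independent part of the NB2 log pmf."""
    return gammaln(y + phi) - gammaln(phi) - gammaln(y + 1) + phi * np.log(phi)


def _plain_nb2_loglik(eta: np.ndarray, y: np.ndarray, phi: float) -> float:
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    return float(
        np.sum(_nb2_logpmf_parts(y, phi) + y * eta - (y + phi) * np.log(mu + phi))
    )


def _conditional_modes(
    eta: np.ndarray, d: _DesignArrays, phi: float, sigma: float,
    a0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton maximisation of the per-unit joint log-density over alpha_j.

    Returns the modes and the (negative) curvature -d2/da2 at the mode.
    """
    a = np.zeros(d.n_units) if a0 is None else a0.copy()
    inv_var = 1.0 / sigma**2
    for _ in range(100):
        mu = np.exp(np.clip(eta + a[d.unit_idx], -_ETA_CLIP, _ETA_CLIP))
        g = d.group_sum(d.y - (d.y + phi) * mu / (mu + phi)) - a * inv_var
        h = d.group_sum((d.y + phi) * phi * mu / (mu + phi) ** 2) + inv_var
        step = g / h
        np.clip(step, -4.0, 4.0, out=step)
        a += step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(np.clip(eta + a[d.unit_idx], -_ETA_CLIP, _ETA_CLIP))
    h = d.group_sum((d.y + phi) * phi * mu / (mu + phi) ** 2) + inv_var
    return a, h


def _marginal(
    theta: np.ndarray,
    d: _DesignArrays,
    n_nodes: int,
    want_grad: bool,
    nodes_cache: dict,
    mode_cache: dict | None = None,
):
    """Marginal log-likelihood (and gradient) at theta = (beta, logphi, logsigma)."""
    p = d.X.shape[1]
    beta = theta[:p]
    phi = float(np.exp(theta[p]))
    sigma = float(np.exp(theta[p + 1]))
    eta = d.X @ beta + d.offset
    if not np.all(np.isfinite(eta)):
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        raise LikelihoodError(f"non-finite linear predictor at design row {bad}")

    if n_nodes not in nodes_cache:
        x, w = roots_hermite(n_nodes)
        nodes_cache[n_nodes] = (x, np.log(w) + x**2)
    x_k, logw = nodes_cache[n_nodes]

    a0 = mode_cache.get("a") if mode_cache else None
    a, h = _conditional_modes(eta, d, phi, sigma, a0=a0)
    if mode_cache is not None:
        mode_cache["a"] = a
    s = 1.0 / np.sqrt(h)

    A = a[None, :] + np.sqrt(2.0) * s[None, :] * x_k[:, None]  # (K, J)
    eta_nodes = eta[None, :] + A[:, d.unit_idx]  # (K, n)
    eta_c = np.clip(eta_nodes, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta_c)
    row_terms = (
        _nb2_logpmf_parts(d.y, phi)[None, :]
        + d.y * eta_c
        - (d.y + phi) * np.log(mu + phi)
    )
    jl = d.group_sum(row_terms)  # (K, J)
    jl += -0.5 * A**2 / sigma**2 - 0.5 * np.log(2 * np.pi * sigma**2)
    lw = np.log(np.sqrt(2.0) * s)[None, :] + logw[:, None] + jl
    ll_j = logsumexp(lw, axis=0)
    ll = float(np.sum(ll_j))
    if not want_grad:
        return ll, None

    post = np.exp(lw - ll_j[None, :])  # (K, J) posterior node weights
    W = post[:, d.unit_idx]  # (K, n)
    resid = d.y[None, :] - (d.y[None, :] + phi) * mu / (mu + phi)
    rbar = np.sum(W * resid, axis=0)
    grad_beta = d.X.T @ rbar
    dphi = (
        digamma(d.y + phi)[None, :]
        - digamma(phi)
        + np.log(phi)
        + 1.0
        - np.log(mu + phi)
        - (d.y[None, :] + phi) / (mu + phi)
    )
    grad_logphi = phi * float(np.sum(W * dphi))
    grad_logsigma = float(np.sum(post * A**2) / sigma**2 - d.n_units)
    grad = np.concatenate([grad_beta, [grad_logphi, grad_logsigma]])
    return ll, grad


def nb2_glmm_loglik(
    beta: np.ndarray | list[float],
    phi: float,
    sigma_alpha: float,
    design: DesignMatrix | pd.DataFrame,
    terms: list[str] | tuple[str, ...],
    n_nodes: int = 15,
) -> float:
    """Marginal log-likelihood of the NB2 random-intercept model.

    ``beta`` is ordered (intercept, *terms*).  With ``sigma_alpha = 0``
    the random effect is degenerate at zero and the plain NB2 regression
    log-likelihood is returned exactly; otherwise the per-unit integrals
    use ``n_nodes``-point adaptive Gauss-Hermite quadrature.
    """
    if phi <= 0:
        raise LikelihoodError("phi must be > 0")
    if sigma_alpha < 0:
        raise LikelihoodError("sigma_alpha must be >= 0")
    data = design.data if isinstance(design, DesignMatrix) else design
    d = _DesignArrays(data, terms)
    beta = np.asarray(beta, dtype=float)
    eta = d.X @ beta + d.offset
    if not np.all(np.isfinite(eta)):
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        raise LikelihoodError(f"non-finite linear predictor at design row {bad}")
    if sigma_alpha == 0.0:
        return _plain_nb2_loglik(eta, d.y, phi)
    theta = np.concatenate([beta, [np.log(phi), np.log(sigma_alpha)]])
    ll, _ = _marginal(theta, d, n_nodes, want_grad=False, nodes_cache={})
    return ll


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_nb2_glmm(
    design: DesignMatrix | pd.DataFrame,
    terms: list[str] | tuple[str, ...],
    n_nodes: int = 15,
    n_starts: int = 3,
    seed: int = 0,
    start: np.ndarray | None = None,
    compute_vcov: bool = True,
    gtol: float = 1e-5,
) -> FitResult:
    """Maximum-likelihood fit of one candidate model.

    Optimises (beta, log phi, log sigma_alpha) by L-BFGS-B with the
    analytic marginal gradient, from ``n_starts`` seeded initialisations
    (plus ``start`` if given, used for warm starts across candidates).
    The sigma_alpha boundary is handled on the log scale; a fit driven to
    the lower bound reports sigma_alpha ~ 0.  Standard errors come from
    the finite-difference Hessian of the analytic gradient.
    """
    data = design.data if isinstance(design, DesignMatrix) else design
    d = _DesignArrays(data, terms)
    p = d.X.shape[1]
    n = d.y.size
    if n <= p + 2:
        raise LikelihoodError(f"need more than {p + 2} rows, have {n}")
    nodes_cache: dict = {}
    mode_cache: dict = {}

    def objective(theta):
        ll, grad = _marginal(theta, d, n_nodes, True, nodes_cache, mode_cache)
        return -ll, -grad

    rate = max(np.mean(d.y), 0.05)
    base = np.zeros(p + 2)
    base[0] = np.log(rate) - np.mean(d.offset)
    base[p] = 0.0  # log phi
    base[p + 1] = np.log(0.5)  # log sigma_alpha
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(n_starts - 1):
        pert = base + rng.normal(0.0, 0.3, size=p + 2)
        starts.append(pert)
    if start is not None:
        starts.insert(0, np.asarray(start, dtype=float))

    bounds = [(-30.0, 30.0)] * p + [(-8.0, 12.0), (-8.0, 4.0)]
    best = None
    for theta0 in starts:
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "gtol": gtol, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.success and best.fun <= res.fun:
            # a converged optimum already in hand; later starts only need
            # to beat it, not converge themselves
            continue
    assert best is not None
    theta = best.x
    ll = -float(best.fun)
    proj_grad = np.where(
        ((theta <= np.array([b[0] for b in bounds]) + 1e-9) & (best.jac > 0))
        | ((theta >= np.array([b[1] for b in bounds]) - 1e-9) & (best.jac < 0)),
        0.0,
        best.jac,
    )
    converged = bool(best.success) and float(np.max(np.abs(proj_grad))) < 1e-3
    if not converged:
        logger.warning("fit for terms %s did not converge cleanly", tuple(terms))

    beta = theta[:p]
    phi = float(np.exp(theta[p]))
    sigma = float(np.exp(theta[p + 1]))
    at_lower = theta[p + 1] <= bounds[p + 1][0] + 1e-6
    sigma_report = 0.0 if at_lower else sigma

    se: dict[str, float] = {}
    vcov = None
    if compute_vcov:
        step = 1e-4 * np.maximum(1.0, np.abs(theta))
        H = np.zeros((p + 2, p + 2))
        for i in range(p + 2):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += step[i]
            tm[i] -= step[i]
            _, gp = _marginal(tp, d, n_nodes, True, nodes_cache, mode_cache)
            _, gm = _marginal(tm, d, n_nodes, True, nodes_cache, mode_cache)
            H[i] = -(gp - gm) / (2 * step[i])
        H = 0.5 * (H + H.T)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
        diag = np.diag(vcov).copy()
        diag[diag < 0] = np.nan
        ses = np.sqrt(diag)
        se = {"intercept": float(ses[0])}
        se.update({t: float(ses[i + 1]) for i, t in enumerate(terms)})

    eta = d.X @ beta + d.offset
    a_modes, _ = _conditional_modes(eta, d, phi, max(sigma, 1e-8))
    beta_dict = {"intercept": float(beta[0])}
    beta_dict.update({t: float(beta[i + 1]) for i, t in enumerate(terms)})
    k = p + 2
    return FitResult(
        terms=tuple(terms),
        beta=beta_dict,
        phi=phi,
        sigma_alpha=sigma_report,
        loglik=ll,
        aicc=_aicc(ll, k, n),
        converged=converged,
        alpha_j_modes=pd.Series(a_modes, index=d.unit_ids, name="alpha_j"),
        se=se,
        vcov=vcov,
        n_obs=n,
        k_params=k,
    )


def enumerate_candidates(
    design: DesignMatrix | None = None,
    annual_terms: list[str] | None = None,
    spatial_terms: list[str] | None = None,
) -> list[tuple[str, ...]]:
    """All-subsets candidate term sets over the annual predictors.

    Spatial predictors (which account for regional differences), the
    intercept, offset, and random intercept appear in every candidate;
    only the annual predictors are toggled.  With a annual terms this
    yields 2^a candidates.
    """
    if design is not None:
        annual_terms = design.annual_terms
        spatial_terms = design.spatial_terms
    annual_terms = list(annual_terms or [])
    spatial_terms = list(spatial_terms or [])
    out = []
    for k in range(len(annual_terms) + 1):
        for subset in itertools.combinations(annual_terms, k):
            out.append(tuple(subset) + tuple(spatial_terms))
    return out


def fit_candidates(
    design: DesignMatrix,
    candidates: list[tuple[str, ...]] | None = None,
    n_nodes: int = 15,
    seed: int = 0,
    warm_start: bool = True,
) -> list[FitResult]:
    """Fit every candidate model, warm-starting from the full model."""
    if candidates is None:
        candidates = enumerate_candidates(design)
    full_terms = max(candidates, key=len)
    full = fit_nb2_glmm(design, full_terms, n_nodes=n_nodes, seed=seed)
    fits = []
    for terms in candidates:
        if terms == full_terms:
            fits.append(full)
            continue
        start = None
        if warm_start:
            p = len(terms)
            start = np.zeros(p + 3)
            start[0] = full.beta["intercept"]
            for i, t in enumerate(terms):
                start[i + 1] = full.beta.get(t, 0.0)
            start[p + 1] = np.log(full.phi)
            start[p + 2] = np.log(max(full.sigma_alpha, 1e-3))
        fits.append(
            fit_nb2_glmm(
                design, terms, n_nodes=n_nodes, seed=seed, start=start, n_starts=2
            )
        )
    return fits


def akaike_weights(aiccs: np.ndarray) -> np.ndarray:
    """exp(-delta/2) weights, normalised; invariant to constant shifts."""
    delta = aiccs - np.min(aiccs)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def model_average(
    fits: list[FitResult],
    conditional: bool = False,
) -> AveragedModel:
    """Akaike-weight model averaging with unconditional uncertainty.

    Full averaging substitutes beta = 0 (variance 0) where a term is
    absent; ``conditional=True`` instead averages only over the models
    containing the term.  Unconditional variance per Burnham-Anderson:
    sum_m w_m (var_m + (beta_m - beta_bar)^2).  RVI of a term is the
    summed weight of candidates containing it.
    """
    usable = [f for f in fits if f.converged and np.isfinite(f.aicc)]
    if not usable:
        raise AveragingError("no converged candidate fits to average")
    dropped = len(fits) - len(usable)
    if dropped:
        logger.warning("%d non-converged candidate(s) excluded from averaging", dropped)
    w = akaike_weights(np.array([f.aicc for f in usable]))
    all_terms: list[str] = []
    for f in usable:
        for t in ("intercept",) + f.terms:
            if t not in all_terms:
                all_terms.append(t)
    from scipy.stats import norm

    z50, z95 = norm.ppf(0.75), norm.ppf(0.975)
    rows = []
    for term in all_terms:
        present = np.array([term == "intercept" or term in f.terms for f in usable])
        betas = np.array(
            [f.beta.get(term, 0.0) for f in usable]
        )
        variances = np.array(
            [f.se.get(term, 0.0) ** 2 if f.se.get(term) is not None else 0.0
             for f in usable]
        )
        rvi = float(w[present].sum())
        if conditional and present.any():
            wc = w[present] / w[present].sum()
            bbar = float(np.sum(wc * betas[present]))
            var = float(
                np.sum(wc * (variances[present] + (betas[present] - bbar) ** 2))
            )
        else:
            bbar = float(np.sum(w * betas))
            var = float(np.sum(w * (variances + (betas - bbar) ** 2)))
        se = np.sqrt(var)
        rows.append(
            {
                "term": term,
                "estimate": bbar,
                "se": se,
                "ci50_lo": bbar - z50 * se,
                "ci50_hi": bbar + z50 * se,
                "ci95_lo": bbar - z95 * se,
                "ci95_hi": bbar + z95 * se,
                "rvi": rvi,
            }
        )
    table = pd.DataFrame(rows)
    weights = pd.Series(w, index=[f.terms for f in usable], name="weight")
    return AveragedModel(table=table, weights=weights, fits=usable)


def salmon_effect_percent(
    beta_salmon_scaled: float,
    sd_avg_log_biomass: float,
    fold: float = 0.5,
    beta_ci: tuple[float, float] | None = None,
):
    """Percent change in expected conflict for a ``fold``-fold change in
    geometric-mean salmon biomass, for a population with average salmon
    variability.

    The coefficient is on log biomass scaled by 2 SD, so a multiplicative
    change by ``fold`` moves the predictor by ln(fold) / (2 sd) where sd
    is the mean across units of the within-unit SD of log geometric-mean
    biomass.  Returns 100 (exp(beta ln(fold) / (2 sd)) - 1); with
    ``beta_ci`` the same transform of the coefficient interval is
    returned as a second value (bounds ordered low-high).
    """
    if sd_avg_log_biomass <= 0:
        raise ValueError("sd_avg_log_biomass must be > 0")
    if not 0 < fold:
        raise ValueError("fold must be positive")

    def _pct(b):
        return 100.0 * (np.exp(b * np.log(fold) / (2.0 * sd_avg_log_biomass)) - 1.0)

    point = float(_pct(beta_salmon_scaled))
    if beta_ci is None:
        return point
    lo, hi = sorted(_pct(b) for b in beta_ci)
    return point, (float(lo), float(hi))


def residual_diagnostics(
    fit: FitResult,
    design: DesignMatrix | pd.DataFrame,
    autocorr_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson residuals and per-unit lag-1 temporal autocorrelation.

    Residuals are conditional on the fitted random-intercept modes:
    (y - mu) / sqrt(mu + mu^2/phi).  Units whose residual series have
    |lag-1 autocorrelation| above the threshold are flagged.
    """
    data = design.data if isinstance(design, DesignMatrix) else design
    d = _DesignArrays(data, fit.terms)
    beta = np.array([fit.beta["intercept"]] + [fit.beta[t] for t in fit.terms])
    a = fit.alpha_j_modes.reindex(d.unit_ids).to_numpy() if fit.alpha_j_modes is not None else np.zeros(d.n_units)
    eta = d.X @ beta + d.offset + a[d.unit_idx]
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    pearson = (d.y - mu) / np.sqrt(mu + mu**2 / fit.phi)
    resid = pd.DataFrame(
        {
            "unit_id": np.array(d.unit_ids)[d.unit_idx],
            "year": data.sort_values(["unit_id", "year"])["year"].to_numpy(),
            "y": d.y,
            "mu": mu,
            "pearson": pearson,
        }
    )
    rows = []
    for unit_id, grp in resid.groupby("unit_id"):
        r = grp.sort_values("year")["pearson"].to_numpy()
        if r.size >= 3 and np.std(r[:-1]) > 0 and np.std(r[1:]) > 0:
            ac = float(np.corrcoef(r[:-1], r[1:])[0, 1])
        else:
            ac = np.nan
        rows.append(
            {
                "unit_id": unit_id,
                "lag1_autocorr": ac,
                "flagged": bool(np.isfinite(ac) and abs(ac) > autocorr_threshold),
            }
        )
    return resid, pd.DataFrame(rows)
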