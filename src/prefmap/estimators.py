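"""The four regression families used to map questionnaire scores to utilities.

Direct models regress the SF-6D utility itself: ordinary least squares,
Tobit (right-censored at full health to absorb the ceiling effect), and a
two-part beta-mixture -- a logit model for the probability mass at utility
1 combined with a mixture of beta densities on the rescaled interior
utilities, optionally truncated at the best non-perfect feasible value
(0.965). The indirect route fits an ordered probit per SF-6D dimension
(see :mod:`prefmap.response_mapping`).

Every fit returns a :class:`FittedModel` carrying named coefficients,
family-specific auxiliary parameters, the maximized log-likelihood and the
parameter count used in AIC/BIC.

Parameter counts follow the conventions of the common econometric software
output these tables descend from: OLS counts only the regression
coefficients (error SD excluded), Tobit counts coefficients plus sigma,
ordered probit counts slopes plus cutpoints, and the beta-mixture counts
C*p mean coefficients + C log-precisions + (C-1) mixing logits + p mass
coefficients.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

from .design import DesignMatrix

__all__ = [
    "FittedModel",
    "fit_ols",
    "fit_tobit",
    "fit_ordered_probit",
    "fit_beta_mixture",
    "predict_direct",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

#: Default RNG seed for multi-start optimisation of the mixture models.
DEFAULT_OPTIMIZER_SEED = 20210501

#: Gradient-norm tolerance for the likelihood optimisers.
GRAD_TOL = 1e-8

_NORM = stats.norm


class FitError(RuntimeError):
    """Estimation failure (rank deficiency, non-convergence, degenerate data)."""


@dataclass
class FittedModel:
    """A fitted mapping model: family tag, named coefficients, extras.

    ``extras`` holds family-specific parameters: ``sigma`` (OLS error SD /
    Tobit scale), ``upper`` (Tobit censor bound), ``cutpoints`` and
    ``level_map`` (ordered probit), and the beta-mixture blocks
    (``beta_components``, ``lnphi``, ``mixing_logits``, ``mass_coefficients``,
    ``bounds``).
    """

    family: str
    spec_id: str
    columns: tuple[str, ...]
    coefficients: dict[str, float]
    loglik: float
    n_params: int
    n_obs: int
    extras: dict = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in self.columns])

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        return {
            "family": self.family,
            "spec_id": self.spec_id,
            "columns": list(self.columns),
            "coefficients": _clean(self.coefficients),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "n_obs": int(self.n_obs),
            "extras": _clean(self.extras),
            "se": _clean(self.se),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "FittedModel":
        return cls(
            family=raw["family"],
            spec_id=raw["spec_id"],
            columns=tuple(raw["columns"]),
            coefficients={k: float(v) for k, v in raw["coefficients"].items()},
            loglik=float(raw["loglik"]),
            n_params=int(raw["n_params"]),
            n_obs=int(raw["n_obs"]),
            extras=raw.get("extras", {}),
            se={k: float(v) for k, v in raw.get("se", {}).items()},
            converged=bool(raw.get("converged", True)),
        )


def save_model(model: FittedModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def load_model(path: str | Path) -> FittedModel:
    with open(path) as fh:
        return FittedModel.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# OLS


def fit_ols(X: DesignMatrix, y: Sequence[float], spec_id: str = "") -> FittedModel:
    """Ordinary least squares with Gaussian log-likelihood (MLE variance)."""
    y = np.asarray(y, dtype=float)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.p:
        u, s, vt = np.linalg.svd(X.values)
        null_cols = [
            X.columns[i] for i in np.argsort(np.abs(vt[-1]))[::-1][: X.p - rank + 1]
        ]
        raise FitError(f"design is rank deficient; collinear columns near {null_cols}")
    if X.n <= X.p:
        raise FitError(f"need more rows ({X.n}) than columns ({X.p})")
    res = sm.OLS(y, X.values).fit()
    sigma = float(np.sqrt(np.mean(res.resid**2)))
    return FittedModel(
        family="ols",
        spec_id=spec_id,
        columns=X.columns,
        coefficients=dict(zip(X.columns, map(float, res.params))),
        loglik=float(res.llf),
        n_params=X.p,  # regression coefficients only; sigma not counted
        n_obs=X.n,
        extras={"sigma": sigma},
        se=dict(zip(X.columns, map(float, res.bse))),
    )


# ---------------------------------------------------------------------------
# Tobit (right-censored Gaussian regression)


def _tobit_negll_grad(params, X, y, upper):
    p = X.shape[1]
    beta, log_sigma = params[:p], params[p]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    cens = y >= upper
    z_unc = (y[~cens] - eta[~cens]) / sigma
    z_cen = (upper - eta[cens]) / sigma

    ll = np.sum(_NORM.logpdf(z_unc) - log_sigma) + np.sum(_NORM.logsf(z_cen))

    g_beta = np.zeros(p)
    # uncensored: d/d eta = z/sigma ; d/d log sigma = z^2 - 1
    g_beta += X[~cens].T @ (z_unc / sigma)
    g_ls = np.sum(z_unc**2 - 1.0)
    # censored: d ll/d eta = lambda(z)/sigma with lambda the hazard phi/sf
    if cens.any():
        lam = np.exp(_NORM.logpdf(z_cen) - _NORM.logsf(z_cen))
        g_beta += X[cens].T @ (lam / sigma)
        g_ls += np.sum(lam * z_cen)
    return -ll, -np.concatenate([g_beta, [g_ls]])


def fit_tobit(
    X: DesignMatrix,
    y: Sequence[float],
    upper: float = 1.0,
    spec_id: str = "",
    compute_se: bool = True,
) -> FittedModel:
    """Tobit regression with right-censoring at ``upper`` (default 1).

    Maximizes sum over uncensored rows of the Gaussian log-density plus,
    for rows at the bound, the log upper-tail probability.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y > upper + 1e-12):
        raise FitError(f"observations exceed the censor bound {upper}")
    if np.all(y >= upper):
        raise FitError("all observations are censored; Tobit is unidentified")
    ols = fit_ols(X, y, spec_id=spec_id)
    # standardise columns for the optimiser: raw squared scores span four
    # orders of magnitude and defeat BFGS's implicit uniform scaling
    scale = np.abs(X.values).max(axis=0)
    scale[scale == 0] = 1.0
    Xs = X.values / scale
    start = np.concatenate(
        [ols.beta * scale, [np.log(max(ols.extras["sigma"], 1e-6))]]
    )
    res = optimize.minimize(
        _tobit_negll_grad,
        start,
        args=(Xs, y, upper),
        jac=True,
        method="BFGS",
        options={"gtol": GRAD_TOL, "maxiter": 1000},
    )
    # BFGS may stop on precision loss with the gradient already negligible
    # relative to the sample size; only a genuinely unconverged fit errors.
    if not res.success and np.linalg.norm(res.jac) > 1e-6 * max(X.n, 100):
        raise FitError(
            f"tobit did not converge: {res.message}; "
            f"|grad|={np.linalg.norm(res.jac):.2e}"
        )
    beta, sigma = res.x[: X.p] / scale, float(np.exp(res.x[X.p]))
    se: dict[str, float] = {}
    if compute_se:
        hess = approx_hess1(res.x, lambda q: _tobit_negll_grad(q, Xs, y, upper)[0])
        try:
            cov = np.linalg.inv(hess)
            se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
            se = dict(zip(X.columns, map(float, se_all[: X.p] / scale)))
            se["log_sigma"] = float(se_all[X.p])
        except np.linalg.LinAlgError:  # pragma: no cover - near-singular Hessian
            pass
    return FittedModel(
        family="tobit",
        spec_id=spec_id,
        columns=X.columns,
        coefficients=dict(zip(X.columns, map(float, beta))),
        loglik=float(-res.fun),
        n_params=X.p + 1,  # coefficients + sigma
        n_obs=X.n,
        extras={"sigma": sigma, "upper": upper},
        se=se,
    )


# ---------------------------------------------------------------------------
# Ordered probit


def _oprobit_unpack(params, p, J):
    beta = params[:p]
    c = params[p:]
    cut = np.empty(J - 1)
    cut[0] = c[0]
    if J > 2:
        cut[1:] = c[0] + np.cumsum(np.exp(c[1:]))
    return beta, cut


def _oprobit_negll_grad(params, X, cat, p, J):
    n = X.shape[0]
    beta, cut = _oprobit_unpack(params, p, J)
    eta = X @ beta if p else np.zeros(n)
    ext = np.concatenate([[-np.inf], cut, [np.inf]])
    u = ext[cat + 1] - eta
    l = ext[cat] - eta
    cdf_u = _NORM.cdf(u)
    cdf_l = _NORM.cdf(l)
    prob = np.clip(cdf_u - cdf_l, 1e-300, None)
    ll = np.sum(np.log(prob))

    pdf_u = np.where(np.isfinite(u), _NORM.pdf(u), 0.0)
    pdf_l = np.where(np.isfinite(l), _NORM.pdf(l), 0.0)
    inv = 1.0 / prob
    # d ll / d eta
    g_eta = (-pdf_u + pdf_l) * inv
    g_beta = X.T @ g_eta if p else np.empty(0)
    # d ll / d cut_m
    g_cut = np.zeros(J - 1)
    for m in range(J - 1):
        contrib = np.where(cat == m, pdf_u * inv, 0.0) - np.where(
            cat == m + 1, pdf_l * inv, 0.0
        )
        g_cut[m] = contrib.sum()
    # chain rule to the unconstrained parametrisation
    g_c = np.zeros(J - 1)
    g_c[0] = g_cut.sum()
    if J > 2:
        for r in range(1, J - 1):
            g_c[r] = np.exp(params[p + r]) * g_cut[r:].sum()
    return -ll, -np.concatenate([g_beta, g_c])


def fit_ordered_probit(
    X: DesignMatrix,
    levels: Sequence[int],
    spec_id: str = "",
    dimension: str = "",
    compute_se: bool = True,
) -> FittedModel:
    """Ordered probit MLE: P(Y <= j) = Phi(kappa_j - x beta).

    The design must not contain an intercept (the cutpoints absorb it).
    Empty response categories are collapsed with a warning; the original ->
    fitted category remapping is stored in ``extras['level_map']`` so level
    indices can be realigned with a tariff downstream.
    """
    if X.has_intercept:
        raise FitError("ordered probit takes a design without intercept")
    levels = np.asarray(levels, dtype=int)
    if levels.size != X.n:
        raise FitError("levels length does not match design rows")
    observed = np.unique(levels)
    J_full = int(observed.max())
    expected = np.arange(1, J_full + 1)
    level_map = {int(lv): rank for rank, lv in enumerate(observed)}
    if len(observed) < len(expected):
        missing = sorted(set(expected) - set(observed))
        warnings.warn(
            f"ordered probit {dimension or spec_id}: empty categories {missing} "
            "collapsed",
            stacklevel=2,
        )
    J = len(observed)
    if J < 2:
        raise FitError(
            f"ordered probit {dimension or spec_id}: single observed category"
        )
    cat = np.vectorize(level_map.get)(levels)

    # column scaling as in the tobit fit (cutpoints are scale-free)
    scale = np.abs(X.values).max(axis=0) if X.p else np.empty(0)
    if X.p:
        scale[scale == 0] = 1.0
    Xs = X.values / scale if X.p else X.values

    # start: beta = 0, cutpoints at Phi^-1 of cumulative frequencies
    freqs = np.bincount(cat, minlength=J) / len(cat)
    cum = np.clip(np.cumsum(freqs)[:-1], 1e-6, 1 - 1e-6)
    cut0 = _NORM.ppf(cum)
    c0 = np.empty(J - 1)
    c0[0] = cut0[0]
    if J > 2:
        c0[1:] = np.log(np.clip(np.diff(cut0), 1e-6, None))
    start = np.concatenate([np.zeros(X.p), c0])

    res = optimize.minimize(
        _oprobit_negll_grad,
        start,
        args=(Xs, cat, X.p, J),
        jac=True,
        method="BFGS",
        options={"gtol": GRAD_TOL, "maxiter": 1000},
    )
    converged = res.success or np.linalg.norm(res.jac) < 1e-4
    if not converged:
        grad_norm = np.linalg.norm(res.jac)
        if grad_norm > 1e-2:
            warnings.warn(
                f"ordered probit {dimension or spec_id}: possible separation or "
                f"non-convergence (|grad|={grad_norm:.2e}); returning bounded fit",
                stacklevel=2,
            )
    beta, cut = _oprobit_unpack(res.x, X.p, J)
    if X.p:
        beta = beta / scale
    se: dict[str, float] = {}
    if compute_se and X.p:
        hess = approx_hess1(
            res.x, lambda q: _oprobit_negll_grad(q, Xs, cat, X.p, J)[0]
        )
        try:
            # beta block is a pure rescaling, so its SEs rescale directly
            cov = np.linalg.inv(hess)
            se_scaled = np.sqrt(np.clip(np.diag(cov)[: X.p], 0, None)) / scale
            se = dict(zip(X.columns, map(float, se_scaled)))
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    return FittedModel(
        family="oprobit",
        spec_id=spec_id,
        columns=X.columns,
        coefficients=dict(zip(X.columns, map(float, beta))),
        loglik=float(-res.fun),
        n_params=X.p + (J - 1),
        n_obs=X.n,
        extras={
            "cutpoints": cut.tolist(),
            "n_categories": J,
            "level_map": {str(k): v for k, v in level_map.items()},
            "dimension": dimension,
        },
        se=se,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Beta mixture with probability mass at full health


def _ridge_logit(X: np.ndarray, y01: np.ndarray, ridge: float = 1e-6):
    """Logistic MLE with a tiny L2 penalty for stability under separation."""
    p = X.shape[1]

    def negll_grad(b):
        eta = X @ b
        ll = np.sum(y01 * eta - np.logaddexp(0.0, eta)) - 0.5 * ridge * b @ b
        mu = special.expit(eta)
        g = X.T @ (y01 - mu) - ridge * b
        return -ll, -g

    res = optimize.minimize(
        negll_grad,
        np.zeros(p),
        jac=True,
        method="BFGS",
        options={"gtol": GRAD_TOL, "maxiter": 2000},
    )
    eta = X @ res.x
    # report the unpenalised log-likelihood
    ll = float(np.sum(y01 * eta - np.logaddexp(0.0, eta)))
    mu = special.expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    hess = (X * w[:, None]).T @ X + ridge * np.eye(p)
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    return res.x, ll, se


def _betamix_negll(params, X, z, C):
    """Negative log-likelihood of the interior beta-mixture part.

    params: [beta_1..beta_C (p each), lnphi_1..C, mixing logits (C-1)].
    z are responses already rescaled to (0,1).
    """
    n, p = X.shape
    betas = params[: C * p].reshape(C, p)
    lnphi = params[C * p : C * p + C]
    logits = params[C * p + C :]
    log_pi = np.concatenate([logits, [0.0]])
    log_pi = log_pi - special.logsumexp(log_pi)

    log_dens = np.empty((n, C))
    for c in range(C):
        mu = special.expit(X @ betas[c])
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        phi = np.exp(lnphi[c])
        a, b = mu * phi, (1 - mu) * phi
        log_dens[:, c] = stats.beta.logpdf(z, a, b) + log_pi[c]
    return -float(special.logsumexp(log_dens, axis=1).sum())


def fit_beta_mixture(
    X: DesignMatrix,
    y: Sequence[float],
    components: int = 1,
    mass_at_ub: bool = True,
    truncated: bool = False,
    bounds: tuple[float, float] | None = None,
    spec_id: str = "",
    n_starts: int = 20,
    seed: int = DEFAULT_OPTIMIZER_SEED,
) -> FittedModel:
    """Two-part beta-mixture regression for bounded utilities.

    Part 1 (when ``mass_at_ub``): a logit model for P(y = 1) on the same
    design. Part 2: conditional on y < 1, z = (y - L)/(U_c - L) with
    U_c = 1 (untruncated) or the best non-perfect feasible value 0.965
    (truncated); the density is a C-component mixture of beta densities
    with logit-linked means mu_c(x) and constant component probabilities.
    The reported log-likelihood includes the change-of-variable term
    -n_interior * log(U_c - L) for the rescaling, so direct-model
    likelihoods remain comparable on the utility scale.
    """
    y = np.asarray(y, dtype=float)
    if bounds is None:
        bounds = (0.315, 0.965 if truncated else 1.0)
    L, U_c = bounds
    if truncated and U_c == 1.0:
        U_c = 0.965
    if np.any(y > 1 + 1e-12):
        raise FitError("utilities above 1")
    if L >= y.min():
        raise FitError(f"lower bound {L} must be below min(y) = {y.min():.4f}")

    at_ub = np.isclose(y, 1.0)
    interior = ~at_ub
    rng = np.random.default_rng(seed)
    C, p = components, X.p

    # part 1: probability mass at full health
    mass_coefficients: dict[str, float] = {}
    mass_se: dict[str, float] = {}
    ll_mass = 0.0
    n_mass_params = 0
    if mass_at_ub:
        if at_ub.all():
            warnings.warn("all responses at the upper bound; degenerate mass fit", stacklevel=2)
            return FittedModel(
                family="betamix",
                spec_id=spec_id,
                columns=X.columns,
                coefficients={},
                loglik=0.0,
                n_params=p,
                n_obs=X.n,
                extras={
                    "degenerate": True,
                    "mass_probability": 1.0,
                    "bounds": [L, U_c],
                    "components": C,
                },
                converged=False,
            )
        bmass, ll_mass, se_mass = _ridge_logit(X.values, at_ub.astype(float))
        mass_coefficients = dict(zip(X.columns, map(float, bmass)))
        mass_se = dict(zip(X.columns, map(float, se_mass)))
        n_mass_params = p
    elif at_ub.any():
        raise FitError("responses equal to 1 require mass_at_ub=True")

    Xi = X.values[interior]
    z = (y[interior] - L) / (U_c - L)
    if np.any((z <= 0) | (z >= 1)):
        raise FitError(
            "rescaled responses touch the beta support boundary; adjust bounds "
            f"(L={L}, U_c={U_c})"
        )

    # starting values: OLS of logit(z) on X, jittered per start
    b0 = np.linalg.lstsq(Xi, special.logit(z), rcond=None)[0]
    resid_var = np.var(special.logit(z) - Xi @ b0)
    lnphi0 = np.log(max(1.0 / max(resid_var, 1e-3), 2.0))

    best = None
    for s in range(n_starts):
        betas0 = np.tile(b0, (C, 1))
        if s > 0:
            betas0 = betas0 + rng.normal(scale=0.3, size=betas0.shape)
            if C > 1 and X.has_intercept:
                betas0[:, 0] += np.linspace(-1.0, 1.0, C) * rng.uniform(0.5, 1.5)
        start = np.concatenate(
            [
                betas0.ravel(),
                np.full(C, lnphi0) + (rng.normal(scale=0.3, size=C) if s else 0.0),
                np.zeros(C - 1),
            ]
        )
        try:
            res = optimize.minimize(
                _betamix_negll,
                start,
                args=(Xi, z, C),
                method="L-BFGS-B",
                options={"maxiter": 2000, "ftol": 1e-12, "gtol": GRAD_TOL},
            )
        except (FloatingPointError, ValueError):  # pragma: no cover
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-10):
            best = res
    if best is None:
        raise FitError("beta mixture failed to converge from any start")

    betas = best.x[: C * p].reshape(C, p)
    lnphi = best.x[C * p : C * p + C]
    logits = np.concatenate([best.x[C * p + C :], [0.0]])
    pi = np.exp(logits - special.logsumexp(logits))

    # relabel components by ascending average fitted mean for identifiability
    order = np.argsort([special.expit(Xi @ b).mean() for b in betas])
    betas, lnphi, pi = betas[order], lnphi[order], pi[order]

    ll_interior = -best.fun - interior.sum() * np.log(U_c - L)
    n_params = C * p + C + (C - 1) + n_mass_params

    se: dict[str, float] = {}
    try:
        packed = np.concatenate([betas.ravel(), lnphi, np.log(pi[:-1] / pi[-1]) if C > 1 else np.empty(0)])
        hess = approx_hess1(packed, _betamix_negll, args=(Xi, z, C))
        cov = np.linalg.inv(hess)
        diag = np.sqrt(np.clip(np.diag(cov), 0, None))
        for c in range(C):
            for j, col in enumerate(X.columns):
                se[f"c{c + 1}_{col}"] = float(diag[c * p + j])
            se[f"c{c + 1}_lnphi"] = float(diag[C * p + c])
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    coefficients = {}
    for c in range(C):
        for j, col in enumerate(X.columns):
            coefficients[f"c{c + 1}_{col}"] = float(betas[c, j])
    return FittedModel(
        family="betamix",
        spec_id=spec_id,
        columns=X.columns,
        coefficients=coefficients,
        loglik=float(ll_mass + ll_interior),
        n_params=n_params,
        n_obs=X.n,
        extras={
            "components": C,
            "beta_components": betas.tolist(),
            "lnphi": lnphi.tolist(),
            "mixing_probs": pi.tolist(),
            "mass_coefficients": mass_coefficients,
            "mass_se": mass_se,
            "bounds": [L, U_c],
            "truncated": bool(truncated),
            "mass_at_ub": bool(mass_at_ub),
            "loglik_mass": float(ll_mass),
            "loglik_interior": float(ll_interior),
        },
        se=se,
        converged=True,
    )


# ---------------------------------------------------------------------------
# Prediction


def predict_direct(
    model: FittedModel,
    X: DesignMatrix,
    clip: bool = False,
    floor: float = 0.315,
    censored_expectation: bool = False,
) -> np.ndarray:
    """Predicted utilities from a direct-mapping model.

    OLS and Tobit return the linear index x'beta (for Tobit the latent
    index by default; ``censored_expectation`` switches to
    E[min(y*, U)]). The beta-mixture returns
    P(y=1) + (1 - P(y=1)) * (L + (U_c - L) * sum_c pi_c mu_c(x)).
    ``clip`` optionally clamps into [floor, 1].
    """
    if tuple(X.columns) != tuple(model.columns):
        raise ValueError(
            f"design columns {X.columns} do not match model columns {model.columns}"
        )
    if model.family in ("ols", "tobit"):
        eta = X.values @ model.beta
        if model.family == "tobit" and censored_expectation:
            sigma = model.extras["sigma"]
            upper = model.extras.get("upper", 1.0)
            z = (upper - eta) / sigma
            # E[min(y*, U)] = eta - sigma*phi(z) + (U - eta + sigma*...)  :
            # = Phi(z)*(eta - sigma*phi(z)/Phi(z)) + (1-Phi(z))*U
            eta = _NORM.cdf(z) * eta - sigma * _NORM.pdf(z) + _NORM.sf(z) * upper
        pred = eta
    elif model.family == "betamix":
        L, U_c = model.extras["bounds"]
        betas = np.asarray(model.extras["beta_components"])
        pi = np.asarray(model.extras["mixing_probs"])
        mix_mean = np.zeros(X.n)
        for c, b in enumerate(betas):
            mix_mean += pi[c] * special.expit(X.values @ b)
        interior = L + (U_c - L) * mix_mean
        mass = model.extras.get("mass_coefficients") or {}
        if mass:
            gamma = np.array([mass[c] for c in model.columns])
            p1 = special.expit(X.values @ gamma)
        else:
            p1 = np.zeros(X.n)
        pred = p1 * 1.0 + (1 - p1) * interior
    else:
        raise ValueError(f"predict_direct does not handle family {model.family!r}")
    if clip:
        pred = np.clip(pred, floor, 1.0)
    return pred
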