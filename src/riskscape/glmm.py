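"""Poisson mixed models for group abundance, with AICc multimodel inference.

The response is the integer count of independent detection events per
camera site and diel stratum, modelled as

    count ~ Poisson( exp( log(effort_days/100) + X beta + b_site ) ),
    b_site ~ Normal(0, sigma^2),

so fixed-effect coefficients are on the log scale of groups per 100 survey
days. The marginal likelihood integrates the per-site random intercept out
by a Laplace approximation (with adaptive Gauss-Hermite quadrature as a
verification mode). A candidate set of fourteen models spanning time of
day (T), vegetation density (V), terrain ruggedness (R), lion encounter
risk (E) and kill probability (K) with the allowed two-way interactions is
ranked by AICc; when no single model carries >= 0.95 of the Akaike weight,
coefficients are model-averaged over the 0.95 cumulative-weight confidence
set with Burnham-Anderson unconditional standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "AveragedModel",
    "MAIN_TERMS",
    "candidate_set",
    "build_design",
    "fit_poisson_glmm",
    "aicc",
    "akaike_weights",
    "model_selection_table",
    "model_average",
    "vif_screen",
    "marginal_curve",
]

logger = logging.getLogger("riskscape")

MAIN_TERMS = ("T", "V", "R", "E", "K")
_HABITAT = ("V", "R")
_RISK = ("E", "K")


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect structure: main terms and two-way interactions.

    Interactions are written "A:B"; every interaction's main effects must be
    present (marginality). The random site intercept is implicit in every
    model.
    """

    name: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            if t in seen:
                raise ValueError(f"duplicate term {t!r} in model {self.name}")
            seen.add(t)
            if ":" in t:
                a, b = t.split(":")
                if a not in self.terms or b not in self.terms:
                    raise ValueError(
                        f"interaction {t!r} in model {self.name} lacks a main effect"
                    )

    @property
    def n_fixed(self) -> int:
        return len(self.terms)

    @property
    def k(self) -> int:
        """Parameter count: fixed terms + intercept + random-effect SD."""
        return self.n_fixed + 2


def candidate_set() -> list[ModelSpec]:
    """The default 14-model candidate set.

    Spans the null and time-only models, habitat models (V, R), direct-risk
    models (E, K), habitat x risk combinations, and a global model; every
    covariate enters with its interaction with time of day, and habitat x
    risk interactions appear in the mixed models. The set is a plain list
    and can be replaced wholesale by the caller.
    """
    structures = [
        (),
        ("T",),
        ("T", "V", "T:V"),
        ("T", "R", "T:R"),
        ("T", "V", "R", "T:V", "T:R"),
        ("T", "E", "T:E"),
        ("T", "K", "T:K"),
        ("T", "E", "K", "T:E", "T:K"),
        ("T", "V", "E", "T:V", "T:E", "V:E"),
        ("T", "V", "K", "T:V", "T:K", "V:K"),
        ("T", "R", "E", "T:R", "T:E", "R:E"),
        ("T", "R", "K", "T:R", "T:K", "R:K"),
        ("T", "V", "R", "K", "T:V", "T:R", "T:K"),
        ("T", "V", "R", "E", "K", "T:V", "T:R", "T:E", "T:K"),
    ]
    specs = [
        ModelSpec(name="+".join(t) if t else "null", terms=t) for t in structures
    ]
    assert len({s.terms for s in specs}) == len(specs)
    return specs


def build_design(
    rows: pd.DataFrame, spec: ModelSpec, reference: str = "night"
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) for a model spec.

    ``rows`` must carry a categorical ``diel`` column ("day"/"night") and
    numeric columns V, R, E, K (already rescaled). The time factor T is an
    indicator for the non-reference diel level (reference "night" means T=1
    during the day, matching the tables' footnote convention; configurable).
    """
    other = "day" if reference == "night" else "night"
    cols = {"T": (rows["diel"] == other).to_numpy(float)}
    for m in MAIN_TERMS[1:]:
        if m in rows.columns:
            cols[m] = rows[m].to_numpy(float)

    names = ["(Intercept)"]
    X = [np.ones(len(rows))]
    for t in spec.terms:
        if ":" in t:
            a, b = t.split(":")
            X.append(cols[a] * cols[b])
        else:
            X.append(cols[t])
        names.append(t)
    return np.column_stack(X), names


@dataclass
class FitResult:
    """A fitted Poisson mixed model."""

    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    sigma_site: float
    logLik: float
    k: int
    n_obs: int
    converged: bool
    ranef: pd.Series = field(default_factory=pd.Series)  # site -> b_hat
    aicc: float = np.nan
    weight: float = np.nan
    reference: str = "night"

    @property
    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "se": self.se, "z": self.z, "p": self.p})


@dataclass
class AveragedModel:
    """Model-averaged coefficients over a cumulative-weight confidence set."""

    beta: pd.Series
    se: pd.Series  # unconditional (includes between-model variance)
    model_names: list[str]
    weights: np.ndarray  # renormalised over the confidence set
    averaged: bool  # False when a single model carried >= cum_weight


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _site_blocks(rows: pd.DataFrame) -> tuple[np.ndarray, int]:
    codes, _ = pd.factorize(rows["site_id"], sort=True)
    return codes, codes.max() + 1


def _newton_bhat(Sy, A, sigma2, tol=1e-12, max_iter=60):
    """Per-site posterior modes of the random intercept, vectorised.

    Solves g'(b) = Sy - exp(b) A - b/sigma2 = 0 for each site (concave).
    """
    b = np.zeros_like(A)
    for _ in range(max_iter):
        eb = np.exp(np.clip(b, -40, 40))
        g1 = Sy - eb * A - b / sigma2
        g2 = -eb * A - 1.0 / sigma2
        step = g1 / g2
        b = np.clip(b - step, -40, 40)
        if np.max(np.abs(step)) < tol:
            break
    return b


from functools import lru_cache


@lru_cache(maxsize=8)
def _hermgauss_cached(n_quad: int):
    return np.polynomial.hermite.hermgauss(n_quad)


def _marginal_loglik(theta, y, X, offset, codes, n_sites, lgamma_y, method, n_quad):
    beta = theta[:-1]
    sigma = np.exp(theta[-1])
    sigma2 = sigma * sigma
    eta = offset + X @ beta
    eeta = np.exp(np.clip(eta, -700, 700))
    Sy = np.bincount(codes, weights=y, minlength=n_sites)
    Seta = np.bincount(codes, weights=y * eta, minlength=n_sites)
    A = np.bincount(codes, weights=eeta, minlength=n_sites)

    bhat = _newton_bhat(Sy, A, sigma2)
    if method == "laplace":
        ebA = np.exp(bhat) * A
        ll = (
            Seta
            + Sy * bhat
            - ebA
            - bhat**2 / (2 * sigma2)
            - 0.5 * np.log1p(sigma2 * ebA)
        )
        return float(ll.sum() - lgamma_y)
    if method == "agq":
        nodes, wts = _hermgauss_cached(n_quad)
        tau = 1.0 / np.sqrt(np.exp(bhat) * A + 1.0 / sigma2)
        b = bhat[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
        logf = (
            Sy[:, None] * b
            - np.exp(b) * A[:, None]
            - b**2 / (2 * sigma2)
            - 0.5 * np.log(2 * np.pi * sigma2)
        )
        log_int = special.logsumexp(
            np.log(wts)[None, :] + nodes[None, :] ** 2 + logf, axis=1
        ) + np.log(np.sqrt(2.0) * tau)
        return float((Seta + log_int).sum() - lgamma_y)
    raise ValueError(f"unknown method {method!r}")


def _plain_poisson(y, X, offset):
    import statsmodels.api as sm

    res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    return res


def fit_poisson_glmm(
    rows: pd.DataFrame,
    spec: ModelSpec,
    method: str = "laplace",
    n_quad: int = 9,
    reference: str = "night",
) -> FitResult:
    """Fit a Poisson random-intercept model by maximum marginal likelihood.

    Parameters
    ----------
    rows : observation table with columns site_id, diel, count, effort_days
        and the rescaled covariates V, R, E, K.
    spec : fixed-effect structure; a per-site random intercept is always
        included.
    method : "laplace" (default) or "agq" (adaptive Gauss-Hermite with
        ``n_quad`` nodes, a verification mode).

    Notes
    -----
    The offset is log(effort_days/100), so coefficients read as log group
    abundance per 100 days. When the random-effect SD collapses to the
    boundary (sigma < 1e-3) the fit is profiled down to a plain Poisson
    regression, which is the exact sigma = 0 limit. Standard errors are
    Wald, from the observed information of the marginal likelihood.
    """
    if rows["site_id"].nunique() < 2:
        raise ValueError("at least 2 sites required")
    y = rows["count"].to_numpy()
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    y = y.astype(float)
    offset = np.log(rows["effort_days"].to_numpy(float) / 100.0)
    X, names = build_design(rows, spec, reference)
    codes, n_sites = _site_blocks(rows)
    lgamma_y = float(special.gammaln(y + 1).sum())
    site_labels = pd.factorize(rows["site_id"], sort=True)[1]

    glm = _plain_poisson(y, X, offset)
    beta0 = np.asarray(glm.params, float)

    def negll(theta):
        return -_marginal_loglik(
            theta, y, X, offset, codes, n_sites, lgamma_y, method, n_quad
        )

    theta0 = np.concatenate([beta0, [np.log(0.3)]])
    bounds = [(None, None)] * len(beta0) + [(np.log(1e-6), np.log(50.0))]
    opt = optimize.minimize(
        negll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not opt.success:
        # L-BFGS-B line searches occasionally stall near the optimum;
        # polish with a derivative-free pass before declaring failure
        polish = optimize.minimize(
            negll, opt.x, method="Nelder-Mead",
            options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8},
        )
        if polish.fun <= opt.fun:
            opt = polish
    sigma_hat = float(np.exp(opt.x[-1]))
    converged = bool(opt.success)
    if not converged:
        logger.warning("model %s: optimizer did not converge (%s)", spec.name, opt.message)

    if sigma_hat < 1e-3:
        # boundary: sigma = 0 is a plain Poisson regression
        beta = pd.Series(np.asarray(glm.params), index=names)
        se = pd.Series(np.asarray(glm.bse), index=names)
        ll = float(glm.llf)
        sigma_hat = 0.0
        ranef = pd.Series(np.zeros(n_sites), index=site_labels)
        converged = True
    else:
        theta_hat = opt.x
        ll = -float(opt.fun)
        from statsmodels.tools.numdiff import approx_hess1

        H = approx_hess1(theta_hat, negll)
        try:
            cov = np.linalg.inv(H)
            se_all = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            se_all = np.full(len(theta_hat), np.nan)
            converged = False
        beta = pd.Series(theta_hat[:-1], index=names)
        se = pd.Series(se_all[:-1], index=names)
        eta = offset + X @ theta_hat[:-1]
        eeta = np.exp(np.clip(eta, -700, 700))
        Sy = np.bincount(codes, weights=y, minlength=n_sites)
        A = np.bincount(codes, weights=eeta, minlength=n_sites)
        bhat = _newton_bhat(Sy, A, sigma_hat**2)
        ranef = pd.Series(bhat, index=site_labels)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    return FitResult(
        spec=spec, beta=beta, se=se, z=z, p=p,
        sigma_site=sigma_hat, logLik=ll, k=spec.k, n_obs=len(rows),
        converged=converged, ranef=ranef, reference=reference,
    )


# ---------------------------------------------------------------------------
# information criteria and multimodel inference
# ---------------------------------------------------------------------------

def aicc(logLik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * logLik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    a = np.asarray(aicc_values, float)
    if a.size == 0:
        raise ValueError("at least one model required")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def model_selection_table(fits: list[FitResult]) -> pd.DataFrame:
    """AICc-ranked selection table; fills each fit's aicc and weight in place.

    Non-converged fits are excluded from the weights (and flagged), since
    their likelihoods are unreliable.
    """
    usable = []
    for f in fits:
        if not f.converged:
            logger.warning("model %s excluded from selection (non-convergence)", f.spec.name)
            continue
        if f.n_obs <= f.k + 1:
            logger.warning(
                "model %s excluded from selection (k=%d too large for n=%d)",
                f.spec.name, f.k, f.n_obs,
            )
            continue
        usable.append(f)
    if not usable:
        raise ValueError("no converged fits to rank")
    for f in usable:
        f.aicc = aicc(f.logLik, f.k, f.n_obs)
    w = akaike_weights([f.aicc for f in usable])
    for f, wi in zip(usable, w):
        f.weight = float(wi)
    usable.sort(key=lambda f: f.aicc)
    best = usable[0].aicc
    return pd.DataFrame(
        {
            "model": [f.spec.name for f in usable],
            "k": [f.k for f in usable],
            "logLik": [f.logLik for f in usable],
            "AICc": [f.aicc for f in usable],
            "dAICc": [f.aicc - best for f in usable],
            "weight": [f.weight for f in usable],
        }
    )


def model_average(fits: list[FitResult], cum_weight: float = 0.95) -> AveragedModel:
    """Average coefficients over the cumulative-weight confidence set.

    ``fits`` must be AICc-ranked with weights set (see
    :func:`model_selection_table`). If the single best model already holds
    ``cum_weight`` of the weight it is returned unaveraged. Otherwise the
    smallest top set reaching the cumulative weight is taken; each term is
    averaged conditionally over the models that contain it (natural
    averaging) with weights renormalised within that subset, and the
    unconditional standard error adds the between-model variance
    (Burnham & Anderson): se = sum_i w_i * sqrt(se_i^2 + (b_i - b_bar)^2).
    """
    ranked = sorted([f for f in fits if f.converged], key=lambda f: f.aicc)
    if not ranked:
        raise ValueError("no converged fits")
    if ranked[0].weight >= cum_weight:
        best = ranked[0]
        return AveragedModel(
            beta=best.beta.copy(), se=best.se.copy(),
            model_names=[best.spec.name], weights=np.array([1.0]), averaged=False,
        )
    cum = np.cumsum([f.weight for f in ranked])
    n_keep = int(np.searchsorted(cum, cum_weight) + 1)
    confset = ranked[:n_keep]
    w = np.array([f.weight for f in confset])
    w = w / w.sum()

    terms: list[str] = []
    for f in confset:
        for t in f.beta.index:
            if t not in terms:
                terms.append(t)
    beta_avg, se_avg = {}, {}
    for t in terms:
        idx = [i for i, f in enumerate(confset) if t in f.beta.index]
        wt = w[idx] / w[idx].sum()
        b = np.array([confset[i].beta[t] for i in idx])
        s = np.array([confset[i].se[t] for i in idx])
        bbar = float(np.sum(wt * b))
        beta_avg[t] = bbar
        se_avg[t] = float(np.sum(wt * np.sqrt(s**2 + (b - bbar) ** 2)))
    return AveragedModel(
        beta=pd.Series(beta_avg), se=pd.Series(se_avg),
        model_names=[f.spec.name for f in confset], weights=w, averaged=True,
    )


def vif_screen(rows: pd.DataFrame, predictors: list[str]):
    """Variance inflation factors and Spearman correlations for predictors.

    VIF_j = 1/(1 - R^2_j) from an OLS regression of predictor j on the
    others (plus intercept). Perfectly collinear predictors get VIF = inf
    (reported, not raised). Values above 3 are logged as warnings; the
    caller decides what to drop.
    """
    Z = rows[predictors].to_numpy(float)
    if Z.shape[1] < 2:
        raise ValueError("need at least two predictors")
    vifs = {}
    for j, name in enumerate(predictors):
        yj = Z[:, j]
        Xj = np.column_stack([np.ones(len(Z)), np.delete(Z, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ coef
        sst = np.sum((yj - yj.mean()) ** 2)
        if sst == 0:
            raise ValueError(f"predictor {name} is constant")
        r2 = 1.0 - np.sum(resid**2) / sst
        vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        if vifs[name] > 3:
            logger.warning("predictor %s has VIF %.2f > 3", name, vifs[name])
    rho = pd.DataFrame(
        stats.spearmanr(Z).statistic if len(predictors) > 2
        else [[1.0, stats.spearmanr(Z[:, 0], Z[:, 1]).statistic],
              [stats.spearmanr(Z[:, 0], Z[:, 1]).statistic, 1.0]],
        index=predictors, columns=predictors,
    )
    return pd.Series(vifs, name="VIF"), rho


def marginal_curve(
    fit: FitResult, rows: pd.DataFrame, focal: str, n_points: int = 40
) -> pd.DataFrame:
    """Median marginal probability of group presence along one predictor.

    The focal predictor is fixed at ``n_points`` evenly spaced values over
    its observed range; for each value every observation row keeps its own
    other covariates, offset, and estimated random intercept, the Poisson
    mean mu is recomputed, and presence probability 1 - exp(-mu) is
    summarised by its median and 25/75% quantiles across rows.
    """
    if focal not in fit.spec.terms:
        raise ValueError(f"focal predictor {focal!r} is not in the fitted model")
    if focal == "T":
        raise ValueError("marginal curves are for continuous predictors")
    lo, hi = rows[focal].min(), rows[focal].max()
    grid = np.linspace(lo, hi, n_points)
    offset = np.log(rows["effort_days"].to_numpy(float) / 100.0)
    b = fit.ranef.reindex(rows["site_id"]).to_numpy(float)
    out = []
    for val in grid:
        mod = rows.copy()
        mod[focal] = val
        X, _ = build_design(mod, fit.spec, fit.reference)
        mu = np.exp(offset + X @ fit.beta.to_numpy() + b)
        p = 1.0 - np.exp(-mu)
        out.append(
            {
                "x": val,
                "p_median": float(np.median(p)),
                "p_q25": float(np.quantile(p, 0.25)),
                "p_q75": float(np.quantile(p, 0.75)),
            }
        )
    return pd.DataFrame(out)
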