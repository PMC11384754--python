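"""Repeated-measures comparisons of antibody-antigen affinities.

Equilibrium dissociation constants (K_D) for inferred-germline antibodies
are summarized per allele group and compared with linear mixed models
carrying a participant random intercept, because antibodies from the same
participant are correlated. Affinities are analyzed on the log10 molar
scale by default (K_D spans picomolar to micromolar).

The random-intercept model  y_ij = x_ij' beta + b_i + e_ij  with
b_i ~ N(0, sigma_b^2), e_ij ~ N(0, sigma_e^2) is fitted by REML, profiling
the criterion over the variance ratio lambda = sigma_b^2 / sigma_e^2;
fixed-effect tests use Satterthwaite's degrees-of-freedom approximation.
When the random intercept is unidentifiable or estimated at zero the fit
collapses to ordinary least squares with residual degrees of freedom (so
the between-group test reduces to a two-sample t-test and the paired test
to a paired t-test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LMEFit",
    "summarize_affinities",
    "profile_reml",
    "fit_between_group_lme",
    "fit_paired_variant_lme",
    "parametric_bootstrap_p",
]


def summarize_affinities(records: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of K_D per group.

    Censored records (non-binders at the maximum analyte concentration)
    are treated as right-censored: they are excluded from the quartiles but
    counted, and if the median order statistic falls among them the median
    is reported as a lower bound (``median_censored`` True, value = largest
    uncensored K_D).
    """
    out = []
    for group, sub in records.groupby("group"):
        cens = sub["censored"].astype(bool) if "censored" in sub else pd.Series(False, index=sub.index)
        kd = sub.loc[~cens, "kd_molar"].to_numpy(dtype=float)
        n_cens = int(cens.sum())
        padded = np.concatenate([np.sort(kd), np.full(n_cens, np.inf)])
        med = float(np.median(padded)) if padded.size else np.nan
        censored_median = not np.isfinite(med)
        out.append(
            {
                "group": group,
                "n": int(sub.shape[0]),
                "n_censored": n_cens,
                "median_kd": float(kd.max()) if censored_median and kd.size else med,
                "median_censored": censored_median,
                "q1_kd": float(np.quantile(kd, 0.25)) if kd.size else np.nan,
                "q3_kd": float(np.quantile(kd, 0.75)) if kd.size else np.nan,
            }
        )
    return pd.DataFrame(out)


@dataclass
class LMEFit:
    """REML fit of a random-intercept linear mixed model."""

    params: pd.Series
    cov: pd.DataFrame
    sigma_e2: float
    sigma_b2: float
    reml_loglik: float
    n: int
    n_groups: int
    method: str  # "reml" or "ols"
    converged: bool = True


def _group_matrix(groups: np.ndarray) -> np.ndarray:
    codes, _ = pd.factorize(groups)
    Z = np.zeros((codes.size, codes.max() + 1))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _profiled_criterion(lam: float, y, X, A):
    """Negative profiled REML log-likelihood at variance ratio lam >= 0."""
    n, p = X.shape
    V = np.eye(n) + lam * A
    L = np.linalg.cholesky(V)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    # guard exact-fit data (zero residual variance)
    sigma2 = max(quad / (n - p), 1e-300)
    logdet_V = 2.0 * float(np.log(np.diag(L)).sum())
    sign, logdet_I = np.linalg.slogdet(XtViX)
    nll = 0.5 * ((n - p) * math.log(sigma2) + logdet_V + logdet_I + (n - p))
    return nll, beta, sigma2, XtViX


def _reml_loglik_theta(theta: np.ndarray, y, X, A) -> float:
    """REML log-likelihood in (sigma_e^2, sigma_b^2), up to a constant."""
    se2, sb2 = theta
    if se2 <= 0 or sb2 < 0:
        return -np.inf
    n, p = X.shape
    V = se2 * np.eye(n) + sb2 * A
    sign, logdet_V = np.linalg.slogdet(V)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, Vi_X.T @ y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    _, logdet_I = np.linalg.slogdet(XtViX)
    return -0.5 * (logdet_V + logdet_I + quad)


def profile_reml(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, names=None
) -> LMEFit:
    """Fit the random-intercept model by 1-D profile REML over lambda.

    The criterion is evaluated on a coarse log-spaced lambda grid
    (including the boundary lambda = 0) and refined with bounded scalar
    minimization around the best grid point. When the maximum sits at the
    boundary, or every participant contributes a single observation (the
    variance components are then unidentifiable), the fit collapses to OLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if names is None:
        names = [f"b{i}" for i in range(p)]
    Z = _group_matrix(groups)
    A = Z @ Z.T
    n_groups = Z.shape[1]
    singleton = bool(np.all(Z.sum(axis=0) == 1))

    if not singleton:
        grid = np.concatenate([[0.0], np.logspace(-8, 8, 81)])
        values = [_profiled_criterion(l, y, X, A)[0] for l in grid]
        best = int(np.argmin(values))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, grid.size - 1)]
        if best == 0:
            lam_hat = 0.0
        else:
            res = optimize.minimize_scalar(
                lambda l: _profiled_criterion(l, y, X, A)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            lam_hat = float(res.x)
            if _profiled_criterion(0.0, y, X, A)[0] <= res.fun:
                lam_hat = 0.0
    else:
        lam_hat = 0.0

    if lam_hat <= 1e-10:
        # boundary / unidentifiable: ordinary least squares
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sigma2 = float(r @ r) / max(n - p, 1)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        ll = _reml_loglik_theta(np.array([max(sigma2, 1e-300), 0.0]), y, X, A)
        return LMEFit(
            params=pd.Series(beta, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            sigma_e2=sigma2,
            sigma_b2=0.0,
            reml_loglik=ll,
            n=n,
            n_groups=n_groups,
            method="ols",
        )

    nll, beta, sigma2, XtViX = _profiled_criterion(lam_hat, y, X, A)
    cov = sigma2 * np.linalg.inv(XtViX)
    theta = np.array([sigma2, lam_hat * sigma2])
    return LMEFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        sigma_e2=float(sigma2),
        sigma_b2=float(lam_hat * sigma2),
        reml_loglik=_reml_loglik_theta(theta, y, X, A),
        n=n,
        n_groups=n_groups,
        method="reml",
    )


def _satterthwaite_df(
    fit: LMEFit, c: np.ndarray, y, X, A
) -> float:
    """Satterthwaite df for contrast c via the gradient-of-variance formula.

    With theta = (sigma_e^2, sigma_b^2) and f(theta) =
    c' (X' V(theta)^-1 X)^-1 c, the approximation is
    df = 2 f^2 / (g' Var(theta_hat) g). Both pieces are analytic:
    g_j = c' C X' V^-1 V_j V^-1 X C c (C the fixed-effect covariance
    factor, V_j = dV/dtheta_j) and Var(theta_hat) is the inverse expected
    REML information I_jk = tr(P V_j P V_k)/2 with P the REML projection.
    """
    n = X.shape[0]
    theta = np.array([fit.sigma_e2, fit.sigma_b2])
    V = theta[0] * np.eye(n) + theta[1] * A
    Vi = np.linalg.inv(V)
    ViX = Vi @ X
    C = np.linalg.inv(X.T @ ViX)
    P = Vi - ViX @ C @ ViX.T
    derivs = (np.eye(n), A)
    g = np.zeros(2)
    info = np.zeros((2, 2))
    for j, Vj in enumerate(derivs):
        g[j] = float(c @ C @ (ViX.T @ Vj @ ViX) @ C @ c)
        for k, Vk in enumerate(derivs):
            if k >= j:
                info[j, k] = info[k, j] = 0.5 * float(
                    np.trace(P @ Vj @ P @ Vk)
                )
    try:
        var_theta = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float(fit.n - len(fit.params))
    denom = float(g @ var_theta @ g)
    if denom <= 0 or not np.isfinite(denom):
        return float(fit.n - len(fit.params))
    fval = float(c @ C @ c)
    return 2.0 * fval**2 / denom


def _contrast_test(fit: LMEFit, c: np.ndarray, y, X, A) -> dict:
    est = float(c @ fit.params.to_numpy())
    var = float(c @ fit.cov.to_numpy() @ c)
    se = math.sqrt(max(var, 0.0))
    if fit.method == "ols" or fit.sigma_b2 <= 0:
        df = float(fit.n - len(fit.params))
    else:
        df = _satterthwaite_df(fit, c, y, X, A)
    if se == 0.0:
        return {"estimate": est, "se": 0.0, "df": df,
                "p_value": 1.0 if est == 0 else 0.0, "degenerate": True}
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return {"estimate": est, "se": se, "df": df, "p_value": float(p),
            "t": t, "degenerate": False}


def _prepare(records: pd.DataFrame, log_scale: bool) -> pd.DataFrame:
    sub = records.copy()
    if "censored" in sub.columns:
        sub = sub[~sub["censored"].astype(bool)]
    if (sub["kd_molar"] <= 0).any():
        raise ValueError("uncensored K_D values must be positive")
    sub["y"] = np.log10(sub["kd_molar"]) if log_scale else sub["kd_molar"]
    return sub


def fit_between_group_lme(records: pd.DataFrame, log_scale: bool = True) -> dict:
    """Between-allele affinity difference with a participant random intercept.

    Fixed effects: intercept (reference group) and the second-group offset,
    whose estimate/SE/df/p are returned. Censored records are excluded.
    With a single participant the model is unidentifiable and an ordinary
    linear fit is used (flagged in ``method``).
    """
    sub = _prepare(records, log_scale)
    levels = sorted(sub["group"].unique())
    if len(levels) != 2:
        raise ValueError("between-group comparison needs exactly two groups")
    y = sub["y"].to_numpy()
    X = np.column_stack(
        [np.ones(len(sub)), (sub["group"] == levels[1]).to_numpy(float)]
    )
    groups = sub["participant_id"].to_numpy()
    Z = _group_matrix(groups)
    A = Z @ Z.T
    fit = profile_reml(y, X, groups, names=["intercept", f"{levels[1]}-{levels[0]}"])
    test = _contrast_test(fit, np.array([0.0, 1.0]), y, X, A)
    test.update(
        {
            "groups": tuple(levels),
            "sigma_b2": fit.sigma_b2,
            "sigma_e2": fit.sigma_e2,
            "method": fit.method,
            "n": fit.n,
            "n_participants": fit.n_groups,
        }
    )
    return test


def fit_paired_variant_lme(records: pd.DataFrame, log_scale: bool = True) -> dict:
    """Mean paired (variant - original) affinity difference, LME on pairs.

    Records must contain each antibody twice (two group labels); the
    per-antibody difference of the second group minus the first (sorted
    labels) is modeled with an intercept and a participant random
    intercept. With one antibody per participant this is exactly the
    paired t-test.
    """
    sub = _prepare(records, log_scale)
    levels = sorted(sub["group"].unique())
    if len(levels) != 2:
        raise ValueError("paired comparison needs exactly two groups")
    wide = sub.pivot_table(
        index=["antibody_id", "participant_id"], columns="group", values="y"
    ).dropna()
    if wide.empty:
        raise ValueError("no complete antibody pairs after censoring")
    d = (wide[levels[1]] - wide[levels[0]]).to_numpy()
    groups = wide.index.get_level_values("participant_id").to_numpy()
    X = np.ones((d.size, 1))
    Z = _group_matrix(groups)
    A = Z @ Z.T
    fit = profile_reml(d, X, groups, names=["difference"])
    test = _contrast_test(fit, np.array([1.0]), d, X, A)
    test.update(
        {
            "groups": tuple(levels),
            "sigma_b2": fit.sigma_b2,
            "sigma_e2": fit.sigma_e2,
            "method": fit.method,
            "n_pairs": int(d.size),
            "n_participants": fit.n_groups,
        }
    )
    return test


def parametric_bootstrap_p(
    records: pd.DataFrame,
    design: str = "between",
    n_boot: int = 1000,
    seed: int | None = None,
    log_scale: bool = True,
) -> float:
    """Parametric-bootstrap p for the fixed contrast, as a cross-check.

    Data are re-simulated from the fitted null model (contrast removed,
    variance components kept) and the observed |t| is compared with the
    bootstrap distribution.
    """
    rng = np.random.default_rng(seed)
    fitter = fit_between_group_lme if design == "between" else fit_paired_variant_lme
    obs = fitter(records, log_scale=log_scale)
    sub = _prepare(records, log_scale)
    t_obs = abs(obs.get("t", 0.0))
    sb, se_ = math.sqrt(obs["sigma_b2"]), math.sqrt(obs["sigma_e2"])
    hits = 0
    participants = sub["participant_id"].unique()
    for _ in range(n_boot):
        intercepts = dict(zip(participants, rng.normal(0, sb, participants.size)))
        null_mean = sub["y"].mean()
        sim = sub.copy()
        sim["y"] = (
            null_mean
            + sim["participant_id"].map(intercepts).to_numpy()
            + rng.normal(0, se_, len(sim))
        )
        sim["kd_molar"] = 10.0 ** sim["y"] if log_scale else sim["y"]
        res = fitter(sim, log_scale=log_scale)
        if abs(res.get("t", 0.0)) >= t_obs:
            hits += 1
    return (hits + 1) / (n_boot + 1)
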