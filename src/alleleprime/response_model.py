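"""Competing quasi-Poisson models of VRC01-class B cell counts.

Four identity-link mean structures relate the VRC01-class count V in a
sample to the total number of IgG B cells sampled N, the dose indicator,
and the participant's *02/*04 zygosity counts:

    Null    E(V) = b_Intercept * N
    Dose    E(V) = b_Dose20 * N + b_DoseDelta * 1[high] * N
    Allele  E(V) = b_02 * n02 * N + b_04 * n04 * N
    Full    E(V) = Allele terms + b_DoseDelta * 1[high] * N

Counts are over-dispersed (variance phi * mu) and the coefficients solve
the quasi-likelihood score equations, fitted here by iteratively
reweighted least squares with step-halving. Models are ranked per
timepoint with the small-sample quasi-likelihood information criterion

    QAICc = -2 lnL / c_hat + 2K + 2K(K+1)/(n - K - 1),

where K counts mean parameters plus one for the estimated dispersion and
lnL is the Poisson log-likelihood at the fitted means. Genotype means,
*02:*04 coefficient ratios (delta method) and differences follow from the
fitted coefficient vector and covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MODELS",
    "QPFit",
    "estimate_v",
    "build_design",
    "fit_quasipoisson",
    "fit_model",
    "fit_all_models",
    "qaicc",
    "rank_models",
    "genotype_mean",
    "allele_ratio",
    "allele_difference",
]

MODELS = ("Null", "Dose", "Allele", "Full")

_MU_FLOOR = 1e-8


def estimate_v(freq_epitope: float, freq_vrc01_among_seq: float, N: int) -> int:
    """VRC01-class count estimate: round(freq_epitope * freq_vrc01 * N), half-up."""
    if not 0.0 <= freq_epitope <= 1.0 or not 0.0 <= freq_vrc01_among_seq <= 1.0:
        raise ValueError("frequencies must be in [0,1]")
    return int(math.floor(freq_epitope * freq_vrc01_among_seq * N + 0.5))


def build_design(
    model: str, samples: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    """Identity-link, no-intercept design matrix for one model.

    Placebo participants are excluded. Returns ``(X, V, column names,
    the retained sample rows)``. Column naming follows the coefficient
    table: b_Intercept, b_Dose20, b_DoseDelta, b_02, b_04.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if "dose_group" in samples.columns:
        samples = samples[samples["dose_group"] != "placebo"]
    N = samples["N"].to_numpy(dtype=float)
    high = samples["dose_high"].to_numpy(dtype=float)
    n02 = samples["n02"].to_numpy(dtype=float)
    n04 = samples["n04"].to_numpy(dtype=float)
    if model == "Null":
        X = np.column_stack([N])
        names = ["b_Intercept"]
    elif model == "Dose":
        X = np.column_stack([N, high * N])
        names = ["b_Dose20", "b_DoseDelta"]
    elif model == "Allele":
        X = np.column_stack([n02 * N, n04 * N])
        names = ["b_02", "b_04"]
    else:  # Full
        X = np.column_stack([n02 * N, n04 * N, high * N])
        names = ["b_02", "b_04", "b_DoseDelta"]
    V = samples["V"].to_numpy(dtype=float)
    return X, V, names, samples


@dataclass
class QPFit:
    """A fitted quasi-Poisson mean structure for one timepoint."""

    model: str
    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    loglik: float
    k: int  # parameter count including the dispersion
    n: int  # rows entering the fit (placebo excluded)
    n_active: int  # rows with non-degenerate (positive) fitted mean
    pearson_chi2: float
    deviance: float
    converged: bool
    n_iter: int
    qaicc: float = np.nan
    qaicc_c_hat: float = np.nan

    @property
    def k_mean(self) -> int:
        return self.k - 1

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """t-based coefficient CIs with df = n_active - K_mean (the
        quasi-family convention)."""
        df = max(self.n_active - self.k_mean, 1)
        tq = stats.t.ppf(0.5 + level / 2, df=df)
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        return pd.DataFrame(
            {
                "estimate": self.params,
                "ci_low": self.params - tq * se,
                "ci_high": self.params + tq * se,
            }
        )


def _poisson_loglik(V: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood at fitted means; (V=0, mu=0) rows contribute 0."""
    out = 0.0
    for v, m in zip(V, mu):
        if m <= 0:
            if v > 0:
                return -np.inf
            continue
        out += v * math.log(m) - m - math.lgamma(v + 1.0)
    return out


def _quasi_deviance(V: np.ndarray, mu: np.ndarray) -> float:
    """Poisson (quasi-)deviance 2*sum[V log(V/mu) - (V - mu)] over active rows."""
    dev = 0.0
    for v, m in zip(V, mu):
        if m <= 0:
            continue
        term = -(v - m)
        if v > 0:
            term += v * math.log(v / m)
        dev += 2.0 * term
    return dev


def fit_quasipoisson(
    X: np.ndarray,
    V: np.ndarray,
    names: Sequence[str],
    model: str = "",
    max_iter: int = 200,
    tol: float = 1e-12,
) -> QPFit:
    """Solve the identity-link quasi-Poisson score equations by IRLS.

    The score sum_i x_i (V_i - mu_i)/mu_i = 0 (variance phi*mu) is solved
    with weights 1/mu and step-halving whenever an update would drive a
    fitted mean non-positive on a row with a nonzero design entry; mu is
    floored at 1e-8 inside the weights. Rows whose design entries are all
    zero have structurally zero mean: they must have V = 0 (else the fit
    is infeasible) and contribute nothing to the score, the Pearson
    statistic, or the likelihood.
    """
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    n, p = X.shape
    active = np.abs(X).sum(axis=1) > 0
    bad = (~active) & (V > 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"row {row} has a structurally zero mean but V = {int(V[row])}"
        )
    if not active.any():
        raise ValueError("design has no row with a nonzero entry")
    Xa, Va = X[active], V[active]

    def wls(beta_w: np.ndarray) -> np.ndarray:
        mu = np.maximum(Xa @ beta_w, _MU_FLOOR)
        w = 1.0 / mu
        XtW = Xa.T * w
        return np.linalg.solve(XtW @ Xa, XtW @ Va)

    # feasible start: scaled least squares (all designs are non-negative,
    # so a positive constant ratio keeps mu positive)
    beta = np.full(p, Va.sum() / (Xa.sum() + _MU_FLOOR))
    ls = np.linalg.lstsq(Xa, Va, rcond=None)[0]
    if np.all(Xa @ ls > 0):
        beta = ls

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        proposal = wls(beta)
        step = proposal - beta
        scale = 1.0
        for _ in range(60):
            trial = beta + scale * step
            if np.all(Xa @ trial > 0):
                break
            scale *= 0.5
        else:
            trial = beta  # no feasible step
        delta = np.max(np.abs(trial - beta) / (1.0 + np.abs(beta)))
        beta = trial
        if delta < tol:
            converged = True
            break

    mu = np.maximum(Xa @ beta, _MU_FLOOR)
    pearson = float(np.sum((Va - mu) ** 2 / mu))
    n_active = int(active.sum())
    dof = max(n_active - p, 1)
    c_hat = pearson / dof
    w = 1.0 / mu
    info = (Xa.T * w) @ Xa
    cov = c_hat * np.linalg.inv(info)
    full_mu = np.where(active, np.nan, 0.0)
    full_mu[active] = mu
    loglik = _poisson_loglik(V, full_mu)
    deviance = _quasi_deviance(Va, mu)
    return QPFit(
        model=model,
        params=pd.Series(beta, index=list(names)),
        cov=pd.DataFrame(cov, index=list(names), columns=list(names)),
        dispersion=c_hat,
        loglik=loglik,
        k=p + 1,
        n=n,
        n_active=n_active,
        pearson_chi2=pearson,
        deviance=deviance,
        converged=converged,
        n_iter=it,
    )


def fit_model(model: str, samples: pd.DataFrame) -> QPFit:
    X, V, names, _ = build_design(model, samples)
    return fit_quasipoisson(X, V, names, model=model)


def fit_all_models(samples: pd.DataFrame) -> dict[str, QPFit]:
    return {m: fit_model(m, samples) for m in MODELS}


def qaicc(loglik: float, c_hat: float, k: int, n: int) -> float:
    """QAICc = -2 lnL / c_hat + 2K + 2K(K+1)/(n-K-1); K includes c_hat.

    Undefined (NaN) when the small-sample correction denominator n-K-1
    is not positive.
    """
    if c_hat <= 0:
        raise ValueError("c_hat must be positive")
    if n - k - 1 <= 0:
        return float("nan")
    return -2.0 * loglik / c_hat + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def rank_models(
    fits: Mapping[str, QPFit], c_hat_policy: str = "full"
) -> pd.DataFrame:
    """Rank competing fits by ascending QAICc (ties: fewer parameters first).

    ``c_hat_policy="full"`` (default) estimates the dispersion from the
    most general model (Full) and shares it across all candidates, the
    standard QAIC practice; ``"per-model"`` uses each fit's own Pearson
    dispersion.
    """
    if c_hat_policy not in ("full", "per-model"):
        raise ValueError("c_hat_policy must be 'full' or 'per-model'")
    shared = None
    if c_hat_policy == "full":
        if "Full" not in fits:
            raise ValueError("shared-c_hat ranking requires a Full fit")
        shared = fits["Full"].dispersion
    rows = []
    for name, fit in fits.items():
        c = shared if shared is not None else fit.dispersion
        value = qaicc(fit.loglik, c, fit.k, fit.n)
        fit.qaicc = value
        fit.qaicc_c_hat = c
        rows.append({"model": name, "K": fit.k, "qaicc": value, "c_hat": c})
    table = pd.DataFrame(rows).sort_values(
        ["qaicc", "K"], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def _contrast(fit: QPFit, c: np.ndarray) -> tuple[float, float]:
    est = float(c @ fit.params.to_numpy())
    var = float(c @ fit.cov.to_numpy() @ c)
    return est, math.sqrt(max(var, 0.0))


def genotype_mean(
    fit: QPFit,
    n02: int,
    n04: int,
    dose_high: int = 0,
    level: float = 0.95,
) -> dict:
    """Model-estimated mean response frequency for a genotype.

    estimate = n02 * b_02 + n04 * b_04 (+ dose term under Full); the
    variance is the quadratic form c' Sigma c and the CI is normal-theory.
    """
    c = np.zeros(len(fit.params))
    for name, mult in (("b_02", n02), ("b_04", n04), ("b_DoseDelta", dose_high)):
        if name in fit.params.index:
            c[fit.params.index.get_loc(name)] = mult
        elif mult:
            raise ValueError(f"model {fit.model!r} has no {name} coefficient")
    est, se = _contrast(fit, c)
    z = stats.norm.ppf(0.5 + level / 2)
    return {
        "estimate": est,
        "se": se,
        "ci_low": est - z * se,
        "ci_high": est + z * se,
    }


def allele_ratio(fit: QPFit, level: float = 0.95) -> dict:
    """Delta-method CI for the coefficient ratio b_02 / b_04.

    The gradient is (1/b_04, -b_02/b_04^2); the lower CI bound is truncated
    at zero. A non-positive b_04 leaves the ratio undefined (flagged).
    """
    b02 = float(fit.params["b_02"])
    b04 = float(fit.params["b_04"])
    if b04 <= 0:
        return {"ratio": np.nan, "defined": False}
    sub = fit.cov.loc[["b_02", "b_04"], ["b_02", "b_04"]].to_numpy()
    grad = np.array([1.0 / b04, -b02 / b04**2])
    var = float(grad @ sub @ grad)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    ratio = b02 / b04
    return {
        "ratio": ratio,
        "se": se,
        "ci_low": max(0.0, ratio - z * se),
        "ci_high": ratio + z * se,
        "defined": True,
    }


def allele_difference(fit: QPFit, level: float = 0.95) -> dict:
    """Normal-theory CI and two-sided p for the contrast b_02 - b_04."""
    c = np.zeros(len(fit.params))
    c[fit.params.index.get_loc("b_02")] = 1.0
    c[fit.params.index.get_loc("b_04")] = -1.0
    est, se = _contrast(fit, c)
    z = stats.norm.ppf(0.5 + level / 2)
    p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else (1.0 if est == 0 else 0.0)
    return {
        "difference": est,
        "se": se,
        "ci_low": est - z * se,
        "ci_high": est + z * se,
        "p_value": float(p),
    }
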