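"""Acute-toxicity dose-response modelling.

Mortality of larvae exposed to a chloride dilution series is modelled as
aggregated binomial counts with a logit link.  The module provides:

* an iteratively-reweighted-least-squares (IRLS) maximum-likelihood fit of
  the binomial GLM, used to estimate LC50 (the concentration killing half
  the exposed animals) per population type with a delta-method confidence
  interval;
* a logit-binomial mixed model with independent normal random intercepts for
  pond of origin and for each experimental unit (the observation-level term
  absorbing overdispersion), fitted by Laplace-approximate maximum
  likelihood, used to test the concentration x population-type interaction;
* AIC model comparison and the NaCl -> chloride unit conversion.

Concentration is standardized internally for optimizer stability; every
reported coefficient and covariance is back-transformed to the raw mg/L
scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, gammaln

Z95 = 1.959964  # normal quantile for 95% intervals
CL_MASS_FRACTION = 35.453 / 58.443  # chloride mass fraction of NaCl

MORTALITY_COLUMNS = ("pond_id", "type", "conc_mg_l", "replicate", "n_exposed", "n_dead")
POPULATION_TYPES = ("roadside", "woodland")


class ConvergenceError(RuntimeError):
    """Raised when a model fit fails to converge (e.g. complete separation)."""


# ---------------------------------------------------------------------------
# Data handling
# ---------------------------------------------------------------------------

def load_mortality_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MORTALITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mortality CSV missing columns: {missing}")
    validate_mortality(df)
    return df


def validate_mortality(df: pd.DataFrame) -> None:
    if len(df) == 0:
        raise ValueError("empty mortality table")
    bad_type = set(df["type"]) - set(POPULATION_TYPES)
    if bad_type:
        raise ValueError(f"unknown population type(s): {sorted(bad_type)}")
    conc = pd.to_numeric(df["conc_mg_l"], errors="coerce")
    if conc.isna().any() or not np.all(np.isfinite(conc)) or (conc < 0).any():
        raise ValueError("concentrations must be finite and non-negative")
    n, y = df["n_exposed"].to_numpy(int), df["n_dead"].to_numpy(int)
    if (n <= 0).any():
        raise ValueError("n_exposed must be positive")
    if ((y < 0) | (y > n)).any():
        raise ValueError("n_dead must lie in [0, n_exposed]")
    key = df[["pond_id", "conc_mg_l", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (pond, concentration, replicate) rows")


def _fingerprint(df: pd.DataFrame) -> str:
    h = hashlib.sha1()
    for col in ("conc_mg_l", "n_exposed", "n_dead"):
        h.update(np.ascontiguousarray(df[col].to_numpy(float)).tobytes())
    return h.hexdigest()[:16]


def _design(df: pd.DataFrame, predictors: Sequence[str]) -> tuple[np.ndarray, list[str], float, float]:
    """Design matrix on the standardized concentration scale.

    Returns (X, names, conc_mean, conc_sd); the type indicator is 1 for
    roadside (the salt-exposed class), 0 for woodland.
    """
    allowed = {"conc", "type", "conc:type"}
    bad = set(predictors) - allowed
    if bad:
        raise ValueError(f"unknown predictor terms: {sorted(bad)}")
    conc = df["conc_mg_l"].to_numpy(float)
    m, s = float(conc.mean()), float(conc.std())
    cols, names = [np.ones(len(df))], ["intercept"]
    if "conc" in predictors:
        if s == 0:
            raise ValueError("need at least 2 distinct concentrations")
        cols.append((conc - m) / s)
        names.append("conc")
    if "type" in predictors or "conc:type" in predictors:
        t = (df["type"] == "roadside").to_numpy(float)
        if "type" in predictors:
            cols.append(t)
            names.append("type")
        if "conc:type" in predictors:
            if "conc" not in predictors:
                raise ValueError("conc:type requires conc")
            cols.append(((conc - m) / s) * t)
            names.append("conc:type")
    return np.column_stack(cols), names, m, s


def _raw_scale_transform(names: list[str], m: float, s: float) -> np.ndarray:
    """Jacobian taking standardized-scale coefficients to raw mg/L scale."""
    p = len(names)
    t = np.eye(p)
    idx = {nm: i for i, nm in enumerate(names)}
    if "conc" in idx:
        t[idx["intercept"], idx["conc"]] = -m / s
        t[idx["conc"], idx["conc"]] = 1.0 / s
    if "conc:type" in idx:
        t[idx["type"], idx["conc:type"]] = -m / s
        t[idx["conc:type"], idx["conc:type"]] = 1.0 / s
    return t


def _binom_loglik(y: np.ndarray, n: np.ndarray, eta: np.ndarray) -> float:
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    # y*log p + (n-y)*log(1-p) written stably in terms of eta
    return float(np.sum(const + y * eta - n * np.logaddexp(0.0, eta)))


# ---------------------------------------------------------------------------
# Binomial GLM by IRLS
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    deviance: float
    aic: float
    k_params: int
    n_obs: int
    converged: bool
    n_iter: int
    fingerprint: str
    label: str = ""


def fit_binomial_glm(
    data: pd.DataFrame, predictors: Sequence[str] = ("conc",), label: str = ""
) -> GlmFit:
    """Maximum-likelihood logit fit of aggregated binomial mortality counts.

    IRLS iterations stop when the relative deviance change falls below 1e-10
    (cap 100 iterations).  The coefficient covariance is the inverse Fisher
    information at the optimum.  Complete separation and fully degenerate
    responses (all dead or all alive everywhere) raise
    :class:`ConvergenceError`.
    """
    validate_mortality(data)
    y = data["n_dead"].to_numpy(float)
    n = data["n_exposed"].to_numpy(float)
    if np.unique(data["conc_mg_l"]).size < 2 and "conc" in predictors:
        raise ValueError("need at least 2 distinct concentrations")
    if np.all(y == 0) or np.all(y == n):
        raise ConvergenceError("degenerate response: all units fully alive or fully dead")
    x, names, m, s = _design(data, predictors)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design matrix")

    beta = np.zeros(x.shape[1])
    beta[0] = np.log((y.sum() + 0.5) / (n.sum() - y.sum() + 0.5))
    dev_old = np.inf
    converged = False
    it = 0
    for it in range(1, 101):
        eta = x @ beta
        p = expit(eta)
        w = np.clip(n * p * (1.0 - p), 1e-12, None)
        z = eta + (y - n * p) / w
        xtw = x.T * w
        beta = np.linalg.solve(xtw @ x, xtw @ z)
        if np.max(np.abs(beta)) > 50.0:
            raise ConvergenceError(
                "coefficients diverging (|beta|>50 on the standardized scale); "
                "likely complete separation of the dose-mortality pattern"
            )
        eta = x @ beta
        dev = -2.0 * _binom_loglik(y, n, eta) + 2.0 * _saturated_loglik(y, n)
        if np.isfinite(dev_old) and abs(dev - dev_old) <= 1e-10 * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    if not converged:
        raise ConvergenceError("IRLS did not converge within 100 iterations")

    p = expit(x @ beta)
    w = np.clip(n * p * (1.0 - p), 1e-12, None)
    cov_std = np.linalg.inv((x.T * w) @ x)
    t = _raw_scale_transform(names, m, s)
    beta_raw = t @ beta
    cov_raw = t @ cov_std @ t.T
    loglik = _binom_loglik(y, n, x @ beta)
    k = len(names)
    return GlmFit(
        params=pd.Series(beta_raw, index=names),
        cov=pd.DataFrame(cov_raw, index=names, columns=names),
        loglik=loglik,
        deviance=2.0 * (_saturated_loglik(y, n) - loglik),
        aic=2.0 * k - 2.0 * loglik,
        k_params=k,
        n_obs=len(data),
        converged=converged,
        n_iter=it,
        fingerprint=_fingerprint(data),
        label=label,
    )


def _saturated_loglik(y: np.ndarray, n: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = y / n
        term = np.where(y > 0, y * np.log(p), 0.0) + np.where(n - y > 0, (n - y) * np.log(1 - p), 0.0)
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return float(np.sum(const + term))


# ---------------------------------------------------------------------------
# LC50 with delta-method interval
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lc50Estimate:
    lc50: float
    se: float
    ci_low: float
    ci_high: float
    population_label: str


def estimate_lc50(fit: GlmFit, population_label: str = "") -> Lc50Estimate:
    """LC50 = -beta0/beta1 from an intercept + concentration fit.

    The variance is first-order (delta method):
    ``var = (v00 + 2*LC50*v01 + LC50^2*v11) / beta1^2``; the 95% interval is
    LC50 +/- 1.959964 * SE on the concentration scale.
    """
    if list(fit.params.index) != ["intercept", "conc"]:
        raise ValueError("LC50 requires a single-population intercept+concentration fit")
    if not fit.converged:
        raise ValueError("fit did not converge")
    b0, b1 = float(fit.params["intercept"]), float(fit.params["conc"])
    se1 = float(np.sqrt(fit.cov.loc["conc", "conc"]))
    if abs(b1) < 1e-12 or abs(b1) / se1 < 1e-6:
        raise ValueError("slope indistinguishable from zero; LC50 unidentified")
    lc50 = -b0 / b1
    v = fit.cov.to_numpy()
    var = (v[0, 0] + 2.0 * lc50 * v[0, 1] + lc50**2 * v[1, 1]) / b1**2
    se = float(np.sqrt(var))
    return Lc50Estimate(lc50, se, lc50 - Z95 * se, lc50 + Z95 * se, population_label or fit.label)


# ---------------------------------------------------------------------------
# Laplace-approximate binomial GLMM
# ---------------------------------------------------------------------------

@dataclass
class GlmmFit:
    fixed_effects: pd.DataFrame  # estimate, se, z, p on the raw mg/L scale
    var_pond: float
    var_unit: float
    loglik: float
    aic: float
    k_params: int
    n_obs: int
    converged: bool
    boundary: bool
    interaction_z: float
    interaction_p: float
    n_outer_evals: int
    fingerprint: str


def fit_glmm_laplace(
    data: pd.DataFrame,
    var_components: Optional[tuple[float, float]] = None,
    max_outer: int = 400,
) -> GlmmFit:
    """Logit-binomial mixed model for the full two-population experiment.

    Fixed effects: intercept, concentration, population type and their
    interaction.  Random effects: independent normal intercepts for pond and
    for each experimental unit (the observation-level term that absorbs
    binomial overdispersion).  The marginal likelihood is approximated by the
    Laplace method around the joint random-effect mode (found by penalized
    IRLS with the coefficient vector profiled in); the two standard
    deviations are optimized by bounded Nelder-Mead, or held fixed when
    ``var_components=(sigma_pond, sigma_unit)`` is given.  With both
    components fixed at zero the model reduces exactly to the GLM.
    """
    validate_mortality(data)
    for t in POPULATION_TYPES:
        if data.loc[data["type"] == t, "pond_id"].nunique() < 2:
            raise ValueError(f"population type {t!r} needs at least 2 ponds")
    if data["conc_mg_l"].nunique() < 2:
        raise ValueError("need at least 2 distinct concentrations")

    y = data["n_dead"].to_numpy(float)
    n = data["n_exposed"].to_numpy(float)
    x, names, m, s = _design(data, ("conc", "type", "conc:type"))
    pond_codes, _ = pd.factorize(data["pond_id"], sort=True)
    n_pond = int(pond_codes.max()) + 1
    zp = np.zeros((len(data), n_pond))
    zp[np.arange(len(data)), pond_codes] = 1.0
    p_fix = x.shape[1]

    state = {"gamma": None}

    def pirls(theta: np.ndarray) -> dict:
        """Joint penalized IRLS for (beta, u_pond); unit effects absorbed.

        The observation-level effect is diagonal, so it is eliminated by a
        Schur complement: weights shrink to W/(1 + s_u^2 W) and the unit
        modes are recovered in closed form.
        """
        sp, su = max(theta[0], 0.0), max(theta[1], 0.0)
        mm = np.column_stack([x, sp * zp])
        pen = np.zeros(mm.shape[1])
        pen[p_fix:] = 1.0
        gamma = state["gamma"]
        if gamma is None or gamma.size != mm.shape[1]:
            gamma = np.zeros(mm.shape[1])
            gamma[0] = np.log((y.sum() + 0.5) / (n.sum() - y.sum() + 0.5))
        u_o = np.zeros(len(y))
        crit_old = np.inf
        ok = False
        for _ in range(200):
            eta = mm @ gamma + su * u_o
            p = expit(eta)
            w = np.clip(n * p * (1.0 - p), 1e-12, None)
            z = eta + (y - n * p) / w
            wt = w / (1.0 + su**2 * w)
            a = (mm.T * wt) @ mm + np.diag(pen)
            gamma = np.linalg.solve(a, (mm.T * wt) @ z)
            resid = z - mm @ gamma
            u_o = su * w * resid / (1.0 + su**2 * w)
            eta = mm @ gamma + su * u_o
            u_p = gamma[p_fix:]
            crit = -2.0 * _binom_loglik(y, n, eta) + float(u_p @ u_p) + float(u_o @ u_o)
            if np.isfinite(crit_old) and abs(crit - crit_old) <= 1e-10 * (abs(crit) + 0.1):
                ok = True
                break
            crit_old = crit
        state["gamma"] = gamma
        p = expit(eta)
        w = np.clip(n * p * (1.0 - p), 1e-12, None)
        wt = w / (1.0 + su**2 * w)
        # log det (I + Lambda' Z' W Z Lambda), split by the Schur complement
        logdet = float(np.sum(np.log1p(su**2 * w)))
        small = np.eye(n_pond) + sp**2 * (zp.T * wt) @ zp
        sign, ld2 = np.linalg.slogdet(small)
        logdet += float(ld2)
        u_p = gamma[p_fix:]
        loglik = (
            _binom_loglik(y, n, eta)
            - 0.5 * (float(u_p @ u_p) + float(u_o @ u_o))
            - 0.5 * logdet
        )
        return {
            "loglik": loglik,
            "beta": gamma[:p_fix].copy(),
            "u_p": u_p.copy(),
            "u_o": u_o.copy(),
            "w": w,
            "ok": ok,
            "theta": (sp, su),
        }

    n_evals = 0

    def negll(theta: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return -pirls(theta)["loglik"]

    if var_components is not None:
        theta_hat = np.asarray(var_components, dtype=float)
        if np.any(theta_hat < 0):
            raise ValueError("variance components must be non-negative")
        k_var = 0
        converged_outer = True
    else:
        res = minimize(
            negll,
            x0=np.array([0.3, 0.3]),
            method="Nelder-Mead",
            bounds=[(0.0, 10.0), (0.0, 10.0)],
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": max_outer},
        )
        theta_hat = np.clip(res.x, 0.0, None)
        k_var = 2
        converged_outer = bool(res.success)
        if not converged_outer:
            raise ConvergenceError(
                f"variance-component optimization did not converge: theta={res.x}, "
                f"nfev={res.nfev}"
            )

    final = pirls(theta_hat)
    if not final["ok"]:
        raise ConvergenceError("inner penalized IRLS did not converge at the optimum")
    sp, su = final["theta"]
    boundary = bool((var_components is None) and (sp < 1e-4 or su < 1e-4))

    # fixed-effect covariance: top-left block of the inverse joint penalized
    # information, built on the full (beta, u_pond, u_unit) system
    w = final["w"]
    a_full = np.column_stack([x, sp * zp, su * np.eye(len(y))])
    h = (a_full.T * w) @ a_full
    h[p_fix:, p_fix:] += np.eye(h.shape[0] - p_fix)
    cov_full = np.linalg.inv(h)
    cov_beta_std = cov_full[:p_fix, :p_fix]

    t = _raw_scale_transform(names, m, s)
    beta_raw = t @ final["beta"]
    cov_raw = t @ cov_beta_std @ t.T
    se = np.sqrt(np.diag(cov_raw))
    z = beta_raw / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    fixed = pd.DataFrame(
        {"estimate": beta_raw, "se": se, "z": z, "p": pvals}, index=names
    )
    k = p_fix + k_var
    loglik = float(final["loglik"])
    i_int = names.index("conc:type")
    return GlmmFit(
        fixed_effects=fixed,
        var_pond=float(sp**2),
        var_unit=float(su**2),
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        k_params=k,
        n_obs=len(data),
        converged=bool(converged_outer and final["ok"]),
        boundary=boundary,
        interaction_z=float(z[i_int]),
        interaction_p=float(pvals[i_int]),
        n_outer_evals=n_evals,
        fingerprint=_fingerprint(data),
    )


def laplace_binomial_loglik(
    y: np.ndarray,
    n: np.ndarray,
    eta_fixed: np.ndarray,
    group_idx: np.ndarray,
    sigma: float,
) -> float:
    """Laplace marginal log-likelihood of a single random-intercept model.

    ``eta = eta_fixed + sigma * u[group]`` with ``u ~ N(0, I)``.  Groups are
    independent, so the mode of each ``u_g`` is found by a scalar Newton
    iteration.  This is the one-random-effect kernel the full mixed model
    reduces to; it exists separately so the approximation can be compared
    against numerical quadrature on toy data.
    """
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    eta_fixed = np.asarray(eta_fixed, float)
    group_idx = np.asarray(group_idx, int)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    total = 0.0
    for g in np.unique(group_idx):
        sel = group_idx == g
        yg, ng, og = y[sel], n[sel], eta_fixed[sel]
        u = 0.0
        for _ in range(100):
            p = expit(og + sigma * u)
            grad = sigma * np.sum(yg - ng * p) - u
            hess = -(sigma**2) * np.sum(ng * p * (1 - p)) - 1.0
            step = grad / hess
            u -= step
            if abs(step) < 1e-12:
                break
        p = expit(og + sigma * u)
        curv = sigma**2 * np.sum(ng * p * (1 - p)) + 1.0
        total += _binom_loglik(yg, ng, og + sigma * u) - 0.5 * u * u - 0.5 * np.log(curv)
    return float(total)


# ---------------------------------------------------------------------------
# AIC comparison and unit conversion
# ---------------------------------------------------------------------------

def compare_aic(fits: Sequence, labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Rank fits of the same data by AIC (ascending, with delta-AIC)."""
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    prints = {f.fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were made on different data (fingerprint mismatch)")
    if labels is None:
        labels = [getattr(f, "label", "") or f"model{i}" for i, f in enumerate(fits)]
    rows = [
        {"model": lab, "k": f.k_params, "loglik": f.loglik, "aic": f.aic}
        for lab, f in zip(labels, fits)
    ]
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out


def nacl_to_chloride(nacl_g_per_l, round_to: Optional[float] = None):
    """Convert NaCl in g/L to chloride in mg/L via the Cl mass fraction.

    ``Cl mg/L = g/L * 1000 * (35.453 / 58.443)``; ``round_to`` rounds to the
    stated granularity (e.g. 100 mg/L, as in reporting nominal treatment
    levels).
    """
    arr = np.asarray(nacl_g_per_l, dtype=float)
    if np.any(arr < 0):
        raise ValueError("NaCl concentration must be non-negative")
    cl = arr * 1000.0 * CL_MASS_FRACTION
    if round_to is not None:
        if round_to <= 0:
            raise ValueError("round_to must be positive")
        cl = np.round(cl / round_to) * round_to
    if np.isscalar(nacl_g_per_l) or arr.ndim == 0:
        return float(cl)
    return cl
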