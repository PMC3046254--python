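"""Binomial mixed-effects model for nested proliferation counts.

Fits, by maximum likelihood with a Laplace approximation, the logistic-link
binomial model

    logit P(proliferating) = beta0 + beta_t * treatment (+ region offsets)
                             + b_individual + b_section(individual)

with independent Gaussian random intercepts for individual and for section
nested within individual.  The integral over the random effects is
approximated per individual: an inner Newton iteration finds the joint mode
of the random-effect vector (standardised parameterisation, so the iteration
stays well conditioned as a variance component approaches zero), and the
Gaussian curvature correction uses the log-determinant of the scaled negative
Hessian.  The outer optimisation over fixed effects and log standard
deviations uses L-BFGS-B started from the no-random-effect logistic fit.

The treatment effect is reported on the log-odds scale and converted to a
difference in proliferating cells per 1000 at the control-arm fitted
baseline.  Two p-values are returned: a t reference with
df = n_individuals - 2 (the default — it reproduces the df convention of
small nested designs, e.g. df = 4 for 3 + 3 specimens) and a Wald normal
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .counts import REGIONS, validate_counts


class GLMMError(ValueError):
    pass


@dataclass
class GLMMResult:
    beta: dict[str, float]
    effect_logodds: float
    se_logodds: float
    effect_per_1000: float
    se_per_1000: float
    baseline_proportion: float
    sd_individual: float
    sd_section: float
    df: int
    p_value: float                 # t reference, df = n_individuals - 2
    p_value_wald: float            # normal reference
    loglik: float
    converged: bool
    separation: bool
    n_individuals: int

    def summary(self) -> str:
        return (
            f"treatment effect {self.effect_logodds:+.4f} log-odds "
            f"(se {self.se_logodds:.4f}); {self.effect_per_1000:+.2f}/1000 cells "
            f"(se {self.se_per_1000:.2f}) at baseline {1000 * self.baseline_proportion:.1f}/1000; "
            f"sd(individual) {self.sd_individual:.3f}, sd(section) {self.sd_section:.3f}; "
            f"p = {self.p_value:.4f} (t, df={self.df}), p = {self.p_value_wald:.4f} (Wald)"
        )


def _design(df: pd.DataFrame, region_effects: bool) -> tuple[np.ndarray, list[str]]:
    names = ["intercept", "treatment"]
    cols = [np.ones(len(df)), (df["treatment"] == "immobilised").to_numpy(float)]
    if region_effects:
        for r in REGIONS[1:]:
            names.append(f"region{r}")
            cols.append((df["region"] == r).to_numpy(float))
    return np.column_stack(cols), names


def _group_structure(df: pd.DataFrame):
    groups = []
    for ind, sub in df.groupby("individual_id", sort=True):
        sec_codes, sec_idx = np.unique(sub["section_id"], return_inverse=True)
        groups.append((sub.index.to_numpy(), sec_idx, len(sec_codes)))
    return groups


def _laplace_loglik(theta, X, y, n, groups, n_beta):
    beta = theta[:n_beta]
    sd_u, sd_v = np.exp(theta[n_beta]), np.exp(theta[n_beta + 1])
    eta_fix = X @ beta
    total = 0.0
    for obs_idx, sec_idx, n_sec in groups:
        yi, ni, eta0 = y[obs_idx], n[obs_idx], eta_fix[obs_idx]
        d = 1 + n_sec
        scale = np.concatenate([[sd_u], np.full(n_sec, sd_v)])
        a = np.zeros(d)
        # Z maps (u, v_1..v_S) to observations: column 0 is 1, then section dummies
        for _ in range(100):
            zb = scale[0] * a[0] + scale[1:][sec_idx] * a[1:][sec_idx]
            p = expit(eta0 + zb)
            resid = yi - ni * p
            w = ni * p * (1 - p)
            grad = np.empty(d)
            grad[0] = scale[0] * resid.sum()
            grad[1:] = scale[1:] * np.bincount(sec_idx, weights=resid, minlength=n_sec)
            grad -= a
            Hs = np.zeros((d, d))
            w_sec = np.bincount(sec_idx, weights=w, minlength=n_sec)
            Hs[0, 0] = scale[0] ** 2 * w.sum()
            Hs[0, 1:] = Hs[1:, 0] = scale[0] * scale[1:] * w_sec
            Hs[1:, 1:][np.diag_indices(n_sec)] = scale[1:] ** 2 * w_sec
            H = Hs + np.eye(d)
            step = np.linalg.solve(H, grad)
            a = a + step
            if np.abs(step).max() < 1e-10:
                break
        zb = scale[0] * a[0] + scale[1:][sec_idx] * a[1:][sec_idx]
        eta = eta0 + zb
        ll = float(np.sum(yi * eta - ni * np.logaddexp(0.0, eta)))
        p = expit(eta)
        w = ni * p * (1 - p)
        w_sec = np.bincount(sec_idx, weights=w, minlength=n_sec)
        Hs = np.zeros((d, d))
        Hs[0, 0] = scale[0] ** 2 * w.sum()
        Hs[0, 1:] = Hs[1:, 0] = scale[0] * scale[1:] * w_sec
        Hs[1:, 1:][np.diag_indices(n_sec)] = scale[1:] ** 2 * w_sec
        sign, logdet = np.linalg.slogdet(Hs + np.eye(d))
        total += ll - 0.5 * float(a @ a) - 0.5 * logdet
    return total


def fit_binomial_glmm(table: pd.DataFrame, region_effects: bool = False,
                      region: int | None = None) -> GLMMResult:
    """Fit the nested binomial GLMM to a proliferation count table.

    ``region`` restricts the fit to a single counting region (the
    "each location separately" analysis); ``region_effects`` adds additive
    region offsets to the combined fit.  Requires at least two individuals
    per arm, else the individual-level variance is inestimable.
    """
    validate_counts(table)
    df = table if region is None else table[table["region"] == region]
    if region is not None and df.empty:
        raise GLMMError(f"no rows for region {region}")
    df = df.reset_index(drop=True)
    arms = df.groupby("treatment")["individual_id"].nunique()
    if len(arms) < 2 or (arms < 2).any():
        raise GLMMError("need >= 2 individuals in each treatment arm")

    X, names = _design(df, region_effects and region is None)
    y = df["n_pos"].to_numpy(float)
    n = df["n_total"].to_numpy(float)
    groups = _group_structure(df)
    n_beta = X.shape[1]

    # starting values: plain logistic fit (no random effects)
    import statsmodels.api as sm
    glm = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial())
    beta0 = glm.fit().params
    theta0 = np.concatenate([beta0, [np.log(0.2), np.log(0.2)]])

    def nll(theta):
        return -_laplace_loglik(theta, X, y, n, groups, n_beta)

    bounds = [(None, None)] * n_beta + [(-6.0, 2.0), (-6.0, 2.0)]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    theta = res.x
    beta = theta[:n_beta]
    sd_u, sd_v = float(np.exp(theta[n_beta])), float(np.exp(theta[n_beta + 1]))

    cov = _beta_covariance(nll, theta, n_beta)
    se_t = float(np.sqrt(max(cov[1, 1], 0.0)))

    n_ind = int(df["individual_id"].nunique())
    dof = max(n_ind - 2, 1)
    eff = float(beta[1])
    tstat = eff / se_t if se_t > 0 else np.inf
    p_t = float(2 * stats.t.sf(abs(tstat), dof))
    p_w = float(2 * stats.norm.sf(abs(tstat)))

    ctrl = (df["treatment"] == "control").to_numpy()
    xbar = X[ctrl].mean(axis=0)
    eta0 = float(xbar @ beta)
    p0 = float(expit(eta0))
    p1 = float(expit(eta0 + eff))
    per1000 = 1000.0 * (p1 - p0)
    se_per1000 = 1000.0 * p1 * (1 - p1) * se_t

    separation = bool(abs(eff) > 10 or se_t > 10)
    return GLMMResult(
        beta=dict(zip(names, map(float, beta))),
        effect_logodds=eff, se_logodds=se_t,
        effect_per_1000=per1000, se_per_1000=se_per1000,
        baseline_proportion=p0,
        sd_individual=sd_u, sd_section=sd_v,
        df=dof, p_value=p_t, p_value_wald=p_w,
        loglik=float(-res.fun), converged=bool(res.success),
        separation=separation, n_individuals=n_ind,
    )


def _beta_covariance(nll, theta, n_beta) -> np.ndarray:
    """Observed-information covariance of the fixed effects.

    Central-difference Hessian over all parameters; if the full information
    is not invertible (variance component on its bound), falls back to the
    fixed-effect block alone.
    """
    d = theta.size
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    H = np.zeros((d, d))
    f0 = nll(theta)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                val = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / h[i] ** 2
            else:
                val = (nll(theta + ei + ej) - nll(theta + ei - ej)
                       - nll(theta - ei + ej) + nll(theta - ei - ej)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.isfinite(cov)) or cov[1, 1] <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.full((d, d), np.nan)
        cov[:n_beta, :n_beta] = np.linalg.inv(H[:n_beta, :n_beta])
    return cov
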