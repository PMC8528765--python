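"""Maximum-likelihood logistic regression with nested random intercepts.

The group comparisons need a three-level logistic model — sessions (level 1)
nested in patients (level 2) nested in therapists (level 3) — with proper
marginal maximum likelihood so that AIC/BIC model comparison is meaningful.
The pre-installed Python stack offers no frequentist GLMM of this form, so
this module implements one directly: the patient and therapist random
intercepts are integrated out with Gauss–Hermite quadrature and the marginal
likelihood is maximized by L-BFGS-B with analytic gradients (posterior-
weighted complete-data scores).

For a therapist ``j`` with patients ``i`` and sessions ``s``::

    logit P(y_ijs = 1) = x_ijs' beta + sigma_t * u_j + sigma_p * b_ij,
    u_j, b_ij ~ N(0, 1) independent.

The quadrature is exact in the limit of many nodes; 15 nodes per level is
the default (225 grid points per session for the full three-level model).
Wald standard errors for the fixed effects come from the beta-block Hessian
at the estimated variance parameters, the convention mixed-model software
reports.  The level-2 intraclass correlation uses the standard logistic
level-1 variance pi^2 / 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
import statsmodels.api as sm

__all__ = ["NestedLogisticResult", "fit_nested_logistic_arrays"]

_LOGISTIC_L1_VAR = np.pi ** 2 / 3.0


@dataclass
class NestedLogisticResult:
    """Fit summary of the nested random-intercept logistic model."""

    param_names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    var_patient: float
    var_therapist: float
    llf: float
    aic: float
    bic: float
    icc_patient: float
    n_obs: int
    n_patients: int
    n_therapists: int
    converged: bool
    separation: bool

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "z": self.zvalues,
             "p": self.pvalues},
            index=list(self.param_names),
        )


def _prepare(y, X, patient_ids, therapist_ids):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    pat = np.asarray(patient_ids)
    ther = (np.zeros(len(y), dtype=int) if therapist_ids is None
            else np.asarray(therapist_ids))
    # order rows so patients are contiguous within contiguous therapists
    _, ther_codes = np.unique(ther, return_inverse=True)
    _, pat_codes = np.unique(pat, return_inverse=True)
    order = np.lexsort((pat_codes, ther_codes))
    y, X = y[order], X[order]
    pat_codes, ther_codes = pat_codes[order], ther_codes[order]
    # per-row patient index in order of appearance
    change = np.empty(len(y), dtype=bool)
    change[0] = True
    change[1:] = pat_codes[1:] != pat_codes[:-1]
    row_starts = np.flatnonzero(change)           # first row of each patient
    pat_idx = np.cumsum(change) - 1               # 0..m-1 per row
    ther_of_pat = ther_codes[row_starts]          # therapist code per patient
    change_t = np.empty(len(row_starts), dtype=bool)
    change_t[0] = True
    change_t[1:] = ther_of_pat[1:] != ther_of_pat[:-1]
    pat_starts_of_ther = np.flatnonzero(change_t)  # first patient of therapist
    return y, X, pat_idx, row_starts, pat_starts_of_ther, len(row_starts), \
        int(change_t.sum())


def _gh_nodes(n_quad: int):
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    return np.sqrt(2.0) * x, np.log(w) - 0.5 * np.log(np.pi)


def _loglik_and_grad(theta, y, X, pat_idx, row_starts, ther_starts,
                     z_t, logw_t, z_p, logw_p):
    """Marginal log-likelihood and its gradient wrt (beta, sigma_p, sigma_t)."""
    p = X.shape[1]
    beta, s_p, s_t = theta[:p], theta[p], theta[p + 1]
    Qt, Qp = z_t.size, z_p.size
    eta = (X @ beta)[:, None, None] + s_t * z_t[None, :, None] \
        + s_p * z_p[None, None, :]
    yv = y[:, None, None]
    ll_rows = yv * eta - np.logaddexp(0.0, eta)            # (n, Qt, Qp)
    l_pat = np.add.reduceat(ll_rows, row_starts, axis=0)   # (m, Qt, Qp)
    logA = special.logsumexp(l_pat + logw_p[None, None, :], axis=2)  # (m, Qt)
    S = np.add.reduceat(logA, ther_starts, axis=0)         # (J, Qt)
    l_ther = special.logsumexp(S + logw_t[None, :], axis=1)  # (J,)
    llf = float(l_ther.sum())

    # posterior weights for the gradient
    ther_of_pat = np.cumsum(
        np.isin(np.arange(l_pat.shape[0]), ther_starts)) - 1
    P = np.exp(S + logw_t[None, :] - l_ther[:, None])      # (J, Qt)
    C = np.exp(l_pat + logw_p[None, None, :] - logA[:, :, None])  # (m, Qt, Qp)
    W = P[ther_of_pat][:, :, None] * C                     # (m, Qt, Qp)
    G = W[pat_idx] * (yv - special.expit(eta))             # (n, Qt, Qp)
    g_rows = G.sum(axis=(1, 2))
    grad = np.empty(p + 2)
    grad[:p] = X.T @ g_rows
    grad[p] = float(np.einsum("nqr,r->", G, z_p))
    grad[p + 1] = float(np.einsum("nqr,q->", G, z_t))
    return llf, grad


def fit_nested_logistic_arrays(y, X, patient_ids, therapist_ids=None,
                               param_names=None, n_quad: int = 15,
                               include_therapist: bool = True
                               ) -> NestedLogisticResult:
    """Fit the nested random-intercept logistic model by marginal ML.

    Parameters
    ----------
    y, X
        Binary outcome and fixed-effect design matrix (include the intercept
        column yourself).
    patient_ids, therapist_ids
        Grouping labels; ``therapist_ids=None`` (or
        ``include_therapist=False``) drops the third level.
    n_quad
        Gauss–Hermite nodes per random-effect level.

    Raises
    ------
    ValueError
        If the outcome has a single class (no information about the odds).
    """
    y_arr = np.asarray(y, dtype=float)
    if y_arr.min() == y_arr.max():
        raise ValueError("outcome has a single class; model not identified")
    if therapist_ids is None:
        include_therapist = False
    prep = _prepare(y, X, patient_ids,
                    therapist_ids if include_therapist else None)
    y_s, X_s, pat_idx, row_starts, ther_starts, m, J = prep
    p = X_s.shape[1]
    if param_names is None:
        param_names = tuple(f"x{i}" for i in range(p))

    z_p, logw_p = _gh_nodes(n_quad)
    if include_therapist:
        z_t, logw_t = _gh_nodes(n_quad)
    else:
        z_t, logw_t = np.zeros(1), np.zeros(1)

    # starting values from a single-level logistic fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            beta0 = sm.GLM(y_s, X_s, family=sm.families.Binomial()).fit().params
        except Exception:
            beta0 = np.zeros(p)
    theta0 = np.concatenate([beta0, [1.0, 0.5 if include_therapist else 0.0]])

    def nll(theta):
        llf, grad = _loglik_and_grad(theta, y_s, X_s, pat_idx, row_starts,
                                     ther_starts, z_t, logw_t, z_p, logw_p)
        return -llf, -grad

    bounds = [(None, None)] * p + [(0.0, 25.0),
                                   (0.0, 25.0) if include_therapist
                                   else (0.0, 0.0)]
    res = optimize.minimize(nll, theta0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": 300, "ftol": 1e-10})
    theta = res.x
    llf = -float(res.fun)
    beta, s_p, s_t = theta[:p], theta[p], theta[p + 1]

    # Wald SEs: beta-block Hessian at the estimated variance parameters,
    # by central differences of the analytic gradient.
    H = np.zeros((p, p))
    h = 1e-5 * np.maximum(1.0, np.abs(beta))
    for i in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        _, gp = _loglik_and_grad(tp, y_s, X_s, pat_idx, row_starts,
                                 ther_starts, z_t, logw_t, z_p, logw_p)
        _, gm = _loglik_and_grad(tm, y_s, X_s, pat_idx, row_starts,
                                 ther_starts, z_t, logw_t, z_p, logw_p)
        H[i] = (gp[:p] - gm[:p]) / (2.0 * h[i])
    H = -(H + H.T) / 2.0
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / bse
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))

    separation = bool(np.any(np.abs(beta) > 15.0) or np.any(bse > 1e3))
    k = p + (2 if include_therapist else 1)
    n = y_s.size
    var_p, var_t = float(s_p ** 2), float(s_t ** 2)
    icc = var_p / (var_p + var_t + _LOGISTIC_L1_VAR)
    return NestedLogisticResult(
        param_names=tuple(param_names),
        params=beta.copy(),
        bse=bse,
        zvalues=zvals,
        pvalues=pvals,
        var_patient=var_p,
        var_therapist=var_t,
        llf=llf,
        aic=-2.0 * llf + 2.0 * k,
        bic=-2.0 * llf + k * np.log(n),
        icc_patient=float(icc),
        n_obs=int(n),
        n_patients=m,
        n_therapists=J,
        converged=bool(res.success),
        separation=separation,
    )
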