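"""Conditional logistic regression on 1:1 matched pairs, and rank AUC.

For 1:1 matching the conditional likelihood reduces to a logistic model on
within-pair covariate differences with all outcomes 1 and no intercept:
with ``d_i = x_case,i - x_ref,i`` the log-likelihood is
``sum_i log sigma(d_i' beta)``.  A covariate constant within every pair
differences out to a zero column and is inert; for a single binary
exposure the conditional MLE is the discordant-pair ratio ``b/c``.

Maximisation is by Newton iterations (gradient infinity-norm < 1e-8,
at most 100 steps).  Complete separation (all informative differences in
one direction) is flagged and the estimate falls back to the
Haldane-Anscombe +0.5 discordant correction in the single-exposure case.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

__all__ = [
    "fit_conditional_logistic",
    "per_exposure_associations",
    "auc_of_model",
]

_TOL = 1e-8
_MAX_ITER = 100


def _newton_difference_logit(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximise sum log sigma(d beta); return (beta, se, converged)."""
    n, p = d.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(_MAX_ITER):
        eta = d @ beta
        s = expit(eta)
        grad = d.T @ (1.0 - s)
        if np.max(np.abs(grad)) < _TOL:
            converged = True
            break
        w = s * (1.0 - s)
        hess = (d * w[:, None]).T @ d
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps to keep divergence detectable rather than fatal
        norm_step = np.max(np.abs(step))
        if norm_step > 5.0:
            step *= 5.0 / norm_step
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0:  # numerically separated
            break
    if converged and np.max(np.abs(beta)) > 15.0:
        # gradient underflow at a diverging estimate, not a finite MLE
        converged = False
    eta = d @ beta
    w = expit(eta) * (1.0 - expit(eta))
    hess = (d * w[:, None]).T @ d
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, converged


def fit_conditional_logistic(
    x_case: pd.DataFrame, x_ref: pd.DataFrame, ci_level: float = 0.95
) -> pd.DataFrame:
    """Joint conditional-logistic fit of all columns on matched pairs.

    ``x_case`` and ``x_ref`` are pair-indexed design matrices (factor
    scores and any covariates); rows are aligned by pair id.  Returns one
    row per column with the coefficient, Wald standard error and CI, the
    odds ratio, carrier counts and status flags (``inert`` for zero-
    difference columns, ``separated`` when the likelihood is unbounded).
    """
    if list(x_case.columns) != list(x_ref.columns):
        raise ValueError("case and reference design matrices differ in columns")
    if set(x_case.index) != set(x_ref.index):
        raise ValueError("case and reference design matrices cover different pairs")
    x_ref = x_ref.reindex(x_case.index)
    d = x_case.to_numpy(dtype=float) - x_ref.to_numpy(dtype=float)
    cols = list(x_case.columns)
    active = np.ptp(d, axis=0) > 0
    zcrit = norm.ppf(0.5 + ci_level / 2)

    beta = np.zeros(len(cols))
    se = np.full(len(cols), np.nan)
    separated = False
    if active.any():
        da = d[:, active]
        b_a, se_a, converged = _newton_difference_logit(da)
        separated = not converged
        if separated and da.shape[1] == 1:
            # single-exposure fallback: +0.5 on both discordant cells
            b = float((da[:, 0] > 0).sum()) + 0.5
            c = float((da[:, 0] < 0).sum()) + 0.5
            b_a = np.array([np.log(b / c)])
            se_a = np.array([np.sqrt(1.0 / b + 1.0 / c)])
        beta[active] = b_a
        se[active] = se_a

    out = pd.DataFrame(index=pd.Index(cols, name="term"))
    out["coefficient"] = beta
    out["se"] = se
    with np.errstate(over="ignore"):
        out["odds_ratio"] = np.exp(beta)
        out["ci_low"] = np.exp(beta - zcrit * se)
        out["ci_high"] = np.exp(beta + zcrit * se)
    out["n_case_pos"] = (x_case.to_numpy() > 0).sum(axis=0)
    out["n_ref_pos"] = (x_ref.to_numpy() > 0).sum(axis=0)
    out["inert"] = ~active
    out["separated"] = separated & active
    out.loc[out["inert"], ["coefficient", "odds_ratio", "ci_low", "ci_high"]] = np.nan
    return out


def per_exposure_associations(
    scores_case: pd.DataFrame,
    scores_ref: pd.DataFrame,
    covariates_case: pd.DataFrame | None = None,
    covariates_ref: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One adjusted conditional-logistic model per factor.

    Each factor score is fitted together with the covariate block
    (sex/age/rurality/income in the paper's design; exactly matched
    covariates difference out and are reported inert), mirroring a
    factor-table layout of ORs with 95% CIs and cohort frequencies.
    """
    rows = []
    for factor in scores_case.columns:
        xc = scores_case[[factor]]
        xr = scores_ref[[factor]]
        if covariates_case is not None:
            xc = pd.concat([xc, covariates_case.reindex(xc.index)], axis=1)
            xr = pd.concat([xr, covariates_ref.reindex(xr.index)], axis=1)
        fit = fit_conditional_logistic(xc, xr)
        rec = fit.loc[factor].copy()
        rec["factor_id"] = factor
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("factor_id")
    return out


def auc_of_model(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: one class is absent")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
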