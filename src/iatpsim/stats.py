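"""Marginal (GEE) models for clustered binary outcomes, and t-tests.

Episodes cluster within patients, so raw episode-level proportions
misstate precision (and, with unequal cluster sizes and within-patient
correlation, can be biased toward prolific patients).  The estimators here
follow Liang & Zeger: a binomial-logit marginal model solved by iteratively
reweighted updates under a working correlation (exchangeable by default,
independence for sensitivity), with the exchangeable parameter estimated by
the moment method from Pearson residuals and inference from the robust
sandwich covariance.  Confidence intervals for proportions are formed on
the log-odds scale and back-transformed, which keeps them inside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "GEEFit",
    "ProportionEstimate",
    "SeparationError",
    "gee_fit",
    "adjusted_proportion",
    "factor_table",
    "two_sample_t",
    "two_sample_t_from_stats",
    "marginal_intercept",
]

MAX_ITER = 100
TOL = 1e-8
SEPARATION_BETA = 15.0


class SeparationError(ValueError):
    """Raised when the binary outcome is (quasi-)separated."""

    def __init__(self, msg: str = "separation_detected"):
        super().__init__(msg)


@dataclass
class GEEFit:
    """Result of a marginal logistic fit with cluster-robust covariance."""

    beta: np.ndarray
    robust_cov: np.ndarray
    alpha_hat: float
    n_clusters: int
    n_obs: int
    converged: bool
    n_iter: int

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))

    def wald_p(self) -> np.ndarray:
        z = self.beta / self.robust_se
        return 2.0 * sps.norm.sf(np.abs(z))


@dataclass
class ProportionEstimate:
    p_hat: float
    ci_low: float
    ci_high: float
    n_obs: int
    n_clusters: int
    scale_note: str = "CI computed on log-odds then back-transformed"


def _cluster_slices(cluster_ids: np.ndarray) -> list[np.ndarray]:
    ids = np.asarray(cluster_ids)
    uniq = np.unique(ids)
    return [np.flatnonzero(ids == u) for u in uniq]


def gee_fit(
    y: Sequence[float],
    X: Sequence[Sequence[float]],
    cluster_ids: Sequence,
    working: str = "exchangeable",
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> GEEFit:
    """Solve the binomial-logit generalized estimating equations.

    Parameters
    ----------
    y
        Binary outcomes (0/1), length n.
    X
        Design matrix (n, p), including the intercept column.
    cluster_ids
        Cluster (patient) label per observation.
    working
        Working correlation: ``"exchangeable"`` or ``"independence"``.

    Raises
    ------
    SeparationError
        When the outcome is separated (including a degenerate all-0/all-1
        outcome).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    if working not in ("exchangeable", "independence"):
        raise ValueError(f"unknown working correlation {working!r}")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    groups = _cluster_slices(np.asarray(cluster_ids))
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    if np.all(y == y[0]):
        raise SeparationError()

    beta = np.zeros(p)
    # intercept warm start when the first column is constant
    if np.allclose(X[:, 0], X[0, 0]) and X[0, 0] != 0:
        pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        beta[0] = logit(pbar) / X[0, 0]

    alpha = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        v = mu * (1.0 - mu)
        if np.any(v < 1e-12):
            raise SeparationError()
        r = (y - mu) / np.sqrt(v)
        phi = float(r @ r) / max(n - p, 1)

        if working == "exchangeable":
            num, denom = 0.0, 0
            for idx in groups:
                ri = r[idx]
                ni = ri.size
                if ni > 1:
                    num += (ri.sum() ** 2 - (ri ** 2).sum()) / 2.0
                    denom += ni * (ni - 1) // 2
            alpha = num / (phi * max(denom - p, 1)) if denom > 0 else 0.0
            nmax = max(len(idx) for idx in groups)
            alpha = float(np.clip(alpha, -1.0 / max(nmax - 1, 1) + 1e-6, 1 - 1e-6))
        else:
            alpha = 0.0

        H = np.zeros((p, p))
        U = np.zeros(p)
        for idx in groups:
            Xi = X[idx]
            si = np.sqrt(v[idx])
            resid = y[idx] - mu[idx]
            ni = idx.size
            # D' V^{-1} = X' A^{1/2} R^{-1} A^{-1/2} / phi
            Za = Xi * si[:, None]              # A^{1/2} X
            ra = resid / si                    # A^{-1/2} (y - mu)
            if alpha != 0.0 and ni > 1:
                c1 = 1.0 / (1.0 - alpha)
                c2 = alpha / ((1.0 - alpha) * (1.0 + (ni - 1) * alpha))
                Rinv_Za = c1 * Za - c2 * np.outer(np.ones(ni), Za.sum(axis=0))
                Rinv_ra = c1 * ra - c2 * ra.sum()
            else:
                Rinv_Za, Rinv_ra = Za, ra
            H += Za.T @ Rinv_Za / phi
            U += Za.T @ Rinv_ra / phi
        delta = np.linalg.solve(H, U)
        beta = beta + delta
        if np.max(np.abs(beta)) > SEPARATION_BETA:
            raise SeparationError()
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    # sandwich covariance at the solution
    eta = X @ beta
    mu = expit(eta)
    v = mu * (1.0 - mu)
    H = np.zeros((p, p))
    M = np.zeros((p, p))
    phi = float(((y - mu) ** 2 / v).sum()) / max(n - p, 1)
    for idx in groups:
        Xi = X[idx]
        si = np.sqrt(v[idx])
        resid = y[idx] - mu[idx]
        ni = idx.size
        Za = Xi * si[:, None]
        ra = resid / si
        if alpha != 0.0 and ni > 1:
            c1 = 1.0 / (1.0 - alpha)
            c2 = alpha / ((1.0 - alpha) * (1.0 + (ni - 1) * alpha))
            Rinv_Za = c1 * Za - c2 * np.outer(np.ones(ni), Za.sum(axis=0))
            Rinv_ra = c1 * ra - c2 * ra.sum()
        else:
            Rinv_Za, Rinv_ra = Za, ra
        H += Za.T @ Rinv_Za / phi
        ui = Za.T @ Rinv_ra / phi
        M += np.outer(ui, ui)
    Hinv = np.linalg.inv(H)
    cov = Hinv @ M @ Hinv
    cov = (cov + cov.T) / 2.0

    return GEEFit(
        beta=beta,
        robust_cov=cov,
        alpha_hat=float(alpha),
        n_clusters=len(groups),
        n_obs=n,
        converged=converged,
        n_iter=it,
    )


def adjusted_proportion(successes: Sequence[float], cluster_ids: Sequence,
                        working: str = "exchangeable") -> ProportionEstimate:
    """Cluster-adjusted proportion with a 95% CI on the logit scale."""
    y = np.asarray(successes, dtype=float)
    fit = gee_fit(y, np.ones((y.size, 1)), cluster_ids, working=working)
    b0 = float(fit.beta[0])
    se = float(fit.robust_se[0])
    return ProportionEstimate(
        p_hat=float(expit(b0)),
        ci_low=float(expit(b0 - 1.959963984540054 * se)),
        ci_high=float(expit(b0 + 1.959963984540054 * se)),
        n_obs=fit.n_obs,
        n_clusters=fit.n_clusters,
    )


def _encode_factor(values: np.ndarray, reference: Optional[str] = None):
    """Dummy-code a categorical column; returns (columns, level names, ref)."""
    levels = sorted(set(values))
    if reference is None:
        reference = levels[0]
    others = [l for l in levels if l != reference]
    cols = [np.asarray(values == l, dtype=float) for l in others]
    return cols, others, reference


def factor_table(df, outcome: str, factors: Sequence[str], cluster: str = "patient_id",
                 continuous: Sequence[str] = ("age_years",)):
    """Univariate and multivariate GEE analysis of factors for an outcome.

    Fits one multivariate model containing every factor (additively, no
    interactions) and, for each level of each categorical factor, a
    univariate cluster-adjusted proportion.  Returns a pandas DataFrame
    ordered by multivariate p-value; levels whose outcome is degenerate
    are retained with a separation note rather than an estimate.
    """
    import pandas as pd

    y = df[outcome].to_numpy(dtype=float)
    clusters = df[cluster].to_numpy()
    cols = [np.ones(len(df))]
    names = ["intercept"]
    factor_cols: dict[str, list[int]] = {}
    degenerate: list[str] = []
    for f in factors:
        vals = df[f].to_numpy()
        if f in continuous:
            x = vals.astype(float)
            cols.append((x - x.mean()) / max(x.std(), 1e-12))
            names.append(f)
            factor_cols[f] = [len(cols) - 1]
        else:
            svals = vals.astype(str)
            levels_all = sorted(set(svals))
            if len(levels_all) < 2:
                warnings.warn(f"factor {f!r} has a single level; dropped")
                continue
            if any(len(set(y[svals == l])) < 2 for l in levels_all):
                # a level with constant outcome separates the fit
                degenerate.append(f)
                continue
            dummies, levels, _ = _encode_factor(svals)
            idxs = []
            for d, l in zip(dummies, levels):
                cols.append(d)
                names.append(f"{f}[{l}]")
                idxs.append(len(cols) - 1)
            factor_cols[f] = idxs
    if factor_cols:
        X = np.column_stack(cols)
        multi = gee_fit(y, X, clusters)
        pvals = multi.wald_p()
    else:
        pvals = np.array([])

    rows = []
    for f in degenerate:
        for level in sorted(set(df[f].astype(str))):
            mask = df[f].astype(str).to_numpy() == level
            note = "separation_detected"
            rate = lo = hi = np.nan
            try:
                est = adjusted_proportion(y[mask], clusters[mask])
                rate, lo, hi = est.p_hat, est.ci_low, est.ci_high
                note = "separation_detected (multivariate)"
            except (SeparationError, ValueError):
                pass
            rows.append({"factor": f, "multivariate_p": np.nan, "level": level,
                         "rate": rate, "ci_low": lo, "ci_high": hi,
                         "n": int(mask.sum()), "note": note})
    for f, idxs in factor_cols.items():
        p_multi = float(min(pvals[i] for i in idxs))
        if f in continuous:
            rows.append({"factor": f, "multivariate_p": p_multi, "level": "continuous",
                         "rate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "n": len(df), "note": "N/A"})
            continue
        for level in sorted(set(df[f].astype(str))):
            mask = df[f].astype(str).to_numpy() == level
            note = ""
            try:
                est = adjusted_proportion(y[mask], clusters[mask])
                rate, lo, hi = est.p_hat, est.ci_low, est.ci_high
            except (SeparationError, ValueError) as e:
                rate = lo = hi = np.nan
                note = str(e)
            rows.append({"factor": f, "multivariate_p": p_multi, "level": level,
                         "rate": rate, "ci_low": lo, "ci_high": hi,
                         "n": int(mask.sum()), "note": note})
    out = pd.DataFrame(rows).sort_values(
        ["multivariate_p", "factor", "level"]).reset_index(drop=True)
    return out


def two_sample_t(x1: Sequence[float], x2: Sequence[float], variant: str = "welch") -> dict:
    """Two-sample t-test (Welch by default, or pooled-variance)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x1) == 0 and np.var(x2) == 0 and x1.mean() == x2.mean():
        raise ValueError("zero variance in both samples")
    equal_var = variant == "pooled"
    res = sps.ttest_ind(x1, x2, equal_var=equal_var)
    df = res.df if hasattr(res, "df") else (x1.size + x2.size - 2)
    return {
        "t": float(res.statistic), "df": float(df), "p": float(res.pvalue),
        "mean1": float(x1.mean()), "sd1": float(x1.std(ddof=1)),
        "mean2": float(x2.mean()), "sd2": float(x2.std(ddof=1)),
    }


def two_sample_t_from_stats(mean1, sd1, n1, mean2, sd2, n2, variant: str = "pooled") -> dict:
    """t-test from summary statistics (for printed-table arithmetic)."""
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        a, b = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue),
            "mean1": mean1, "sd1": sd1, "mean2": mean2, "sd2": sd2}


def marginal_intercept(p: float, frailty_sd: float) -> float:
    """Logit intercept b0 such that E_z[expit(b0 + frailty_sd * z)] = p
    for standard-normal patient frailty z (Gauss-Hermite quadrature)."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if frailty_sd == 0:
        return float(logit(p))
    nodes, w = np.polynomial.hermite.hermgauss(60)
    z = np.sqrt(2.0) * nodes
    w = w / np.sqrt(np.pi)
    f = lambda b0: float(w @ expit(b0 + frailty_sd * z)) - p
    return float(brentq(f, -30, 30))
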