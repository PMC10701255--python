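"""Pseudo-likelihood logistic regression for case-cohort samples.

In the case-cohort design of interest, a logistic regression of the
membership indicator D (1 = case sample, 0 = subcohort sample) on the
covariates is fitted to the stacked "pseudo dataset", treating a
participant who belongs to both the case set and the subcohort as two
distinct rows.  The non-intercept coefficients of this fit are consistent
estimators of log risk ratios in the source population.

This module provides the maximum-likelihood fit (IRLS with step-halving),
the model-based (inverse-information) covariance, the robust sandwich
covariance A^{-1} B A^{-1} that treats every pseudo-row as independent —
deliberately so, since quantifying that estimator's bias under duplication
is the point of the surrounding package — and Wald/risk-ratio reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import (
    DegenerateDataError,
    DataIntegrityError,
    NonConvergenceError,
    RankDeficiencyError,
    SingularityError,
)

__all__ = [
    "PseudoDataset",
    "FitResult",
    "fit_logistic",
    "robust_covariance",
    "wald_interval",
    "risk_ratio_report",
]

#: Coefficient magnitude beyond which a fit is declared separated.
_SEPARATION_BOUND = 30.0


@dataclass(frozen=True)
class PseudoDataset:
    """Stacked case (D=1) and subcohort (D=0) rows with an intercept column.

    Parameters
    ----------
    X
        Design matrix of shape ``(n, p+1)``; the first column is the
        intercept (all ones by convention of the assemblers).
    d
        Membership indicator per row (1 = case sample, 0 = subcohort).
    ids
        Optional participant identifier per row.  An identifier may appear
        at most twice, and when it does, once with ``d=1`` and once with
        ``d=0`` — those are the duplicated participants of the design.
    columns
        Column names of ``X``.
    """

    X: np.ndarray
    d: np.ndarray
    ids: np.ndarray | None = None
    columns: tuple[str, ...] = field(default=())

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "d", d)
        if X.ndim != 2 or d.ndim != 1 or X.shape[0] != d.shape[0]:
            raise ValueError("X must be (n, p+1) and d length n")
        vals = np.unique(d)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise DegenerateDataError("membership indicator D must be binary")
        if vals.size < 2:
            raise DegenerateDataError(
                "both D=1 (case) and D=0 (subcohort) rows are required"
            )
        if not self.columns:
            object.__setattr__(
                self,
                "columns",
                ("intercept",) + tuple(f"x{j}" for j in range(1, X.shape[1])),
            )
        if len(self.columns) != X.shape[1]:
            raise ValueError("columns must match the design-matrix width")
        if self.ids is not None:
            ids = np.asarray(self.ids)
            object.__setattr__(self, "ids", ids)
            if ids.shape[0] != X.shape[0]:
                raise ValueError("ids must have one entry per row")
            uniq, counts = np.unique(ids, return_counts=True)
            if (counts > 2).any():
                bad = uniq[counts > 2][0]
                raise DataIntegrityError(
                    f"participant id {bad!r} appears more than twice"
                )
            for pid in uniq[counts == 2]:
                dvals = np.sort(d[ids == pid])
                if dvals[0] != 0.0 or dvals[1] != 1.0:
                    raise DataIntegrityError(
                        f"participant id {pid!r} appears twice with identical D"
                    )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.d.sum())

    @property
    def n_subcohort(self) -> int:
        return self.n - self.n_cases


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood logistic fit with two covariance estimates."""

    beta: np.ndarray
    model_cov: np.ndarray
    robust_cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    columns: tuple[str, ...] = ()


def _loglik(eta: np.ndarray, d: np.ndarray) -> float:
    # sum_i d_i eta_i - log(1 + exp(eta_i)), numerically stable
    return float(d @ eta - np.logaddexp(0.0, eta).sum())


def _irls(X: np.ndarray, d: np.ndarray, tol: float, max_iter: int):
    """Newton/IRLS maximization with step-halving on likelihood decrease.

    Returns ``(beta, mu, loglik, n_iter)``; raises on non-convergence or a
    singular information matrix.  Uses the expected-information form, which
    coincides with the observed information for the canonical logit link.
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = np.zeros(n)
    ll = _loglik(eta, d)
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        score = X.T @ (d - mu)
        if np.abs(score).max() < tol:
            return beta, mu, ll, it - 1
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SingularityError("information matrix is singular") from exc
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            eta_c = X @ cand
            ll_c = _loglik(eta_c, d)
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        beta, eta, ll = cand, eta_c, ll_c
        if np.abs(beta).max() > _SEPARATION_BOUND:
            raise NonConvergenceError(
                "coefficients diverged (likely complete or quasi-separation)",
                beta=beta,
                n_iter=it,
            )
    mu = expit(eta)
    score = X.T @ (d - mu)
    if np.abs(score).max() < tol:
        return beta, mu, ll, max_iter
    raise NonConvergenceError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(score max-norm {np.abs(score).max():.3e})",
        beta=beta,
        n_iter=max_iter,
    )


def _sandwich(X: np.ndarray, d: np.ndarray, mu: np.ndarray) -> np.ndarray:
    w = mu * (1.0 - mu)
    a = X.T @ (X * w[:, None])
    resid2 = (d - mu) ** 2
    b = X.T @ (X * resid2[:, None])
    a_inv = np.linalg.inv(a)
    cov = a_inv @ b @ a_inv
    return 0.5 * (cov + cov.T)


def fit_logistic(
    data: PseudoDataset, tol: float = 1e-8, max_iter: int = 100
) -> FitResult:
    """Fit the pseudo-likelihood logistic regression by IRLS.

    Parameters
    ----------
    data
        The assembled pseudo dataset (intercept column included).
    tol
        Convergence tolerance on the max-norm of the score vector.
    max_iter
        Maximum number of Newton iterations.

    Returns
    -------
    FitResult
        Coefficients, the model-based covariance (inverse information) and
        the robust sandwich covariance, both evaluated at the optimum.

    Raises
    ------
    RankDeficiencyError
        If the design matrix is column-rank deficient.
    NonConvergenceError
        If IRLS fails to converge, including separated configurations.
    """
    if tol <= 0 or max_iter <= 0:
        raise ValueError("tol and max_iter must be positive")
    X, d = data.X, data.d
    if X.shape[0] <= X.shape[1]:
        raise DegenerateDataError("need more rows than parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("design matrix is not of full column rank")
    beta, mu, ll, n_iter = _irls(X, d, tol, max_iter)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    try:
        model_cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SingularityError("information matrix is singular") from exc
    model_cov = 0.5 * (model_cov + model_cov.T)
    robust_cov = _sandwich(X, d, mu)
    return FitResult(
        beta=beta,
        model_cov=model_cov,
        robust_cov=robust_cov,
        loglik=ll,
        converged=True,
        n_iter=n_iter,
        columns=tuple(data.columns),
    )


def robust_covariance(data: PseudoDataset, fit: FitResult) -> np.ndarray:
    """Sandwich covariance A⁻¹ B A⁻¹ treating every pseudo-row as independent.

    ``A`` is the (expected = observed) information ``Σ p̂ᵢ(1−p̂ᵢ) xᵢxᵢᵀ`` and
    ``B`` the sum of per-row score outer products ``Σ (Dᵢ−p̂ᵢ)² xᵢxᵢᵀ``.
    Duplicated participants contribute two "independent" rows, which is
    exactly the assumption whose failure biases this estimator upward.
    """
    if not fit.converged:
        raise NonConvergenceError("robust covariance requires a converged fit")
    mu = expit(data.X @ fit.beta)
    return _sandwich(data.X, data.d, mu)


def wald_interval(estimate: float, se: float, level: float = 0.95):
    """Normal-theory interval ``estimate ± z_{(1+level)/2} · se``."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = norm.ppf(0.5 * (1.0 + level))
    return estimate - z * se, estimate + z * se


def risk_ratio_report(
    fit: FitResult,
    cov_choice: str = "robust",
    supplied_cov: np.ndarray | None = None,
    supplied_se: np.ndarray | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-covariate risk ratios with Wald confidence intervals.

    The intercept is excluded: in the pseudo-likelihood fit only the slope
    coefficients estimate log risk ratios; the intercept absorbs the
    sampling fractions and is not interpretable.

    Parameters
    ----------
    fit
        A converged fit.
    cov_choice
        ``"model"``, ``"robust"`` or ``"supplied"``.
    supplied_cov, supplied_se
        With ``cov_choice="supplied"``, either a full covariance matrix or
        a vector of per-coefficient standard errors (e.g. bootstrap SEs).
    level
        Confidence level for the Wald intervals.

    Returns
    -------
    pandas.DataFrame
        Indexed by covariate name with columns ``coef``, ``se``, ``rr``,
        ``rr_lower``, ``rr_upper``.
    """
    if not fit.converged:
        raise NonConvergenceError("risk-ratio report requires a converged fit")
    if cov_choice == "model":
        se = np.sqrt(np.diag(fit.model_cov))
    elif cov_choice == "robust":
        se = np.sqrt(np.diag(fit.robust_cov))
    elif cov_choice == "supplied":
        if supplied_se is not None:
            se = np.asarray(supplied_se, dtype=float)
        elif supplied_cov is not None:
            se = np.sqrt(np.diag(np.asarray(supplied_cov, dtype=float)))
        else:
            raise ValueError("cov_choice='supplied' needs supplied_cov or supplied_se")
    else:
        raise ValueError(f"unknown cov_choice {cov_choice!r}")
    rows = []
    names = []
    for j in range(1, fit.beta.size):  # row 0 is the intercept
        b = fit.beta[j]
        lo, hi = wald_interval(b, se[j], level)
        rows.append(
            {
                "coef": b,
                "se": se[j],
                "rr": math.exp(b),
                "rr_lower": math.exp(lo),
                "rr_upper": math.exp(hi),
            }
        )
        names.append(fit.columns[j] if fit.columns else f"x{j}")
    return pd.DataFrame(rows, index=pd.Index(names, name="covariate"))
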