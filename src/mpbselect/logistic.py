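"""Maximum-likelihood logistic regression via IRLS, BIC, and standardized fits.

The presence/absence model is

    pi = exp(b0 + sum_i b_i X_i) / (1 + exp(b0 + sum_i b_i X_i)),

fitted by iteratively reweighted least squares. Convergence is declared when
the largest absolute coefficient change falls below 1e-8 (at most 100
iterations); non-convergence and quasi-complete separation are reported on
the fit rather than raised, so model enumeration can carry on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import (
    DegenerateResponseError,
    NotConvergedError,
    RankDeficientError,
    UnknownCovariateError,
    ZeroVarianceError,
)

#: Linear predictors are clipped to +/- this before the logistic link to
#: avoid overflow; expit(30) differs from 1 by ~1e-13.
LOGIT_CLIP = 30.0

#: |standardized beta| beyond which a fit is flagged as quasi-separated.
SEPARATION_BETA = 15.0

_IRLS_TOL = 1e-8
_IRLS_MAXITER = 100


@dataclass
class LogisticFit:
    """A fitted logistic regression.

    ``coef`` maps covariate name -> coefficient; the intercept is separate.
    ``k`` counts the intercept plus covariates.
    """

    intercept: float
    coef: dict[str, float]
    se: dict[str, float]
    loglik: float
    n: int
    k: int
    converged: bool
    separation: bool = False
    covariates: tuple[str, ...] = field(default_factory=tuple)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing = set(self.covariates) - set(X.columns)
        if missing:
            raise UnknownCovariateError(
                f"covariates missing from data: {sorted(missing)}"
            )
        eta = np.full(len(X), self.intercept)
        for name in self.covariates:
            eta += self.coef[name] * X[name].to_numpy(dtype=float)
        return eta

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted probabilities, strictly inside (0, 1)."""
        return expit(np.clip(self.linear_predictor(X), -LOGIT_CLIP, LOGIT_CLIP))


def _design(X: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(X))]
    for name in covariates:
        cols.append(X[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_logistic(
    X: pd.DataFrame, y: np.ndarray, covariates: list[str] | None = None
) -> LogisticFit:
    """Fit the presence/absence logistic regression by IRLS.

    ``covariates`` selects columns of ``X`` (default: all columns, in
    order); an intercept is always included. Raises on a one-class
    response or a rank-deficient design; separation is flagged, not raised.
    """
    if covariates is None:
        covariates = list(X.columns)
    missing = set(covariates) - set(X.columns)
    if missing:
        raise UnknownCovariateError(f"unknown covariates: {sorted(missing)}")
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise DegenerateResponseError("response contains a single class")

    D = _design(X, covariates)
    n, k = D.shape
    if np.linalg.matrix_rank(D) < k:
        raise RankDeficientError(
            "design matrix is rank deficient (perfectly collinear columns)"
        )

    def loglik_at(b: np.ndarray) -> float:
        eta = D @ b
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    beta = np.zeros(k)
    beta[0] = np.log(y.mean() / (1 - y.mean()))  # warm start at prevalence
    ll = loglik_at(beta)
    converged = False
    for _ in range(_IRLS_MAXITER):
        eta = D @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        WD = D * w[:, None]
        try:
            beta_prop = np.linalg.solve(D.T @ WD, WD.T @ z)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise RankDeficientError(str(exc)) from exc
        # step-halving: never accept a step that lowers the log-likelihood
        direction = beta_prop - beta
        for halving in range(31):
            cand = beta + direction / (2.0 ** halving)
            ll_cand = loglik_at(cand)
            if np.isfinite(ll_cand) and ll_cand >= ll - 1e-12:
                break
        step = np.max(np.abs(cand - beta))
        ll_change = abs(ll_cand - ll)
        beta, ll = cand, ll_cand
        # coefficient-change criterion, with a deviance-change fallback for
        # ill-conditioned designs where round-off dominates the step
        if step < _IRLS_TOL or ll_change < 1e-10 * (abs(ll) + 1.0):
            converged = True
            break

    mu = expit(np.clip(D @ beta, -LOGIT_CLIP, LOGIT_CLIP))
    loglik = loglik_at(beta)
    w = np.maximum(mu * (1 - mu), 1e-12)
    cov = np.linalg.pinv(D.T @ (D * w[:, None]))
    ses = np.sqrt(np.maximum(np.diag(cov), 0.0))

    scales = np.array([1.0] + [max(X[c].to_numpy(dtype=float).std(), 0.0)
                               for c in covariates])
    separation = bool(np.any(np.abs(beta[1:] * scales[1:]) > SEPARATION_BETA))

    return LogisticFit(
        intercept=float(beta[0]),
        coef={c: float(b) for c, b in zip(covariates, beta[1:])},
        se={c: float(s) for c, s in zip(["(intercept)"] + covariates, ses)},
        loglik=loglik,
        n=n,
        k=k,
        converged=converged,
        separation=separation,
        covariates=tuple(covariates),
    )


def bic(fit: LogisticFit) -> float:
    """Bayesian Information Criterion, k*ln(n) - 2*logLik, intercept counted in k."""
    if not fit.converged:
        raise NotConvergedError("BIC requires a converged fit")
    return fit.k * np.log(fit.n) - 2.0 * fit.loglik


def delta_bic(bics: list[float]) -> list[float]:
    """ΔBIC of each model relative to the minimum of the list."""
    best = min(bics)
    return [b - best for b in bics]


#: ΔBIC at or below which two models are considered indistinguishable.
DELTA_BIC_INDISTINGUISHABLE = 2.0
#: ΔBIC at or above which the lower-BIC model has strong evidence.
DELTA_BIC_STRONG = 8.0


def evidence_flag(delta: float) -> str:
    """Evidence label for a ΔBIC value: indistinguishable / - / strong."""
    if delta <= DELTA_BIC_INDISTINGUISHABLE:
        return "indistinguishable"
    if delta >= DELTA_BIC_STRONG:
        return "strong"
    return "-"


def standardized_estimates(
    X: pd.DataFrame, y: np.ndarray, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Fit on z-scored covariates and order coefficients by importance.

    Covariates are centered and scaled to unit variance on the supplied
    (training) rows before fitting, so coefficient magnitudes are comparable
    across covariates with different units. Returns a DataFrame with columns
    covariate / estimate / se / sign, sorted by |estimate| descending (ties
    broken alphabetically).
    """
    if covariates is None:
        covariates = list(X.columns)
    Z = pd.DataFrame(index=X.index)
    for name in covariates:
        col = X[name].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            raise ZeroVarianceError(f"covariate {name!r} has zero variance")
        Z[name] = (col - col.mean()) / sd
    fit = fit_logistic(Z, y, covariates)
    rows = [
        {
            "covariate": name,
            "estimate": fit.coef[name],
            "se": fit.se[name],
            "sign": int(np.sign(fit.coef[name])),
        }
        for name in covariates
    ]
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["estimate", "covariate"],
        key=lambda s: -s.abs() if s.name == "estimate" else s,
        kind="stable",
    ).reset_index(drop=True)
    return out
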