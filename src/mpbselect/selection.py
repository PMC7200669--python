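"""Model selection machinery: correlation screening, VIF, exhaustive BIC search.

The workflow, per outbreak phase:

1. screen the candidate covariates within thematic categories (weather,
   vegetation, topography, beetle), dropping covariates involved in
   within-category pairs with |Pearson rho| > 0.6 until none remain;
2. enumerate all 2^p subsets of the survivors, fit each by logistic
   regression on the phase's rows, and rank by BIC (ΔBIC <= 2:
   indistinguishable; >= 8: strong evidence for the lower BIC);
3. a posteriori, exclude models whose maximum variance inflation factor
   exceeds 10 (poorly estimated coefficients due to multicollinearity);
4. report, per subset size, the best model and competitors within ΔBIC <= 8,
   with leave-one-year-out AUROC and AUPR computed under one common fold
   scheme for every reported model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateResponseError,
    EnumerationCapError,
    RankDeficientError,
    UnknownCovariateError,
)
from .logistic import (
    LogisticFit,
    bic,
    evidence_flag,
    fit_logistic,
)

#: Thematic covariate categories used for within-category screening.
DEFAULT_CATEGORIES = {
    "weather": ["T_max", "T_min", "SMI", "CT", "Peak"],
    "vegetation": ["Cover", "Age", "Height"],
    "topography": ["Dist", "N", "E"],
    "beetle": ["I_c", "I_u"],
}

#: Survivor preference for screening, highest priority first: process-based
#: indices (soil moisture, emergence timing) are preferred over the raw
#: temperature extreme they derive from, and stand height over stand age.
DEFAULT_KEEP_PRIORITY = [
    "I_u", "I_c", "SMI", "Peak", "T_min", "CT", "Height", "Cover",
    "Dist", "N", "E", "T_max", "Age",
]

VIF_EXCLUDE = 10.0
SCREEN_THRESHOLD = 0.6


@dataclass
class ScreeningReport:
    """Outcome of within-category correlation screening."""

    categories: dict[str, list[str]]
    rho: pd.DataFrame
    removed: list[tuple[str, str, float]]  # (removed, partner, rho)
    retained: list[str]


@dataclass
class ModelRecord:
    """One covariate subset and its selection statistics."""

    subset: tuple[str, ...]
    size: int
    bic: float
    delta_bic: float = np.nan
    vif_max: float = np.nan
    auroc: float = np.nan
    aupr: float = np.nan
    excluded_by_vif: bool = False
    separation: bool = False
    evidence: str = "-"
    fit: LogisticFit | None = None


def screen_correlated(
    table: pd.DataFrame,
    categories: dict[str, list[str]] | None = None,
    threshold: float = SCREEN_THRESHOLD,
    keep_priority: list[str] | None = None,
) -> ScreeningReport:
    """Remove highly correlated covariates within each category.

    While any within-category pair has |rho| strictly greater than
    ``threshold``, the lowest-priority covariate among those involved in a
    violating pair is dropped. Cross-category correlations never trigger
    removal. Priority is the position in ``keep_priority`` (earlier = kept).
    """
    categories = categories or {
        cat: [c for c in cols if c in table.columns]
        for cat, cols in DEFAULT_CATEGORIES.items()
    }
    keep_priority = keep_priority or DEFAULT_KEEP_PRIORITY
    all_cands = [c for cols in categories.values() for c in cols]
    missing = set(all_cands) - set(table.columns)
    if missing:
        raise UnknownCovariateError(f"covariates not in table: {sorted(missing)}")

    def priority(name: str) -> int:
        return keep_priority.index(name) if name in keep_priority else len(keep_priority)

    rho = table[all_cands].corr(method="pearson")
    removed: list[tuple[str, str, float]] = []
    retained: list[str] = []
    for cat, cols in categories.items():
        active = list(cols)
        while True:
            violating = [
                (a, b)
                for a, b in itertools.combinations(active, 2)
                if abs(rho.loc[a, b]) > threshold
            ]
            if not violating:
                break
            involved = {c for pair in violating for c in pair}
            drop = max(involved, key=lambda c: (priority(c), c))
            partner = max(
                (c for pair in violating if drop in pair for c in pair if c != drop),
                key=lambda c: abs(rho.loc[drop, c]),
            )
            removed.append((drop, partner, float(rho.loc[drop, partner])))
            active.remove(drop)
        retained.extend(active)
    return ScreeningReport(
        categories=categories, rho=rho, removed=removed, retained=retained
    )


def vif(X: pd.DataFrame) -> tuple[dict[str, float], float]:
    """Variance inflation factors, VIF_j = 1 / (1 - R_j^2).

    R_j^2 comes from the OLS regression (with intercept) of covariate j on
    the remaining covariates. Perfect collinearity yields an infinite VIF.
    Requires at least two non-constant columns.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least two covariates")
    M = X.to_numpy(dtype=float)
    if np.any(M.std(axis=0) == 0):
        raise ValueError("VIF requires non-constant columns")
    out: dict[str, float] = {}
    for j, name in enumerate(cols):
        yj = M[:, j]
        others = np.delete(M, j, axis=1)
        D = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(D, yj, rcond=None)
        resid = yj - D @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out, max(out.values())


def _subset_vif_max(table: pd.DataFrame, subset: tuple[str, ...]) -> float:
    if len(subset) == 0:
        return np.nan
    if len(subset) == 1:
        return 1.0  # single covariate: R^2 = 0 by convention
    return vif(table[list(subset)])[1]


def exhaustive_selection(
    table: pd.DataFrame,
    candidates: list[str],
    response: str = "response",
    year_col: str = "year",
    with_cv: bool = True,
    max_candidates: int = 20,
    competitor_delta: float = 8.0,
) -> list[ModelRecord]:
    """Enumerate all covariate subsets and select by BIC.

    Fits all 2^p subsets (including the null, intercept-only model) on the
    supplied rows (one outbreak phase). Returns the reported rows of a
    selection table: per size, the minimum-BIC model plus competitors within
    ``competitor_delta`` of that size's best; ΔBIC is relative to the overall
    minimum across all converged models. Models with VIF_max > 10 or
    quasi-separation are marked and never eligible as overall best (the
    exclusion is applied a posteriori, after enumeration). With ``with_cv``,
    leave-one-year-out AUROC/AUPR are attached to every reported record under
    one identical fold scheme.
    """
    from .validation import loyo_cv

    p = len(candidates)
    if p > max_candidates:
        raise EnumerationCapError(
            f"{p} candidates would require {2 ** p} fits; screen covariates "
            f"or raise max_candidates (currently {max_candidates})"
        )
    missing = set(candidates) - set(table.columns)
    if missing:
        raise UnknownCovariateError(f"candidates not in table: {sorted(missing)}")

    y = table[response].to_numpy(dtype=float)
    records: list[ModelRecord] = []
    for size in range(p + 1):
        for subset in itertools.combinations(candidates, size):
            try:
                fit = fit_logistic(table, y, list(subset))
            except (RankDeficientError, DegenerateResponseError) as exc:
                warnings.warn(f"subset {subset}: {exc}; skipped")
                continue
            if not fit.converged:
                warnings.warn(f"subset {subset}: IRLS did not converge; skipped")
                continue
            vmax = _subset_vif_max(table, subset)
            records.append(
                ModelRecord(
                    subset=subset,
                    size=size,
                    bic=bic(fit),
                    vif_max=vmax,
                    excluded_by_vif=bool(vmax > VIF_EXCLUDE),
                    separation=fit.separation,
                    fit=fit,
                )
            )

    eligible = [r for r in records if not r.excluded_by_vif and not r.separation]
    best_overall = min(eligible, key=lambda r: r.bic)
    for r in records:
        r.delta_bic = r.bic - best_overall.bic
        r.evidence = evidence_flag(r.delta_bic)

    reported: list[ModelRecord] = []
    for size in sorted({r.size for r in records}):
        at_size = [r for r in records if r.size == size]
        best_at_size = min(at_size, key=lambda r: r.bic)
        for r in sorted(at_size, key=lambda r: r.bic):
            if r.bic - best_at_size.bic <= competitor_delta:
                reported.append(r)

    if with_cv:
        for r in reported:
            res = loyo_cv(table, list(r.subset), response=response, year_col=year_col)
            r.auroc = res.mean_auroc
            r.aupr = res.mean_aupr
    return reported


def best_model(records: list[ModelRecord]) -> ModelRecord:
    """Overall best: minimum BIC among models not excluded by VIF/separation."""
    eligible = [r for r in records if not r.excluded_by_vif and not r.separation]
    return min(eligible, key=lambda r: r.bic)


def selection_table(records: list[ModelRecord]) -> pd.DataFrame:
    """Report mirroring the published layout: one row per reported model."""
    return pd.DataFrame(
        {
            "size": [r.size for r in records],
            "variables": [
                ", ".join(r.subset) if r.subset else "null" for r in records
            ],
            "vif_max": [r.vif_max for r in records],
            "bic": [r.bic for r in records],
            "delta_bic": [r.delta_bic for r in records],
            "auroc": [r.auroc for r in records],
            "aupr": [r.aupr for r in records],
            "excluded_by_vif": [r.excluded_by_vif for r in records],
            "evidence": [r.evidence for r in records],
        }
    )
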