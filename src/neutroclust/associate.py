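"""Confounder-adjusted logistic regression of dichotomized neutrophils
against severe-disease outcomes (FACED >= 5, EFACED >= 7).

The fitter is a plain maximum-likelihood IRLS (Newton with step-halving, so
the log-likelihood never decreases across iterations), with Wald 95 %
confidence intervals ``exp(b +/- 1.96 SE)`` and a quasi-separation heuristic:
if the fit fails to converge and any coefficient magnitude exceeds 15, the
``separation`` flag is raised and estimates are still reported with a
warning. Rows with any missing covariate are dropped (complete-case) and the
dropped count is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort
from .threshold import ClusterAssignment

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "adjusted_association",
    "DEFAULT_CONFOUNDERS",
    "SCORE_CUTOFFS",
]

#: Fixed adjustment set: chronic PA colonization, Charlson index, total
#: leukocytes, % lymphocytes, % eosinophils, platelets, CRP, fibrinogen,
#: total protein, albumin, ESR. Percentages are derived from the absolute
#: counts at model-building time.
DEFAULT_CONFOUNDERS: tuple[str, ...] = (
    "pa_colonization",
    "charlson",
    "leukocytes",
    "lymphocytes_pct",
    "eosinophils_pct",
    "platelets",
    "crp",
    "fibrinogen",
    "total_protein",
    "albumin",
    "esr",
)

SCORE_CUTOFFS: dict[str, int] = {"FACED": 5, "EFACED": 7}

_SEPARATION_BETA = 15.0
_MAX_ITER = 100
_SCORE_TOL = 1e-8


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    n_used: int
    n_dropped: int
    converged: bool
    separation: bool
    loglik_path: list[float] = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def conf_int(self) -> np.ndarray:
        lo = np.exp(self.coef - 1.96 * self.se)
        hi = np.exp(self.coef + 1.96 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        return 2.0 * sps.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "se": self.se,
                "or": self.odds_ratios,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.p_values,
            }
        )

    def term(self, name: str) -> pd.Series:
        s = self.summary().set_index("term")
        return s.loc[name]


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    outcome,
    design: pd.DataFrame,
    add_intercept: bool = True,
) -> LogisticFit:
    """Fit a binary logistic model by IRLS with step-halving.

    Parameters
    ----------
    outcome
        0/1 vector; must contain both classes.
    design
        Covariate table (one column per term). Rows with any missing value
        (in outcome or covariates) are dropped. An intercept column is
        prepended unless ``add_intercept=False``.
    """
    y_all = pd.to_numeric(pd.Series(outcome), errors="coerce")
    X_all = design.apply(pd.to_numeric, errors="coerce")
    X_all = X_all.reset_index(drop=True)
    y_all = y_all.reset_index(drop=True)
    ok = y_all.notna() & X_all.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    y = y_all[ok].to_numpy(float)
    X = X_all[ok].to_numpy(float)
    terms = list(design.columns)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        terms = ["intercept"] + terms
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns via QR pivoting
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = [terms[i] for i in sorted(piv[rank:])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    # standardise continuous columns internally for conditioning; back-transform
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    center = X.mean(axis=0)
    if add_intercept:
        scale[0], center[0] = 1.0, 0.0
    Xs = (X - center) / scale

    beta = np.zeros(X.shape[1])
    eta = Xs @ beta
    ll = _loglik(y, eta)
    path = [ll]
    converged = False
    for _ in range(_MAX_ITER):
        p = 1.0 / (1.0 + np.exp(-eta))
        score = Xs.T @ (y - p)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (Xs * w[:, None]).T @ Xs
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        # step-halving guarantees a non-decreasing log-likelihood
        t = 1.0
        for _half in range(40):
            cand = beta + t * step
            cand_ll = _loglik(y, Xs @ cand)
            if cand_ll >= ll - 1e-12:
                break
            t /= 2.0
        beta, eta, ll = cand, Xs @ cand, cand_ll
        path.append(ll)

    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (Xs * w[:, None]).T @ Xs
    cov_s = np.linalg.pinv(H)

    # back-transform to the original covariate scale
    coef = beta / scale
    if add_intercept:
        coef[0] = beta[0] - np.sum(beta[1:] * center[1:] / scale[1:])
    J = np.diag(1.0 / scale)
    if add_intercept:
        J[0, 1:] = -center[1:] / scale[1:]
    cov = J @ cov_s @ J.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    separation = (not converged) and bool(np.max(np.abs(coef)) > _SEPARATION_BETA)
    if not separation and converged:
        # perfect separation can also converge the score with huge betas
        separation = bool(np.max(np.abs(coef[1:] if add_intercept else coef)) > _SEPARATION_BETA)
    if separation:
        warnings.warn(
            "quasi-separation detected: estimates unstable, interpret with care",
            stacklevel=2,
        )
    return LogisticFit(
        terms=terms,
        coef=coef,
        se=se,
        n_used=int(len(y)),
        n_dropped=n_dropped,
        converged=converged,
        separation=separation,
        loglik_path=path,
    )


def _with_percent_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "leukocytes" not in out.columns:
        return out
    leuk = pd.to_numeric(out["leukocytes"], errors="coerce")
    for absolute, pct in (("lymphocytes", "lymphocytes_pct"), ("eosinophils", "eosinophils_pct")):
        if pct not in out.columns and absolute in out.columns:
            out[pct] = 100.0 * pd.to_numeric(out[absolute], errors="coerce") / leuk
    return out


def adjusted_association(
    cohort: Cohort | pd.DataFrame,
    assignment: ClusterAssignment,
    scale: str,
    cutoff: int | None = None,
    confounders: Sequence[str] = DEFAULT_CONFOUNDERS,
) -> LogisticFit:
    """Adjusted OR of the above-threshold cluster for a severe score.

    Outcome: score total >= cutoff (default FACED >= 5 / EFACED >= 7);
    exposure: above-threshold cluster membership (1 = above). The exposure
    term is named ``neutrophils_above``; its row is the headline OR.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    df = _with_percent_columns(df)
    score_col = scale.lower()
    if score_col not in df.columns:
        raise ValueError(f"scored column '{score_col}' missing; score the cohort first")
    if cutoff is None:
        cutoff = SCORE_CUTOFFS[scale.upper()]
    totals = pd.to_numeric(df[score_col], errors="coerce")
    max_seen = {"faced": 7, "efaced": 9, "bsi": 26}[score_col]
    if cutoff > max_seen:
        raise ValueError(f"cutoff {cutoff} exceeds {scale} maximum {max_seen}: no events possible")
    labels = assignment.label_frame(df)
    keep = labels.isin(["above", "below"]).to_numpy()
    outcome = (totals >= cutoff).where(totals.notna()).astype(float)[keep]
    design = df.loc[keep, list(confounders)].copy()
    design.insert(0, "neutrophils_above", (labels[keep] == "above").astype(float).to_numpy())
    return fit_logistic(outcome, design)
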