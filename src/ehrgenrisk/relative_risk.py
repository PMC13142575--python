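"""Relative-risk regression for binary outcomes (modified Poisson).

A Poisson working model with log link is fit to the binary case indicator so
that exponentiated coefficients are relative risks; the misspecified Poisson
variance is corrected by a robust (HC0) sandwich estimator
A⁻¹ B A⁻¹ with bread A = Xᵀ diag(μ) X and meat B = Σᵢ xᵢxᵢᵀ (yᵢ − μᵢ)².
Fitting is iteratively reweighted least squares with step-halving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = float(stats.norm.ppf(0.975))  # two-sided 95% normal quantile

STRATA = ("overall", "female", "male", "18-39", "40-49", "50-59", "60-69", ">70")
AGE_BANDS = {
    "18-39": (-np.inf, 40.0),
    "40-49": (40.0, 50.0),
    "50-59": (50.0, 60.0),
    "60-69": (60.0, 70.0),
    ">70": (70.0, np.inf),
}
EXPOSURES = ("monogenic", "high_prs")


@dataclass
class ModelSpec:
    """Which outcome, exposures, covariates, and stratum to fit."""

    outcome: str = "ehr"  # {"ehr", "self_report", "combined"}
    exposures: Sequence[str] = EXPOSURES
    stratum: str = "overall"


@dataclass
class ModelFit:
    params: pd.Series
    robust_vcov: Optional[pd.DataFrame]
    converged: bool
    n_obs: int
    n_events: int
    n_iter: int = 0
    reason: str = ""
    model_vcov: Optional[pd.DataFrame] = None
    notes: list = field(default_factory=list)

    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.robust_vcov)), index=self.params.index)


def _check_rank(X: np.ndarray, labels: Sequence[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [labels[i] for i in np.flatnonzero(diag <= tol)]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_modified_poisson(
    y: np.ndarray,
    X: np.ndarray,
    labels: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ModelFit:
    """IRLS fit of the log-link Poisson working model with HC0 sandwich vcov.

    Converges on a coefficient change below ``tol`` (sup-norm). Zero events
    returns a non-converged fit rather than raising, matching how degenerate
    strata are reported downstream ("N/A").
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    labels = list(labels) if labels is not None else [f"x{i}" for i in range(p)]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    empty = pd.Series(np.full(p, np.nan), index=labels)
    if y.sum() == 0:
        return ModelFit(empty, None, False, n, 0, reason="no events in stratum")
    _check_rank(X, labels)

    beta = np.zeros(p)
    eta = X @ beta
    mu = np.exp(eta)
    loglik = float(y @ eta - mu.sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = mu
        info = X.T @ (X * W[:, None])
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return ModelFit(empty, None, False, n, int(y.sum()),
                            n_iter=it, reason="singular information matrix")
        step = 1.0
        ll_slack = 1e-10 * (abs(loglik) + 1.0)
        for _ in range(30):  # step-halving on likelihood decrease
            cand = beta + step * delta
            eta_c = X @ cand
            mu_c = np.exp(np.clip(eta_c, -500, 500))
            ll_c = float(y @ eta_c - mu_c.sum())
            if np.isfinite(ll_c) and ll_c >= loglik - ll_slack:
                break
            step *= 0.5
        else:
            return ModelFit(pd.Series(beta, index=labels), None, False, n, int(y.sum()),
                            n_iter=it, reason="divergence: no likelihood-improving step")
        change = float(np.max(np.abs(cand - beta)))
        ll_change = abs(ll_c - loglik)
        beta, eta, mu, loglik = cand, eta_c, mu_c, ll_c
        # coefficient-change criterion, with a likelihood-change fallback for
        # infinite MLEs in nuisance columns (e.g. zero events in a rare group)
        if change < tol or ll_change < 1e-13 * (abs(loglik) + 1.0):
            converged = True
            break
    if not converged:
        return ModelFit(pd.Series(beta, index=labels), None, False, n, int(y.sum()),
                        n_iter=it, reason="maximum iterations reached")

    A = X.T @ (X * mu[:, None])
    resid2 = (y - mu) ** 2
    B = X.T @ (X * resid2[:, None])
    A_inv = np.linalg.inv(A)
    robust = A_inv @ B @ A_inv
    return ModelFit(
        params=pd.Series(beta, index=labels),
        robust_vcov=pd.DataFrame(robust, index=labels, columns=labels),
        model_vcov=pd.DataFrame(A_inv, index=labels, columns=labels),
        converged=True,
        n_obs=n,
        n_events=int(y.sum()),
        n_iter=it,
    )


def filter_stratum(cohort: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Subset the cohort to one analysis stratum (sex or enrollment-age band)."""
    if stratum == "overall":
        return cohort
    if stratum in ("female", "male"):
        return cohort.loc[cohort["sex"] == stratum]
    if stratum in AGE_BANDS:
        lo, hi = AGE_BANDS[stratum]
        age = cohort["enrollment_age_years"]
        return cohort.loc[(age >= lo) & (age < hi)]
    raise ValueError(f"unknown stratum {stratum!r}")


def build_design(
    cohort: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Outcome vector and design matrix with deterministic column ordering.

    Columns: intercept, exposure indicators, enrollment age (linear), sex
    indicator (omitted in sex strata), clinical-site dummies (reference =
    lexicographically first site; the block is dropped with a note when the
    stratum has a single site), and maximum observation length in years.
    Returns (y, X, labels, notes).
    """
    outcome_col = {"ehr": "ehr_chd", "self_report": "sr_chd", "combined": "combined_chd"}[
        spec.outcome
    ]
    y = cohort[outcome_col].astype(bool).to_numpy().astype(float)
    n = len(cohort)
    cols, labels, notes = [np.ones(n)], ["intercept"], []
    for exp_name in spec.exposures:
        cols.append(cohort[exp_name].astype(bool).to_numpy().astype(float))
        labels.append(exp_name)
    cols.append(cohort["enrollment_age_years"].to_numpy(dtype=float))
    labels.append("enrollment_age_years")
    if spec.stratum not in ("female", "male"):
        cols.append((cohort["sex"] == "male").to_numpy().astype(float))
        labels.append("sex_male")
    sites = sorted(cohort["site"].unique())
    if len(sites) > 1:
        for site in sites[1:]:
            cols.append((cohort["site"] == site).to_numpy().astype(float))
            labels.append(f"site[{site}]")
    else:
        notes.append("single site level in stratum; site block dropped")
    cols.append(cohort["obs_years"].to_numpy(dtype=float))
    labels.append("obs_years")
    return y, np.column_stack(cols), labels, notes


def wald_effects(fit: ModelFit, exposures: Sequence[str] = EXPOSURES) -> pd.DataFrame:
    """Exponentiated effects with Wald 95% CIs and two-sided normal p-values."""
    if not fit.converged:
        raise ValueError(f"cannot compute effects from a non-converged fit ({fit.reason})")
    rows = []
    se = fit.robust_se()
    for name in exposures:
        b, s = fit.params[name], se[name]
        rows.append(
            {
                "exposure": name,
                "estimate": float(np.exp(b)),
                "lower95": float(np.exp(b - Z_95 * s)),
                "upper95": float(np.exp(b + Z_95 * s)),
                "p_value": float(2 * stats.norm.sf(abs(b) / s)),
            }
        )
    return pd.DataFrame(rows)


def rr_analysis(
    cohort: pd.DataFrame,
    outcomes: Sequence[str] = ("ehr", "self_report", "combined"),
    strata: Sequence[str] = STRATA,
) -> pd.DataFrame:
    """Tidy RR table over case definitions × strata × exposures.

    ``cohort`` needs columns ehr_chd, sr_chd (nullable), combined_chd,
    monogenic, high_prs, sex, site, enrollment_age_years, obs_years.
    Self-report models are restricted to survey completers. Strata whose
    model does not converge (e.g. too few cases) appear with NaN estimates
    and converged=False.
    """
    rows = []
    for outcome in outcomes:
        data = cohort
        if outcome == "self_report":
            data = cohort.loc[cohort["sr_chd"].notna()]
        for stratum in strata:
            sub = filter_stratum(data, stratum)
            spec = ModelSpec(outcome=outcome, stratum=stratum)
            base = {"outcome": outcome, "stratum": stratum, "n": len(sub)}
            if sub.empty:
                for exp_name in spec.exposures:
                    rows.append({**base, "exposure": exp_name, "converged": False,
                                 "reason": "empty stratum"})
                continue
            y, X, labels, _ = build_design(sub, spec)
            try:
                fit = fit_modified_poisson(y, X, labels)
            except ValueError as err:
                # e.g. an exposure with no carriers in the stratum
                for exp_name in spec.exposures:
                    rows.append({**base, "exposure": exp_name, "converged": False,
                                 "reason": str(err)})
                continue
            base["events"] = fit.n_events
            if fit.converged:
                for _, eff in wald_effects(fit, spec.exposures).iterrows():
                    rows.append(
                        {**base, "exposure": eff["exposure"], "rr": eff["estimate"],
                         "lower95": eff["lower95"], "upper95": eff["upper95"],
                         "p_value": eff["p_value"], "converged": True, "reason": ""}
                    )
            else:
                for exp_name in spec.exposures:
                    rows.append({**base, "exposure": exp_name, "converged": False,
                                 "reason": fit.reason})
    return pd.DataFrame(rows)


def format_rr_table(tidy: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Wide report table: rows = strata, columns = outcome × exposure.

    Non-converged cells print as "N/A".
    """
    def cell(row):
        if not row.get("converged", False) or pd.isna(row.get("rr", np.nan)):
            return "N/A"
        return (f"{row['rr']:.{ndigits}f} "
                f"[{row['lower95']:.{ndigits}f}, {row['upper95']:.{ndigits}f}]")

    tidy = tidy.copy()
    tidy["cell"] = tidy.apply(cell, axis=1)
    wide = tidy.pivot(index="stratum", columns=["outcome", "exposure"], values="cell")
    order = [s for s in STRATA if s in wide.index]
    return wide.loc[order]
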