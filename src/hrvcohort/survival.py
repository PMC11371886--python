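"""Standardized association and survival models.

Association models are per-marker multivariable linear regressions with the
standardized marker (divided by its sample SD) as the dependent variable.
Survival models are Cox proportional-hazards fits reporting per-SD hazard
ratios with Wald confidence intervals, under configurable adjustment tiers
(age + sex, or the full set of cardiovascular risk factors, comorbidities,
and medication classes). Cumulative incidence curves are 1 - Kaplan-Meier
per stratum.

The Cox partial likelihood is maximised in-package by Newton-Raphson with
Breslow tie handling (Efron available behind a flag); linear models go
through statsmodels OLS and Kaplan-Meier through lifelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "AdjustmentSet",
    "CoxPH",
    "CoxPHResults",
    "LinearFitResults",
    "standardize_columns",
    "cox_fit",
    "linear_fit",
    "cumulative_incidence",
    "run_model_battery",
]

Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class AdjustmentSet:
    """Named covariate tier for the model batteries; age and sex are always in."""

    tier: str  # "age_sex" | "full"
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = {"age", "sex"} - set(self.covariates)
        if missing:
            raise ValueError(f"adjustment set must contain age and sex; missing {missing}")


def standardize_columns(X) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each column by its sample SD (no centering).

    Returns the scaled matrix and the SDs for back-transformation. Centering
    is deliberately omitted: it does not affect Cox fits or slope terms, and
    the scaled values keep their original sign and zero.
    """
    df = pd.DataFrame(X).copy()
    sds = df.std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero-SD column(s): {list(zero.index)}")
    return df / sds, sds


# ---------------------------------------------------------------------------
# Cox proportional hazards


class ConvergenceWarning(UserWarning):
    pass


class CoxPH:
    """Cox proportional-hazards model maximised by Newton-Raphson.

    Breslow tie handling by default ("efron" behind the flag). Convergence
    when the score norm drops below ``tol`` (default 1e-9) within
    ``max_iter`` iterations; monotone-likelihood separation is flagged when
    any coefficient exceeds 20 in absolute value.
    """

    def __init__(self, time, event, X, names=None, ties="breslow"):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and len(np.asarray(time)) > 1:
            X = X.T
        self.X = X
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if self.event.sum() < 1:
            raise ValueError("Cox model needs at least one event")
        if np.isnan(self.X).any():
            raise ValueError("X must not contain missing values")
        self.names = list(names) if names is not None else [
            f"x{j}" for j in range(self.X.shape[1])
        ]
        if ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        self.ties = ties

    def _loglik_score_info(self, beta: np.ndarray):
        order = np.argsort(self.time, kind="mergesort")
        t = self.time[order]
        e = self.event[order]
        x = self.X[order]
        n, p = x.shape
        eta = x @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        # reversed cumulative sums: risk set of an event is everyone with t >= t_i
        c0 = np.cumsum(w[::-1])[::-1]
        c1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
        xx = x[:, :, None] * x[:, None, :]
        c2 = np.cumsum((w[:, None, None] * xx)[::-1], axis=0)[::-1]
        first = np.searchsorted(t, t, side="left")  # tie-group start
        ev = e.astype(bool)
        if self.ties == "breslow":
            s0 = c0[first[ev]]
            s1 = c1[first[ev]]
            s2 = c2[first[ev]]
        else:  # efron: downweight tied deaths' own terms
            s0_list, s1_list, s2_list = [], [], []
            for i in np.nonzero(ev)[0]:
                fi = first[i]
                ties_idx = np.nonzero((t == t[i]) & ev)[0]
                d = len(ties_idx)
                rank = int(np.searchsorted(ties_idx, i))
                frac = rank / d
                wd = w[ties_idx].sum()
                s0_list.append(c0[fi] - frac * wd)
                s1_list.append(c1[fi] - frac * (w[ties_idx, None] * x[ties_idx]).sum(0))
                s2_list.append(
                    c2[fi] - frac * (w[ties_idx, None, None] * xx[ties_idx]).sum(0)
                )
            s0 = np.asarray(s0_list)
            s1 = np.asarray(s1_list)
            s2 = np.asarray(s2_list)
        loglik = float(np.sum(eta[ev]) - np.sum(np.log(s0)))
        mean1 = s1 / s0[:, None]
        score = np.sum(x[ev] - mean1, axis=0)
        info = np.sum(
            s2 / s0[:, None, None] - mean1[:, :, None] * mean1[:, None, :], axis=0
        )
        return loglik, score, info

    def fit(self, tol: float = 1e-9, max_iter: int = 50) -> "CoxPHResults":
        p = self.X.shape[1]
        beta = np.zeros(p)
        converged = False
        loglik = -np.inf
        for _ in range(max_iter):
            loglik, score, info = self._loglik_score_info(beta)
            if np.linalg.norm(score) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                warnings.warn("singular information matrix", ConvergenceWarning)
                break
            # halve steps that decrease the partial likelihood
            for _h in range(30):
                new_ll = self._loglik_score_info(beta + step)[0]
                if new_ll >= loglik - 1e-12:
                    break
                step /= 2.0
            beta = beta + step
            if np.any(np.abs(beta) > 20):
                warnings.warn(
                    "separation suspected (|beta| > 20)", ConvergenceWarning
                )
                break
        loglik, score, info = self._loglik_score_info(beta)
        if converged is False and np.linalg.norm(score) < tol:
            converged = True
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        return CoxPHResults(self, beta, cov, loglik, converged)


class CoxPHResults:
    """Fitted Cox model: coefficients, Wald inference, and a summary table."""

    def __init__(self, model: CoxPH, beta, cov, loglik, converged):
        self.model = model
        self.params = pd.Series(beta, index=model.names)
        self.cov = cov
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=model.names)
        self.loglik = float(loglik)
        self.converged = bool(converged)
        self.n = len(model.time)
        self.events = int(model.event.sum())

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"hr_lower": lo, "hr_upper": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "hr": self.hazard_ratios,
                "hr_lower": ci["hr_lower"],
                "hr_upper": ci["hr_upper"],
                "p": self.pvalues,
            }
        )


def cox_fit(X, time, event, ties: str = "breslow", names=None) -> CoxPHResults:
    """Fit a Cox model; see :class:`CoxPH`."""
    return CoxPH(time, event, X, names=names, ties=ties).fit()


# ---------------------------------------------------------------------------
# Linear association models


class LinearFitResults:
    """OLS fit of a standardized marker on the clinical profile."""

    def __init__(self, sm_results, names):
        self._res = sm_results
        self.params = pd.Series(sm_results.params, index=names)
        self.bse = pd.Series(sm_results.bse, index=names)
        self.pvalues = pd.Series(sm_results.pvalues, index=names)
        ci = sm_results.conf_int()
        self.conf_int = pd.DataFrame(
            np.asarray(ci), index=names, columns=["lower", "upper"]
        )
        self.resid = np.asarray(sm_results.resid)
        self.nobs = int(sm_results.nobs)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "ci_lower": self.conf_int["lower"],
                "ci_upper": self.conf_int["upper"],
                "p": self.pvalues,
            }
        )


def linear_fit(y, X, names=None) -> LinearFitResults:
    """Least-squares fit of y on X with an intercept.

    Raises on rank deficiency, listing the offending columns (identified by
    a pivoted QR of the design matrix).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    design = np.column_stack([np.ones(len(y)), X])
    all_names = ["intercept"] + names
    if len(y) <= design.shape[1]:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, r, piv = _qr_pivot(design)
        bad = [all_names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    res = sm.OLS(y, design).fit()
    return LinearFitResults(res, all_names)


def _qr_pivot(a):
    from scipy.linalg import qr

    q, r, piv = qr(a, pivoting=True)
    return q, r, piv


# ---------------------------------------------------------------------------
# Cumulative incidence


def cumulative_incidence(time, event, groups) -> dict[str, pd.DataFrame]:
    """1 - Kaplan-Meier per group, as step-function coordinates.

    Returns {group: DataFrame(time, cum_incidence)}. Empty groups are
    omitted with a warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups, dtype=object)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups[pd.notna(groups)]):
        mask = groups == g
        if not mask.any():
            warnings.warn(f"group {g!r} has no subjects; omitted")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "cum_incidence": 1.0 - sf.iloc[:, 0].to_numpy()}
        )
    return out


# ---------------------------------------------------------------------------
# Per-marker model battery


def run_model_battery(
    markers: pd.DataFrame,
    cohort: pd.DataFrame,
    adjustment: AdjustmentSet,
    outcome: str = "all_cause",
    time_col: str | None = None,
    event_col: str | None = None,
    predictor: str = "continuous",
    ranges: dict | None = None,
    max_missing_frac: float = 0.5,
    ties: str = "breslow",
) -> pd.DataFrame:
    """One standardized Cox fit per marker under one adjustment tier.

    ``predictor='continuous'`` divides each marker by its sample SD in the
    modelled sample, so the reported hazard ratio is per SD;
    ``predictor='out_of_range'`` uses a binary outside-reference-range
    indicator instead (``ranges`` maps marker name -> ReferenceRange).
    Markers missing for more than ``max_missing_frac`` of subjects are
    skipped with a warning. Returns a tidy table
    (marker, tier, outcome, hr, lo, hi, p, n, events, converged).
    """
    time_col = time_col or f"time_{outcome}"
    event_col = event_col or f"event_{outcome}"
    for col in (time_col, event_col):
        if col not in cohort:
            raise ValueError(f"cohort table lacks outcome column {col!r}")
    if pd.to_numeric(cohort[event_col], errors="coerce").fillna(0).sum() < 1:
        warnings.warn(f"no {outcome!r} events in the modelled sample; no fits")
        return pd.DataFrame(
            columns=["marker", "tier", "outcome", "predictor", "hr", "lo",
                     "hi", "p", "n", "events", "converged"]
        )
    rows = []
    marker_cols = [c for c in markers.columns if c != "record_id"]
    base = cohort.reset_index(drop=True)
    mk = markers.reset_index(drop=True)
    for marker in marker_cols:
        vals = pd.to_numeric(mk[marker], errors="coerce")
        if vals.isna().mean() > max_missing_frac:
            warnings.warn(f"marker {marker!r} missing for >50% of subjects; skipped")
            continue
        frame = pd.DataFrame({"marker": vals})
        for c in adjustment.covariates:
            frame[c] = pd.to_numeric(base[c], errors="coerce")
        frame["_t"] = base[time_col]
        frame["_e"] = base[event_col]
        frame = frame.dropna()
        if predictor == "continuous":
            sd = frame["marker"].std(ddof=1)
            if sd == 0:
                warnings.warn(f"marker {marker!r} constant in modelled sample; skipped")
                continue
            frame["marker"] = frame["marker"] / sd
        elif predictor == "out_of_range":
            if ranges is None or marker not in ranges:
                warnings.warn(f"no reference range for {marker!r}; skipped")
                continue
            rng = ranges[marker]
            frame["marker"] = (
                (frame["marker"] < rng.lower) | (frame["marker"] > rng.upper)
            ).astype(float)
            if frame["marker"].nunique() < 2:
                warnings.warn(f"out-of-range indicator constant for {marker!r}; skipped")
                continue
        else:
            raise ValueError("predictor must be 'continuous' or 'out_of_range'")
        X = frame[["marker"] + list(adjustment.covariates)]
        res = cox_fit(X, frame["_t"].to_numpy(), frame["_e"].to_numpy(), ties=ties)
        ci = res.conf_int()
        rows.append(
            {
                "marker": marker,
                "tier": adjustment.tier,
                "outcome": outcome,
                "predictor": predictor,
                "hr": float(res.hazard_ratios["marker"]),
                "lo": float(ci.loc["marker", "hr_lower"]),
                "hi": float(ci.loc["marker", "hr_upper"]),
                "p": float(res.pvalues["marker"]),
                "n": res.n,
                "events": res.events,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)
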