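"""Cohort-level statistics: paired tests, Kaplan-Meier, log-rank, Cox.

All tests are two-sided and reported with raw (unadjusted) p-values; the
report counts the tests performed so users can adjust for multiplicity
post hoc.  Conventions mirror common clinical-statistics software
defaults: Breslow tie handling in Cox regression (Efron available),
zero differences dropped in the Wilcoxon signed-rank test (Pratt mode
available), and chi-square without continuity correction (Yates flag
available).

Survival endpoints are progression-free survival (PFS: treatment start
to progression or death) and overall survival (OS: treatment start to
death); times are in months and censoring is right censoring.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "KMCurve",
    "CoxFit",
    "AnalysisPlan",
    "chi_square_2x2",
    "wilcoxon_signed_rank",
    "km_fit",
    "logrank",
    "cox_fit",
    "analyze_cohort",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (two-sided p)."""

    name: str
    statistic: float
    df: int | None
    p: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value out of range: {self.p}")


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate for one group.

    ``median`` is the smallest time with S(t) <= 0.5 and is ``inf`` when
    the curve never reaches 0.5.  The median confidence interval inverts
    the survival-function confidence band (Brookmeyer-Crowley-type).
    ``greenwood_var`` is Greenwood's variance of S(t) at each time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int
    n_events: int

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if s.size and (np.any(np.diff(s) > 1e-12) or s[0] > 1.0 + 1e-12):
            raise ValueError("survival must start at <= 1 and be nonincreasing")

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary.

    ``table`` has one row per covariate: coef, hr, ci_low, ci_high, p.
    """

    table: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    ties: str
    converged: bool
    flagged: bool = False  # monotone likelihood / separation suspicion

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def chi_square_2x2(table, *, correction: bool = False) -> TestResult:
    """Pearson chi-square test on a 2x2 contingency table (df = 1).

    ``correction`` applies the Yates continuity correction.  All row and
    column marginals must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all row and column marginals must be positive")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=correction)
    return TestResult("chi_square_2x2", float(stat), int(dof), float(p), int(t.sum()))


def wilcoxon_signed_rank(
    d1, d8, *, zero_method: str = "drop", exact_limit: int = 25
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired counts.

    Zero differences are dropped by default (``zero_method="pratt"``
    keeps them in the ranking).  The exact null distribution is used for
    up to ``exact_limit`` nonzero untied pairs; larger or tied samples
    use the normal approximation with tie correction.  All differences
    zero yields p = 1 with a warning.
    """
    x = np.asarray(d1, dtype=float)
    y = np.asarray(d8, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult("wilcoxon_signed_rank", 0.0, None, 1.0, int(x.size))

    scipy_zero = {"drop": "wilcox", "pratt": "pratt"}[zero_method]
    sample = diffs if zero_method == "pratt" else nonzero
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    if nonzero.size <= exact_limit and not has_ties and zero_method == "drop":
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(sample, zero_method=scipy_zero, method=method, correction=False)
    return TestResult(
        "wilcoxon_signed_rank", float(res.statistic), None, float(res.pvalue), int(x.size)
    )


def km_fit(time_months, event, *, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group."""
    t = np.asarray(time_months, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("at least one record required")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, e)

    table = kmf.event_table  # index: times (incl. 0); removed/observed/at_risk
    times = table.index.to_numpy(dtype=float)
    sf = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)

    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    d = table["observed"].to_numpy(dtype=float)
    n_at = at_risk
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at - d > 0, d / (n_at * (n_at - d)), 0.0)
    greenwood = sf**2 * np.cumsum(terms)

    median = float(kmf.median_survival_time_)
    ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
    return KMCurve(
        times=times,
        survival=sf,
        at_risk=at_risk,
        greenwood_var=greenwood,
        median=median,
        median_ci=(lo, hi),
        n=int(t.size),
        n_events=int(e.sum()),
    )


def logrank(time_months, event, group) -> TestResult:
    """Two-sided log-rank test between two groups (df = 1)."""
    t = np.asarray(time_months, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {levels.size}")
    a = g == levels[0]
    res = logrank_test(t[a], t[~a], event_observed_A=e[a], event_observed_B=e[~a])
    return TestResult("logrank", float(res.test_statistic), 1, float(res.p_value), int(t.size))


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    *,
    time_col: str = "time_months",
    event_col: str = "event",
    ties: str = "breslow",
    alpha: float = 0.05,
) -> CoxFit:
    """Cox proportional-hazards regression by partial-likelihood Newton steps.

    Ties are handled by the Breslow approximation by default (Efron
    available via ``ties="efron"``).  Wald confidence intervals and
    p-values per covariate.  Degenerate design matrices (constant or
    collinear covariates, fewer than two events) raise; suspected
    monotone likelihood (complete separation) warns and flags the fit.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unsupported ties method {ties!r}")
    X = records[list(covariates)].to_numpy(dtype=float)
    t = records[time_col].to_numpy(dtype=float)
    e = records[event_col].to_numpy(dtype=int)
    if e.sum() < 2:
        raise ValueError(f"need at least 2 events, got {int(e.sum())}")
    if np.any(X.std(axis=0) == 0):
        const = [c for c, s in zip(covariates, X.std(axis=0)) if s == 0]
        raise ValueError(f"constant covariate(s): {const}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates")

    model = PHReg(t, X, status=e, ties=ties)
    with warnings.catch_warnings():
        # convergence is re-checked below via the score norm; separation
        # is reported through the `flagged` field instead of a warning storm
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)

    grad = np.asarray(model.score(params))
    converged = bool(np.linalg.norm(grad) < 1e-4 * max(1, e.sum()))
    if not converged:
        raise RuntimeError(
            f"Cox fit did not converge: |score| = {np.linalg.norm(grad):.3g} at {params}"
        )
    flagged = bool(np.any(np.abs(params) > 15) or np.any(bse > 100))
    if flagged:
        warnings.warn(
            "possible monotone partial likelihood (complete separation); "
            "coefficients unreliable",
            stacklevel=2,
        )

    z = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(over="ignore"):  # separated fits legitimately give inf CI
        table = pd.DataFrame(
            {
                "coef": params,
                "hr": np.exp(params),
                "ci_low": np.exp(params - z * bse),
                "ci_high": np.exp(params + z * bse),
                "se": bse,
                "p": 2 * stats.norm.sf(np.abs(params / bse)),
            },
            index=list(covariates),
        )
    return CoxFit(
        table=table,
        log_likelihood=float(model.loglike(params)),
        n=int(len(t)),
        n_events=int(e.sum()),
        ties=ties,
        converged=converged,
        flagged=flagged,
    )


@dataclass(frozen=True)
class AnalysisPlan:
    """What to compute in :func:`analyze_cohort`.

    One KM pair + log-rank per flag per endpoint; one univariate Cox per
    covariate per endpoint; one multivariate Cox per endpoint over
    ``multivariate`` (skipped when empty).
    """

    endpoints: tuple = ("OS",)
    flags: tuple = ("has_cluster", "has_cluster_mctc", "has_cluster_pdl1pos_mctc")
    univariate: tuple = ("has_cluster", "has_cluster_mctc", "has_cluster_pdl1pos_mctc")
    multivariate: tuple = ()
    ties: str = "breslow"

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisPlan":
        known = {"endpoints", "flags", "univariate", "multivariate", "ties"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown analysis plan keys: {sorted(unknown)}")
        kwargs = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in d.items()}
        return cls(**kwargs)


def _km_summary(curve: KMCurve) -> dict:
    def _num(v):
        return None if not np.isfinite(v) else float(v)

    return {
        "n": curve.n,
        "n_events": curve.n_events,
        "median_months": _num(curve.median),
        "median_ci": [_num(curve.median_ci[0]), _num(curve.median_ci[1])],
    }


def analyze_cohort(
    profiles: pd.DataFrame,
    survival: pd.DataFrame,
    plan: AnalysisPlan | None = None,
) -> dict:
    """Run the full survival-association analysis of a cohort.

    ``profiles`` carries ``patient_id`` plus boolean subpopulation flag
    columns; ``survival`` is long-format with ``patient_id``,
    ``endpoint``, ``time_months``, ``event``.  Every profile patient must
    join a survival record for each analyzed endpoint (orphans raise).
    Flags with no positive (or no negative) patients are skipped with a
    warning.  P-values are raw; ``n_tests`` counts tests performed.
    """
    plan = plan or AnalysisPlan()
    report: dict = {"endpoints": {}, "skipped": [], "n_tests": 0}

    for endpoint in plan.endpoints:
        surv = survival.loc[survival["endpoint"] == endpoint]
        merged = profiles.merge(surv, on="patient_id", how="left", validate="one_to_one")
        orphans = merged.loc[merged["time_months"].isna(), "patient_id"].tolist()
        if orphans:
            raise ValueError(
                f"no {endpoint} survival record for patients: {orphans}"
            )
        section: dict = {"km_logrank": {}, "univariate_cox": {}, "multivariate_cox": None}

        for flag in plan.flags:
            g = merged[flag].astype(bool)
            if g.all() or not g.any():
                msg = f"{endpoint}/{flag}: single-group flag, analysis skipped"
                logger.warning(msg)
                report["skipped"].append(msg)
                continue
            lr = logrank(merged["time_months"], merged["event"], g)
            report["n_tests"] += 1
            section["km_logrank"][flag] = {
                "logrank_statistic": lr.statistic,
                "logrank_p": lr.p,
                "positive": _km_summary(
                    km_fit(merged.loc[g, "time_months"], merged.loc[g, "event"])
                ),
                "negative": _km_summary(
                    km_fit(merged.loc[~g, "time_months"], merged.loc[~g, "event"])
                ),
            }

        for cov in plan.univariate:
            vals = merged[cov].astype(float)
            if vals.nunique() < 2:
                msg = f"{endpoint}/{cov}: constant covariate, Cox skipped"
                logger.warning(msg)
                report["skipped"].append(msg)
                continue
            try:
                fit = cox_fit(merged.assign(**{cov: vals}), [cov], ties=plan.ties)
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                msg = f"{endpoint}/{cov}: Cox fit failed ({exc}), skipped"
                logger.warning(msg)
                report["skipped"].append(msg)
                continue
            report["n_tests"] += 1
            row = fit.table.loc[cov]
            section["univariate_cox"][cov] = {
                "hr": float(row["hr"]),
                "ci": [float(row["ci_low"]), float(row["ci_high"])],
                "p": float(row["p"]),
                "flagged": fit.flagged,
            }

        if plan.multivariate:
            usable = [c for c in plan.multivariate if merged[c].astype(float).nunique() > 1]
            dropped = sorted(set(plan.multivariate) - set(usable))
            if dropped:
                msg = f"{endpoint}: constant covariates dropped from multivariate: {dropped}"
                logger.warning(msg)
                report["skipped"].append(msg)
            if len(usable) >= 1:
                try:
                    fit = cox_fit(merged, usable, ties=plan.ties)
                except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                    msg = f"{endpoint}: multivariate Cox failed ({exc}), skipped"
                    logger.warning(msg)
                    report["skipped"].append(msg)
                    report["endpoints"][endpoint] = section
                    continue
                report["n_tests"] += len(usable)
                section["multivariate_cox"] = {
                    "covariates": usable,
                    "table": {
                        c: {
                            "hr": float(fit.table.loc[c, "hr"]),
                            "ci": [
                                float(fit.table.loc[c, "ci_low"]),
                                float(fit.table.loc[c, "ci_high"]),
                            ],
                            "p": float(fit.table.loc[c, "p"]),
                        }
                        for c in usable
                    },
                    "flagged": fit.flagged,
                }
        report["endpoints"][endpoint] = section
    return report


def report_to_json(report: dict, path) -> None:
    """Serialize an analysis report to JSON (stable key order)."""
    from pathlib import Path

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
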