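"""Association, variance-explained, contingency, ANOVA and survival
statistics for the PRS analyses.

Linear models report the adjusted R²
``1 - (1 - R²)(n - 1)/(n - p - 1)``; logistic models report Nagelkerke's
pseudo-R² ``[1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)]``. Coefficient p-values
are two-sided t (linear) or Wald z (logistic) tests for the score term.
The per-cutoff scan fits one model per P_T cutoff and reports the
maximum variance explained without multiplicity correction; the
three-group diagnosis analysis codes HC=0, FR=1, SCZ=2 as a linear
trend. Survival comparisons use the Kaplan-Meier product-limit estimate
and the k-group log-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AssocResult", "fit_linear", "fit_logistic", "scan_thresholds",
    "group_trend", "interaction_test", "pearson_chi2",
    "anova_from_summaries", "km_logrank", "late_initiation_rates",
    "code_groups", "SurvivalSummary",
]

GROUP_CODE = {"HC": 0, "FR": 1, "SCZ": 2}


@dataclass
class AssocResult:
    """One fitted model at one P_T cutoff."""

    threshold: float | None
    coefficient: float
    variance_explained: float
    p_value: float
    model: str                      # "linear" | "logistic"
    n: int
    covariates: tuple = ()
    se: float = float("nan")
    extra: dict = field(default_factory=dict)


def code_groups(groups: Sequence[str]) -> np.ndarray:
    """HC=0, FR=1, SCZ=2 equidistant ordinal coding."""
    try:
        return np.array([GROUP_CODE[g] for g in groups], dtype=float)
    except KeyError as e:
        raise ValueError(f"unknown group label {e.args[0]!r}") from None


def _design(predictors: pd.DataFrame) -> pd.DataFrame:
    X = predictors.copy()
    for col in X.columns:
        if X[col].dtype == object or isinstance(X[col].dtype, pd.CategoricalDtype):
            vals = pd.unique(X[col].dropna())
            if set(vals) <= {"M", "F"}:
                X[col] = (X[col] == "M").astype(float)
            else:
                raise ValueError(f"non-numeric predictor {col!r}")
    X = X.astype(float)
    return sm.add_constant(X, has_constant="add")


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        tol = max(arr.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1)
        bad = [X.columns[i] for i in np.where(diag < max(tol, 1e-10))[0]]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def fit_linear(y, predictors: pd.DataFrame, term: str | None = None,
               threshold: float | None = None) -> AssocResult:
    """OLS with adjusted R² and a two-sided t-test for ``term``.

    ``term`` defaults to the first predictor column (the score).
    """
    y = np.asarray(y, dtype=float)
    X = _design(predictors)
    n, p = len(y), X.shape[1] - 1
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors")
    _check_full_rank(X)
    term = term or predictors.columns[0]
    fit = sm.OLS(y, X).fit()
    adj = 1.0 - (1.0 - fit.rsquared) * (n - 1) / (n - p - 1)
    return AssocResult(threshold=threshold,
                       coefficient=float(fit.params[term]),
                       variance_explained=float(adj),
                       p_value=float(fit.pvalues[term]),
                       model="linear", n=n,
                       covariates=tuple(c for c in predictors.columns
                                        if c != term),
                       se=float(fit.bse[term]),
                       extra={"r_squared": float(fit.rsquared)})


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke rescaling of the Cox-Snell likelihood-ratio R²."""
    cox_snell = 1.0 - math.exp(2.0 * (llnull - llf) / n)
    denom = 1.0 - math.exp(2.0 * llnull / n)
    if denom <= 0:
        return 0.0
    return float(min(1.0, max(0.0, cox_snell / denom)))


def fit_logistic(y, predictors: pd.DataFrame, term: str | None = None,
                 threshold: float | None = None) -> AssocResult:
    """Maximum-likelihood logistic fit with Nagelkerke pseudo-R².

    Raises on a single-class outcome, rank deficiency, or complete
    separation (diverging coefficients).
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    term = term or predictors.columns[0]
    # a constant lone score column collapses the model to the null
    if predictors.shape[1] == 1 and np.std(predictors[term].to_numpy(float)) == 0:
        return AssocResult(threshold=threshold, coefficient=0.0,
                           variance_explained=0.0, p_value=1.0,
                           model="logistic", n=len(y),
                           extra={"degenerate": True})
    X = _design(predictors)
    _check_full_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as e:  # statsmodels PerfectSeparationError etc.
            raise ValueError(f"logistic fit failed: {e}") from e
    if not np.all(np.isfinite(fit.params)) or np.abs(fit.params).max() > 1e3:
        raise ValueError("diverging logistic fit (complete separation?)")
    r2 = nagelkerke_r2(fit.llf, fit.llnull, len(y))
    return AssocResult(threshold=threshold,
                       coefficient=float(fit.params[term]),
                       variance_explained=r2,
                       p_value=float(fit.pvalues[term]),
                       model="logistic", n=len(y),
                       covariates=tuple(c for c in predictors.columns
                                        if c != term),
                       se=float(fit.bse[term]),
                       extra={"llf": float(fit.llf),
                              "llnull": float(fit.llnull)})


def results_table(results: Sequence[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "threshold": r.threshold, "coefficient": r.coefficient,
        "se": r.se, "variance_explained": r.variance_explained,
        "p_value": r.p_value, "model": r.model, "n": r.n,
        "covariates": ",".join(r.covariates),
    } for r in results])


def scan_thresholds(profile, y, covariates: pd.DataFrame | None = None,
                    model: str = "linear"):
    """One fit per P_T cutoff; returns ``(results, best)``.

    ``best`` is the cutoff with maximum variance explained (first such on
    ties). Cutoff p-values are deliberately not corrected for the scan.
    """
    if model not in ("linear", "logistic"):
        raise ValueError("model must be 'linear' or 'logistic'")
    y = np.asarray(y, dtype=float)
    if len(y) != len(profile.samples):
        raise ValueError("outcome is not aligned with the profile samples")
    if covariates is not None and len(covariates) != len(y):
        raise ValueError("covariates are not aligned with the profile samples")
    fitter = fit_linear if model == "linear" else fit_logistic
    results = []
    for k, cutoff in enumerate(profile.cutoffs):
        prs = profile.scores[:, k]
        pred = pd.DataFrame({"prs": prs})
        if covariates is not None:
            pred = pd.concat([pred, covariates.reset_index(drop=True)], axis=1)
        if np.std(prs) == 0:
            results.append(AssocResult(cutoff, 0.0, 0.0, 1.0, model, len(y),
                                       tuple(covariates.columns) if covariates
                                       is not None else (),
                                       extra={"degenerate": True}))
            continue
        results.append(fitter(y, pred, term="prs", threshold=cutoff))
    best = max(results, key=lambda r: r.variance_explained)
    return results, best


def group_trend(scores: np.ndarray, groups: Sequence[str],
                covariates: pd.DataFrame | None = None):
    """Linear trend of diagnosis (HC=0, FR=1, SCZ=2) on the score.

    Returns ``(AssocResult, per-group summary)`` where the summary holds
    each group's n, mean and quartiles of the score (box-plot numbers).
    """
    groups = list(groups)
    if len(set(groups)) < 2:
        raise ValueError("at least two groups required")
    y = code_groups(groups)
    pred = pd.DataFrame({"prs": np.asarray(scores, dtype=float)})
    if covariates is not None:
        pred = pd.concat([pred, covariates.reset_index(drop=True)], axis=1)
    if np.std(pred["prs"]) == 0:
        res = AssocResult(None, 0.0, 0.0, 1.0, "linear", len(y),
                          extra={"degenerate": True})
    else:
        res = fit_linear(y, pred, term="prs")
    df = pd.DataFrame({"group": groups, "score": scores})
    summary = (df.groupby("group", sort=False)["score"]
                 .agg(n="size", mean="mean",
                      q1=lambda s: s.quantile(0.25), median="median",
                      q3=lambda s: s.quantile(0.75))
                 .reset_index())
    return res, summary


def interaction_test(prs: np.ndarray, smoking_status: np.ndarray,
                     diagnosis: np.ndarray) -> float:
    """Wald p of the PRS x ever/never product term on binary diagnosis."""
    prs = np.asarray(prs, dtype=float)
    status = np.asarray(smoking_status, dtype=float)
    diag = np.asarray(diagnosis, dtype=float)
    for name, v in (("smoking status", status), ("diagnosis", diag)):
        if len(np.unique(v)) < 2:
            raise ValueError(f"{name} has a single level")
    pred = pd.DataFrame({"prs": prs, "status": status,
                         "prs_x_status": prs * status})
    res = fit_logistic(diag, pred, term="prs_x_status")
    return res.p_value


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson χ² of independence on an r x c count table.

    Returns ``(statistic, df, p)``; no continuity correction.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(dof), float(p)


def anova_from_summaries(groups: Sequence[tuple]) -> tuple[float, int, int, float]:
    """One-way ANOVA from per-group ``(n, mean, sd)`` triples.

    Between-group SS from n(mean - grand mean)²; within-group SS from
    (n-1)sd². Returns ``(F, df_between, df_within, p)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(sds < 0):
        raise ValueError("negative standard deviation")
    n_tot = ns.sum()
    grand = float((ns * means).sum() / n_tot)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    dfb = len(groups) - 1
    dfw = int(n_tot) - len(groups)
    if ssw == 0:
        return (math.inf if ssb > 0 else 0.0), dfb, dfw, (0.0 if ssb > 0 else 1.0)
    f = (ssb / dfb) / (ssw / dfw)
    return float(f), dfb, dfw, float(sps.f.sf(f, dfb, dfw))


@dataclass
class SurvivalSummary:
    """Kaplan-Meier curves per group plus the k-group log-rank test."""

    curves: dict               # group -> DataFrame(time, at_risk, events, survival)
    statistic: float | None
    df: int | None
    p_value: float | None
    test_error: str | None = None


def km_logrank(time, event, group) -> SurvivalSummary:
    """Kaplan-Meier estimate per group and the log-rank comparison.

    ``event`` False means the time is a censoring age. With no events at
    all the curves are still returned and the test is flagged as
    undefined rather than raised.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    labels = pd.unique(group)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    curves = {}
    for g in labels:
        m = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event_observed=event[m])
        tbl = kmf.event_table
        curves[str(g)] = pd.DataFrame({
            "time": tbl.index.to_numpy(dtype=float),
            "at_risk": tbl["at_risk"].to_numpy(dtype=int),
            "events": tbl["observed"].to_numpy(dtype=int),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
        })
    if not event.any():
        return SurvivalSummary(curves, None, None, None,
                               test_error="all observations censored")
    res = multivariate_logrank_test(time, group, event)
    return SurvivalSummary(curves, float(res.test_statistic),
                           int(len(labels) - 1), float(res.p_value))


def late_initiation_rates(phenotypes: pd.DataFrame, cutoff_age: float = 20.0,
                          covariates: Sequence[str] = ("age", "sex")):
    """Per-group rate of smoking initiation after ``cutoff_age``.

    Among ever-smokers, the late-initiation indicator (initiation age
    strictly above the cutoff) is summarized per diagnostic group and
    tested with a logistic fit on the HC/FR/SCZ trend plus covariates.
    Returns ``(rates DataFrame, adjusted p or None, note)``.
    """
    ever = phenotypes[(phenotypes["ever_smoker"] == 1)
                      & phenotypes["age_initiation"].notna()].copy()
    rows = []
    for g in GROUP_CODE:
        sub = ever[ever["group"] == g]
        n = len(sub)
        late = int((sub["age_initiation"] > cutoff_age).sum())
        rows.append({"group": g, "n_ever": n, "n_late": late,
                     "proportion": late / n if n else np.nan,
                     "flag": "" if n else "no ever-smokers"})
    rates = pd.DataFrame(rows)
    late_all = (ever["age_initiation"] > cutoff_age).astype(float)
    note = None
    p = None
    if late_all.nunique() < 2:
        note = "degenerate: late-initiation indicator is constant"
    else:
        pred = pd.DataFrame({"group_trend": code_groups(ever["group"])})
        for c in covariates:
            pred[c] = ever[c].to_numpy()
        try:
            res = fit_logistic(late_all.to_numpy(), pred, term="group_trend")
            p = res.p_value
        except ValueError as e:
            note = str(e)
    return rates, p, note
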