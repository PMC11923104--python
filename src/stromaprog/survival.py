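"""Kaplan–Meier estimation, group comparisons, and Cox modelling.

The analysis skeleton: perioperative deaths (within 30 days of surgery) are
excluded; Kaplan–Meier curves with median overall survival and 95%
confidence intervals summarize each group; the log-rank test compares
survival distributions; covariates are screened by univariate Cox
proportional-hazards fits and every variable with p < 0.05 is carried
forward into a single multivariate Cox model, whose p < 0.05 survivors are
reported as independent predictors.  Baseline characteristics are compared
by the Mann–Whitney U test (continuous) and the chi-square or
linear-by-linear trend test (categorical).

Estimation is delegated to lifelines (Efron tie handling for Cox,
log(−log)-transformed confidence bands for the median).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SurvivalSummary:
    """Median OS with 95% CI, the KM curve, and optional test results."""

    median_os: float  # np.inf when the curve never reaches 0.5 ("not reached")
    median_ci: tuple[float, float]
    km_curve: pd.DataFrame  # columns: time, survival, at_risk
    n: int
    n_events: int
    logrank_p: float | None = None
    hr_table: pd.DataFrame | None = None

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median_os)


def filter_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Exclude perioperative mortality and incomplete survival records.

    Deaths within 30 days of surgery are removed — as ``os_days <= 30`` when
    a day-resolution column is present, otherwise ``os_months < 1``.
    Censored records of any length are kept.  Records missing time or event
    are dropped.  Removals are logged.
    """
    out = records.copy()
    n0 = len(out)
    missing = out["os_months"].isna() | out["event"].isna()
    out = out[~missing]
    if "os_days" in out.columns:
        peri = (out["event"] == 1) & (out["os_days"] <= 30)
    else:
        peri = (out["event"] == 1) & (out["os_months"] < 1)
    out = out[~peri]
    removed = n0 - len(out)
    if removed:
        logger.info(
            "filter_cohort: removed %d records (%d missing, %d perioperative deaths)",
            removed, int(missing.sum()), int(peri.sum()),
        )
    if len(out) == 0:
        raise ValueError("all records removed by filtering")
    return out.reset_index(drop=True)


def km_fit(times, events) -> SurvivalSummary:
    """Product-limit estimate with median OS and 95% CI.

    The median is the earliest time at which the survival estimate falls to
    0.5 or below; its confidence interval comes from the log(−log) survival
    band.  If the curve never reaches 0.5 the median is "not reached"
    (reported as inf).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf_vals = kmf.survival_function_.iloc[:, 0].to_numpy()
    sf_times = kmf.survival_function_.index.to_numpy(dtype=float)
    below = sf_vals <= 0.5 + 1e-12  # earliest time with survival <= 0.5
    median = float(sf_times[below][0]) if below.any() else float("inf")
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    sf = kmf.survival_function_
    curve = pd.DataFrame(
        {
            "time": sf.index.values,
            "survival": sf.iloc[:, 0].values,
            "at_risk": kmf.event_table["at_risk"].reindex(sf.index).values,
        }
    )
    return SurvivalSummary(
        median_os=median,
        median_ci=(lo, hi),
        km_curve=curve,
        n=len(times),
        n_events=int(events.sum()),
    )


def _cox_hr(df: pd.DataFrame, var: str) -> dict:
    """One univariate Cox fit; returns HR, CI, p for ``var``."""
    cph = CoxPHFitter()
    cph.fit(df[["os_months", "event", var]], "os_months", "event")
    s = cph.summary.loc[var]
    return {
        "variable": var,
        "hr": float(s["exp(coef)"]),
        "ci_low": float(s["exp(coef) lower 95%"]),
        "ci_high": float(s["exp(coef) upper 95%"]),
        "p": float(s["p"]),
    }


def compare_groups(records: pd.DataFrame, group_var: str) -> dict:
    """Per-group KM summaries, overall log-rank, and group-1 contrasts.

    Empty groups are dropped with a warning.  When the grouping is the
    combined risk group (values 1/2/3), univariate Cox hazard ratios for the
    contrasts 1 vs 2, 1 vs 3 and 1 vs others are included, mirroring the
    usual reporting of a three-group stratification.
    """
    df = records.copy()
    counts = df[group_var].value_counts()
    empty = [g for g in counts.index if counts[g] == 0]
    if empty:
        warnings.warn(f"dropping empty groups: {empty}")
    groups = [g for g in sorted(counts.index) if counts[g] > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    res = multivariate_logrank_test(df["os_months"], df[group_var], df["event"])
    out = {
        "logrank_chi2": float(res.test_statistic),
        "logrank_p": float(res.p_value),
        "groups": {},
    }
    for g in groups:
        sub = df[df[group_var] == g]
        out["groups"][g] = km_fit(sub["os_months"], sub["event"])
    contrasts = []
    for other in groups:
        if other == groups[0]:
            continue
        sub = df[df[group_var].isin([groups[0], other])].copy()
        sub["_is_ref"] = (sub[group_var] == groups[0]).astype(int)
        row = _cox_hr(sub, "_is_ref")
        row["variable"] = f"{groups[0]} vs {other}"
        contrasts.append(row)
    if len(groups) > 2:
        sub = df.copy()
        sub["_is_ref"] = (sub[group_var] == groups[0]).astype(int)
        row = _cox_hr(sub, "_is_ref")
        row["variable"] = f"{groups[0]} vs others"
        contrasts.append(row)
    out["hr_table"] = pd.DataFrame(contrasts)
    return out


def cox_univariate(records: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """One Cox proportional-hazards fit per variable (Efron ties).

    Categorical variables are dummy-coded against their first level.
    Non-converging or degenerate variables are flagged (``converged=False``)
    and excluded from downstream selection.
    """
    if records["event"].sum() < 1:
        raise ValueError("need at least one event")
    rows = []
    for var in variables:
        df = records[["os_months", "event", var]].dropna()
        x = df[var]
        if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(x, prefix=var, drop_first=True, dtype=float)
            df = pd.concat([df[["os_months", "event"]], dummies], axis=1)
            cols = list(dummies.columns)
        else:
            cols = [var]
        if any(df[c].nunique() < 2 for c in cols) or not cols:
            rows.append(
                {"variable": var, "source": var, "hr": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan, "converged": False}
            )
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, "os_months", "event")
        except Exception:
            rows.append(
                {"variable": var, "source": var, "hr": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan, "converged": False}
            )
            continue
        for c in cols:
            s = cph.summary.loc[c]
            rows.append(
                {
                    "variable": c,
                    "source": var,
                    "hr": float(s["exp(coef)"]),
                    "ci_low": float(s["exp(coef) lower 95%"]),
                    "ci_high": float(s["exp(coef) upper 95%"]),
                    "p": float(s["p"]),
                    "converged": True,
                }
            )
    return pd.DataFrame(rows)


def cox_multivariate(records: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Joint Cox fit on the selected variables with adjusted HRs.

    ``variables`` is typically the set that passed the univariate p < 0.05
    screen.  Variables retaining p < 0.05 in the joint model are marked as
    independent predictors.  Collinear selections surface as a diagnostic
    error rather than being silently regularized.
    """
    df = records[["os_months", "event"] + list(variables)].dropna()
    num = df[["os_months", "event"]].copy()
    for var in variables:
        x = df[var]
        if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
            num = pd.concat(
                [num, pd.get_dummies(x, prefix=var, drop_first=True, dtype=float)],
                axis=1,
            )
        else:
            num[var] = x.astype(float)
    covs = [c for c in num.columns if c not in ("os_months", "event")]
    mat = num[covs].to_numpy()
    if np.linalg.matrix_rank(np.c_[np.ones(len(mat)), mat]) <= len(covs):
        raise np.linalg.LinAlgError(
            "collinear covariate selection; remove redundant variables"
        )
    cph = CoxPHFitter()
    cph.fit(num, "os_months", "event")
    out = []
    for c in covs:
        s = cph.summary.loc[c]
        out.append(
            {
                "variable": c,
                "hr": float(s["exp(coef)"]),
                "ci_low": float(s["exp(coef) lower 95%"]),
                "ci_high": float(s["exp(coef) upper 95%"]),
                "p": float(s["p"]),
                "independent_predictor": bool(s["p"] < 0.05),
            }
        )
    return pd.DataFrame(out)


def group_baseline_tables(records: pd.DataFrame, group_var: str,
                          covariates: list[str] | None = None) -> pd.DataFrame:
    """Baseline characteristics compared across groups.

    Continuous covariates use the Mann–Whitney U test (two groups) or the
    Kruskal–Wallis rank test (more); unordered categoricals use the
    chi-square test; ordered categoricals use the linear-by-linear
    association (trend) test.  All-missing covariates are skipped with a
    warning.
    """
    groups = [g for g, n in records[group_var].value_counts().items() if n > 0]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if covariates is None:
        covariates = [
            c for c in records.columns
            if c not in (group_var, "patient_id", "os_months", "event")
        ]
    rows = []
    for cov in covariates:
        col = records[cov]
        if col.isna().all():
            warnings.warn(f"covariate {cov!r} all missing; skipped")
            continue
        by_group = [col[records[group_var] == g].dropna() for g in sorted(groups)]
        if col.dtype.kind in "fiu" and col.nunique() > 10:
            if len(by_group) == 2:
                stat, p = stats.mannwhitneyu(*by_group, alternative="two-sided")
                test = "mann-whitney"
            else:
                stat, p = stats.kruskal(*by_group)
                test = "kruskal-wallis"
            summary = "; ".join(
                f"{g}: {v.median():.3g} [{v.quantile(0.25):.3g}-{v.quantile(0.75):.3g}]"
                for g, v in zip(sorted(groups), by_group)
            )
        else:
            table = pd.crosstab(records[cov], records[group_var]).to_numpy()
            if isinstance(col.dtype, pd.CategoricalDtype) and col.cat.ordered:
                stat, p = _linear_by_linear(records, cov, group_var)
                test = "linear-by-linear"
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
                test = "chi-square"
            summary = "; ".join(
                f"{g}: n={len(v)}" for g, v in zip(sorted(groups), by_group)
            )
        rows.append({"covariate": cov, "test": test, "statistic": float(stat),
                     "p": float(p), "summary": summary})
    return pd.DataFrame(rows)


def _linear_by_linear(records: pd.DataFrame, cov: str, group_var: str):
    """Mantel–Haenszel trend statistic: (n−1)·r² on integer scores."""
    x = records[cov].cat.codes.to_numpy(dtype=float)
    g = pd.Categorical(records[group_var]).codes.astype(float)
    ok = (x >= 0) & (g >= 0)
    r = np.corrcoef(x[ok], g[ok])[0, 1]
    stat = (ok.sum() - 1) * r**2
    return stat, float(stats.chi2.sf(stat, df=1))


def plot_km(records: pd.DataFrame, group_var: str, ax=None):
    """Kaplan–Meier step plot per group (matplotlib axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g in sorted(records[group_var].unique()):
        sub = records[records[group_var] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_months"], sub["event"], label=str(g))
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("overall survival (months)")
    ax.set_ylabel("survival probability")
    return ax
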