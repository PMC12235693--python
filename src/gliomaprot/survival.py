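"""Survival association of protein abundance.

The clinical-validation route for candidate proteins: dichotomize abundance
at the cohort median into high/low expression groups, estimate Kaplan-Meier
curves and compare them with the log-rank test, and separately quantify the
per-unit-log2 hazard with univariable Cox proportional-hazards regression
(Efron handling of tied event times), reporting the hazard ratio with a 95%
Wald confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test


@dataclass
class CoxFit:
    beta: float          # log hazard per unit of x
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float             # two-sided Wald
    converged: bool
    n: int
    n_events: int


def median_dichotomize(abundance: pd.Series | np.ndarray) -> np.ndarray:
    """Split at the median: 'high' where value > median, 'low' otherwise
    (ties go to 'low'). Requires >= 4 samples and a non-degenerate split."""
    x = np.asarray(abundance, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples to dichotomize")
    med = np.median(x)
    labels = np.where(x > med, "high", "low")
    if len(set(labels)) < 2:
        raise ValueError("median split is degenerate (constant or all-tied values)")
    return labels


def km_estimate(time, event, groups) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per group.

    Returns per group a step-function table with columns time, survival,
    at_risk, events (the row at t=0 has survival 1).
    """
    df = pd.DataFrame({"time": time, "event": event, "group": groups})
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    out = {}
    for g, sub in df.groupby("group", sort=True):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        table = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        out[str(g)] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.to_numpy(dtype=float),
                "at_risk": table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
                "events": table["observed"].reindex(surv.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Log-rank chi-square statistic and p across >= 2 groups."""
    df = pd.DataFrame({"time": time, "event": event, "group": groups})
    if df["group"].nunique() < 2:
        raise ValueError("need at least two groups")
    if int(df["event"].sum()) == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_univariable(time, event, x, max_steps: int = 50) -> CoxFit:
    """Univariable Cox PH regression of the hazard on continuous x.

    Efron partial likelihood, Newton optimization; monotone-likelihood
    separation or failure to converge is reported via ``converged=False``
    (beta then carries the last iterate) rather than raised.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    df = pd.DataFrame({"time": np.asarray(time, float), "event": np.asarray(event, int), "x": x})
    if df["event"].sum() == 0:
        raise ValueError("no events observed")
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            try:
                cph.fit(df, duration_col="time", event_col="event")
            except UserWarning:
                converged = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return CoxFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False,
                      len(df), int(df["event"].sum()))
    s = cph.summary.loc["x"]
    beta, se = float(s["coef"]), float(s["se(coef)"])
    if not np.isfinite(beta) or abs(beta) > 20:
        converged = False
    return CoxFit(
        beta=beta,
        se=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p=float(s["p"]),
        converged=converged,
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def survival_screen(
    matrix_log2: pd.DataFrame,
    metadata: pd.DataFrame,
    protein_ids,
) -> pd.DataFrame:
    """Median-split log-rank plus continuous Cox for each listed protein.

    Returns a table indexed by protein with columns logrank_chi2, logrank_p,
    hr, ci_low, ci_high, cox_p, converged.
    """
    meta = metadata.set_index("sample_id").loc[matrix_log2.columns]
    rows = []
    for pid in protein_ids:
        if pid not in matrix_log2.index:
            raise ValueError(f"protein {pid!r} absent from the matrix")
        x = matrix_log2.loc[pid]
        labels = median_dichotomize(x)
        chi2, lp = logrank_test(meta["survival_months"], meta["event"], labels)
        fit = cox_univariable(meta["survival_months"], meta["event"], x.to_numpy())
        rows.append(
            {"protein_id": pid, "logrank_chi2": chi2, "logrank_p": lp, "hr": fit.hr,
             "ci_low": fit.ci_low, "ci_high": fit.ci_high, "cox_p": fit.p,
             "converged": fit.converged}
        )
    return pd.DataFrame(rows).set_index("protein_id")
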