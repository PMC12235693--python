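"""Inhibitor dose-response analysis.

Viability assays are normalized to the mean of the untreated control wells,
fitted with the variable-slope four-parameter logistic model

    Y = bottom + (top - bottom) / (1 + 10**((logIC50 - X) * hill)),

X = log10 molar concentration, and compared across patient samples per
compound and concentration with a Kruskal-Wallis global test followed by
Dunn's post hoc z-tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import kruskal_wallis
from .simulate import four_pl


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    log_ic50: float
    hill: float
    sse: float
    converged: bool
    degenerate: bool  # flat data: hill/logIC50 unidentifiable


def normalize_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw signal to the untreated controls per (sample, compound).

    Expects columns sample, compound, concentration_molar, replicate,
    raw_signal, is_control. Adds a ``response`` column: raw / mean(control
    raw); control wells then average exactly 1.0, making plates with
    different raw scales comparable.
    """
    out = plate.copy()
    out["response"] = np.nan
    for (s, cpd), idx in out.groupby(["sample", "compound"]).groups.items():
        sub = out.loc[idx]
        ctrl = sub.loc[sub["is_control"] == 1, "raw_signal"]
        if len(ctrl) == 0:
            raise ValueError(f"no untreated control wells for ({s}, {cpd})")
        mean = ctrl.mean()
        if mean <= 0:
            raise ValueError(f"non-positive control mean for ({s}, {cpd})")
        out.loc[idx, "response"] = sub["raw_signal"] / mean
    return out


def fit_4pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
    flat_tolerance: float = 1e-3,
) -> DoseResponseFit:
    """Least-squares variable-slope 4PL fit on log10 concentration.

    Requires >= 5 distinct positive concentrations. Multi-start
    initialization (top = max, bottom = min, logIC50 at the lower/upper
    median X, hill = +-1) guards the hill-sign ambiguity; the best-SSE start
    wins, ties resolved to the first. Data whose response range is below
    ``flat_tolerance`` are flagged degenerate (the curve reduces to a flat
    line, hill unidentifiable) rather than raising.
    """
    conc = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    if len(np.unique(conc)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    x = np.log10(conc)

    if np.ptp(y) < flat_tolerance:
        flat = float(np.mean(y))
        sse = float(((y - flat) ** 2).sum())
        return DoseResponseFit(flat, flat, float(np.median(x)), 0.0, sse, True, True)

    top0, bot0 = float(np.max(y)), float(np.min(y))
    med = float(np.median(x))
    starts = [
        (bot0, top0, med, 1.0),
        (bot0, top0, med, -1.0),
        (bot0, top0, med - 1.0, 1.0),
        (bot0, top0, med + 1.0, 1.0),
    ]
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(four_pl, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        sse = float(((y - four_pl(x, *popt)) ** 2).sum())
        if best is None or sse < best[1] - 1e-15:
            best = (popt, sse)
    if best is None:
        return DoseResponseFit(bot0, top0, med, np.nan, np.inf, False, False)
    (bottom, top, log_ic50, hill), sse = best
    return DoseResponseFit(
        float(bottom), float(top), float(log_ic50), float(hill), sse, True, False
    )


def fit_plate(plate_norm: pd.DataFrame) -> pd.DataFrame:
    """Fit one 4PL curve per (sample, compound) from a normalized plate,
    using treated wells only (controls serve normalization, not the fit)."""
    rows = []
    for (s, cpd), sub in plate_norm.groupby(["sample", "compound"]):
        treated = sub.loc[sub["is_control"] == 0]
        fit = fit_4pl(treated["concentration_molar"], treated["response"])
        rows.append(
            {"sample": s, "compound": cpd, "bottom": fit.bottom, "top": fit.top,
             "log_ic50": fit.log_ic50, "hill": fit.hill, "sse": fit.sse,
             "converged": fit.converged, "degenerate": fit.degenerate}
        )
    return pd.DataFrame(rows).set_index(["sample", "compound"])


def kw_dunn(groups: dict[str, Sequence[float]], alpha: float = 0.05) -> dict:
    """Kruskal-Wallis global test plus Dunn's pairwise z-tests (Bonferroni).

    ``groups`` maps group label -> replicate observations (>= 2 each). The
    Dunn statistic for groups i, j uses mean ranks of the pooled data with
    tie correction:

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
        T = sum(t^3 - t) / (12 (N - 1)) over tie groups.

    Pairwise two-sided normal p-values are multiplied by the number of
    comparisons and capped at 1. Returns {'h', 'p_global', 'pairwise':
    DataFrame(group1, group2, z, p, p_adj, significant)}.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if any(len(d) < 2 for d in data):
        raise ValueError("each group needs at least two observations")
    h, p_global = kruskal_wallis(data)

    pooled = np.concatenate(data)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(d) for d in data]
    split = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, split)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))
    var_base = n * (n + 1) / 12.0 - tie_term

    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, j in combinations(range(len(names)), 2):
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p = 2.0 * stats.norm.sf(abs(z)) if denom > 0 else 1.0
        p_adj = min(p * m, 1.0)
        rows.append(
            {"group1": names[i], "group2": names[j], "z": z, "p": p,
             "p_adj": p_adj, "significant": p_adj < alpha}
        )
    return {"h": h, "p_global": p_global, "pairwise": pd.DataFrame(rows)}


def compare_samples(plate_norm: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per (compound, concentration): compare normalized viability across
    samples with Kruskal-Wallis + Dunn-Bonferroni. Returns the stacked
    pairwise table with compound/concentration/global-p columns."""
    treated = plate_norm.loc[plate_norm["is_control"] == 0]
    frames = []
    for (cpd, conc), sub in treated.groupby(["compound", "concentration_molar"]):
        groups = {s: g["response"].to_numpy() for s, g in sub.groupby("sample")}
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            continue
        res = kw_dunn(groups, alpha)
        tab = res["pairwise"].copy()
        tab.insert(0, "compound", cpd)
        tab.insert(1, "concentration_molar", conc)
        tab.insert(2, "p_global", res["p_global"])
        frames.append(tab)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
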