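"""Baseline cohort statistics.

Categorical baseline variables are compared across the five glioma
subgroups with the exact conditional test for r x c contingency tables
(the r x c generalization of Fisher's exact test): conditional on both
margins, a table's probability is multivariate hypergeometric,

    P(T) = prod_i R_i! * prod_j C_j! / (N! * prod_ij x_ij!),

and the two-sided p-value is the total probability of all margin-consistent
tables no more probable than the observed one. Enumeration walks the table
row by row over bounded compositions of each row total (vectorized, with a
node budget); a seeded Monte-Carlo mode samples margin-conditioned tables
for problems beyond the budget. Quantitative variables use the
Kruskal-Wallis rank-sum test with tie correction.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

# relative slack when comparing a table's probability to the observed one
# (floating-point equality hazard in the "no more probable" rule)
REL_TOL = 1e-7


class EnumerationBudgetError(RuntimeError):
    """Exact enumeration would visit too many tables; use mode='montecarlo'."""


def _bounded_compositions(n: int, bounds: np.ndarray, budget: list) -> np.ndarray:
    """All length-len(bounds) nonnegative integer vectors with given sum and
    per-entry upper bounds, enumerated vectorized (rows of the result)."""
    bounds = np.asarray(bounds, dtype=np.int64)
    c = len(bounds)
    suffix = np.concatenate([np.cumsum(bounds[::-1])[::-1][1:], [0]])
    parts = np.zeros((1, 0), dtype=np.int64)
    sums = np.zeros(1, dtype=np.int64)
    for j in range(c - 1):
        lo = np.maximum(0, n - sums - suffix[j])
        hi = np.minimum(bounds[j], n - sums)
        counts = hi - lo + 1
        keep = counts > 0
        parts, sums, lo, counts = parts[keep], sums[keep], lo[keep], counts[keep]
        if len(counts) == 0:
            return np.zeros((0, c), dtype=np.int64)
        total = int(counts.sum())
        budget[0] -= total
        if budget[0] < 0:
            raise EnumerationBudgetError(
                "enumeration budget exceeded; rerun with mode='montecarlo'"
            )
        rep = np.repeat(np.arange(len(counts)), counts)
        offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        vals = lo[rep] + offs
        parts = np.column_stack([parts[rep], vals])
        sums = sums[rep] + vals
    last = n - sums
    ok = (last >= 0) & (last <= bounds[-1])
    return np.column_stack([parts[ok], last[ok]])


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("all margins must be positive")
    return t


def fisher_exact_rxc(
    table,
    mode: str = "exact",
    seed: Optional[int] = None,
    n_mc: int = 1_000_000,
    max_tables: float = 5e7,
) -> float:
    """Two-sided exact conditional test for an r x c contingency table.

    mode='exact' enumerates every table with the observed margins and sums
    the probabilities of those no more probable than the observed table (a
    relative tolerance of 1e-7 guards the comparison); it raises
    :class:`EnumerationBudgetError` past ``max_tables`` visited nodes.
    mode='montecarlo' instead samples ``n_mc`` margin-conditioned tables
    (seeded) and applies the same rule. The p-value is invariant under row
    and column permutations.
    """
    t = _validate_table(table)
    R = np.sort(t.sum(axis=1))  # ascending: small rows first keeps recursion shallow
    C = t.sum(axis=0)
    N = int(t.sum())
    lf = gammaln(np.arange(N + 1) + 1.0)
    const = lf[t.sum(axis=1)].sum() + lf[C].sum() - lf[N]
    logp_obs = const - lf[t].sum()
    thresh = logp_obs + np.log1p(REL_TOL)

    if mode == "exact":
        budget = [float(max_tables)]
        total = _enumerate_tail(R, C, const, thresh, lf, budget)
        return float(min(total, 1.0))
    if mode == "montecarlo":
        if n_mc < 1:
            raise ValueError("n_mc must be positive")
        rng = np.random.default_rng(seed)
        logp = _sample_logp(rng, R, C, n_mc, const, lf)
        return float((logp <= thresh).mean())
    raise ValueError("mode must be 'exact' or 'montecarlo'")


def _enumerate_tail(R, C, const, thresh, lf, budget) -> float:
    """Sum P over all tables with margins (R, C) whose log-probability is at
    most ``thresh``. Recursive over rows; the last two rows are vectorized."""
    r = len(R)

    def rec(i: int, remaining: np.ndarray, acc: float) -> float:
        if i == r - 2:
            X = _bounded_compositions(int(R[i]), remaining, budget)
            if len(X) == 0:
                return 0.0
            L = remaining[None, :] - X
            logp = const - acc - lf[X].sum(axis=1) - lf[L].sum(axis=1)
            sel = logp <= thresh
            return float(np.exp(logp[sel]).sum())
        total = 0.0
        X = _bounded_compositions(int(R[i]), remaining, budget)
        for x in X:
            total += rec(i + 1, remaining - x, acc + lf[x].sum())
        return total

    if r == 1:  # pragma: no cover - excluded by validation
        return 1.0
    return rec(0, C.copy(), 0.0)


def _sample_logp(rng, R, C, n_mc, const, lf) -> np.ndarray:
    """Log-probabilities of margin-conditioned tables sampled row by row via
    multivariate hypergeometric draws (grouped by identical remaining
    margins so the vectorized sampler is used)."""
    r, c = len(R), len(C)
    rem = np.tile(C, (n_mc, 1))
    neg = np.zeros(n_mc)
    for i in range(r - 1):
        uniq, inv = np.unique(rem, axis=0, return_inverse=True)
        draw = np.empty_like(rem)
        for u, colors in enumerate(uniq):
            sel = inv == u
            draw[sel] = rng.multivariate_hypergeometric(
                colors, int(R[i]), size=int(sel.sum())
            )
        neg += lf[draw].sum(axis=1)
        rem -= draw
    neg += lf[rem].sum(axis=1)
    return const - neg


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p over >= 2 groups.

    All values identical is a defined degenerate case: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


CATEGORICAL_VARS = ("sex", "epilepsy", "chemo", "radio", "steroids")
QUANTITATIVE_VARS = ("age", "survival_months")


def baseline_table(
    metadata: pd.DataFrame,
    categorical: Sequence[str] = CATEGORICAL_VARS,
    quantitative: Sequence[str] = QUANTITATIVE_VARS,
    subgroup_col: str = "subgroup",
) -> dict:
    """Baseline-characteristics summary per subgroup.

    Categorical variables: per-subgroup level counts with percentages and an
    exact Fisher p; quantitative: median (range) and a Kruskal-Wallis p.
    With a single subgroup only the descriptive columns are produced.
    Returns {'categorical': {...}, 'quantitative': {...}, 'formatted':
    DataFrame} where the formatted table holds display strings per variable.
    """
    subgroups = list(pd.unique(metadata[subgroup_col]))
    single = len(subgroups) < 2
    out: dict = {"categorical": {}, "quantitative": {}}
    rows = []
    for var in categorical:
        counts = (
            metadata.groupby([subgroup_col, var]).size().unstack(var, fill_value=0).T
        )
        counts = counts[subgroups]
        pct = counts / counts.sum(axis=0) * 100.0
        p = None if single else fisher_exact_rxc(counts.to_numpy())
        out["categorical"][var] = {"counts": counts, "percent": pct, "p": p}
        top = counts.index.max()  # summarise the 'positive' level for display
        cells = {
            g: f"{counts.loc[top, g]}/{counts[g].sum()} ({pct.loc[top, g]:.1f}%)"
            for g in subgroups
        }
        rows.append({"variable": var, **cells,
                     "p_value": "" if p is None else f"{p:.3f}", "test": "fisher"})
    for var in quantitative:
        med = metadata.groupby(subgroup_col)[var].median()
        lo = metadata.groupby(subgroup_col)[var].min()
        hi = metadata.groupby(subgroup_col)[var].max()
        p = (
            None
            if single
            else kruskal_wallis(
                [metadata.loc[metadata[subgroup_col] == g, var] for g in subgroups]
            )[1]
        )
        out["quantitative"][var] = {"median": med, "min": lo, "max": hi, "p": p}
        cells = {g: f"{med[g]:.1f} ({lo[g]:.1f}-{hi[g]:.1f})" for g in subgroups}
        rows.append({"variable": var, **cells,
                     "p_value": "" if p is None else f"{p:.3f}", "test": "kruskal-wallis"})
    out["formatted"] = pd.DataFrame(rows).set_index("variable")
    return out
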