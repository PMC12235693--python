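"""Over-representation and gene-set enrichment analysis.

ORA tests a query set (e.g., the DEPs of one contrast) against GMT gene sets
with the one-sided hypergeometric upper tail. GSEA scores a whole ranked
protein list with the weighted Kolmogorov-Smirnov running sum: walking down
the ranking, members of a set add |score|^weight (normalized by the set
total) and non-members subtract 1/(N - |S|); the enrichment score ES is the
maximal deviation from zero. The null is built by gene-label permutation
(random same-size sets), ES is normalized to NES against the same-sign null
mean, and permutation p-values are BH-adjusted across sets.

Two ranking metrics are supported — the contrast log2 fold-change and the
signed p-value, sign(log2FC) * (-log10 p) — and a consensus step keeps only
the sets significant under both with agreeing NES sign.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

SIGNED_P_CAP = 320.0  # -log10 of the smallest positive double, rounded up


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, tab-delimited name, description,
    then member ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate gene set name {parts[0]!r}")
            members = [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"gene set {parts[0]!r} is empty")
            sets[parts[0]] = members
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# ORA


def ora_test(
    query: Sequence[str],
    universe: Sequence[str],
    sets: dict[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe first. Returns a DataFrame indexed
    by set name with columns set_size, overlap, p, adj_p; p is the upper-tail
    probability of drawing at least the observed overlap.
    """
    uni = set(universe)
    q = set(query)
    if not q or not uni:
        raise ValueError("query and universe must be nonempty")
    if not q <= uni:
        raise ValueError("query must be a subset of the universe")
    M, N = len(uni), len(q)
    rows = []
    for name, members in sets.items():
        s = set(members) & uni
        if not s:
            continue
        k = len(s & q)
        p = float(stats.hypergeom.sf(k - 1, M, len(s), N))
        rows.append({"set": name, "set_size": len(s), "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set")
    out["adj_p"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# ranking


def rank_proteins(result: pd.DataFrame, metric: str = "log2fc") -> pd.Series:
    """Rank a contrast table into an ordered score series.

    metric='log2fc' scores by the fold-change; metric='signed_p' by
    sign(log2FC) * (-log10 raw p), capped at +-320 when p underflows to 0.
    Descending score, ties broken by protein id, so the ranking is invariant
    to input row order.
    """
    if metric not in ("log2fc", "signed_p"):
        raise ValueError(f"unknown metric {metric!r}")
    fc = result["log2fc"].to_numpy(dtype=float)
    if metric == "log2fc":
        score = fc
    else:
        p = result["p"].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            mag = np.minimum(-np.log10(p), SIGNED_P_CAP)
        score = np.sign(fc) * mag
    if not np.isfinite(score).all():
        raise ValueError("ranking scores must be finite")
    s = pd.Series(score, index=result.index, name=metric)
    return s.sort_index().sort_values(ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# GSEA


def enrichment_score(
    ranked: pd.Series, members: set, weight: float = 1.0
) -> tuple[float, int, list[str]]:
    """Weighted running-sum enrichment score of one set on one ranking.

    Returns (ES, position of the extreme, leading-edge ids). ES is the
    deviation of maximal absolute value; the leading edge is the hits at or
    before a positive peak (or at/after a negative trough).
    """
    ids = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    hit = np.fromiter((i in members for i in ids), dtype=bool, count=len(ids))
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == len(ids):
        raise ValueError("set must hit a proper nonempty subset of the ranking")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member scores are zero: fall back to unweighted hits
        hit_w = hit.astype(float)
        total = hit_w.sum()
    miss = 1.0 / (len(ids) - n_hit)
    running = np.cumsum(hit_w / total - np.where(hit, 0.0, miss))
    pos = int(np.argmax(np.abs(running)))
    es = float(running[pos])
    if es >= 0:
        leading = [i for i, h in zip(ids[: pos + 1], hit[: pos + 1]) if h]
    else:
        leading = [i for i, h in zip(ids[pos:], hit[pos:]) if h]
    return es, pos, leading


def _null_es(
    ranked: pd.Series,
    set_size: int,
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
    exhaustive: bool,
) -> np.ndarray:
    n = len(ranked)
    if exhaustive:
        idx_sets = combinations(range(n), set_size)
        out = []
        ids = ranked.index.to_numpy()
        for comb in idx_sets:
            es, _, _ = enrichment_score(ranked, set(ids[list(comb)]), weight)
            out.append(es)
        return np.asarray(out)
    ids = ranked.index.to_numpy()
    out = np.empty(n_perm)
    for b in range(n_perm):
        members = set(ids[rng.choice(n, size=set_size, replace=False)])
        out[b], _, _ = enrichment_score(ranked, members, weight)
    return out


def gsea(
    ranked: pd.Series,
    sets: dict[str, Sequence[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Gene-set enrichment over a ranked list with a gene-label permutation null.

    Sets are intersected with the ranking and filtered to [min_size,
    max_size] (skipped sets are reported with NaN statistics). NES = ES /
    mean(|null ES| of the same sign); the two-sided permutation p counts
    same-sign null ES at least as extreme, with the +1 guarantee p >=
    1/(n_perm+1). ``exhaustive=True`` enumerates every same-size label set
    instead of sampling (feasible only for toy problems).
    """
    if len(ranked) == 0:
        raise ValueError("empty ranking")
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 23]))
    known = set(ranked.index)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        inset = set(members) & known
        size = len(inset)
        if size < min_size or size > max_size or size == len(ranked):
            rows.append(
                {"set": name, "size": size, "es": np.nan, "nes": np.nan,
                 "p": np.nan, "leading_edge": "", "skipped": True}
            )
            continue
        es, _, leading = enrichment_score(ranked, inset, weight)
        if size not in null_cache:
            null_cache[size] = _null_es(ranked, size, weight, n_perm, rng, exhaustive)
        null = null_cache[size]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if len(same) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        extreme = int((np.abs(same) >= abs(es) - 1e-12).sum())
        p = (1.0 + extreme) / (1.0 + len(same))
        rows.append(
            {"set": name, "size": size, "es": es, "nes": nes, "p": min(p, 1.0),
             "leading_edge": ";".join(leading), "skipped": False}
        )
    out = pd.DataFrame(rows).set_index("set")
    tested = ~out["skipped"]
    adj = np.full(len(out), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["adj_p"] = adj
    return out


def consensus_terms(
    res_log2fc: pd.DataFrame, res_signed_p: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Sets significant under BOTH ranking metrics with matching NES sign."""
    if set(res_log2fc.index) != set(res_signed_p.index):
        raise ValueError("the two runs must cover the same set collection")
    a = res_log2fc
    b = res_signed_p.loc[a.index]
    keep = (
        (a["adj_p"] < alpha)
        & (b["adj_p"] < alpha)
        & (np.sign(a["nes"]) == np.sign(b["nes"]))
        & ~a["skipped"]
        & ~b["skipped"]
    )
    out = a.loc[keep, ["size", "es", "nes", "p", "adj_p"]].copy()
    out.columns = [f"{c}_log2fc" for c in out.columns]
    for c in ("es", "nes", "p", "adj_p"):
        out[f"{c}_signed_p"] = b.loc[keep, c]
    out["consensus"] = True
    return out.sort_index()


def select_extreme_terms(results: pd.DataFrame, k: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k sets by highest NES and top-k by lowest NES (ties by set name)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if len(results) == 0:
        raise ValueError("empty results")
    col = "nes" if "nes" in results.columns else "nes_log2fc"
    usable = results.loc[results[col].notna()].sort_index()
    highest = usable.sort_values(col, ascending=False, kind="mergesort").head(k)
    lowest = usable.sort_values(col, ascending=True, kind="mergesort").head(k)
    return highest, lowest
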