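"""Reporter-ion quantification post-processing.

Turns PSM-level reporter intensities into a cross-plex-comparable, log2,
complete-case protein x sample matrix in four steps:

1. sum PSM intensities within protein group per (plex, channel);
2. quantile-normalize channels within each plex (reference channel included —
   it is an ordinary channel at this stage);
3. bridge plexes on the pooled reference channel: per protein, compute the
   geometric mean of its reference intensities over plexes and rescale each
   plex so its reference hits that geometric mean;
4. drop reference columns, keep complete cases, take log2.

A raw zero intensity is treated as missing (no pseudocount), so it is
removed by the complete-case filter rather than producing -inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

VALID_STATES = ("raw", "quantile_normalized", "reference_scaled", "log2_complete")


@dataclass
class ProteinMatrix:
    """Proteins x columns abundance matrix with a processing-state flag.

    ``data`` columns are channel ids (per-plex matrices) or sample ids (after
    reference scaling); missing values are NaN. ``state`` tracks which steps
    have been applied.
    """

    data: pd.DataFrame
    state: str = "raw"
    dropped_proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("protein and column ids must be unique")
        if self.state == "log2_complete" and self.data.isna().any().any():
            raise ValueError("log2_complete matrix may not contain missing values")


def aggregate_psms(psm: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Sum PSM intensities within protein group per (plex, channel).

    ``psm`` is a long table with columns protein_id, plex, channel, intensity.
    Returns one raw proteins x channels DataFrame per plex; a channel with no
    PSM for a protein is NaN (missing), not zero. Duplicate records are summed,
    not deduplicated. Record order never affects the result.
    """
    required = {"protein_id", "plex", "channel", "intensity"}
    if not required.issubset(psm.columns):
        raise ValueError(f"PSM table needs columns {sorted(required)}")
    if len(psm) == 0:
        raise ValueError("empty PSM table")
    if (psm["intensity"] < 0).any():
        raise ValueError("negative PSM intensity")
    sums = psm.groupby(["plex", "protein_id", "channel"], sort=True)["intensity"].sum()
    out = {}
    for plex, sub in sums.groupby(level="plex"):
        mat = sub.droplevel("plex").unstack("channel")
        mat = mat.sort_index().sort_index(axis=1)
        mat.index.name = None
        mat.columns.name = None
        out[plex] = mat
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of one plex's matrix.

    After normalization every column's sorted value vector equals the target
    profile (the mean across columns of the sorted input columns). Tied values
    within a column receive the mean of the target quantiles they span.
    Missing cells stay missing; a column's non-missing values are mapped
    through the target profile by rank interpolation.
    """
    X = matrix.to_numpy(dtype=float)
    n, m = X.shape
    if m == 0 or n == 0:
        raise ValueError("empty matrix")
    if np.isnan(X).all(axis=0).any():
        bad = matrix.columns[np.isnan(X).all(axis=0)].tolist()
        raise ValueError(f"channel(s) entirely missing: {bad}")

    # target profile on a common grid of n quantiles, averaging columns;
    # columns with missing cells contribute via interpolation on [0, 1]
    grid = np.linspace(0.0, 1.0, n)
    target = np.zeros(n)
    for j in range(m):
        col = X[:, j]
        col = np.sort(col[~np.isnan(col)])
        k = len(col)
        if k == n:
            target += col
        else:
            target += np.interp(grid, np.linspace(0.0, 1.0, k), col)
    target /= m

    out = np.full_like(X, np.nan)
    for j in range(m):
        col = X[:, j]
        obs = ~np.isnan(col)
        vals = col[obs]
        k = len(vals)
        order = np.argsort(vals, kind="mergesort")
        ranks = np.empty(k)
        ranks[order] = np.arange(k)
        if k == n:
            tgt = target
        else:
            tgt = np.interp(np.linspace(0.0, 1.0, k), grid, target)
        mapped = tgt[ranks.astype(int)]
        # ties: average the target values over each tied span
        sorted_vals = vals[order]
        tie_starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
        tie_ends = np.r_[tie_starts[1:], k]
        for a, b in zip(tie_starts, tie_ends):
            if b - a > 1:
                mapped[order[a:b]] = tgt[a:b].mean()
        out[obs, j] = mapped
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def reference_scale(
    plex_matrices: dict[str, pd.DataFrame],
    layout: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bridge plexes on the pooled reference channel.

    ``layout`` is long-format with columns plex, channel, sample_id, the
    reference rows carrying sample_id == 'REF'. For each protein, g = the
    geometric mean of its reference intensities over the plexes where the
    reference is present and positive; each plex is scaled by g / reference
    so the protein's reference intensity equals g in every contributing plex.
    A zero or missing reference makes the protein missing in that whole plex.

    Returns (proteins x samples matrix with sample-id columns, per-plex scale
    factor table proteins x plexes).
    """
    ref_of = (
        layout.loc[layout["sample_id"] == "REF"].set_index("plex")["channel"].to_dict()
    )
    missing_ref = set(plex_matrices) - set(ref_of)
    if missing_ref:
        raise ValueError(f"no reference channel in layout for plex(es) {sorted(missing_ref)}")

    proteins = sorted(set().union(*[m.index for m in plex_matrices.values()]))
    plexes = sorted(plex_matrices)
    ref = pd.DataFrame(np.nan, index=proteins, columns=plexes)
    for plex, mat in plex_matrices.items():
        ch = ref_of[plex]
        if ch not in mat.columns:
            raise ValueError(f"reference channel {ch} absent from plex {plex} matrix")
        ref.loc[mat.index, plex] = mat[ch].to_numpy()
    ref = ref.where(ref > 0)  # zero reference -> missing in that plex

    with np.errstate(invalid="ignore"):
        g = np.exp(np.nanmean(np.log(ref.to_numpy(dtype=float)), axis=1))
    factors = pd.DataFrame(
        g[:, None] / ref.to_numpy(dtype=float), index=proteins, columns=plexes
    )

    sample_cols = layout.loc[layout["sample_id"] != "REF"]
    pieces = {}
    for plex, mat in plex_matrices.items():
        f = factors[plex].reindex(mat.index)
        scaled = mat.mul(f, axis=0)
        rows = sample_cols.loc[sample_cols["plex"] == plex]
        for r in rows.itertuples():
            if r.channel not in scaled.columns:
                raise ValueError(f"channel {r.channel} of plex {plex} absent from matrix")
            pieces[r.sample_id] = scaled[r.channel]
    merged = pd.DataFrame(pieces).reindex(proteins)
    merged = merged[sorted(merged.columns)]
    return merged, factors


def complete_case_log2(matrix: pd.DataFrame) -> ProteinMatrix:
    """Keep proteins observed (finite, positive) in every sample; log2 them.

    Returns a :class:`ProteinMatrix` in state ``log2_complete`` whose
    ``dropped_proteins`` lists the removed protein ids.
    """
    X = matrix.to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1) & (np.nan_to_num(X, nan=-1.0) > 0).all(axis=1)
    dropped = matrix.index[~ok].tolist()
    kept = matrix.loc[ok]
    if len(kept) == 0:
        raise ValueError("complete-case filter removed every protein")
    return ProteinMatrix(
        data=np.log2(kept), state="log2_complete", dropped_proteins=dropped
    )


def normalize_psm_table(
    psm: pd.DataFrame,
    layout: pd.DataFrame,
    quantile: bool = True,
) -> tuple[ProteinMatrix, dict]:
    """Full chain: aggregate -> (quantile per plex) -> reference-scale -> log2
    complete-case. Returns the final matrix and a provenance dict (state
    history, dropped protein ids, per-plex scale factors)."""
    per_plex = aggregate_psms(psm)
    states = ["raw"]
    if quantile:
        per_plex = {p: quantile_normalize(m) for p, m in per_plex.items()}
        states.append("quantile_normalized")
    merged, factors = reference_scale(per_plex, layout)
    states.append("reference_scaled")
    result = complete_case_log2(merged)
    states.append("log2_complete")
    provenance = {
        "states": states,
        "n_proteins_in": int(len(merged)),
        "n_proteins_retained": int(len(result.data)),
        "dropped_proteins": result.dropped_proteins,
        "scale_factors": factors,
    }
    return result, provenance
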