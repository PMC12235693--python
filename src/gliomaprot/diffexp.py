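"""Protein-wise linear models with empirical-Bayes variance moderation.

Each protein's log2 abundance is regressed on subgroup indicators (diffuse
LGG as the reference level), clinical confounders (age, sex, prior
chemotherapy / radiotherapy / steroids, epilepsy) and the log2 abundances of
three non-neoplastic cell markers — PTPRC/CD45 and HG2A for immune cells,
SEPT3 for neurons — which act as a tumor-purity surrogate. Residual
variances are moderated with the standard empirical-Bayes construction:
gene-wise variances are modelled as s0^2 * F(d, d0); the prior (d0, s0^2)
is estimated by method of moments on log s^2 and each protein's posterior
variance is the d0/d-weighted blend, giving moderated t-statistics with
d + d0 degrees of freedom.

Proteins whose abundance is significantly associated with the purity
markers (by default a joint moderated F-test on the three marker
coefficients — the markers are correlated proxies of one purity variable,
so a joint test pools evidence that per-coefficient tests lose to
collinearity) are flagged and excluded from reported DEP lists, so
differential calls reflect neoplastic-cell biology rather than varying
tumor purity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .normalize import ProteinMatrix
from .simulate import MARKER_PROTEINS, SUBGROUPS


@dataclass(frozen=True)
class DesignSpec:
    """Model specification for the protein-wise linear models."""

    subgroup_col: str = "subgroup"
    reference_level: str = "LGG"
    covariates: tuple[str, ...] = ("age", "sex", "chemo", "radio", "steroids", "epilepsy")
    marker_proteins: tuple[str, ...] = MARKER_PROTEINS
    use_markers: bool = True


@dataclass
class LinearFit:
    """Per-protein OLS results, optionally with moderation parameters."""

    coef: pd.DataFrame            # proteins x design columns
    stdev_unscaled: pd.DataFrame  # sqrt(diag((X'X)^-1)) per coefficient (same for all proteins)
    sigma2: pd.Series             # residual variance per protein
    df_resid: int
    design: pd.DataFrame
    xtx_inv: np.ndarray
    d0: Optional[float] = None    # prior df (np.inf allowed)
    s02: Optional[float] = None   # prior variance
    post_var: Optional[pd.Series] = None

    @property
    def moderated(self) -> bool:
        return self.post_var is not None

    @property
    def df_total(self) -> float:
        return self.df_resid + (self.d0 if np.isfinite(self.d0) else np.inf)


def build_design(
    metadata: pd.DataFrame, matrix: ProteinMatrix, spec: DesignSpec = DesignSpec()
) -> pd.DataFrame:
    """Build the n_samples x p design matrix.

    Columns: intercept; one indicator per non-reference subgroup; the
    clinical covariates; and (if ``spec.use_markers``) the log2 abundance of
    each marker protein taken from the matrix. Raises on rank deficiency,
    naming the offending column(s).
    """
    samples = list(matrix.data.columns)
    meta = metadata.set_index("sample_id").loc[samples]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    levels = [g for g in SUBGROUPS if g != spec.reference_level]
    observed = set(meta[spec.subgroup_col])
    for g in levels:
        if g in observed:
            cols[f"subgroup_{g}"] = (meta[spec.subgroup_col] == g).to_numpy(float)
    for c in spec.covariates:
        if c not in meta.columns:
            raise ValueError(f"covariate {c!r} missing from metadata")
        cols[c] = meta[c].to_numpy(float)
    if spec.use_markers:
        for m in spec.marker_proteins:
            if m not in matrix.data.index:
                raise ValueError(f"marker protein {m!r} absent from the expression matrix")
            cols[f"marker_{m}"] = matrix.data.loc[m].to_numpy(float)
    X = pd.DataFrame(cols, index=samples)

    # diagnose rank deficiency with named columns: constant non-intercept
    # columns first, then any remaining collinearity
    bad = [c for c in X.columns[1:] if np.ptp(X[c].to_numpy()) == 0]
    if bad:
        raise ValueError(f"design is rank deficient: constant column(s) {bad}")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design is rank deficient (collinear columns)")
    return X


def marker_columns(design: pd.DataFrame) -> list[str]:
    return [c for c in design.columns if c.startswith("marker_")]


def fit_linear_models(matrix: ProteinMatrix, design: pd.DataFrame) -> LinearFit:
    """Ordinary least squares per protein row against the shared design."""
    if matrix.state != "log2_complete":
        raise ValueError("matrix must be in log2_complete state")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} samples cannot fit {p} design columns")
    # drop marker proteins themselves from the tested set
    tested = matrix.data.drop(
        index=[m for m in MARKER_PROTEINS if m in matrix.data.index], errors="ignore"
    )
    Y = tested.to_numpy(dtype=float)  # proteins x samples
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv.T  # proteins x p
    resid = Y - B @ X.T
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    # snap float rounding to exact zero: coefficients and residual variances
    # below 1e-9 relative to the data scale are artefacts of finite precision
    # (matters for exactly noise-free data, where 0/0 must read "no evidence")
    scale = np.sqrt((Y**2).mean(axis=1)) + 1.0
    B[np.abs(B) < 1e-9 * scale[:, None]] = 0.0
    sigma2[sigma2 < (1e-9 * scale) ** 2] = 0.0
    stdev = np.sqrt(np.diag(xtx_inv))
    return LinearFit(
        coef=pd.DataFrame(B, index=tested.index, columns=design.columns),
        stdev_unscaled=pd.DataFrame(
            np.tile(stdev, (len(tested), 1)), index=tested.index, columns=design.columns
        ),
        sigma2=pd.Series(sigma2, index=tested.index, name="sigma2"),
        df_resid=df,
        design=design,
        xtx_inv=xtx_inv,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of s^2 ~ s0^2 F(df, d0) on the log scale.

    Returns (d0, s02); d0 = inf when the observed spread of log s^2 does not
    exceed what sampling noise alone (trigamma(df/2)) explains, in which case
    moderation collapses every variance to the common s02.
    """
    s2 = np.asarray(sigma2, dtype=float)
    s2 = np.where(s2 < 1e-300, 1e-300, s2)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # no excess spread beyond sampling noise: infinite prior df, and the
        # pooled variance is the natural common value (exact when all s^2 tie)
        return np.inf, float(s2.mean())
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s02 = np.exp(emean + special.digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s02)


def ebayes_moderate(fit: LinearFit, d0: Optional[float] = None, s02: Optional[float] = None) -> LinearFit:
    """Moderate residual variances toward the empirical-Bayes prior.

    posterior variance = (d0*s02 + d*s^2) / (d0 + d); d0 = inf gives the
    pooled variance s02 for every protein, d0 = 0 leaves s^2 untouched.
    Pass (d0, s02) to override the method-of-moments estimates.
    """
    if len(fit.sigma2) < 10 and d0 is None:
        raise ValueError("need >= 10 proteins to estimate the variance prior")
    if d0 is None or s02 is None:
        d0_est, s02_est = estimate_prior(fit.sigma2.to_numpy(), fit.df_resid)
        d0 = d0_est if d0 is None else d0
        s02 = s02_est if s02 is None else s02
    d = fit.df_resid
    s2 = fit.sigma2.to_numpy()
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + d * s2) / (d0 + d)
    fit.d0, fit.s02 = float(d0), float(s02)
    fit.post_var = pd.Series(post, index=fit.sigma2.index, name="post_var")
    return fit


def _moderated_t_p(
    effect: np.ndarray, var_unscaled: float, fit: LinearFit
) -> tuple[np.ndarray, np.ndarray]:
    """t and two-sided p for effects with unscaled variance c'(X'X)^-1 c."""
    post = (fit.post_var if fit.moderated else fit.sigma2).to_numpy()
    se = np.sqrt(post * var_unscaled)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    t = np.where((se == 0) & (effect == 0), 0.0, t)  # 0/0 -> no evidence
    df = fit.df_total if fit.moderated else fit.df_resid
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(t == 0.0, 1.0, p)
    return t, p


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def subgroup_contrasts(design: pd.DataFrame, versus: str = "LGG") -> dict[str, np.ndarray]:
    """Contrast vectors for each subgroup-vs-reference comparison.

    Positive log2FC means higher in the HGG subgroup than in the reference
    (diffuse LGG). With reference coding, each contrast simply selects that
    subgroup's indicator coefficient.
    """
    names = [c for c in design.columns if c.startswith("subgroup_")]
    out = {}
    for c in names:
        v = np.zeros(design.shape[1])
        v[design.columns.get_loc(c)] = 1.0
        out[f"{c.removeprefix('subgroup_')}_vs_{versus}"] = v
    return out


def pooled_others_contrast(design: pd.DataFrame, group: str) -> np.ndarray:
    """Contrast of one subgroup against the unweighted mean of all other
    subgroups (reference level included with coefficient 0)."""
    names = [c for c in design.columns if c.startswith("subgroup_")]
    tgt = f"subgroup_{group}"
    if tgt not in names:
        raise ValueError(f"{group!r} is not a modelled subgroup")
    others = [c for c in names if c != tgt]
    v = np.zeros(design.shape[1])
    v[design.columns.get_loc(tgt)] = 1.0
    n_other_groups = len(others) + 1  # + the reference level
    for c in others:
        v[design.columns.get_loc(c)] = -1.0 / n_other_groups
    return v


def test_contrasts(
    fit: LinearFit,
    contrasts: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Moderated-t tests for each contrast, BH-adjusted within contrast.

    Returns per contrast a DataFrame indexed by protein with columns log2fc,
    t, p, adj_p, dep (adjusted p < alpha).
    """
    out = {}
    B = fit.coef.to_numpy()
    for name, cvec in contrasts.items():
        cvec = np.asarray(cvec, dtype=float)
        if cvec.shape != (fit.coef.shape[1],):
            raise ValueError(
                f"contrast {name!r} has length {cvec.size}, design has {fit.coef.shape[1]} columns"
            )
        effect = B @ cvec
        var_unscaled = float(cvec @ fit.xtx_inv @ cvec)
        t, p = _moderated_t_p(effect, var_unscaled, fit)
        adj = bh_adjust(p)
        out[name] = pd.DataFrame(
            {
                "log2fc": effect,
                "t": t,
                "p": p,
                "adj_p": adj,
                "dep": adj < alpha,
            },
            index=fit.coef.index,
        )
    return out


def marker_association(
    fit: LinearFit,
    threshold: float = 0.05,
    method: str = "joint",
    adjust: str = "none",
) -> pd.DataFrame:
    """Test every protein's association with the purity-marker covariates.

    method='joint' (default): moderated F-test on the block of marker
    coefficients, BH across proteins. The markers are all proxies of the
    same non-neoplastic contamination, so their columns are strongly
    correlated and a contaminated protein's association is split across the
    three coefficients; the joint test pools that evidence, whereas
    per-coefficient tests lose it to collinearity.
    method='any': moderated t on each marker coefficient, associated if any
    marker passes.

    ``adjust`` controls the multiplicity handling of the screen: 'none'
    (default) thresholds raw p-values — an exclusion screen should control
    the rate of *missed* confounded proteins, and BH, which limits false
    discoveries, is conservative in exactly the wrong direction there —
    while 'bh' thresholds BH-adjusted p-values across proteins.

    Returns per-marker / joint adjusted-p columns and a boolean
    ``marker_associated`` column.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    mcols = marker_columns(fit.design)
    if not mcols:
        raise ValueError("design contains no marker covariates")
    if method not in ("joint", "any"):
        raise ValueError("method must be 'joint' or 'any'")
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    out = pd.DataFrame(index=fit.coef.index)
    idx = [fit.design.columns.get_loc(c) for c in mcols]
    if method == "joint":
        q = len(idx)
        B = fit.coef.to_numpy()[:, idx]  # proteins x q
        V = fit.xtx_inv[np.ix_(idx, idx)]
        Vinv = np.linalg.inv(V)
        quad = np.einsum("pi,ij,pj->p", B, Vinv, B)
        post = (fit.post_var if fit.moderated else fit.sigma2).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            F = quad / (q * post)
        F = np.where((post == 0) & (quad == 0), 0.0, F)
        df2 = fit.df_total if fit.moderated else fit.df_resid
        if np.isinf(df2):
            p = stats.chi2.sf(q * F, q)
        else:
            p = stats.f.sf(F, q, df2)
        p = np.where(np.isinf(F), 0.0, np.where(F == 0.0, 1.0, p))
        out["p_joint"] = p
        out["adj_p_joint"] = bh_adjust(p)
        crit = out["adj_p_joint"] if adjust == "bh" else out["p_joint"]
        out["marker_associated"] = crit < threshold
        return out
    assoc = np.zeros(len(fit.coef), dtype=bool)
    for c, j in zip(mcols, idx):
        effect = fit.coef.iloc[:, j].to_numpy()
        var_unscaled = float(fit.xtx_inv[j, j])
        _, p = _moderated_t_p(effect, var_unscaled, fit)
        out[f"p_{c.removeprefix('marker_')}"] = p
        out[f"adj_p_{c.removeprefix('marker_')}"] = bh_adjust(p)
        assoc |= (bh_adjust(p) if adjust == "bh" else p) < threshold
    out["marker_associated"] = assoc
    return out


def marker_exclusion(
    fit: LinearFit,
    results: dict[str, pd.DataFrame],
    threshold: float = 0.05,
    unadjusted_results: Optional[dict[str, pd.DataFrame]] = None,
    method: str = "joint",
    adjust: str = "none",
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Flag marker-associated proteins and drop them from the DEP lists.

    Adds ``marker_associated`` and ``excluded`` columns to each contrast
    table (excluded = marker-associated AND dep). The report counts excluded
    DEPs per contrast and, when ``unadjusted_results`` from a marker-free
    model are supplied, the proteins removed from / added to the DEP lists
    by the purity adjustment.
    """
    assoc = marker_association(fit, threshold, method, adjust)
    flagged: dict[str, pd.DataFrame] = {}
    report: dict = {"threshold": threshold, "contrasts": {}}
    for name, tab in results.items():
        tab = tab.copy()
        tab["marker_associated"] = assoc["marker_associated"].reindex(tab.index).fillna(False)
        tab["excluded"] = tab["marker_associated"] & tab["dep"]
        tab["dep_final"] = tab["dep"] & ~tab["excluded"]
        flagged[name] = tab
        entry = {
            "n_dep_raw": int(tab["dep"].sum()),
            "n_excluded": int(tab["excluded"].sum()),
            "n_dep_final": int(tab["dep_final"].sum()),
        }
        if unadjusted_results is not None and name in unadjusted_results:
            before = set(unadjusted_results[name].index[unadjusted_results[name]["dep"]])
            after = set(tab.index[tab["dep_final"]])
            entry["n_removed_vs_unadjusted"] = len(before - after)
            entry["n_added_vs_unadjusted"] = len(after - before)
        report["contrasts"][name] = entry
    report["n_marker_associated"] = int(assoc["marker_associated"].sum())
    return flagged, report


def differential_expression(
    matrix: ProteinMatrix,
    metadata: pd.DataFrame,
    spec: DesignSpec = DesignSpec(),
    alpha: float = 0.05,
    marker_threshold: float = 0.05,
    marker_method: str = "joint",
    with_counterfactual: bool = True,
) -> tuple[dict[str, pd.DataFrame], dict, LinearFit]:
    """End-to-end differential expression for the subgroup-vs-LGG contrasts.

    Fits the purity-adjusted model, moderates, tests, and excludes
    marker-associated proteins; optionally also fits the marker-free model so
    the exclusion report can state how many DEPs the adjustment removed and
    added. Returns (per-contrast tables, exclusion report, fitted model).
    """
    design = build_design(metadata, matrix, spec)
    fit = ebayes_moderate(fit_linear_models(matrix, design))
    results = test_contrasts(fit, subgroup_contrasts(design, spec.reference_level), alpha)
    if not spec.use_markers:  # marker-free model: nothing to exclude
        for tab in results.values():
            tab["marker_associated"] = False
            tab["excluded"] = False
            tab["dep_final"] = tab["dep"]
        return results, {"threshold": marker_threshold, "contrasts": {}}, fit
    unadj = None
    if with_counterfactual and spec.use_markers:
        spec0 = DesignSpec(
            subgroup_col=spec.subgroup_col,
            reference_level=spec.reference_level,
            covariates=spec.covariates,
            marker_proteins=spec.marker_proteins,
            use_markers=False,
        )
        design0 = build_design(metadata, matrix, spec0)
        fit0 = ebayes_moderate(fit_linear_models(matrix, design0))
        unadj = test_contrasts(fit0, subgroup_contrasts(design0, spec.reference_level), alpha)
    flagged, report = marker_exclusion(fit, results, marker_threshold, unadj, marker_method)
    return flagged, report, fit
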