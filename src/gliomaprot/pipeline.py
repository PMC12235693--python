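"""End-to-end orchestration and PCA.

`run_pipeline` drives the full analysis from a config: PSM normalization ->
purity-adjusted differential expression -> dual-ranked enrichment ->
survival association of the extreme DEPs -> baseline cohort statistics
(-> dose-response when plates are supplied), writing every tabular artifact
plus a manifest JSON with content hashes so a fixed seed yields
hash-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import dose as dose_mod
from . import enrichment as enr
from . import survival as surv
from .diffexp import DesignSpec, differential_expression
from .normalize import ProteinMatrix, normalize_psm_table

log = logging.getLogger("gliomaprot")


@dataclass
class PipelineConfig:
    psm_table: str
    metadata: str
    plex_layout: str
    gmt: str
    outdir: str
    plates: Optional[str] = None
    alpha: float = 0.05
    marker_threshold: float = 0.05
    quantile: bool = True
    use_markers: bool = True
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    n_extreme_survival: int = 3  # top over-/underexpressed DEPs screened for survival
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("psm_table", "metadata", "plex_layout", "gmt"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")
        if self.plates is not None and not Path(self.plates).exists():
            raise FileNotFoundError(f"config path plates does not exist: {self.plates}")


def pca_samples(matrix: ProteinMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the samples of a log2 complete-case matrix.

    Samples are observations, proteins are features; features are centered
    and the scores come from the SVD of the centered matrix. Returns
    (sample x component coordinates, variance-explained fractions).
    """
    if matrix.state != "log2_complete":
        raise ValueError("PCA expects a log2_complete matrix")
    X = matrix.data.to_numpy(dtype=float).T  # samples x proteins
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if n_components > n:
        raise ValueError(f"cannot extract {n_components} components from {n} samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (S**2).sum()
    frac = S**2 / total if total > 0 else np.zeros_like(S)
    coords = pd.DataFrame(
        (U * S)[:, :n_components],
        index=matrix.data.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return coords, frac[:n_components]


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the artifact manifest.

    Stage failures abort with the stage name and cause. Outputs land in
    ``config.outdir``; the manifest (also written as manifest.json) maps each
    artifact to its path and sha256, making determinism checkable by hash.
    """
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "load"
    try:
        psm = pd.read_csv(config.psm_table, sep="\t")
        metadata = pd.read_csv(config.metadata)
        layout = pd.read_csv(config.plex_layout)
        gene_sets = enr.read_gmt(config.gmt)

        stage = "normalize"
        matrix, provenance = normalize_psm_table(psm, layout, quantile=config.quantile)
        log.info(
            "normalize: %d proteins in, %d retained after complete-case filter",
            provenance["n_proteins_in"], provenance["n_proteins_retained"],
        )
        p = out / "expression_log2.tsv"
        _write(matrix.data, p, index_label="protein_id")
        artifacts["expression_log2"] = p
        p = out / "normalization_provenance.json"
        p.write_text(json.dumps(
            {k: v for k, v in provenance.items() if k != "scale_factors"}, indent=1
        ))
        artifacts["normalization_provenance"] = p

        stage = "pca"
        coords, frac = pca_samples(matrix, n_components=min(5, len(matrix.data.columns) - 1))
        coords["subgroup"] = metadata.set_index("sample_id").loc[coords.index, "subgroup"]
        p = out / "pca_samples.tsv"
        _write(coords, p, index_label="sample_id")
        artifacts["pca_samples"] = p

        stage = "differential_expression"
        spec = DesignSpec(use_markers=config.use_markers)
        results, report, fit = differential_expression(
            matrix, metadata, spec,
            alpha=config.alpha, marker_threshold=config.marker_threshold,
            with_counterfactual=config.use_markers,
        )
        for name, tab in results.items():
            log.info("DE %s: %d DEPs (%d excluded as marker-associated)",
                     name, int(tab["dep_final"].sum()), int(tab["excluded"].sum()))
            p = out / f"de_{name}.tsv"
            _write(tab, p, index_label="protein_id")
            artifacts[f"de_{name}"] = p
        p = out / "marker_exclusion_report.json"
        p.write_text(json.dumps(report, indent=1))
        artifacts["marker_exclusion_report"] = p

        stage = "enrichment"
        universe = list(fit.coef.index)
        for name, tab in results.items():
            deps = tab.index[tab["dep_final"]].tolist()
            if deps:
                ora = enr.ora_test(deps, universe, gene_sets)
                p = out / f"ora_{name}.tsv"
                _write(ora, p, index_label="set")
                artifacts[f"ora_{name}"] = p
            runs = {}
            for metric in ("log2fc", "signed_p"):
                ranked = enr.rank_proteins(tab, metric)
                runs[metric] = enr.gsea(
                    ranked, gene_sets, n_perm=config.gsea_n_perm,
                    weight=config.gsea_weight, seed=config.seed,
                    min_size=config.gsea_min_size, max_size=config.gsea_max_size,
                )
                p = out / f"gsea_{metric}_{name}.tsv"
                _write(runs[metric], p, index_label="set")
                artifacts[f"gsea_{metric}_{name}"] = p
            consensus = enr.consensus_terms(runs["log2fc"], runs["signed_p"], config.alpha)
            p = out / f"gsea_consensus_{name}.tsv"
            _write(consensus, p, index_label="set")
            artifacts[f"gsea_consensus_{name}"] = p

        stage = "survival"
        frames = []
        for name, tab in results.items():
            deps = tab.loc[tab["dep_final"]].sort_values("log2fc")
            k = config.n_extreme_survival
            chosen = pd.concat([deps.tail(k), deps.head(k)]).index.unique().tolist()
            if not chosen:
                continue
            st = surv.survival_screen(matrix.data, metadata, chosen)
            st.insert(0, "contrast", name)
            frames.append(st)
        if frames:
            p = out / "survival_extreme_deps.tsv"
            _write(pd.concat(frames), p, index_label="protein_id")
            artifacts["survival_extreme_deps"] = p

        stage = "cohort_statistics"
        table = cohort_mod.baseline_table(metadata)
        p = out / "baseline_table.tsv"
        _write(table["formatted"], p)
        artifacts["baseline_table"] = p

        if config.plates is not None:
            stage = "dose_response"
            plate = pd.read_csv(config.plates)
            norm = dose_mod.normalize_viability(plate)
            fits = dose_mod.fit_plate(norm)
            p = out / "dose_response_fits.tsv"
            _write(fits, p)
            artifacts["dose_response_fits"] = p
            comp = dose_mod.compare_samples(norm, config.alpha)
            p = out / "dose_response_comparisons.tsv"
            _write(comp, p, index=False)
            artifacts["dose_response_comparisons"] = p
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "artifacts": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
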