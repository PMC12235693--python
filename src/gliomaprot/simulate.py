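"""Synthetic TMT glioma studies with known ground truth.

Generates complete studies — PSM-level reporter-ion tables, sample metadata,
gene sets, survival outcomes, and dose-response plates — that emulate a
multi-plex isobaric-labelling design: 82 gliomas in five subgroups (diffuse
LGG, IDH-mutant HGG, and the three IDH-wildtype glioblastoma methylation
subgroups GB PN / GB CL / GB MES) spread over 16-channel plexes, each plex
carrying one pooled-reference channel used to bridge quantification across
plexes.

Every stochastic quantity flows from a single seed through named child
streams, so identical configurations reproduce byte-identical outputs and
the ground truth (planted fold-changes, contamination fractions, plex batch
factors, survival coefficients, true dose-response parameters) is returned
alongside the data for downstream recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SUBGROUPS = ("LGG", "IDH_HGG", "GB_PN", "GB_CL", "GB_MES")
MARKER_PROTEINS = ("PTPRC", "HG2A", "SEPT3")

# Cohort demographics emulated by the generator (fractions / distribution
# parameters per subgroup, in SUBGROUPS order).
_AGE_MEAN = (44.5, 38.0, 60.0, 66.0, 59.0)
_AGE_SD = 10.0
_AGE_RANGE = (20.0, 80.0)
_P_MALE = (24 / 34, 6 / 12, 7 / 9, 9 / 14, 8 / 13)
_P_EPILEPSY = (29 / 34, 6 / 12, 6 / 9, 9 / 14, 9 / 13)
_P_CHEMO = 2 / 82
_P_RADIO = 1 / 82
_P_STEROIDS = 46 / 82


class CapacityError(ValueError):
    """Requested more samples than the plex layout can hold."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic study.

    Abundance effects are on the log2 scale; intensities are 2**abundance.
    ``contamination_mean_per_subgroup=None`` draws contamination fractions
    i.i.d. Beta(2, 5); supplying five means shifts the Beta mean per subgroup
    at fixed concentration a+b=7, emulating purity confounded with subgroup.
    """

    n_per_subgroup: tuple[int, ...] = (34, 12, 9, 14, 13)
    n_proteins: int = 2000
    n_plexes: int = 6
    channels_per_plex: int = 16  # one channel per plex reserved for the reference pool
    frac_dep: float = 0.10
    planted_log2fc: float = 1.0
    sigma_protein: float = 0.5
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 1.5
    plex_effect_sd: float = 0.25
    contamination_beta: float = 2.0
    n_contaminant_proteins: int = 50
    contamination_mean_per_subgroup: Optional[tuple[float, ...]] = None
    contamination_concentration: float = 7.0
    marker_slope: float = 1.0
    marker_baseline_offset: float = 4.0
    n_confounded_proteins: int = 50
    confounder_sd: float = 0.2
    psm_per_protein: int = 3
    psm_noise_sd: float = 0.10
    psm_dirichlet: float = 5.0
    reference_scope: str = "study"  # "study" or "plex": composition of the pooled reference
    baseline_hazard: float = 1.0 / 24.0
    survival_beta: float = 0.7
    n_survival_proteins: int = 3
    censor_time: float = 60.0
    dose_noise_sd: float = 0.05
    dose_replicates: int = 4
    dose_n_concentrations: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_subgroup) != len(SUBGROUPS):
            raise ValueError(f"n_per_subgroup must have {len(SUBGROUPS)} entries")
        if any(n <= 0 for n in self.n_per_subgroup):
            raise ValueError("subgroup sizes must be positive")
        if not 0.0 <= self.frac_dep <= 1.0:
            raise ValueError("frac_dep must lie in [0, 1]")
        for name in ("sigma_protein", "plex_effect_sd", "psm_noise_sd",
                     "baseline_log2_sd", "dose_noise_sd", "confounder_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_proteins <= 0 or self.psm_per_protein <= 0:
            raise ValueError("n_proteins and psm_per_protein must be positive")
        if self.channels_per_plex < 2:
            raise ValueError("need at least one sample channel plus the reference")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.reference_scope not in ("study", "plex"):
            raise ValueError("reference_scope must be 'study' or 'plex'")
        capacity = self.n_plexes * (self.channels_per_plex - 1)
        if self.n_samples > capacity:
            raise CapacityError(
                f"{self.n_samples} samples do not fit {self.n_plexes} plexes x "
                f"{self.channels_per_plex - 1} non-reference channels (capacity {capacity})"
            )
        if self.contamination_mean_per_subgroup is not None:
            means = self.contamination_mean_per_subgroup
            if len(means) != len(SUBGROUPS) or any(not 0 < m < 1 for m in means):
                raise ValueError("contamination_mean_per_subgroup needs 5 means in (0,1)")

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_subgroup))

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery checks downstream."""

    protein_ids: list[str]
    dep_ids: dict[str, list[str]]  # contrast name ("GB_PN_vs_LGG", ...) -> planted DEP ids
    true_log2fc: pd.DataFrame      # proteins x contrasts, 0 where nothing planted
    contamination: pd.Series       # per sample, fraction in [0, 1]
    plex_effects: pd.Series        # per plex, log2 batch factor
    contaminant_ids: list[str]
    marker_ids: list[str]
    confounded_ids: list[str]
    survival_protein_ids: list[str]
    survival_beta: float
    risk_score: pd.Series          # latent per-sample score driving the hazard


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), stream]))


def contrast_names() -> list[str]:
    return [f"{g}_vs_LGG" for g in SUBGROUPS[1:]]


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate the sample metadata table.

    One row per sample with subgroup, (plex, channel) assignment, clinical
    covariates (age, sex, epilepsy, prior chemo/radio/steroids), survival
    time (months) with event flag, and two ground-truth carrier columns used
    by :func:`simulate_psm_table`: ``contamination`` (non-neoplastic cell
    fraction) and ``risk_score`` (latent score the survival proteins track).

    Survival is exponential: hazard = baseline_hazard * exp(survival_beta *
    risk_score), administratively censored at ``censor_time``. Samples are
    block-randomized over plexes; each plex keeps exactly one channel free
    for the pooled reference (the last channel by convention).
    """
    rng = _rng(config, 1)
    n = config.n_samples
    subgroup = np.repeat(list(SUBGROUPS), list(config.n_per_subgroup))

    # shuffled round-robin assignment to plexes; reference channel is the last
    order = rng.permutation(n)
    n_sample_ch = config.channels_per_plex - 1
    plex_idx = np.empty(n, dtype=int)
    chan_idx = np.empty(n, dtype=int)
    for pos, i in enumerate(order):
        plex_idx[i] = pos % config.n_plexes
        chan_idx[i] = pos // config.n_plexes
    if chan_idx.max() >= n_sample_ch:  # pragma: no cover - guarded by SimConfig
        raise CapacityError("plex layout overflow")

    g = np.searchsorted(np.cumsum(config.n_per_subgroup), np.arange(n), side="right")
    age = np.clip(rng.normal(np.asarray(_AGE_MEAN)[g], _AGE_SD), *_AGE_RANGE).round(1)
    sex = (rng.random(n) < np.asarray(_P_MALE)[g]).astype(int)
    epilepsy = (rng.random(n) < np.asarray(_P_EPILEPSY)[g]).astype(int)
    # prior-treatment flags have fixed study-level prevalence (rare events:
    # exact counts, not Bernoulli, so the design matrix never degenerates)
    def fixed_count(p_frac: float) -> np.ndarray:
        k = max(1, int(round(p_frac * n)))
        flag = np.zeros(n, dtype=int)
        flag[rng.choice(n, size=k, replace=False)] = 1
        return flag

    chemo = fixed_count(_P_CHEMO)
    radio = fixed_count(_P_RADIO)
    steroids = fixed_count(_P_STEROIDS)

    if config.contamination_mean_per_subgroup is None:
        contamination = rng.beta(2.0, 5.0, size=n)
    else:
        means = np.asarray(config.contamination_mean_per_subgroup)[g]
        a = means * config.contamination_concentration
        b = (1.0 - means) * config.contamination_concentration
        contamination = rng.beta(a, b)

    risk = rng.standard_normal(n)
    rate = config.baseline_hazard * np.exp(config.survival_beta * risk)
    t = rng.exponential(1.0 / rate)
    event = (t <= config.censor_time).astype(int)
    time = np.minimum(t, config.censor_time)

    meta = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:03d}" for i in range(n)],
            "subgroup": subgroup,
            "plex": [f"plex{p + 1}" for p in plex_idx],
            "channel": [f"ch{c + 1:02d}" for c in chan_idx],
            "age": age,
            "sex": sex,
            "epilepsy": epilepsy,
            "chemo": chemo,
            "radio": radio,
            "steroids": steroids,
            "survival_months": np.maximum(time, 1e-3).round(4),
            "event": event,
            "contamination": contamination.round(6),
            "risk_score": risk.round(6),
        }
    )
    return meta


def reference_channel_id(config: SimConfig) -> str:
    return f"ch{config.channels_per_plex:02d}"


def plex_layout(metadata: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Long-format layout: one row per (plex, channel) with the sample id, the
    reference channel rows carrying sample_id='REF'."""
    rows = [
        {"plex": r.plex, "channel": r.channel, "sample_id": r.sample_id}
        for r in metadata.itertuples()
    ]
    for plex in sorted(metadata["plex"].unique()):
        rows.append({"plex": plex, "channel": reference_channel_id(config), "sample_id": "REF"})
    return pd.DataFrame(rows).sort_values(["plex", "channel"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# abundances and PSM table


def _protein_roles(config: SimConfig, rng: np.random.Generator):
    """Assign disjoint roles: markers, contaminant-correlated, confounded,
    planted-DEP, survival proteins."""
    ids = [f"P{i + 1:05d}" for i in range(config.n_proteins - len(MARKER_PROTEINS))]
    ids += list(MARKER_PROTEINS)
    non_marker = np.array(ids[: -len(MARKER_PROTEINS)])
    perm = rng.permutation(len(non_marker))
    n_cont = min(config.n_contaminant_proteins, len(non_marker))
    cont_ids = list(non_marker[perm[:n_cont]])
    rest = perm[n_cont:]
    n_conf = min(config.n_confounded_proteins, len(rest))
    conf_ids = list(non_marker[rest[:n_conf]])
    rest = rest[n_conf:]
    n_dep = min(int(round(config.frac_dep * config.n_proteins)), len(rest))
    dep_ids = list(non_marker[rest[:n_dep]])
    rest = rest[n_dep:]
    n_surv = min(config.n_survival_proteins, len(rest))
    surv_ids = list(non_marker[rest[:n_surv]])
    return ids, cont_ids, conf_ids, dep_ids, surv_ids


def simulate_protein_abundance(
    metadata: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """True per-sample log2 abundances (proteins x samples) plus ground truth.

    abundance = baseline + planted subgroup effect + confounder effects
    + contamination_beta * contamination (contaminant proteins)
    + marker_slope * contamination (markers) + N(0, sigma_protein).
    Plex batch effects are NOT included here; they are applied to intensities
    in :func:`simulate_psm_table` (they are a measurement artifact).
    """
    rng = _rng(config, 2)
    ids, cont_ids, conf_ids, dep_ids, surv_ids = _protein_roles(config, rng)
    n_p, n_s = len(ids), len(metadata)
    idx = {p: i for i, p in enumerate(ids)}

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_p)
    A = np.tile(baseline[:, None], (1, n_s))

    # planted subgroup effects: each DEP affects exactly one HGG subgroup, sign +-
    cnames = contrast_names()
    true_fc = pd.DataFrame(0.0, index=ids, columns=cnames)
    dep_by_contrast: dict[str, list[str]] = {c: [] for c in cnames}
    sub = metadata["subgroup"].to_numpy()
    if dep_ids:
        target = rng.integers(0, len(cnames), size=len(dep_ids))
        sign = rng.choice([-1.0, 1.0], size=len(dep_ids))
        for pid, tg, sg in zip(dep_ids, target, sign):
            contrast = cnames[tg]
            group = SUBGROUPS[1:][tg]
            eff = sg * config.planted_log2fc
            A[idx[pid], sub == group] += eff
            true_fc.loc[pid, contrast] = eff
            dep_by_contrast[contrast].append(pid)

    # confounder effects on a subset of proteins
    age_c = (metadata["age"].to_numpy() - metadata["age"].mean()) / 10.0
    covs = np.vstack(
        [age_c]
        + [metadata[c].to_numpy().astype(float) for c in ("sex", "epilepsy", "steroids")]
    )
    if conf_ids:
        betas = rng.normal(0.0, config.confounder_sd, size=(len(conf_ids), covs.shape[0]))
        rows = [idx[p] for p in conf_ids]
        A[rows, :] += betas @ covs

    contam = metadata["contamination"].to_numpy()
    for pid in cont_ids:
        A[idx[pid], :] += config.contamination_beta * contam
    # marker protein amount is proportional to the non-neoplastic cell
    # fraction (cells carry the marker, tumor cells do not), so its log2
    # abundance tracks log2(contamination); marker_slope=1 is proportionality
    for m in MARKER_PROTEINS:
        A[idx[m], :] = (
            config.baseline_log2_mean
            + config.marker_baseline_offset
            + config.marker_slope * np.log2(contam)
        )

    # survival proteins track the latent risk score
    risk = metadata["risk_score"].to_numpy()
    for pid in surv_ids:
        A[idx[pid], :] += risk

    A += rng.normal(0.0, config.sigma_protein, size=(n_p, n_s))

    abundance = pd.DataFrame(A, index=ids, columns=metadata["sample_id"].to_numpy())
    truth = GroundTruth(
        protein_ids=ids,
        dep_ids=dep_by_contrast,
        true_log2fc=true_fc,
        contamination=pd.Series(contam, index=abundance.columns, name="contamination"),
        plex_effects=pd.Series(dtype=float),
        contaminant_ids=cont_ids,
        marker_ids=list(MARKER_PROTEINS),
        confounded_ids=conf_ids,
        survival_protein_ids=surv_ids,
        survival_beta=config.survival_beta,
        risk_score=pd.Series(risk, index=abundance.columns, name="risk_score"),
    )
    return abundance, truth


def simulate_psm_table(
    metadata: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the PSM-level reporter-ion table for the whole study.

    Per-sample intensity = 2**abundance * 2**plex_effect. The reference
    channel of each plex carries the pooled profile (arithmetic mean of the
    sample intensities, study-wide by default) under the same plex effect.
    Each protein/plex intensity vector is split over ``psm_per_protein`` PSM
    records with Dirichlet shares and multiplicative log-normal noise.

    Returns the long-format table (protein_id, plex, channel, intensity) and
    the :class:`GroundTruth`.
    """
    abundance, truth = simulate_protein_abundance(metadata, config)
    rng = _rng(config, 3)
    plexes = sorted(metadata["plex"].unique())
    plex_eff = rng.normal(0.0, config.plex_effect_sd, size=len(plexes))
    truth.plex_effects = pd.Series(plex_eff, index=plexes, name="plex_log2_effect")

    intens = np.power(2.0, abundance.to_numpy())
    ref_ch = reference_channel_id(config)
    sample_plex = metadata.set_index("sample_id")["plex"]
    sample_channel = metadata.set_index("sample_id")["channel"]

    frames = []
    for pi, plex in enumerate(plexes):
        cols = [s for s in abundance.columns if sample_plex[s] == plex]
        if config.reference_scope == "study":
            ref = intens.mean(axis=1)
        else:
            ref = intens[:, [abundance.columns.get_loc(s) for s in cols]].mean(axis=1)
        chan_ids = [sample_channel[s] for s in cols] + [ref_ch]
        mat = np.column_stack(
            [intens[:, abundance.columns.get_loc(s)] for s in cols] + [ref]
        )
        mat = mat * 2.0 ** plex_eff[pi]

        k = config.psm_per_protein
        if k == 1:
            shares = np.ones((len(abundance), 1))
        else:
            shares = rng.dirichlet(np.full(k, config.psm_dirichlet), size=len(abundance))
        for j in range(k):
            noise = (
                2.0 ** rng.normal(0.0, config.psm_noise_sd, size=mat.shape)
                if config.psm_noise_sd > 0
                else 1.0
            )
            sub_mat = mat * shares[:, [j]] * noise
            df = pd.DataFrame(sub_mat, index=abundance.index, columns=chan_ids)
            long = df.reset_index(names="protein_id").melt(
                id_vars="protein_id", var_name="channel", value_name="intensity"
            )
            long.insert(1, "plex", plex)
            frames.append(long)
    psm = pd.concat(frames, ignore_index=True)
    psm = psm.sort_values(["plex", "channel", "protein_id"], kind="mergesort").reset_index(
        drop=True
    )
    return psm, truth


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(
    truth: GroundTruth,
    n_random_sets: int = 20,
    set_size: int = 25,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Gene-set collection with one enriched set per contrast plus random sets.

    Each planted set takes the contrast's *up-regulated* DEPs (coherent
    direction — members shifted in opposite directions cancel in a running
    enrichment sum), padded with random proteins up to ``set_size``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 17]))
    pool = [p for p in truth.protein_ids if p not in truth.marker_ids]
    sets: dict[str, list[str]] = {}
    for contrast, deps in truth.dep_ids.items():
        up = [p for p in deps if truth.true_log2fc.loc[p, contrast] > 0]
        members = list(up[:set_size])
        if len(members) < set_size:
            extra = [p for p in pool if p not in members]
            members += list(rng.choice(extra, size=set_size - len(members), replace=False))
        sets[f"PLANTED_{contrast}"] = sorted(members)
    for i in range(n_random_sets):
        sets[f"RANDOM_{i + 1:02d}"] = sorted(
            rng.choice(pool, size=set_size, replace=False).tolist()
        )
    return sets


# ---------------------------------------------------------------------------
# dose-response plates


def four_pl(x_log10: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float):
    """Variable-slope 4PL: Y = bottom + (top-bottom)/(1+10**((logIC50-X)*hill))."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - x_log10) * hill))


def simulate_dose_response(
    config: SimConfig,
    samples: Sequence[str] = ("GB1", "GB2", "GB3", "GB4"),
    compounds: Sequence[str] = ("inhibitorA", "inhibitorB"),
    conc_range: tuple[float, float] = (5e-11, 5e-4),
    n_control_wells: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate viability plates: an n-point log-dilution series per
    sample/compound in ``dose_replicates`` replicates plus untreated control
    wells, luminescence on an arbitrary raw scale.

    Returns (plate table, true parameter table). Plate columns: sample,
    compound, concentration_molar, replicate, raw_signal, is_control.
    True parameters (per sample x compound): bottom, top, log_ic50, hill on
    the normalized-viability scale.
    """
    lo, hi = conc_range
    if lo <= 0 or hi <= 0:
        raise ValueError("concentrations must be strictly positive")
    rng = _rng(config, 4)
    concs = np.logspace(np.log10(lo), np.log10(hi), config.dose_n_concentrations)
    rows, params = [], []
    for s in samples:
        scale = rng.uniform(5e4, 5e5)  # raw luminescence per unit viability
        for cpd in compounds:
            bottom = rng.uniform(0.0, 0.25)
            top = 1.0
            log_ic50 = rng.uniform(np.log10(lo) + 1.0, np.log10(hi) - 1.0)
            hill = rng.uniform(0.6, 2.0)
            params.append(
                {"sample": s, "compound": cpd, "bottom": bottom, "top": top,
                 "log_ic50": log_ic50, "hill": hill}
            )
            for c in concs:
                mu = four_pl(np.log10(c), bottom, top, log_ic50, hill)
                for rep in range(1, config.dose_replicates + 1):
                    y = mu + (rng.normal(0.0, config.dose_noise_sd) if config.dose_noise_sd > 0 else 0.0)
                    rows.append(
                        {"sample": s, "compound": cpd, "concentration_molar": c,
                         "replicate": rep, "raw_signal": y * scale, "is_control": 0}
                    )
            for rep in range(1, n_control_wells + 1):
                y = top + (rng.normal(0.0, config.dose_noise_sd) if config.dose_noise_sd > 0 else 0.0)
                rows.append(
                    {"sample": s, "compound": cpd, "concentration_molar": 0.0,
                     "replicate": rep, "raw_signal": y * scale, "is_control": 1}
                )
    return pd.DataFrame(rows), pd.DataFrame(params)


# ---------------------------------------------------------------------------
# writers


def write_study(
    outdir,
    metadata: pd.DataFrame,
    psm: pd.DataFrame,
    layout: pd.DataFrame,
    truth: GroundTruth,
    gene_sets: Optional[dict[str, list[str]]] = None,
) -> dict[str, str]:
    """Write a simulated study to disk (PSM TSV, metadata CSV, layout CSV,
    ground-truth JSON, optional GMT). Returns the path map."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = out / "psm_table.tsv"
    psm.to_csv(p, sep="\t", index=False, float_format="%.6f")
    paths["psm_table"] = str(p)
    p = out / "metadata.csv"
    metadata.to_csv(p, index=False)
    paths["metadata"] = str(p)
    p = out / "plex_layout.csv"
    layout.to_csv(p, index=False)
    paths["plex_layout"] = str(p)
    p = out / "ground_truth.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "dep_ids": truth.dep_ids,
                "contaminant_ids": truth.contaminant_ids,
                "marker_ids": truth.marker_ids,
                "confounded_ids": truth.confounded_ids,
                "survival_protein_ids": truth.survival_protein_ids,
                "survival_beta": truth.survival_beta,
                "plex_effects": truth.plex_effects.to_dict(),
                "contamination": truth.contamination.to_dict(),
            },
            fh,
            indent=1,
        )
    paths["ground_truth"] = str(p)
    if gene_sets is not None:
        from .enrichment import write_gmt

        p = out / "gene_sets.gmt"
        write_gmt(gene_sets, p)
        paths["gene_sets"] = str(p)
    return paths
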