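import numpy as np
import pandas as pd
import pytest

import gliomaprot as gp


@pytest.fixture(scope="session")
def small_config() -> gp.SimConfig:
    """A fast default-noise study: 82 samples, 6 plexes, 300 proteins."""
    return gp.SimConfig(seed=101, n_proteins=300)


@pytest.fixture(scope="session")
def small_study(small_config):
    meta = gp.simulate_cohort(small_config)
    psm, truth = gp.simulate_psm_table(meta, small_config)
    return small_config, meta, psm, truth


@pytest.fixture(scope="session")
def small_matrix(small_study):
    config, meta, psm, truth = small_study
    layout = gp.plex_layout(meta, config)
    matrix, provenance = gp.normalize_psm_table(psm, layout)
    return matrix, meta, truth, provenance


def zero_noise_config(seed: int = 2, n_proteins: int = 400) -> gp.SimConfig:
    """All noise terms off; no survival-tracking proteins (their latent risk
    signal is variance the design does not model)."""
    return gp.SimConfig(
        seed=seed,
        n_proteins=n_proteins,
        sigma_protein=0.0,
        psm_noise_sd=0.0,
        baseline_log2_sd=0.0,
        plex_effect_sd=0.0,
        n_survival_proteins=0,
    )


def contamination_config(seed: int, n_proteins: int = 2000) -> gp.SimConfig:
    """Purity confounded with subgroup: infiltrative LGG carry the most
    non-neoplastic tissue."""
    return gp.SimConfig(
        seed=seed,
        n_proteins=n_proteins,
        contamination_mean_per_subgroup=(0.40, 0.25, 0.20, 0.20, 0.20),
    )
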