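"""Linear models, moderation, BH, contrasts, and purity-marker exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import gliomaprot as gp
from gliomaprot.diffexp import (
    bh_adjust,
    estimate_prior,
    marker_association,
    subgroup_contrasts,
)
from gliomaprot.diffexp import test_contrasts as run_contrasts
from gliomaprot.normalize import ProteinMatrix

from conftest import contamination_config, zero_noise_config


def toy_matrix(Y, sample_ids=None):
    sample_ids = sample_ids or [f"S{i}" for i in range(Y.shape[1])]
    return ProteinMatrix(
        data=pd.DataFrame(Y, index=[f"P{i}" for i in range(Y.shape[0])], columns=sample_ids),
        state="log2_complete",
    )


def two_group_design(n1, n2):
    X = pd.DataFrame(
        {"intercept": np.ones(n1 + n2), "group": [0.0] * n1 + [1.0] * n2}
    )
    X.index = [f"S{i}" for i in range(n1 + n2)]
    return X


class TestBuildDesign:
    def test_default_design_has_14_columns(self, small_matrix):
        matrix, meta, _, _ = small_matrix
        X = gp.build_design(meta, matrix)
        assert X.shape == (82, 14)  # intercept + 4 subgroups + 6 covariates + 3 markers
        assert np.linalg.matrix_rank(X.to_numpy()) == 14

    def test_constant_covariate_named_in_error(self, small_matrix):
        matrix, meta, _, _ = small_matrix
        meta = meta.copy()
        meta["sex"] = 1
        with pytest.raises(ValueError, match="sex"):
            gp.build_design(meta, matrix)

    def test_missing_marker_protein_rejected(self, small_matrix):
        matrix, meta, _, _ = small_matrix
        spec = gp.DesignSpec(marker_proteins=("NOT_A_PROTEIN",))
        with pytest.raises(ValueError, match="NOT_A_PROTEIN"):
            gp.build_design(meta, matrix, spec)


class TestOls:
    def test_two_group_exact_means(self):
        Y = np.array([[1.0, 1.0, 3.0, 3.0]])
        fit = gp.fit_linear_models(toy_matrix(Y), two_group_design(2, 2))
        assert fit.coef.loc["P0", "group"] == pytest.approx(2.0)
        assert fit.sigma2["P0"] == 0.0

    def test_identical_groups_zero_coefficient(self):
        Y = np.array([[2.0, 2.0, 2.0, 2.0]])
        fit = gp.fit_linear_models(toy_matrix(Y), two_group_design(2, 2))
        assert fit.coef.loc["P0", "group"] == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        n, p, k = 12, 4, 20
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        Y = rng.standard_normal((k, n))
        design = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)],
                              index=[f"S{i}" for i in range(n)])
        fit = gp.fit_linear_models(toy_matrix(Y), design)
        for g in range(k):
            beta = np.linalg.solve(X.T @ X, X.T @ Y[g])  # brute-force normal equations
            assert np.allclose(fit.coef.iloc[g].to_numpy(), beta, atol=1e-10)
            resid = Y[g] - X @ beta
            assert fit.sigma2.iloc[g] == pytest.approx(resid @ resid / (n - p), abs=1e-10)

    def test_underdetermined_rejected(self):
        Y = np.zeros((3, 2))
        with pytest.raises(ValueError):
            gp.fit_linear_models(toy_matrix(Y), two_group_design(1, 1))


class TestEbayes:
    def test_d0_zero_keeps_ordinary_variances(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((20, 10))
        fit = gp.fit_linear_models(toy_matrix(Y), two_group_design(5, 5))
        mod = gp.ebayes_moderate(fit, d0=0.0, s02=1.0)
        assert np.allclose(mod.post_var, mod.sigma2)

    def test_equal_variances_are_shrinkage_fixed_point(self):
        fit = gp.fit_linear_models(
            toy_matrix(np.tile([0.0, 1.0, 0.0, 1.0], (12, 1))), two_group_design(2, 2)
        )
        # all residual variances equal -> pooled branch, posterior == common value
        mod = gp.ebayes_moderate(fit)
        assert np.isinf(mod.d0)
        assert np.allclose(mod.post_var, mod.sigma2.iloc[0])

    def test_posterior_between_s2_and_s02(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((50, 8)) * rng.uniform(0.5, 2.0, size=(50, 1))
        fit = gp.ebayes_moderate(gp.fit_linear_models(toy_matrix(Y), two_group_design(4, 4)))
        lo = np.minimum(fit.sigma2, fit.s02)
        hi = np.maximum(fit.sigma2, fit.s02)
        assert ((fit.post_var >= lo - 1e-12) & (fit.post_var <= hi + 1e-12)).all()

    def test_prior_recovery_from_simulated_variances(self):
        # s^2 ~ s02 * F(d, d0) with d0=4, s02=2: moments estimate within 20%
        rng = np.random.default_rng(2024)
        d, d0, s02, k = 10, 4.0, 2.0, 5000
        sigma_g2 = s02 * d0 / rng.chisquare(d0, size=k)
        s2 = sigma_g2 * rng.chisquare(d, size=k) / d
        d0_hat, s02_hat = estimate_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.2)
        assert s02_hat == pytest.approx(s02, rel=0.2)


class TestContrasts:
    def test_zero_contrast_gives_null_result(self):
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((15, 10))
        fit = gp.ebayes_moderate(gp.fit_linear_models(toy_matrix(Y), two_group_design(5, 5)))
        res = run_contrasts(fit, {"null": np.zeros(2)})["null"]
        assert (res["log2fc"] == 0).all()
        assert (res["p"] == 1.0).all()

    def test_planted_effect_recovered_exactly_without_noise(self):
        Y = np.vstack([
            np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]),
            np.array([5.0, 5.0, 5.0, 5.0, 5.0, 5.0]),
        ] * 6)
        fit = gp.ebayes_moderate(gp.fit_linear_models(toy_matrix(Y), two_group_design(3, 3)))
        res = run_contrasts(fit, {"g": np.array([0.0, 1.0])})["g"]
        assert res["log2fc"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] == 0.0  # zero residual variance, nonzero effect

    def test_contrast_length_mismatch(self):
        rng = np.random.default_rng(5)
        fit = gp.fit_linear_models(toy_matrix(rng.standard_normal((12, 6))), two_group_design(3, 3))
        with pytest.raises(ValueError, match="length"):
            run_contrasts(fit, {"bad": np.zeros(5)})


class TestBhAdjust:
    def test_closed_form_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_step_up_definition(self, ps):
        p = np.asarray(ps)
        adj = bh_adjust(p)
        # brute-force step-up definition
        m = len(p)
        expected = np.empty(m)
        for i, pi in enumerate(p):
            rank_vals = []
            for j, pj in enumerate(p):
                if pj >= pi:
                    rank = (p <= pj).sum()
                    rank_vals.append(pj * m / rank)
            expected[i] = min(1.0, min(rank_vals))
        assert np.allclose(adj, expected, atol=1e-12)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


class TestMarkerExclusion:
    def test_zero_marker_coefficients_not_excluded(self):
        rng = np.random.default_rng(6)
        n = 20
        X = pd.DataFrame({
            "intercept": np.ones(n),
            "group": rng.integers(0, 2, n).astype(float),
            "marker_PTPRC": rng.standard_normal(n),
        }, index=[f"S{i}" for i in range(n)])
        # responses independent of the marker: coefficients near zero
        Y = np.tile(X["group"].to_numpy(), (15, 1)) + rng.standard_normal((15, n)) * 0.1
        fit = gp.ebayes_moderate(gp.fit_linear_models(toy_matrix(Y), X))
        assoc = marker_association(fit, 0.05)
        assert assoc["marker_associated"].mean() < 0.3

    def test_contaminant_proteins_excluded_and_planted_retained(self):
        # purity screen: contamination-correlated proteins are flagged,
        # planted DEPs (independent of contamination) survive
        excluded = np.zeros(2)
        totals = np.zeros(2)
        for seed in range(6):
            cfg = gp.SimConfig(seed=seed, n_proteins=2000)
            meta = gp.simulate_cohort(cfg)
            psm, truth = gp.simulate_psm_table(meta, cfg)
            matrix, _ = gp.normalize_psm_table(psm, gp.plex_layout(meta, cfg))
            fit = gp.ebayes_moderate(
                gp.fit_linear_models(matrix, gp.build_design(meta, matrix))
            )
            assoc = marker_association(fit, 0.05)
            flagged = set(assoc.index[assoc["marker_associated"]])
            excluded[0] += len(set(truth.contaminant_ids) & flagged)
            totals[0] += len(truth.contaminant_ids)
            planted = {p for v in truth.dep_ids.values() for p in v}
            excluded[1] += len(planted & flagged)
            totals[1] += len(planted)
        assert excluded[0] / totals[0] >= 0.9       # contaminants caught
        assert 1 - excluded[1] / totals[1] >= 0.9   # planted DEPs retained

    def test_threshold_validation(self, small_matrix):
        matrix, meta, _, _ = small_matrix
        fit = gp.ebayes_moderate(gp.fit_linear_models(matrix, gp.build_design(meta, matrix)))
        with pytest.raises(ValueError):
            marker_association(fit, threshold=1.5)

    def test_exclusion_report_counts(self, small_matrix):
        matrix, meta, _, _ = small_matrix
        results, report, _ = gp.differential_expression(matrix, meta)
        for name, entry in report["contrasts"].items():
            tab = results[name]
            assert entry["n_dep_final"] == int(tab["dep_final"].sum())
            assert entry["n_excluded"] == int(tab["excluded"].sum())
            assert (tab.loc[tab["excluded"], "marker_associated"]).all()


class TestFdrControl:
    def test_null_simulations_control_fdr(self):
        # no planted effects: fraction of BH-significant proteins stays at
        # or below the nominal level on average
        fractions = []
        for seed in range(10):
            cfg = gp.SimConfig(seed=seed + 500, n_proteins=1000, frac_dep=0.0,
                               n_contaminant_proteins=0)
            meta = gp.simulate_cohort(cfg)
            psm, _ = gp.simulate_psm_table(meta, cfg)
            matrix, _ = gp.normalize_psm_table(psm, gp.plex_layout(meta, cfg))
            results, _, _ = gp.differential_expression(
                matrix, meta, with_counterfactual=False
            )
            for tab in results.values():
                fractions.append(tab["dep"].mean())
        assert np.mean(fractions) <= 0.05 + 0.03


class TestPooledOthersContrast:
    def test_contrast_vector_structure(self, small_matrix):
        matrix, meta, _, _ = small_matrix
        X = gp.build_design(meta, matrix)
        v = gp.pooled_others_contrast(X, "GB_PN")
        assert v[X.columns.get_loc("subgroup_GB_PN")] == 1.0
        others = [c for c in X.columns if c.startswith("subgroup_") and c != "subgroup_GB_PN"]
        for c in others:
            assert v[X.columns.get_loc(c)] == pytest.approx(-0.25)
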