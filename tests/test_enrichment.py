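"""ORA hypergeometrics, ranking metrics, GSEA running sum and permutation null."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

import gliomaprot as gp
from gliomaprot.enrichment import enrichment_score

from conftest import contamination_config


TOY_RANK = pd.Series(
    [3.0, 2.0, 1.0, 0.5, -0.5, -1.0, -2.0, -3.0], index=list("ABCDEFGH")
)


def oracle_es(ranked: pd.Series, members: set, weight: float) -> float:
    """Hand-coded running-sum oracle, step by step."""
    total = sum(abs(s) ** weight for i, s in ranked.items() if i in members)
    miss = 1.0 / (len(ranked) - len(members))
    run, best = 0.0, 0.0
    for i, s in ranked.items():
        run += (abs(s) ** weight) / total if i in members else -miss
        if abs(run) > abs(best):
            best = run
    return best


class TestOra:
    def test_zero_overlap_p_one(self):
        uni = [f"g{i}" for i in range(50)]
        res = gp.ora_test(uni[:10], uni, {"s": uni[40:]})
        assert res.loc["s", "p"] == pytest.approx(1.0)

    def test_matches_direct_hypergeometric_sum(self):
        # universe 100, set 10, query 20, overlap 5
        uni = [f"g{i}" for i in range(100)]
        gene_set = uni[:10]
        query = uni[:5] + uni[50:65]
        res = gp.ora_test(query, uni, {"s": gene_set})
        expected = sum(
            comb(10, k) * comb(90, 20 - k) / comb(100, 20) for k in range(5, 11)
        )
        assert res.loc["s", "p"] == pytest.approx(expected, rel=1e-12)

    def test_query_equals_universe_degenerate(self):
        uni = [f"g{i}" for i in range(30)]
        res = gp.ora_test(uni, uni, {"s": uni[:7]})
        assert res.loc["s", "overlap"] == 7
        assert res.loc["s", "p"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            gp.ora_test(["x"], ["a", "b"], {"s": ["a"]})

    def test_agrees_with_fisher_2x2(self):
        # cross-module consistency: upper-tail hypergeometric equals the
        # one-sided Fisher tail of the equivalent 2x2 table
        from scipy.stats import fisher_exact

        M, S, N, k = 60, 12, 15, 6
        uni = [f"g{i}" for i in range(M)]
        gene_set = uni[:S]
        query = uni[:k] + uni[S : S + N - k]
        res = gp.ora_test(query, uni, {"s": gene_set})
        table = [[k, S - k], [N - k, M - S - (N - k)]]
        _, p = fisher_exact(table, alternative="greater")
        assert res.loc["s", "p"] == pytest.approx(p, rel=1e-9)


class TestRankProteins:
    def test_signed_p_formula(self):
        tab = pd.DataFrame(
            {"log2fc": [2.0, -1.0], "p": [0.01, 0.1]}, index=["up", "down"]
        )
        ranked = gp.rank_proteins(tab, "signed_p")
        assert ranked["up"] == pytest.approx(2.0)    # +(-log10 0.01)
        assert ranked["down"] == pytest.approx(-1.0)  # -(-log10 0.1)

    def test_p_zero_capped(self):
        tab = pd.DataFrame({"log2fc": [1.0], "p": [0.0]}, index=["a"])
        assert gp.rank_proteins(tab, "signed_p")["a"] == pytest.approx(320.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {"log2fc": rng.standard_normal(30), "p": rng.uniform(0.001, 1, 30)},
            index=[f"p{i}" for i in range(30)],
        )
        a = gp.rank_proteins(tab, "log2fc")
        b = gp.rank_proteins(tab.sample(frac=1, random_state=1), "log2fc")
        assert list(a.index) == list(b.index)


class TestGsea:
    def test_top_ranked_singleton_hits_es_one(self):
        es, pos, _ = enrichment_score(TOY_RANK, {"A"}, weight=0.0)
        assert es == pytest.approx(1.0)
        assert pos == 0

    def test_es_matches_exhaustive_oracle(self):
        for members in combinations(TOY_RANK.index, 3):
            es, _, _ = enrichment_score(TOY_RANK, set(members), 1.0)
            assert es == pytest.approx(oracle_es(TOY_RANK, set(members), 1.0), abs=1e-12)

    def test_exact_permutation_p_matches_enumeration(self):
        # 8-item ranking, 3-item set: the exhaustive gene-label null is all
        # C(8,3) = 56 labelings; compare gsea's p against direct enumeration
        members = {"A", "B", "C"}
        res = gp.gsea(
            TOY_RANK, {"top": sorted(members)}, weight=1.0,
            min_size=1, max_size=8, exhaustive=True,
        )
        es_obs = oracle_es(TOY_RANK, members, 1.0)
        null = [
            oracle_es(TOY_RANK, set(c), 1.0)
            for c in combinations(TOY_RANK.index, 3)
        ]
        same = [e for e in null if np.sign(e) == np.sign(es_obs)]
        expected_p = (1 + sum(abs(e) >= abs(es_obs) - 1e-12 for e in same)) / (1 + len(same))
        assert res.loc["top", "p"] == pytest.approx(expected_p, rel=1e-12)
        assert res.loc["top", "es"] == pytest.approx(es_obs, abs=1e-12)
        assert len(null) == 56

    def test_set_absent_from_ranking_skipped(self):
        res = gp.gsea(TOY_RANK, {"ghost": ["X", "Y", "Z"]}, min_size=1, max_size=8)
        assert bool(res.loc["ghost", "skipped"])
        assert np.isnan(res.loc["ghost", "es"])

    def test_permutation_p_floor(self):
        rng = np.random.default_rng(3)
        ranked = pd.Series(
            np.sort(rng.standard_normal(60))[::-1], index=[f"g{i}" for i in range(60)]
        )
        res = gp.gsea(ranked, {"s": list(ranked.index[:12])}, n_perm=99,
                      min_size=1, max_size=60, seed=1)
        assert res.loc["s", "p"] >= 1.0 / 100.0

    def test_nes_sign_matches_es_sign(self):
        rng = np.random.default_rng(5)
        ranked = pd.Series(
            np.sort(rng.standard_normal(80))[::-1], index=[f"g{i}" for i in range(80)]
        )
        sets = {"hi": list(ranked.index[:15]), "lo": list(ranked.index[-15:])}
        res = gp.gsea(ranked, sets, n_perm=200, min_size=1, max_size=80, seed=2)
        tested = res[~res["skipped"]]
        assert (np.sign(tested["nes"]) == np.sign(tested["es"])).all()

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        ranked = pd.Series(
            np.sort(rng.standard_normal(50))[::-1], index=[f"g{i}" for i in range(50)]
        )
        sets = {"s": list(ranked.index[5:20])}
        a = gp.gsea(ranked, sets, n_perm=100, min_size=1, max_size=50, seed=7)
        b = gp.gsea(ranked, sets, n_perm=100, min_size=1, max_size=50, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestConsensus:
    def _toy_results(self, adj_a, adj_b, nes_a=2.0, nes_b=2.0):
        mk = lambda adj, nes: pd.DataFrame(
            {"size": 10, "es": np.sign(nes) * 0.5, "nes": nes, "p": adj,
             "adj_p": adj, "skipped": False}, index=["s"],
        )
        return mk(adj_a, nes_a), mk(adj_b, nes_b)

    def test_one_sided_significance_not_consensus(self):
        a, b = self._toy_results(0.01, 0.5)
        assert len(gp.consensus_terms(a, b)) == 0

    def test_sign_disagreement_not_consensus(self):
        a, b = self._toy_results(0.01, 0.01, nes_a=2.0, nes_b=-2.0)
        assert len(gp.consensus_terms(a, b)) == 0

    def test_both_significant_same_sign_kept(self):
        a, b = self._toy_results(0.01, 0.02)
        out = gp.consensus_terms(a, b)
        assert list(out.index) == ["s"]
        assert bool(out["consensus"].iloc[0])

    def test_mismatched_collections_rejected(self):
        a, b = self._toy_results(0.01, 0.01)
        b.index = ["other"]
        with pytest.raises(ValueError):
            gp.consensus_terms(a, b)

    def test_planted_enriched_set_reaches_consensus(self):
        # a set whose members are the up-regulated planted DEPs of one
        # contrast is significant under both ranking metrics, with matching
        # NES sign, in nearly every seeded study
        from gliomaprot.normalize import ProteinMatrix

        hits = 0
        n_runs = 20
        contrast = "GB_MES_vs_LGG"
        for seed in range(n_runs):
            cfg = gp.SimConfig(seed=seed, n_proteins=2000)
            meta = gp.simulate_cohort(cfg)
            abundance, truth = gp.simulate_protein_abundance(meta, cfg)
            matrix = ProteinMatrix(data=abundance, state="log2_complete")
            results, _, _ = gp.differential_expression(
                matrix, meta, with_counterfactual=False
            )
            up = [
                p for p in truth.dep_ids[contrast]
                if truth.true_log2fc.loc[p, contrast] > 0
            ]
            rng = np.random.default_rng(seed)
            pool = [p for p in truth.protein_ids if p not in truth.marker_ids]
            sets = {"ENRICHED": up}
            for i in range(10):
                sets[f"RANDOM_{i}"] = list(rng.choice(pool, size=len(up), replace=False))
            tab = results[contrast]
            runs_by_metric = {}
            for metric in ("log2fc", "signed_p"):
                ranked = gp.rank_proteins(tab, metric)
                runs_by_metric[metric] = gp.gsea(
                    ranked, sets, n_perm=1000, seed=seed, min_size=5, max_size=500
                )
            cons = gp.consensus_terms(
                runs_by_metric["log2fc"], runs_by_metric["signed_p"], alpha=0.05
            )
            if "ENRICHED" in cons.index:
                hits += 1
        assert hits >= 18


class TestSelectExtreme:
    def _results(self, nes: dict):
        return pd.DataFrame(
            {"nes": list(nes.values()), "skipped": False}, index=list(nes)
        )

    def test_k1_highest_and_lowest(self):
        hi, lo = gp.select_extreme_terms(self._results({"A": 2.1, "B": -1.7, "C": 0.3}), 1)
        assert list(hi.index) == ["A"]
        assert list(lo.index) == ["B"]

    def test_k_larger_than_results(self):
        hi, lo = gp.select_extreme_terms(self._results({"A": 1.0, "B": -1.0}), 5)
        assert list(hi.index) == ["A", "B"]
        assert list(lo.index) == ["B", "A"]

    def test_ties_break_lexicographically(self):
        hi, _ = gp.select_extreme_terms(self._results({"B": 1.0, "A": 1.0, "C": 0.0}), 2)
        assert list(hi.index) == ["A", "B"]

    def test_k_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gp.select_extreme_terms(self._results({"A": 1.0}), 0)


def test_gmt_round_trip(tmp_path):
    sets = {"alpha": ["g1", "g2", "g3"], "beta": ["g4", "g5"]}
    path = tmp_path / "sets.gmt"
    gp.write_gmt(sets, path)
    assert gp.read_gmt(path) == sets
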