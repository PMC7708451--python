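"""Frequent-itemset mining and rule statistics."""

import numpy as np
import pandas as pd
import pytest

from reggrammar import rules as rl


def random_occurrence(n_genes, n_motifs, density, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.random((n_genes, n_motifs)) < density,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"m{j}" for j in range(n_motifs)],
    )


class TestFPGrowth:
    def test_trivial_full_cooccurrence(self):
        occ = pd.DataFrame(True, index=["a", "b", "c"], columns=["m1", "m2"])
        out = rl.mine_itemsets(occ, min_genes=3, max_size=2)
        assert out == {frozenset({"m1", "m2"}): 3}

    def test_min_genes_above_cohort_size(self):
        occ = random_occurrence(5, 4, 0.9, 0)
        assert rl.mine_itemsets(occ, min_genes=10) == {}

    def test_empty_matrix(self):
        occ = pd.DataFrame(index=[], columns=["m1"], dtype=bool)
        assert rl.mine_itemsets(occ) == {}

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force(self, seed):
        occ = random_occurrence(50, 12, 0.3, seed)
        fp = rl.mine_itemsets(occ, min_genes=3, max_size=6)
        bf = rl.brute_force_itemsets(occ, min_genes=3, max_size=6)
        assert fp == bf

    def test_support_anti_monotone(self):
        occ = random_occurrence(60, 8, 0.4, 5)
        out = rl.mine_itemsets(occ, min_genes=3, max_size=4)
        for s, c in out.items():
            for sub, csub in out.items():
                if sub < s:
                    assert csub >= c


class TestRuleStats:
    def test_lift_hand_computation(self):
        # N=100: A in 20, B in 10, both in 8 -> lift 4.0
        occ = pd.DataFrame(False, index=[f"g{i}" for i in range(100)],
                           columns=["A", "B"])
        occ.iloc[:20, 0] = True
        occ.iloc[12:22, 1] = True  # 8 overlap with A (12..19)
        both = int((occ["A"] & occ["B"]).sum())
        assert both == 8
        r = rl.rule_stats(frozenset(["A", "B"]), occ)
        assert r.lift == pytest.approx(0.08 / (0.2 * 0.1))

    def test_chi2_closed_form(self):
        chi2, p = rl.chi2_2x2(np.array([[10, 10], [10, 70]]))
        assert chi2 == pytest.approx(14.0625)
        assert 0 < p < 1e-3

    def test_chi2_matches_scipy_oracle(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(2)
        for _ in range(20):
            t = rng.integers(1, 60, size=(2, 2))
            chi2, p = rl.chi2_2x2(t)
            ref = chi2_contingency(t, correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_confidence_all_splits_is_most_conservative(self):
        rng = np.random.default_rng(4)
        occ = pd.DataFrame(rng.random((60, 3)) < 0.5,
                           index=[f"g{i}" for i in range(60)],
                           columns=["A", "B", "C"])
        occ.iloc[:5] = True  # guarantee support
        s = frozenset(["A", "B", "C"])
        last = rl.rule_stats(s, occ, confidence_split="last")
        every = rl.rule_stats(s, occ, confidence_split="all")
        assert every.confidence <= last.confidence + 1e-12

    def test_zero_marginal_flagged(self):
        occ = pd.DataFrame(True, index=["a", "b", "c"], columns=["A", "B"])
        r = rl.rule_stats(frozenset(["A", "B"]), occ)
        assert "chi2_undefined" in r.flags

    def test_constant_carrier_expression_snr_infinite(self):
        occ = pd.DataFrame(True, index=["a", "b", "c"], columns=["A", "B"])
        tpm = pd.Series([5.0, 5.0, 5.0], index=["a", "b", "c"])
        r = rl.rule_stats(frozenset(["A", "B"]), occ, median_tpm=tpm)
        assert r.snr_infinite and np.isinf(r.snr)


class TestSignificantRules:
    def test_all_p_one_yields_empty(self):
        rs = [rl.Rule(frozenset({"a", "b"}), frozenset({"g1", "g2", "g3"}),
                      0.1, 0.5, 1.0, 0.0, 1.0) for _ in range(5)]
        kept, _ = rl.significant_rules(rs, alpha=0.05)
        assert kept == []

    def test_bh_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        rs = [rl.Rule(frozenset({f"a{i}", f"b{i}"}),
                      frozenset({"g1", "g2", "g3"}),
                      0.1, 0.5, 2.0, 1.0, float(p))
              for i, p in enumerate(rng.random(50) ** 3)]
        strict, _ = rl.significant_rules(list(rs), alpha=0.01)
        loose, _ = rl.significant_rules(list(rs), alpha=0.05)
        assert {r.motif_ids for r in strict} <= {r.motif_ids for r in loose}

    def test_fdr_calibration_under_null(self):
        """BH on an all-null occurrence matrix keeps realized FDR <= alpha."""
        rng = np.random.default_rng(7)
        fdrs = []
        for _ in range(300):
            occ = pd.DataFrame(
                rng.random((40, 8)) < 0.35,
                index=[f"g{i}" for i in range(40)],
                columns=[f"m{j}" for j in range(8)],
            )
            itemsets = rl.mine_itemsets(occ, min_genes=3, max_size=3)
            if not itemsets:
                fdrs.append(0.0)
                continue
            rs = [rl.rule_stats(s, occ) for s in itemsets]
            kept, _ = rl.significant_rules(rs, alpha=0.05)
            fdrs.append(1.0 if kept else 0.0)  # any discovery is false
        assert np.mean(fdrs) <= 0.05 + 0.03


class TestSpecificity:
    def _setup(self):
        occ = pd.DataFrame(False, index=[f"g{i}" for i in range(6)],
                           columns=["A", "B"])
        occ.loc[["g0", "g1", "g2"], "A"] = True
        occ.loc[["g0", "g1", "g2"], "B"] = True
        tpm = pd.Series([1.0, 10.0, 100.0, 5.0, 5.0, 1000.0],
                        index=occ.index)
        rule = rl.rule_stats(frozenset(["A", "B"]), occ, median_tpm=tpm)
        return occ, tpm, rule

    def test_identical_carrier_sets_identical_snr(self):
        occ, tpm, rule = self._setup()
        df = rl.specificity_contrast(occ, [rule], tpm)
        snrs = df.groupby("kind")["snr"].first()
        assert snrs["motif"] == pytest.approx(snrs["rule"])

    def test_full_range_recovery(self):
        occ = pd.DataFrame(False, index=["lo", "mid", "hi"], columns=["A", "B"])
        occ.loc[["lo", "hi"], ["A", "B"]] = True
        tpm = pd.Series([1.0, 50.0, 1000.0], index=occ.index)
        rule = rl.rule_stats(frozenset(["A", "B"]), occ, median_tpm=tpm)
        # single rule carrying the extremes: its mean is fixed, so the
        # across-item span is 0 -- range recovery needs >= 2 items
        df = rl.specificity_contrast(occ, [rule], tpm)
        assert set(df["kind"]) == {"motif", "rule"}


class TestRepurposing:
    def _rule(self, ids, mean_tpm):
        return rl.Rule(frozenset(ids), frozenset({"g1", "g2", "g3"}),
                       0.1, 0.5, 2.0, 5.0, 0.01, mean_tpm=mean_tpm)

    def test_common_motif_fold_range(self):
        r1 = self._rule(["A", "B", "C"], 5.0)
        r2 = self._rule(["A", "D", "E"], 50.0)
        df = rl.repurposing_groups([r1, r2], mode="common_motif")
        assert df.set_index("group").loc["A", "fold_range"] == pytest.approx(10.0)

    def test_equal_means_fold_one(self):
        r1 = self._rule(["A", "B", "C"], 7.0)
        r2 = self._rule(["A", "C", "D"], 7.0)
        df = rl.repurposing_groups([r1, r2], mode="common_motif")
        assert (df["fold_range"] == 1.0).all()

    def test_groups_of_one_excluded(self):
        df = rl.repurposing_groups([self._rule(["A", "B", "C"], 5.0)],
                                   mode="common_motif")
        assert df.empty


class TestCodonSpecificity:
    def test_basis_vectors_distance(self):
        occ = pd.DataFrame({"A": [True, True]}, index=["g1", "g2"])
        cp = pd.DataFrame(np.eye(2), index=["g1", "g2"])
        df = rl.codon_specificity(occ, [], cp)
        assert df.loc[0, "median_distance"] == pytest.approx(np.sqrt(2))

    def test_identical_vectors_zero(self):
        occ = pd.DataFrame({"A": [True, True]}, index=["g1", "g2"])
        cp = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["g1", "g2"])
        df = rl.codon_specificity(occ, [], cp)
        assert df.loc[0, "median_distance"] == 0.0

    def test_singletons_excluded(self):
        occ = pd.DataFrame({"A": [True, False]}, index=["g1", "g2"])
        cp = pd.DataFrame(np.eye(2), index=["g1", "g2"])
        assert rl.codon_specificity(occ, [], cp).empty
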