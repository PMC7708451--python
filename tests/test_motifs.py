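"""Window extraction, identity clustering, PWM building and comparison."""

import numpy as np
import pytest

from reggrammar import motifs as mt
from reggrammar.features import RegionLengths
from reggrammar.relevance import RelevanceProfile


def _window(seq, gene="g1", region="promoter", offset=0, rel=1.0):
    return mt.RelevantWindow(gene, region, offset, seq, rel)


class TestExtractWindows:
    def _profile(self, mask_promoter, values=None):
        lengths = RegionLengths.scaled()
        vals = {r: np.zeros(getattr(lengths, r)) for r in
                ("promoter", "utr5", "utr3", "terminator")}
        if values is not None:
            vals["promoter"] = values
        p = RelevanceProfile("g1", vals, 1.0)
        masks = {"g1": {r: np.zeros(getattr(lengths, r), bool) for r in vals}}
        masks["g1"]["promoter"] = mask_promoter
        return p, masks

    def _seqs(self):
        rng = np.random.default_rng(0)
        lengths = RegionLengths.scaled()
        return {"g1": {r: "".join(rng.choice(list("ACGT"),
                                             size=getattr(lengths, r)))
                       for r in ("promoter", "utr5", "utr3", "terminator")}}

    def test_empty_mask_empty_list(self):
        p, masks = self._profile(np.zeros(200, bool))
        assert mt.extract_windows([p], masks, self._seqs()) == []

    def test_exact_run_gives_one_window(self):
        m = np.zeros(200, bool)
        m[37:47] = True
        p, masks = self._profile(m)
        out = mt.extract_windows([p], masks, self._seqs())
        assert len(out) == 1 and out[0].offset == 37

    def test_long_run_tiled_with_right_aligned_tail(self):
        m = np.zeros(200, bool)
        m[40:65] = True  # 25 bp run, window 10
        p, masks = self._profile(m)
        out = mt.extract_windows([p], masks, self._seqs())
        assert [w.offset for w in out] == [40, 50, 55]

    def test_short_run_centred(self):
        m = np.zeros(200, bool)
        m[100:104] = True
        p, masks = self._profile(m)
        out = mt.extract_windows([p], masks, self._seqs())
        assert len(out) == 1
        assert out[0].offset == 97  # centre 102, window start 102-5


class TestIdentityCluster:
    def test_identical_sequences_one_cluster(self):
        ws = [_window("ACGTACGTAC", gene=f"g{i}") for i in range(5)]
        out = mt.identity_cluster(ws, 0.8, 5)
        assert len(out) == 1 and len(out[0][1]) == 5

    def test_hand_counted_identity(self):
        # 9 matches of 10 at shift 0 -> identity 0.9 >= 0.8
        ws = [_window("ACGTACGTAC", rel=2.0)] * 4 + [_window("ACGTACGTAG")]
        out = mt.identity_cluster(ws, 0.8, 5)
        assert len(out) == 1 and len(out[0][1]) == 5

    def test_min_cluster_filter(self):
        ws = [_window("ACGTACGTAC", gene=f"g{i}") for i in range(4)]
        assert mt.identity_cluster(ws, 0.8, 5) == []

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            mt.identity_cluster([_window("ACGT"), _window("ACGTA")])

    def test_deterministic_given_sort_order(self):
        rng = np.random.default_rng(1)
        ws = [_window("".join(rng.choice(list("ACGT"), 10)), gene=f"g{i}",
                      rel=float(rng.random())) for i in range(50)]
        a = mt.identity_cluster(list(ws), 0.8, 2)
        b = mt.identity_cluster(list(reversed(ws)), 0.8, 2)
        assert [[w.sequence for w in c[1]] for c in a] == \
               [[w.sequence for w in c[1]] for c in b]


class TestBuildPWM:
    def test_homogeneous_cluster_high_information(self):
        ws = [_window("AAAAAAAAAA", gene=f"g{i}") for i in range(5)]
        m = mt.build_pwm(ws[0], ws, [0] * 5, "m0")
        assert m is not None
        # columns are (5 + 0.25)/6 = 0.875 vs 0.25/6: information
        # 2 + 0.875 log2 0.875 + 3 * (0.25/6) log2 (0.25/6) = 1.2583 bits
        info = m.information_content()
        np.testing.assert_allclose(info, 1.2583, atol=1e-3)
        np.testing.assert_allclose(m.pwm.sum(axis=0), 1.0, atol=1e-9)

    def test_uniform_cluster_fully_trimmed(self):
        # four rotations of ACGT at every column: ~0 bits everywhere
        seqs = ["ACGTACGTAC", "CGTACGTACG", "GTACGTACGT", "TACGTACGTA"] * 2
        ws = [_window(s, gene=f"g{i}") for i, s in enumerate(seqs)]
        m = mt.build_pwm(ws[0], ws, [0] * len(ws), "m0")
        assert m is None

    def test_edge_trimming_keeps_interior(self):
        # conserved core, random-ish edges
        core = ["TT" + "ACGTAC" + "GA"]
        seqs = ["AA" + "ACGTAC" + "CC", "CC" + "ACGTAC" + "GG",
                "GG" + "ACGTAC" + "TT", "TT" + "ACGTAC" + "AA",
                "AC" + "ACGTAC" + "TG", "CA" + "ACGTAC" + "GT",
                "GT" + "ACGTAC" + "CA", "TG" + "ACGTAC" + "AC"]
        ws = [_window(s, gene=f"g{i}") for i, s in enumerate(seqs)]
        m = mt.build_pwm(ws[0], ws, [0] * len(ws), "m0")
        assert m is not None and m.width == 6
        assert m.consensus() == "ACGTAC"


class TestComparePWMs:
    def _motif(self, consensus, n=6):
        pwm = np.full((4, len(consensus)), 0.04)
        for j, ch in enumerate(consensus):
            pwm["ACGT".index(ch), j] = 0.88
        return mt.Motif("m", "promoter", pwm, [], [])

    def test_self_similarity_is_one(self):
        m = self._motif("ACGTACGT")
        score, p = mt.compare_pwms(m, m, n_permutations=50)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert p < 0.05

    def test_palindrome_matches_its_reverse_complement(self):
        # ACGCGT is its own reverse complement: the column-reversed
        # complement PWM scores 1.0 against the original
        pal = self._motif("ACGCGT")
        rc = pal.pwm[[3, 2, 1, 0], :][:, ::-1]
        rc_motif = mt.Motif("rc", "promoter", rc, [], [])
        score, _ = mt.compare_pwms(pal, rc_motif, n_permutations=50)
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_consensus_not_significant(self):
        a = self._motif("AAAAAAAA")
        b = self._motif("CCCCCCCC")
        _, p = mt.compare_pwms(a, b, n_permutations=500)
        assert p > 0.05

    def test_too_narrow_overlap_rejected(self):
        a = self._motif("ACG")
        with pytest.raises(ValueError):
            mt.compare_pwms(a, a)


class TestOccurrence:
    def test_member_window_semantics(self):
        ws = [_window("ACGTACGTAC", gene=f"g{i}") for i in range(5)]
        ws.append(_window("ACGTACGTAC", gene="g0"))  # duplicate gene
        m = mt.Motif("m0", "promoter", np.full((4, 10), 0.25), ws, [0] * 6)
        occ = mt.occurrence_matrix([m], [f"g{i}" for i in range(6)])
        assert occ["m0"].sum() == 5  # boolean per gene
        assert occ.loc["g5", "m0"] == False  # noqa: E712

    def test_total_true_bounded_by_windows(self):
        ws = [_window("ACGTACGTAC", gene=f"g{i % 3}") for i in range(7)]
        m = mt.Motif("m0", "promoter", np.full((4, 10), 0.25), ws, [0] * 7)
        occ = mt.occurrence_matrix([m], ["g0", "g1", "g2"])
        assert occ.values.sum() <= len(ws)


class TestScanOccurrence:
    def test_pwm_scan_mode_finds_planted_instances(self):
        from reggrammar import synth

        cfg = synth.GeneratorConfig(n_genes=30, n_motifs=4, n_rules=3,
                                    cds_length=300)
        genes, truth = synth.generate_genome(cfg, seed=1)
        found = [mt.Motif(m.motif_id, m.region, m.pwm, [], [])
                 for m in truth.planted_motifs]
        seqs = {g.gene_id: g.regions for g in genes}
        occ = mt.scan_occurrence_matrix(found, seqs, score_fraction=0.8)
        for g in genes:
            for m in truth.planted_motifs:
                if g.carries(m.motif_id):
                    assert occ.loc[g.gene_id, m.motif_id]


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        pwm = rng.dirichlet(np.ones(4), size=8).T
        path = tmp_path / "m.meme"
        mt.write_meme([("motif_a", pwm, 12)], path)
        out = mt.read_meme(path)
        assert out[0][0] == "motif_a"
        np.testing.assert_allclose(out[0][1], pwm, atol=1e-6)
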