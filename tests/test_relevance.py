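"""Occlusion mechanics, profile averaging, masking, consensus clustering."""

import numpy as np
import pytest

from reggrammar import relevance as rv
from reggrammar.features import RegionLengths

LENGTHS = RegionLengths.scaled()  # 200/50/50/100


class _LinearModel:
    """Deterministic stand-in: prediction = w . columns-sums + b."""

    def __init__(self, w=None, b=3.0, L=LENGTHS.total):
        rng = np.random.default_rng(0)
        self.w = rng.normal(0, 0.1, (4, L)) if w is None else w
        self.b = b

    def predict(self, x_seq, x_num, batch=None):
        return np.array([(self.w * x).sum() + self.b for x in x_seq])


class _ConstantModel:
    def predict(self, x_seq, x_num, batch=None):
        return np.full(len(x_seq), 2.0)


def _onehot(seed=0):
    rng = np.random.default_rng(seed)
    x = np.zeros((4, LENGTHS.total), dtype=np.float32)
    x[rng.integers(0, 4, LENGTHS.total), np.arange(LENGTHS.total)] = 1
    return x


class TestOcclude:
    def test_whole_region(self):
        x = _onehot()
        out = rv.occlude(x, 0, x.shape[1])
        assert out.sum() == 0
        assert x.sum() > 0  # input not mutated

    def test_zero_width_is_identity(self):
        x = _onehot()
        np.testing.assert_array_equal(rv.occlude(x, 5, 0), x)

    def test_exact_column_counts(self):
        x = _onehot()
        out = rv.occlude(x, 3, 10)
        assert out[:, 3:13].sum() == 0
        np.testing.assert_array_equal(out[:, :3], x[:, :3])
        np.testing.assert_array_equal(out[:, 13:], x[:, 13:])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rv.occlude(_onehot(), 395, 10)


class TestRelevanceProfile:
    def test_constant_model_zero_relevance(self):
        p = rv.relevance_profile(_ConstantModel(), _onehot(), np.zeros(72),
                                 "g", LENGTHS)
        assert all(np.allclose(v, 0) for v in p.values.values())

    def test_single_window_region_uniform_value(self):
        """utr5 (50 bp) occluded with window 50 = whole-region mode."""
        m = _LinearModel()
        p = rv.relevance_profile(m, _onehot(), np.zeros(72), "g", LENGTHS,
                                 whole_regions=True)
        for region in ("promoter", "utr5", "utr3", "terminator"):
            v = p.values[region]
            assert np.allclose(v, v[0])

    def test_brute_force_window_equivalence(self):
        """Per-position averages equal direct recomputation from all
        window predictions (the occlusion oracle, to 1e-12)."""
        m = _LinearModel()
        x = _onehot(3)
        xn = np.zeros(72)
        p = rv.relevance_profile(m, x, xn, "g", LENGTHS, window=10)
        y = m.predict(x[None], xn[None])[0]
        spans = LENGTHS.offsets()
        for region in ("utr5", "terminator"):
            lo, hi = spans[region]
            L = hi - lo
            acc, cnt = np.zeros(L), np.zeros(L)
            for s in range(lo, hi - 10 + 1):
                yo = m.predict(rv.occlude(x, s, 10)[None], xn[None])[0]
                rel = (y - yo) / y
                acc[s - lo : s - lo + 10] += rel
                cnt[s - lo : s - lo + 10] += 1
            np.testing.assert_allclose(p.values[region], acc / cnt, atol=1e-12)

    def test_window_count_combinatorics(self):
        """L=100, window 10, stride 1 -> 91 windows; interior positions
        covered by 10 windows."""
        m = _LinearModel()
        calls = []
        orig = m.predict

        def counting(x_seq, x_num, batch=None):
            calls.append(len(x_seq))
            return orig(x_seq, x_num)

        m.predict = counting
        p = rv.relevance_profile(m, _onehot(), np.zeros(72), "g", LENGTHS)
        total_windows = sum(calls) - 1  # minus the intact prediction
        expected = sum(
            getattr(LENGTHS, r) - 10 + 1
            for r in ("promoter", "utr5", "utr3", "terminator")
        )
        assert total_windows == expected  # terminator: 91 windows

    def test_near_zero_y_flagged_unscaled(self):
        m = _LinearModel(w=np.zeros((4, LENGTHS.total)), b=0.0)
        p = rv.relevance_profile(m, _onehot(), np.zeros(72), "g", LENGTHS)
        assert p.unscaled


class TestSignificantPositions:
    def _profiles(self, values_list):
        out = []
        for i, vals in enumerate(values_list):
            out.append(rv.RelevanceProfile(f"g{i}", vals, 1.0))
        return out

    def _flat(self, fill=0.0):
        return {r: np.full(getattr(LENGTHS, r), fill)
                for r in ("promoter", "utr5", "utr3", "terminator")}

    def test_equal_relevance_nothing_significant(self):
        profiles = self._profiles([self._flat(0.5), self._flat(0.5)])
        with pytest.warns(UserWarning):
            masks = rv.significant_positions(profiles)
        assert all(not m.any() for gm in masks.values() for m in gm.values())

    def test_planted_spike_flagged_exactly(self):
        rng = np.random.default_rng(0)
        base = [self._flat() for _ in range(10)]
        for vals in base:
            for r in vals:
                vals[r] = rng.normal(0, 0.01, vals[r].size)
        base[0]["promoter"][40:50] += 10 * 0.01  # +10 SD spike
        profiles = self._profiles(base)
        masks = rv.significant_positions(profiles, cutoff_sd=2)
        assert masks["g0"]["promoter"][40:50].all()
        flagged = sum(m.sum() for gm in masks.values() for m in gm.values())
        assert flagged <= 10 + int(0.046 * 10 * LENGTHS.total * 1.5)

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            rv.significant_positions(self._profiles([self._flat()]))


class TestConsensusCluster:
    def test_two_duplicated_groups_block_diagonal(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0, 1, 60)
        X = np.stack([a + rng.normal(0, 0.01, 60) for _ in range(10)]
                     + [b + rng.normal(0, 0.01, 60) for _ in range(10)])
        out = rv.consensus_cluster(X, k_range=(2, 4), reps=30, seed=0)
        assert out["k"] == 2
        labels = out["labels"]
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]
        cons = out["consensus"][2]
        assert cons[:10, :10].min() > 0.9
        assert cons[:10, 10:].max() < 0.1

    def test_consensus_matrix_properties(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (15, 30))
        out = rv.consensus_cluster(X, k_range=(2, 3), reps=20, seed=1)
        for c in out["consensus"].values():
            assert np.allclose(c, c.T)
            assert np.allclose(np.diag(c), 1.0)
            assert c.min() >= 0 and c.max() <= 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (20, 25))
        a = rv.consensus_cluster(X, reps=10, seed=7)
        b = rv.consensus_cluster(X, reps=10, seed=7)
        np.testing.assert_array_equal(a["labels"], b["labels"])
        assert a["k"] == b["k"]

    def test_reps_validation(self):
        with pytest.raises(ValueError):
            rv.consensus_cluster(np.zeros((5, 5)), reps=1)
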