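import numpy as np
import pytest

from mgecompare.orf_finder import OrfCall
from mgecompare.seq_io import CircularSequence, revcomp
from mgecompare.skew_ori import (cumulative_skew, find_repeats,
                                 intergenic_regions, predict_ori)


def _orf(seq_id, start, end, strand="+"):
    return OrfCall(seq_id, start, end, strand, "ATG",
                   (end - start) // 3 - 1, 0, None, "")


class TestCumulativeSkew:
    def test_all_at_sequence_is_flat(self):
        p = cumulative_skew(CircularSequence("x", "ATATATAT"))
        assert np.allclose(p.values, 0.0)

    def test_hand_computed_walk(self):
        # GGGGCCCC: centered increments are the raw ones (mean 0);
        # walk 1,2,3,4,3,2,1,0 -> max after position 3, closure at 0
        p = cumulative_skew(CircularSequence("x", "GGGGCCCC"))
        assert list(p.values) == [1, 2, 3, 4, 3, 2, 1, 0]
        assert (int(np.argmax(p.values)) - int(np.argmin(p.values))) % 8 == 4

    def test_closure_at_zero(self, random_circle):
        for seed in range(3):
            s = random_circle(length=500, seed=seed)
            p = cumulative_skew(s)
            assert abs(p.values[-1]) < 1e-9

    def test_rotation_shifts_argmin(self, random_circle):
        s = random_circle(length=400, seed=3)
        base = int(np.argmin(cumulative_skew(s).values))
        for k in (1, 137, 399):
            rot = int(np.argmin(cumulative_skew(s.rotate(k)).values))
            assert (rot + k) % 400 == base

    def test_window_smoothing_preserves_length(self, random_circle):
        s = random_circle(length=300, seed=4)
        p = cumulative_skew(s, window=25)
        assert len(p.values) == 300


def _brute_force_repeats(s, min_len, circular):
    """All maximal repeat pairs by direct enumeration (small inputs only)."""
    L = len(s)

    def char(x, i):
        return x[i % L] if circular else (x[i] if 0 <= i < L else None)

    def maximal(i, j, kind):
        # extend a seed of length min_len at i, j to its maximal pair
        k = min_len
        if kind == "direct":
            while k < L - 1:
                a, b = char(s, i - 1), char(s, j - 1)
                if a is None or b is None or a != b:
                    break
                i, j, k = i - 1, j - 1, k + 1
            while k < L - 1:
                a, b = char(s, i + k), char(s, j + k)
                if a is None or b is None or a != b:
                    break
                k += 1
        else:
            comp = dict(zip("ACGTN", "TGCAN"))
            while k < L - 1:
                a, b = char(s, i - 1), char(s, j + k)
                if a is None or b is None or a != comp[b]:
                    break
                i, k = i - 1, k + 1
            while k < L - 1:
                a, b = char(s, i + k), char(s, j - 1)
                if a is None or b is None or a != comp[b]:
                    break
                j, k = j - 1, k + 1
        return (kind, *sorted(((i % L) if circular else i,
                               (j % L) if circular else j)), k)

    found = set()
    span = range(L) if circular else range(L - min_len + 1)

    def sub(i):
        return "".join(char(s, i + t) for t in range(min_len))

    for i in span:
        for j in span:
            if i < j and sub(i) == sub(j):
                found.add(maximal(i, j, "direct"))
            rc = revcomp(sub(j))
            if i < j and sub(i) == rc:
                found.add(maximal(i, j, "inverted"))
    return found


class TestFindRepeats:
    def test_planted_direct_repeat(self, rng):
        unit = "ACGTACGTACGT"
        base = list(rng.choice(list("ACGT"), size=200))
        base[20:32] = unit
        base[150:162] = unit
        seq = CircularSequence("x", "".join(base), circular=False)
        hits = find_repeats(seq, min_len=12)
        assert any(h.kind == "direct" and h.rep_len >= 12
                   and {20, 150} <= {h.pos1, h.pos2} for h in hits)

    def test_planted_inverted_repeat(self, rng):
        unit = "ACCGTTGACCAT"
        base = list(rng.choice(list("ACGT"), size=200))
        base[30:42] = unit
        base[160:172] = revcomp(unit)
        seq = CircularSequence("x", "".join(base), circular=False)
        hits = find_repeats(seq, min_len=12)
        assert any(h.kind == "inverted" and {30, 160} <= {h.pos1, h.pos2}
                   for h in hits)

    @pytest.mark.parametrize("circular", [False, True])
    def test_oracle_equivalence_small(self, circular):
        rng = np.random.default_rng(77)
        for trial in range(6):
            base = list(rng.choice(list("ACGT"), size=260))
            unit = "".join(rng.choice(list("ACGT"), size=14))
            base[10:24] = unit
            base[200:214] = unit if trial % 2 else revcomp(unit)
            s = "".join(base)
            seq = CircularSequence("x", s, circular=circular)
            impl = {(h.kind, h.pos1, h.pos2, h.rep_len)
                    for h in find_repeats(seq, min_len=9, max_pairs=10000)}
            oracle = _brute_force_repeats(s, 9, circular)
            assert impl == oracle


class TestIntergenicRegions:
    def test_complement_of_single_orf(self):
        seq = CircularSequence("x", "A" * 1000)
        regions = intergenic_regions(seq, [_orf("x", 0, 300)], min_len=150)
        assert regions == [(300, 1000)]

    def test_full_tiling_gives_empty(self):
        seq = CircularSequence("x", "A" * 600)
        assert intergenic_regions(seq, [_orf("x", 0, 600)]) == []

    def test_threshold_edge(self):
        seq = CircularSequence("x", "A" * 1000)
        orfs = [_orf("x", 0, 300), _orf("x", 449, 1000)]  # gap of 149
        assert intergenic_regions(seq, orfs, min_len=150) == []
        orfs = [_orf("x", 0, 300), _orf("x", 450, 1000)]  # gap of 150
        assert intergenic_regions(seq, orfs, min_len=150) == [(300, 450)]

    def test_wrap_around_gap(self):
        seq = CircularSequence("x", "A" * 1000)
        regions = intergenic_regions(seq, [_orf("x", 200, 900)], min_len=150)
        assert regions == [(900, 1200)]


class TestPredictOri:
    def _skewed_circle(self, L=4000, ori=1000, seed=0, bias=0.8):
        rng = np.random.default_rng(seed)
        ter = (ori + L // 2) % L
        bases = []
        for i in range(L):
            leading = (i - ori) % L < L // 2
            pg = 0.5 * (bias if leading else 1 - bias)
            pc = 0.5 - pg
            bases.append(rng.choice(list("AGCT"), p=[0.25, pg, pc, 0.25]))
        return CircularSequence("sk", "".join(bases))

    def test_minimum_found_near_planted_switch(self):
        seq = self._skewed_circle(seed=1)
        profile = cumulative_skew(seq, window=50)
        preds = predict_ori(seq, profile, [(800, 1200)], [])
        assert preds and preds[0].rank == 1
        d = min((preds[0].skew_min_pos - 1000) % 4000,
                (1000 - preds[0].skew_min_pos) % 4000)
        assert d <= 250

    def test_no_region_is_error(self):
        seq = self._skewed_circle(seed=2)
        profile = cumulative_skew(seq)
        with pytest.raises(ValueError):
            predict_ori(seq, profile, [], [])

    def test_flat_profile_warns_and_returns_empty(self):
        seq = CircularSequence("x", "AT" * 500)
        profile = cumulative_skew(seq)
        with pytest.warns(UserWarning):
            assert predict_ori(seq, profile, [(0, 100)], []) == []

    def test_two_valleys_both_reported(self):
        # two planted compositional switches -> two skew minima, one per
        # intergenic region; both candidate regions must be returned
        rng = np.random.default_rng(5)
        L = 4000
        bases = []
        # G-rich on (500..1500) and (2500..3500); C-rich elsewhere: minima
        # near 500 (shallower) and near 2500
        for i in range(L):
            g_rich = 500 <= i < 1500 or 2500 <= i < 3500
            pg = 0.42 if g_rich else 0.08
            bases.append(rng.choice(list("AGCT"), p=[0.25, pg, 0.5 - pg, 0.25]))
        seq = CircularSequence("x", "".join(bases))
        profile = cumulative_skew(seq, window=50)
        regions = [(400, 700), (2400, 2700)]
        preds = predict_ori(seq, profile, regions, [])
        assert len(preds) == 2
        assert {p.rank for p in preds} == {1, 2}
        assert {p.region for p in preds} == set(regions)
        assert all(p.dist_to_min == 0 for p in preds)

    def test_repeat_support_optional(self):
        seq = self._skewed_circle(seed=3)
        profile = cumulative_skew(seq, window=50)
        preds = predict_ori(seq, profile, [(800, 1200)], [])
        assert preds[0].repeat_support == 0

    def test_rotation_invariance_of_top_region(self):
        seq = self._skewed_circle(seed=4)
        profile = cumulative_skew(seq, window=50)
        top = predict_ori(seq, profile, [(800, 1200)], [])[0]
        k = 1234
        rot = seq.rotate(k)
        profile_r = cumulative_skew(rot, window=50)
        region_r = ((800 - k) % 4000, (800 - k) % 4000 + 400)
        top_r = predict_ori(rot, profile_r, [region_r], [])[0]
        assert (top_r.skew_min_pos + k) % 4000 == top.skew_min_pos % 4000


class TestPlantedOriRecovery:
    def test_recovery_on_synthetic_replicons(self):
        from mgecompare.evaluation import ori_recovery_check
        hits, n = ori_recovery_check(n_replicates=10, seed=321)
        assert hits >= 9  # >= 90% of replicates
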