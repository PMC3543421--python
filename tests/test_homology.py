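import numpy as np
import pytest

from mgecompare.homology import (AlignParams, ProteinRecord, align_pair,
                                 all_vs_all, cluster_families, cross_screen,
                                 family_of, modular_map)

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def _protein(rng, n):
    return "".join(rng.choice(AAS, size=n))


def _mutate(rng, p, rate):
    out = list(p)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([a for a in AAS if a != out[i]])
    return "".join(out)


class TestAlignPair:
    def test_self_alignment_identity_and_coverage(self, rng):
        p = _protein(rng, 100)
        hit = align_pair(p, p)
        assert hit.identity == pytest.approx(1.0)
        assert hit.coverage_short == pytest.approx(1.0)
        assert hit.q_interval == (1, 100) and hit.s_interval == (1, 100)

    def test_score_symmetry(self, rng):
        a, b = _protein(rng, 80), _protein(rng, 60)
        pa = AlignParams(min_score=0)
        assert align_pair(a, b, pa).score == align_pair(b, a, pa).score

    def test_disjoint_charge_runs_give_no_hit(self):
        assert align_pair("KKKKKKKK", "EEEEEEEE") is None

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            align_pair("ACDEF", "AC1EF")

    def test_dp_oracle_equivalence(self):
        from mgecompare.evaluation import alignment_oracle_check
        agree, n = alignment_oracle_check(n_pairs=60, seed=99)
        assert agree == n


class TestAllVsAll:
    def test_clique_of_identical_proteins(self, rng):
        p = _protein(rng, 120)
        prots = [ProteinRecord(f"p{i}", f"r{i}", p) for i in range(3)]
        prots.append(ProteinRecord("odd", "r3", _protein(rng, 120)))
        hits = all_vs_all(prots)
        full = [h for h in hits if not h.partial]
        assert len(full) == 3
        assert all({h.query_id, h.subject_id} <= {"p0", "p1", "p2"} for h in full)

    def test_random_decoys_produce_no_hits(self, rng):
        prots = [ProteinRecord(f"d{i}", "r", _protein(rng, 150))
                 for i in range(6)]
        assert all_vs_all(prots) == []

    def test_chimera_yields_partial_hits_with_disjoint_intervals(self, rng):
        x, y = _protein(rng, 200), _protein(rng, 200)
        chim = x[:100] + y[100:]
        prots = [ProteinRecord("X", "r1", x), ProteinRecord("Y", "r2", y),
                 ProteinRecord("C", "r3", chim)]
        hits = all_vs_all(prots)
        cx = [h for h in hits if {h.query_id, h.subject_id} == {"X", "C"}]
        cy = [h for h in hits if {h.query_id, h.subject_id} == {"X", "Y"}]
        assert cx and cx[0].partial
        assert not cy

    def test_needs_two_proteins(self, rng):
        with pytest.raises(ValueError):
            all_vs_all([ProteinRecord("p", "r", _protein(rng, 50))])


class TestClusterFamilies:
    def _family_sets(self, families):
        return {frozenset(pid for _, pid in f.members) for f in families}

    def test_single_linkage_transitivity(self, rng):
        # A-B and B-C full hits, A-C below threshold -> one family
        anc = _protein(rng, 150)
        a = anc
        b = _mutate(rng, anc, 0.2)   # ~80% id to both
        c = _mutate(rng, b, 0.2)
        prots = [ProteinRecord(n, "r" + n, s) for n, s in
                 zip("ABC", (a, b, c))]
        fams = cluster_families(all_vs_all(prots), prots)
        assert self._family_sets(fams) == {frozenset("ABC")}

    def test_partial_hits_never_merge(self, rng):
        x, y = _protein(rng, 200), _protein(rng, 200)
        chim = x[:100] + y[100:]
        prots = [ProteinRecord("X", "r1", x), ProteinRecord("Y", "r2", y),
                 ProteinRecord("C", "r3", chim)]
        fams = cluster_families(all_vs_all(prots), prots)
        assert self._family_sets(fams) == {frozenset("X"), frozenset("Y"),
                                           frozenset("C")}

    def test_order_invariance_and_deterministic_ids(self, rng):
        anc = _protein(rng, 120)
        prots = [ProteinRecord(f"p{i}", f"r{i}", _mutate(rng, anc, 0.05))
                 for i in range(4)]
        prots += [ProteinRecord(f"q{i}", f"r{i}", _protein(rng, 120))
                  for i in range(3)]
        f1 = cluster_families(all_vs_all(prots), prots)
        rev = list(reversed(prots))
        f2 = cluster_families(all_vs_all(rev), rev)
        assert {f.family_id for f in f1} == {f.family_id for f in f2}
        assert self._family_sets(f1) == self._family_sets(f2)

    def test_planted_families_recovered_exactly(self):
        rng = np.random.default_rng(1)
        truth = {}
        prots = []
        for fam in range(5):
            anc = _protein(rng, int(rng.integers(100, 300)))
            for m in range(int(rng.integers(2, 5))):
                pid = f"f{fam}m{m}"
                prots.append(ProteinRecord(pid, f"rep{m}",
                                           _mutate(rng, anc, 0.15)))
                truth[pid] = fam
        fams = cluster_families(all_vs_all(prots), prots)
        got = {frozenset(pid for _, pid in f.members) for f in fams}
        want = {frozenset(p for p in truth if truth[p] == f) for f in range(5)}
        assert got == want


class TestModularMap:
    def test_full_length_hit_single_segment(self, rng):
        p = _protein(rng, 150)
        prots = [ProteinRecord("A", "r1", p), ProteinRecord("B", "r2", p)]
        hits = all_vs_all(prots)
        fams = cluster_families(hits, prots)
        segs = modular_map("A", hits, fams)
        assert len(segs) == 1
        (a, b), _fam, ident = segs[0]
        assert a == 1 and b == 150 and ident == pytest.approx(1.0)

    def test_chimera_breakpoint_recovered(self, rng):
        x, y = _protein(rng, 240), _protein(rng, 240)
        chim = x[:120] + y[120:]
        prots = [ProteinRecord("X", "r1", x), ProteinRecord("X2", "r1b", x),
                 ProteinRecord("Y", "r2", y), ProteinRecord("Y2", "r2b", y),
                 ProteinRecord("C", "r3", chim)]
        hits = all_vs_all(prots)
        fams = cluster_families(hits, prots)
        fam = family_of(fams)
        segs = modular_map("C", hits, fams)
        partners = {s[1] for s in segs}
        assert fam["X"] in partners and fam["Y"] in partners
        for (a, b), pf, _ in segs:
            if pf == fam["X"]:
                assert abs(b - 120) <= 10
            if pf == fam["Y"]:
                assert abs(a - 121) <= 10

    def test_no_hits_empty_map(self):
        assert modular_map("Z", [], []) == []


class TestCrossScreen:
    def test_identical_query_maps_with_full_identity(self, rng):
        p = _protein(rng, 150)
        prots = [ProteinRecord("A", "r1", p), ProteinRecord("B", "r2", p)]
        fams = cluster_families(all_vs_all(prots), prots)
        res = cross_screen([("q", p)], fams, prots)
        assert res.assignments["q"].identity == pytest.approx(1.0)
        assert not res.orphans

    def test_unrelated_query_is_orphan(self, rng):
        p = _protein(rng, 150)
        prots = [ProteinRecord("A", "r1", p), ProteinRecord("B", "r2", p)]
        fams = cluster_families(all_vs_all(prots), prots)
        res = cross_screen([("q", _protein(rng, 150))], fams, prots)
        assert res.orphans == ["q"]

    def test_half_shared_decoy_proteome(self):
        from mgecompare.evaluation import cross_screen_check
        mapped, orphans, n = cross_screen_check(seed=19)
        assert (mapped, orphans) == (n // 2, n // 2)
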