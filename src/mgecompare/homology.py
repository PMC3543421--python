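"""Protein homology: pairwise local alignment, gene families, domain maps.

All-vs-all Smith-Waterman local alignment (BLOSUM62, affine gaps) with
identity/coverage thresholds stands in for database searches: hits covering
most of the shorter protein define gene families by single-linkage
clustering; shorter domain-level ("partial") hits are kept for mapping
modular multi-domain proteins but never merge families. Coverage is always
measured against the shorter protein, matching the "identity over N aa
region" way domain hits are usually reported.

There is no E-value model: the search spaces here are tiny and fixed, so
significance is a raw-score floor plus identity and coverage thresholds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0    # cost of a gap of length 1
    gap_extend: float = 1.0   # each additional gapped position
    min_score: float = 75.0
    full_identity: float = 0.30
    full_coverage: float = 0.70
    partial_coverage: float = 0.25


@dataclass(frozen=True)
class PairwiseHit:
    query_id: str
    subject_id: str
    score: float
    identity: float        # identical / aligned residue pairs
    q_interval: tuple[int, int]  # 1-based inclusive
    s_interval: tuple[int, int]
    coverage_short: float  # aligned residue pairs / shorter protein length
    partial: bool


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    replicon_id: str
    seq: str


@dataclass
class GeneFamily:
    family_id: str
    members: frozenset  # of (replicon_id, protein_id)
    representative: str  # protein_id of the longest member

    def member_ids(self) -> list[str]:
        return sorted(pid for _, pid in self.members)


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load(params.matrix)
    a.open_gap_score = -params.gap_open
    a.extend_gap_score = -params.gap_extend
    return a


def _check_protein(p: str, name: str) -> None:
    if not p:
        raise ValueError(f"{name}: empty protein")
    bad = set(p) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{name}: non-amino-acid characters {sorted(bad)}")


def align_pair(prot_a: str, prot_b: str, params: AlignParams = AlignParams(),
               query_id: str = "query", subject_id: str = "subject",
               aligner: Align.PairwiseAligner | None = None) -> PairwiseHit | None:
    """Optimal local alignment; None when below the score floor."""
    _check_protein(prot_a, query_id)
    _check_protein(prot_b, subject_id)
    aligner = aligner or _aligner(params)
    score = aligner.score(prot_a, prot_b)
    if score < params.min_score:
        return None
    aln = next(iter(aligner.align(prot_a, prot_b)))
    q_blocks, s_blocks = aln.aligned
    pairs = 0
    ident = 0
    for (qa, qb), (sa, sb) in zip(q_blocks, s_blocks):
        pairs += qb - qa
        ident += sum(1 for x, y in zip(prot_a[qa:qb], prot_b[sa:sb]) if x == y)
    if pairs == 0:
        return None
    coverage = pairs / min(len(prot_a), len(prot_b))
    identity = ident / pairs
    partial = coverage < params.full_coverage
    return PairwiseHit(
        query_id=query_id, subject_id=subject_id, score=float(score),
        identity=identity,
        q_interval=(int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])),
        s_interval=(int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])),
        coverage_short=coverage, partial=partial,
    )


def _passes(hit: PairwiseHit, params: AlignParams) -> bool:
    return (hit.identity >= params.full_identity
            and hit.coverage_short >= params.partial_coverage)


def all_vs_all(proteins: list[ProteinRecord],
               params: AlignParams = AlignParams()) -> list[PairwiseHit]:
    """Every unordered pair aligned once; sub-threshold pairs omitted."""
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    aligner = _aligner(params)
    hits = []
    for pa, pb in combinations(proteins, 2):
        hit = align_pair(pa.seq, pb.seq, params, pa.protein_id, pb.protein_id,
                         aligner=aligner)
        if hit is not None and _passes(hit, params):
            hits.append(hit)
    return hits


def _family_id(member_pids: list[str]) -> str:
    digest = hashlib.sha1("|".join(sorted(member_pids)).encode()).hexdigest()
    return f"fam_{digest[:10]}"


def cluster_families(hits: list[PairwiseHit],
                     proteins: list[ProteinRecord]) -> list[GeneFamily]:
    """Single-linkage transitive closure over full (non-partial) hits.

    Partial (domain-level) hits never merge families; proteins without full
    hits become singleton families. Family ids hash the sorted member list,
    so the partition is invariant to input order.
    """
    by_id = {p.protein_id: p for p in proteins}
    parent = {p.protein_id: p.protein_id for p in proteins}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            # deterministic union by lexicographic root
            if ry < rx:
                rx, ry = ry, rx
            parent[ry] = rx

    for h in hits:
        if not h.partial:
            union(h.query_id, h.subject_id)
    groups: dict[str, list[str]] = {}
    for pid in parent:
        groups.setdefault(find(pid), []).append(pid)
    families = []
    for pids in groups.values():
        members = frozenset((by_id[p].replicon_id, p) for p in pids)
        rep = max(pids, key=lambda p: (len(by_id[p].seq), p))
        families.append(GeneFamily(_family_id(pids), members, rep))
    families.sort(key=lambda f: f.family_id)
    return families


def family_of(families: list[GeneFamily]) -> dict[str, str]:
    """protein_id -> family_id lookup."""
    return {pid: f.family_id for f in families for _, pid in f.members}


def modular_map(protein_id: str, hits: list[PairwiseHit],
                families: list[GeneFamily]) -> list[tuple[tuple[int, int], str, float]]:
    """Partition a protein's axis into segments supported by hits.

    Each segment is (interval on the protein, partner family id, best
    identity); overlapping segments from the same partner family are merged.
    Mirrors bar-style domain maps of modular replicases.
    """
    fam = family_of(families)
    per_family: dict[str, list[tuple[int, int, float]]] = {}
    for h in hits:
        if h.query_id == protein_id:
            partner, interval = h.subject_id, h.q_interval
        elif h.subject_id == protein_id:
            partner, interval = h.query_id, h.s_interval
        else:
            continue
        pf = fam.get(partner, partner)
        per_family.setdefault(pf, []).append((interval[0], interval[1], h.identity))
    segments = []
    for pf, ivals in per_family.items():
        ivals.sort()
        cur_a, cur_b, cur_id = ivals[0]
        for a, b, ident in ivals[1:]:
            if a <= cur_b + 1:
                cur_b = max(cur_b, b)
                cur_id = max(cur_id, ident)
            else:
                segments.append(((cur_a, cur_b), pf, cur_id))
                cur_a, cur_b, cur_id = a, b, ident
        segments.append(((cur_a, cur_b), pf, cur_id))
    segments.sort(key=lambda s: (s[0], s[1]))
    return segments


@dataclass
class ScreenResult:
    assignments: dict[str, PairwiseHit] = field(default_factory=dict)
    orphans: list[str] = field(default_factory=list)


def cross_screen(queries: list[tuple[str, str]], families: list[GeneFamily],
                 proteins: list[ProteinRecord],
                 params: AlignParams = AlignParams(),
                 all_members: bool = False) -> ScreenResult:
    """Best family hit per external query protein; misses become orphans.

    Queries are aligned to each family representative (or to every member
    with ``all_members``); the best hit above the partial thresholds is
    reported.
    """
    by_id = {p.protein_id: p.seq for p in proteins}
    aligner = _aligner(params)
    result = ScreenResult()
    for qid, qseq in queries:
        best: PairwiseHit | None = None
        for f in families:
            targets = f.member_ids() if all_members else [f.representative]
            for tid in targets:
                hit = align_pair(qseq, by_id[tid], params, qid, tid, aligner=aligner)
                if hit is None or not _passes(hit, params):
                    continue
                if best is None or (hit.score, hit.identity) > (best.score, best.identity):
                    best = hit
        if best is None:
            result.orphans.append(qid)
        else:
            result.assignments[qid] = best
    return result


def hits_to_tsv(hits: list[PairwiseHit]) -> str:
    header = ("query\tsubject\tscore\tidentity_pct\tq_start\tq_end\t"
              "s_start\ts_end\tcoverage_short\tpartial")
    rows = [header]
    for h in hits:
        rows.append("\t".join([
            h.query_id, h.subject_id, f"{h.score:.1f}", f"{100 * h.identity:.1f}",
            str(h.q_interval[0]), str(h.q_interval[1]),
            str(h.s_interval[0]), str(h.s_interval[1]),
            f"{h.coverage_short:.3f}", str(int(h.partial)),
        ]))
    return "\n".join(rows) + "\n"
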