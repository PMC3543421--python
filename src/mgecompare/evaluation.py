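"""Independent oracles and parameter-recovery benchmarks.

Every checker here recomputes its expectation through a route independent
of the implementation it validates: a rotate-and-rescan ORF oracle, a plain
quadratic Smith-Waterman dynamic program, exhaustive least-squares tree
search, and planted-truth comparisons on synthetic data. Tests and the
acceptance script both drive these functions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .homology import (AlignParams, ProteinRecord, _aligner, all_vs_all,
                       cluster_families, cross_screen)
from .orf_finder import OrfParams, choose_start, find_orfs, score_sd_on_strand
from .pangenome import (classify_conservation, delineate_subfamilies,
                        gene_content_distance, nj_tree, presence_matrix)
from .seq_io import CircularSequence, revcomp
from .skew_ori import cumulative_skew, find_repeats, intergenic_regions, predict_ori
from .synthetic import (SynthConfig, generate_decoy_proteome, generate_set)

# ---------------------------------------------------------------------------
# ORF brute-force oracle: rotate to every offset, scan linearly, dedupe


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _codon_ids(s: str) -> np.ndarray:
    x = np.array([_BASE_CODE[b] for b in s], dtype=np.int16)
    ids = 25 * x[:-2] + 5 * x[1:-1] + x[2:]
    return ids


def _id_set(codons) -> np.ndarray:
    return np.array(sorted(25 * _BASE_CODE[c[0]] + 5 * _BASE_CODE[c[1]]
                           + _BASE_CODE[c[2]] for c in codons))


def brute_force_orfs(seq: CircularSequence,
                     params: OrfParams = OrfParams()) -> set[tuple[str, int, int]]:
    """ORF set {(strand, start mod L, span)} via rotation and linear rescans.

    Every rotation of each coding strand is rescanned linearly; runs must
    end at a stop, and per circular stop only the longest appearance across
    rotations is kept (a rotation cutting exactly at a run's first codon
    shows the run complete, even in frames with a single stop). Results are
    deduplicated modulo length. Start choice reuses the public SD rule.
    """
    L = seq.length
    out: set[tuple[str, int, int]] = set()
    for strand in "+-":
        coding0 = seq.residues if strand == "+" else revcomp(seq.residues)
        if not seq.circular:
            rotations = [0]
            dbl = coding0
        else:
            rotations = range(L)
            dbl = coding0 + coding0
        ids = _codon_ids(dbl)
        is_stop = np.isin(ids, _id_set(params.stop_codons))
        has_n = np.array([b == "N" for b in dbl])
        barrier = is_stop.copy()
        n_codon = has_n[:-2] | has_n[1:-1] | has_n[2:]
        barrier |= n_codon
        best: dict[int, tuple[int, int, int]] = {}  # stop_circ -> (len, rho, run_start)
        for rho in rotations:
            for frame in range(3):
                lo = rho + frame
                hi = rho + L - 2
                if lo >= hi:
                    continue
                b = barrier[lo:hi:3]
                hits = np.flatnonzero(b)
                prev = 0  # run start codon index within this frame slice
                for h in hits:
                    h = int(h)
                    if is_stop[lo + 3 * h]:
                        run_len = h - prev
                        stop_circ = (frame + 3 * h + rho) % L
                        cur = best.get(stop_circ)
                        if cur is None or run_len > cur[0]:
                            best[stop_circ] = (run_len, rho,
                                               frame + 3 * prev)
                    prev = h + 1
        for stop_circ, (run_len, rho, run_start) in best.items():
            rot = (coding0[rho:] + coding0[:rho]) if seq.circular else coding0
            stop_pos = run_start + 3 * run_len
            cands = [c for c in range(run_start, stop_pos, 3)
                     if rot[c:c + 3] in params.start_codons
                     and (stop_pos - c) // 3 >= params.min_codons
                     and stop_pos + 3 - c <= L]
            if not cands:
                continue
            sd = [score_sd_on_strand(coding0, (c + rho) % L if seq.circular else c,
                                     seq.circular, params)[0] for c in cands]
            chosen = choose_start(cands, sd, params)
            span = stop_pos + 3 - chosen
            a = (chosen + rho) % L if seq.circular else chosen
            if strand == "+":
                start_f = a
            else:
                start_f = (L - (a + span)) % L
            out.add((strand, start_f % L, span))
    return out


def orf_oracle_check(n_seqs: int = 100, length: int = 600,
                     seed: int = 12345) -> tuple[int, int]:
    """(# agreeing sequences, n) for find_orfs vs the brute-force oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_seqs):
        residues = "".join(rng.choice(list("ACGT"), size=length))
        seq = CircularSequence(f"rand{i}", residues, circular=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            impl = {(o.strand, o.start % length, o.span) for o in find_orfs(seq)}
            oracle = brute_force_orfs(seq)
        if impl == oracle:
            agree += 1
    return agree, n_seqs


# ---------------------------------------------------------------------------
# Smith-Waterman quadratic DP oracle (affine gaps, same cost convention)


def sw_score_dp(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Textbook three-state local-alignment DP; O(len(a)*len(b)) memory-lite.

    A gap of length k costs gap_open + (k-1)*gap_extend.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    best = 0.0
    prev_h = [0.0] * (m + 1)
    prev_e = [neg] * (m + 1)  # gap in a (horizontal) ending states per row
    for i in range(1, n + 1):
        cur_h = [0.0] * (m + 1)
        cur_e = [neg] * (m + 1)
        f = neg  # gap in b within this row
        for j in range(1, m + 1):
            e = max(prev_h[j] - gap_open, prev_e[j] - gap_extend)
            f = max(cur_h[j - 1] - gap_open, f - gap_extend)
            sub = prev_h[j - 1] + matrix[a[i - 1], b[j - 1]]
            h = max(0.0, sub, e, f)
            cur_h[j], cur_e[j] = h, e
            if h > best:
                best = h
        prev_h, prev_e = cur_h, cur_e
    return best


def alignment_oracle_check(n_pairs: int = 200, max_len: int = 50,
                           seed: int = 23456) -> tuple[int, int]:
    """(# score-agreeing pairs, n) for the aligner vs the DP oracle."""
    from Bio.Align import substitution_matrices
    rng = np.random.default_rng(seed)
    params = AlignParams(min_score=0.0)
    aligner = _aligner(params)
    matrix = substitution_matrices.load(params.matrix)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    agree = 0
    for _ in range(n_pairs):
        la, lb = int(rng.integers(5, max_len + 1)), int(rng.integers(5, max_len + 1))
        a = "".join(rng.choice(aas, size=la))
        b = "".join(rng.choice(aas, size=lb))
        s_impl = float(aligner.score(a, b))
        s_dp = sw_score_dp(a, b, matrix, params.gap_open, params.gap_extend)
        if abs(s_impl - s_dp) < 1e-6:
            agree += 1
    return agree, n_pairs


# ---------------------------------------------------------------------------
# NJ oracles: additive recovery and exhaustive least squares


def random_additive_tree(rng: np.random.Generator, taxa: list[str]):
    """Random unrooted binary tree as edge list; returns (edges, dist df).

    Edges: (node_a, node_b, length); leaves are taxon names, internal nodes
    ints. Path metric is exactly additive.
    """
    import pandas as pd
    nodes = list(taxa[:3])
    internal = itertools.count()
    root = next(internal)
    edges = [[t, root, float(rng.uniform(0.2, 1.5))] for t in taxa[:3]]
    for t in taxa[3:]:
        ei = int(rng.integers(len(edges)))
        a, b, ln = edges.pop(ei)
        mid, frac = next(internal), float(rng.uniform(0.25, 0.75))
        edges += [[a, mid, ln * frac], [mid, b, ln * (1 - frac)],
                  [t, mid, float(rng.uniform(0.2, 1.5))]]
    # all-pairs path lengths between leaves
    adj: dict = {}
    for a, b, ln in edges:
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for src in taxa:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for t in taxa:
            D.loc[src, t] = dist[t]
    return edges, D


def _edge_splits(edges, taxa: list[str]) -> set[frozenset]:
    """Non-trivial splits of an edge-list tree."""
    adj: dict = {}
    for a, b, _ in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    splits = set()
    for a, b, _ in edges:
        # leaves on the a-side of edge (a, b)
        side, stack = set(), [a]
        seen = {b, a}
        while stack:
            u = stack.pop()
            if u in taxa:
                side.add(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if 1 < len(side) < len(taxa) - 1:
            other = frozenset(taxa) - frozenset(side)
            splits.add(min(frozenset(side), other, key=lambda s: (len(s), sorted(s))))
    return splits


def _five_taxon_topologies(taxa: list[str]):
    """All 15 unrooted binary topologies on 5 taxa, as edge structures."""
    assert len(taxa) == 5
    base_trees = []
    internal0 = "i0"
    base = [(taxa[0], internal0), (taxa[1], internal0), (taxa[2], internal0)]
    trees = [base]
    for new_leaf, new_node in ((taxa[3], "i1"), (taxa[4], "i2")):
        grown = []
        for t in trees:
            for ei, (a, b) in enumerate(t):
                t2 = [e for j, e in enumerate(t) if j != ei]
                t2 += [(a, new_node), (new_node, b), (new_leaf, new_node)]
                grown.append(t2)
        trees = grown
    return trees


def _ls_fit(topology, taxa: list[str], D) -> float:
    """Least-squares SSE of branch lengths fitted to D for one topology."""
    edges = list(topology)
    pairs = list(itertools.combinations(taxa, 2))
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    X = np.zeros((len(pairs), len(edges)))
    y = np.array([D.loc[a, b] for a, b in pairs])
    eidx = {frozenset(e): i for i, e in enumerate(edges)}
    for pi, (a, b) in enumerate(pairs):
        # path from a to b
        prev = {a: None}
        stack = [a]
        while stack:
            u = stack.pop()
            if u == b:
                break
            for v in adj[u]:
                if v not in prev:
                    prev[v] = u
                    stack.append(v)
        node = b
        while prev[node] is not None:
            X[pi, eidx[frozenset((node, prev[node]))]] = 1.0
            node = prev[node]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def nj_additive_check(n_trees: int = 25, n_taxa: int = 5,
                      seed: int = 34567) -> tuple[int, int]:
    """(# recovered topologies, n) for NJ on random additive matrices."""
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n_taxa)]
    agree = 0
    for _ in range(n_trees):
        edges, D = random_additive_tree(rng, taxa)
        tree = nj_tree(D)
        if tree.splits() == _edge_splits(edges, taxa):
            agree += 1
    return agree, n_trees


def nj_least_squares_check(n_trees: int = 25, seed: int = 45678) -> tuple[int, int]:
    """NJ topology vs exhaustive least-squares over all 15 5-taxon trees."""
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(5)]
    topos = _five_taxon_topologies(taxa)
    agree = 0
    for _ in range(n_trees):
        edges, D = random_additive_tree(rng, taxa)
        best = min(topos, key=lambda t: _ls_fit(t, taxa, D))
        best_splits = _edge_splits([(a, b, 1.0) for a, b in best], taxa)
        if nj_tree(D).splits() == best_splits:
            agree += 1
    return agree, n_trees


# ---------------------------------------------------------------------------
# planted-truth recovery benchmarks


def ori_recovery_check(n_replicates: int = 50, seed: int = 56789,
                       ori_bias: float = 0.7,
                       max_dist: int = 250) -> tuple[int, int]:
    """Rank-1 ori region contains the planted ori and the skew minimum
    lands within ``max_dist`` bp of it."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        cfg = SynthConfig(n_replicons=1, subfamily_split=(1, 0),
                          ori_bias=ori_bias, seed=int(rng.integers(2 ** 31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (seq,), truth = generate_set(cfg)
            orfs = find_orfs(seq)
            profile = cumulative_skew(seq, window=100)
            regions = intergenic_regions(seq, orfs, min_len=150)
            repeats = find_repeats(seq, min_len=12)
            preds = predict_ori(seq, profile, regions, repeats)
        if not preds:
            continue
        top = preds[0]
        ori = truth.replicons[seq.id].ori_pos
        L = seq.length
        a, b = top.region
        inside = a <= ori < b or (b > L and ori < b - L)
        d = min((top.skew_min_pos - ori) % L, (ori - top.skew_min_pos) % L)
        if inside and d <= max_dist:
            hits += 1
    return hits, n_replicates


def _adjusted_rand(labels_a: dict[str, str], labels_b: dict[str, str]) -> float:
    from scipy.special import comb
    keys = sorted(labels_a)
    la = [labels_a[k] for k in keys]
    lb = [labels_b[k] for k in keys]
    cats_a = {c: i for i, c in enumerate(dict.fromkeys(la))}
    cats_b = {c: i for i, c in enumerate(dict.fromkeys(lb))}
    table = np.zeros((len(cats_a), len(cats_b)))
    for x, y in zip(la, lb):
        table[cats_a[x], cats_b[y]] += 1
    sum_comb = comb(table, 2).sum()
    a_comb = comb(table.sum(axis=1), 2).sum()
    b_comb = comb(table.sum(axis=0), 2).sum()
    n_comb = comb(len(keys), 2)
    expected = a_comb * b_comb / n_comb
    max_index = (a_comb + b_comb) / 2
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


@dataclass
class PangenomeOutcome:
    ari: float
    split_ok: bool
    classes_ok: bool

    @property
    def ok(self) -> bool:
        return self.ari == 1.0 and self.split_ok and self.classes_ok


def pangenome_recovery_once(seed: int) -> PangenomeOutcome:
    """Run the full pipeline on one synthetic 8-replicon set vs truth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seqs, truth = generate_set(SynthConfig(seed=seed))
        proteins = []
        orf_truth_ids: dict[str, str] = {}
        for seq in seqs:
            calls = find_orfs(seq)
            rt = truth.replicons[seq.id]
            by_pos = {(g.strand, g.start % seq.length): g for g in rt.genes}
            for i, o in enumerate(sorted(calls, key=lambda o: (o.start, o.end)),
                                  start=1):
                pid = f"{seq.id}_gp{i}"
                proteins.append(ProteinRecord(pid, seq.id, o.protein))
                g = by_pos.get((o.strand, o.start % seq.length))
                if g is not None:
                    orf_truth_ids[pid] = g.family_id
        hits = all_vs_all(proteins)
        families = cluster_families(hits, proteins)
    # family-partition agreement
    pred = {}
    for f in families:
        for _, pid in f.members:
            pred[pid] = f.family_id
    ari = _adjusted_rand(pred, {p: orf_truth_ids.get(p, f"?{p}") for p in pred})
    m = presence_matrix(families, [s.id for s in seqs])
    d = gene_content_distance(m, method="jaccard")
    labels = delineate_subfamilies(d, k=2)
    true_labels = {r: truth.replicons[r].subfamily for r in labels}
    split_ok = _adjusted_rand(
        {k: str(v) for k, v in labels.items()},
        {k: str(v) for k, v in true_labels.items()}) == 1.0
    # conservation classes, mapped back through the truth family ids
    classes = classify_conservation(m, labels)
    fam_to_truth: dict[str, str] = {}
    consistent = True
    for f in families:
        tids = {orf_truth_ids.get(pid) for _, pid in f.members}
        if len(tids) != 1 or None in tids:
            consistent = False
            break
        fam_to_truth[f.family_id] = tids.pop()
    classes_ok = consistent and all(
        classes[fid].value == truth.family_class[fam_to_truth[fid]]
        for fid in classes)
    return PangenomeOutcome(ari, split_ok, classes_ok)


def pangenome_recovery_check(n_replicates: int = 20,
                             seed: int = 67890) -> tuple[int, int]:
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_replicates):
        if pangenome_recovery_once(int(rng.integers(2 ** 31))).ok:
            ok += 1
    return ok, n_replicates


def cross_screen_check(seed: int = 78901, n: int = 12,
                       fraction_shared: float = 0.5,
                       divergence: float = 0.4) -> tuple[int, int, int]:
    """(# correctly mapped, # correct orphans, n) on a decoy proteome."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seqs, truth = generate_set(SynthConfig(seed=seed))
        proteins = []
        pid_truth: dict[str, str] = {}  # predicted protein id -> planted family
        for seq in seqs:
            rt = truth.replicons[seq.id]
            by_pos = {(g.strand, g.start % seq.length): g.family_id
                      for g in rt.genes}
            for i, o in enumerate(sorted(find_orfs(seq),
                                         key=lambda o: (o.start, o.end)), start=1):
                pid = f"{seq.id}_gp{i}"
                proteins.append(ProteinRecord(pid, seq.id, o.protein))
                fid = by_pos.get((o.strand, o.start % seq.length))
                if fid is not None:
                    pid_truth[pid] = fid
        hits = all_vs_all(proteins)
        families = cluster_families(hits, proteins)
        # representatives per planted family for the decoy source pool
        partition = truth.family_partition()
        reps: dict[str, str] = {}
        for rt in truth.replicons.values():
            for g in rt.genes:
                reps.setdefault(g.family_id, g.protein)
        pool = sorted(reps.items())
        queries, qtruth = generate_decoy_proteome(n, pool, fraction_shared,
                                                  divergence, seed + 1)
        result = cross_screen(queries, families, proteins)
    mapped_correct = 0
    for qid, hit in result.assignments.items():
        if qtruth[qid] is None:
            continue  # decoy mapped: wrong, not counted as correct
        # the hit subject's planted family must equal the query's source
        if pid_truth.get(hit.subject_id) == qtruth[qid]:
            mapped_correct += 1
    orphan_correct = sum(1 for q in result.orphans if qtruth[q] is None)
    return mapped_correct, orphan_correct, n
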