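"""Synthetic circular plasmid sets with planted ground truth.

The generator emulates the data regime of small (8-14 kb) circular
archaeal plasmids: 9-13 protein-coding genes per replicon, Shine-Dalgarno
motifs 8 bp upstream of starts, a two-subfamily gene-sharing structure with
core / semi-conserved / group-specific / singleton families, a replication-
strand compositional switch planted at a known ori inside the large
intergenic region preceding the replication cassette, and a direct repeat
pair near the ori.

Two design points matter for how the output can be used:

* Proteins of one family derive from a family ancestor by point
  substitutions only (no indels), so identity and coverage analytics have
  exact expectations.
* The planted gene set is, by construction, the exact ORF complement of
  each replicon: synonymous codon choice is biased toward codons whose
  reverse complements contain stop codons, and a repair pass re-chooses
  synonymous/spacer bases to break any residual chance ORF (>= 39 codons)
  on other frames or strands, leaving planted proteins untouched. Without
  this, ~10 kb of coding DNA carries dozens of spurious reading frames and
  no exact parameter-recovery statement would be possible.

GC-skew bias is injected only at synonymous third positions inside genes
and freely in intergenic spacers; planted protein sequences are preserved
exactly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .orf_finder import OrfParams, find_orfs
from .seq_io import CircularSequence

# ---------------------------------------------------------------------------
# codon machinery (translation table 11)

_T11 = CodonTable.unambiguous_dna_by_id[11]
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in _T11.forward_table.items():
    CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in CODONS_BY_AA:
    CODONS_BY_AA[aa].sort()

STOPS = ("TAA", "TGA", "TAG")
# codons whose reverse complement is a stop: planting these on one strand
# seeds stops on the other, which keeps chance reverse-strand ORFs short
_REV_STOP_SEED = {"TTA", "CTA", "TCA"}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# amino-acid background loosely matching hyperthermophile proteomes
# (charged/hydrophobic rich, AT-leaning codons)
_AA_BG = {
    "L": 0.10, "E": 0.09, "K": 0.09, "I": 0.08, "V": 0.07, "G": 0.07,
    "A": 0.06, "S": 0.06, "R": 0.05, "F": 0.05, "T": 0.05, "D": 0.05,
    "N": 0.04, "Y": 0.04, "P": 0.04, "Q": 0.03, "M": 0.02, "H": 0.02,
    "W": 0.015, "C": 0.005,
}
_AA = list(_AA_BG)
_AA_P = np.array([_AA_BG[a] for a in _AA])
_AA_P /= _AA_P.sum()

# weight nudging synonymous third-position A/T picks, tuned so whole-replicon
# G+C lands near the configured target under the background above
_THIRD_AT_WEIGHT = 1.4


class RepliconInfeasible(RuntimeError):
    """Raised when a replicon cannot be made clean of chance ORFs.

    ``stuck`` lists (gene index, codon lo, codon hi) windows of host genes
    whose amino-acid content guarantees an unbreakable chance ORF; the
    set-level driver repairs the family ancestor there and rebuilds.
    """

    def __init__(self, msg: str, stuck: list[tuple[int, int, int]] | None = None):
        super().__init__(msg)
        self.stuck = stuck or []


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic plasmid sets."""

    n_replicons: int = 8
    subfamily_split: tuple[int, int] = (4, 4)
    n_core: int = 2
    n_semi: int = 3
    n_group_specific: int = 4   # per subfamily
    n_singleton: int = 2        # per replicon (topped up to min_genes)
    min_genes: int = 9
    protein_len_range: tuple[int, int] = (80, 900)
    intra_family_divergence: float = 0.10
    intergenic_len_range: tuple[int, int] = (30, 400)
    ori_region_range: tuple[int, int] = (300, 600)
    ori_bias: float = 0.7
    repeat_near_ori: bool = True
    repeat_len: int = 25
    sd_offset: int = 8
    gc_target: float = 0.45
    min_length: int = 8200
    seed: int = 0

    def __post_init__(self):
        if not 0.5 < self.ori_bias <= 1.0:
            raise ValueError("ori_bias must be in (0.5, 1]")
        if min(self.n_core, self.n_semi, self.n_group_specific,
               self.n_singleton) < 0:
            raise ValueError("family counts must be >= 0")
        if sum(self.subfamily_split) != self.n_replicons:
            raise ValueError("subfamily_split must sum to n_replicons")


@dataclass
class TruthGene:
    protein_id: str
    start: int
    end: int
    strand: str
    family_id: str
    protein: str


@dataclass
class RepliconTruth:
    ori_pos: int
    subfamily: int
    genes: list[TruthGene]


@dataclass
class SyntheticTruth:
    replicons: dict[str, RepliconTruth]
    family_class: dict[str, str]

    def family_partition(self) -> dict[str, str]:
        """protein_id -> family_id over all replicons."""
        return {g.protein_id: g.family_id
                for rt in self.replicons.values() for g in rt.genes}


# ---------------------------------------------------------------------------
# protein-level helpers

_BREAKER_BLOCK = 25


def _ensure_breakable(chars: list[str], rng: np.random.Generator) -> list[str]:
    """Guarantee a Leu or Ser in every 25-residue block.

    Leu (TTA/CTA) and Ser (TCA) are the only residues whose codons place a
    stop on the reverse strand; the repair pass needs at least one inside
    any window long enough to host a chance reverse-strand ORF. Natural
    proteins carry ~16% L+S, so this is a light touch.
    """
    for a in range(1, len(chars) - _BREAKER_BLOCK + 1, _BREAKER_BLOCK):
        block = chars[a:a + _BREAKER_BLOCK]
        if "L" not in block and "S" not in block:
            chars[a + int(rng.integers(_BREAKER_BLOCK))] = "L"
    return chars


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = list(rng.choice(_AA, size=length - 1, p=_AA_P))
    return "M" + "".join(_ensure_breakable(["M"] + body, rng)[1:])


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    chars = list(protein)
    if rate > 0:
        for i in range(1, len(chars)):  # keep the start Met
            if rng.random() < rate:
                alt = [a for a in _AA if a != chars[i]]
                chars[i] = alt[rng.integers(len(alt))]
    return "".join(_ensure_breakable(chars, rng))


# ---------------------------------------------------------------------------
# family structure

def _plan_families(cfg: SynthConfig, rng: np.random.Generator,
                   replicon_ids: list[str]) -> tuple[dict, dict, dict]:
    """Decide family membership, ancestors, and conservation classes."""
    n = cfg.n_replicons
    gA = replicon_ids[: cfg.subfamily_split[0]]
    gB = replicon_ids[cfg.subfamily_split[0]:]
    lo, hi = cfg.protein_len_range
    members: dict[str, list[str]] = {}
    lengths: dict[str, int] = {}
    classes: dict[str, str] = {}

    def _len(a: int, b: int) -> int:
        return int(rng.integers(max(a, lo), min(b, hi) + 1))

    for i in range(cfg.n_core):
        fid = f"core_{i + 1}"
        members[fid] = list(replicon_ids)
        # one large replicase-like core family, the rest small regulators
        lengths[fid] = _len(600, 900) if i == 0 else _len(80, 150)
        classes[fid] = "core"
    # a semi-conserved family needs >=1 member in each subfamily yet not all
    # replicons, which requires at least 3 replicons and two real groups
    n_semi = cfg.n_semi if (gA and gB and n >= 3) else 0
    for i in range(n_semi):
        fid = f"semi_{i + 1}"
        # semi-conserved genes sit in a few members of each subfamily,
        # never in every replicon
        kA = int(rng.integers(1, min(2, len(gA)) + 1))
        kB = int(rng.integers(1, min(2, len(gB)) + 1))
        if kA + kB >= n:
            kB = max(1, n - kA - 1)
        sel = (list(rng.choice(gA, size=kA, replace=False))
               + list(rng.choice(gB, size=kB, replace=False)))
        members[fid] = sel
        lengths[fid] = _len(90, 350)
        classes[fid] = "semi_conserved"
    for tag, grp in (("A", gA), ("B", gB)):
        if len(grp) < 2:
            continue
        fids = []
        for i in range(cfg.n_group_specific):
            fid = f"group{tag}_{i + 1}"
            # group-specific genes are carried by nearly every group member,
            # giving each subfamily a coherent shared gene block
            while True:
                sel = [r for r in grp if rng.random() < 0.85]
                if 2 <= len(sel) <= len(grp) and (len(sel) < n):
                    break
            members[fid] = sel
            lengths[fid] = _len(90, 350)
            classes[fid] = "group_specific"
            fids.append(fid)
        # no group member is an outlier: each carries >=2 group families,
        # so the subfamily forms a coherent block of shared genes
        for r in grp:
            short = max(0, min(2, len(fids)) - sum(r in members[f] for f in fids))
            for fid in fids:
                if short and r not in members[fid]:
                    members[fid].append(r)
                    short -= 1
    # singletons, topped up so every replicon carries >= min_genes genes
    per_rep = {r: sum(r in m for m in members.values()) for r in replicon_ids}
    for r in replicon_ids:
        want = max(cfg.n_singleton, cfg.min_genes - per_rep[r])
        for i in range(want):
            fid = f"single_{r}_{i + 1}"
            members[fid] = [r]
            lengths[fid] = _len(100, 250)
            classes[fid] = "singleton"
    ancestors = {fid: _random_protein(rng, lengths[fid]) for fid in members}
    return members, ancestors, classes


# ---------------------------------------------------------------------------
# sequence assembly for one replicon

class _Assembly:
    """Forward-strand base array with per-position edit semantics.

    Each position is FREE (intergenic), FIXED (start/stop codons, SD motifs,
    planted repeats), or belongs to a host gene codon that may be rewritten
    to any synonymous codon. The repair pass uses this to edit sequence
    without ever changing a planted protein.
    """

    def __init__(self):
        self.bases: list[str] = []
        self.free: list[bool] = []
        self.host: list[tuple[int, int] | None] = []  # (gene idx, codon idx)
        # (gene idx, codon idx) -> (aa, strand, fwd positions in coding order)
        self.codons: dict[tuple[int, int], tuple[str, str, tuple[int, int, int]]] = {}

    def append(self, base: str, free: bool = False,
               host: tuple[int, int] | None = None) -> None:
        self.bases.append(base)
        self.free.append(free)
        self.host.append(host)

    def __len__(self) -> int:
        return len(self.bases)


def _choose_codon(rng: np.random.Generator, aa: str, strand: str,
                  leading: bool, bias: float) -> str:
    """Synonymous codon choice with reverse-stop seeding and skew bias."""
    options = CODONS_BY_AA[aa]
    w = []
    for c in options:
        wt = 3.0 if c in _REV_STOP_SEED else 1.0
        third = c[2]
        fwd_third = third if strand == "+" else _COMP[third]
        if fwd_third == ("G" if leading else "C"):
            b = min(bias, 0.99)
            wt *= b / (1 - b)
        if third in "AT":
            wt *= _THIRD_AT_WEIGHT
        w.append(wt)
    w = np.array(w)
    return options[rng.choice(len(options), p=w / w.sum())]


def _emit_gene(asm: _Assembly, rng: np.random.Generator, gene_idx: int,
               protein: str, strand: str, start_codon: str, stop_codon: str,
               ori: int, half: int, total_len: int, bias: float) -> None:
    """Append one CDS cassette (already strand-oriented) to the assembly."""

    def leading_at(pos: int) -> bool:
        return ((pos - ori) % total_len) < half

    # build coding-strand codons, then emit forward-strand bases
    codons = [start_codon]
    span = 3 * (len(protein) + 1)
    gene_start = len(asm)
    for i, aa in enumerate(protein[1:], start=1):
        # forward position of this codon's third base
        if strand == "+":
            pos3 = gene_start + 3 * i + 2
        else:
            pos3 = gene_start + span - 3 * i - 3
        codons.append(_choose_codon(rng, aa, strand, leading_at(pos3), bias))
    codons.append(stop_codon)
    aas = "x" + protein[1:] + "x"  # x = fixed start/stop slots
    emitted: list[tuple[str, tuple[int, int] | None]] = []
    for ci, (codon, aa) in enumerate(zip(codons, aas)):
        host = (gene_idx, ci) if aa != "x" else None
        for b in codon:
            emitted.append((b, host))
    if strand == "-":
        emitted = [(_COMP[b], host) for b, host in reversed(emitted)]
    base0 = len(asm)
    for b, host in emitted:
        asm.append(b, free=False, host=host)
    # register rewritable codons with their forward positions in coding order
    for ci, (codon, aa) in enumerate(zip(codons, aas)):
        if aa == "x":
            continue
        if strand == "+":
            p = base0 + 3 * ci
            fpos = (p, p + 1, p + 2)
        else:
            p = base0 + span - 3 * ci - 3
            fpos = (p + 2, p + 1, p)
        asm.codons[(gene_idx, ci)] = (aa, strand, fpos)


def _emit_spacer(asm: _Assembly, rng: np.random.Generator, length: int,
                 ori: int, half: int, total_len: int, cfg: SynthConfig) -> None:
    gc = cfg.gc_target
    for _ in range(length):
        pos = len(asm)
        leading = ((pos - ori) % total_len) < half
        pg = gc * (cfg.ori_bias if leading else 1 - cfg.ori_bias)
        pc = gc - pg
        b = rng.choice(["A", "T", "G", "C"],
                       p=[(1 - gc) / 2, (1 - gc) / 2, pg, pc])
        asm.append(str(b), free=True)


def _stamp(asm: _Assembly, pos: int, motif: str) -> None:
    for k, b in enumerate(motif):
        asm.bases[pos + k] = b
        asm.free[pos + k] = False
        asm.host[pos + k] = None


# ---------------------------------------------------------------------------
# repair: make the planted genes the exact ORF complement

_ALL_CODONS = sorted("".join(c) for c in itertools.product("ACGT", repeat=3))
_START_SET = {"ATG", "GTG", "TTG"}


def _codon_fwd_positions(call_start: int, call_end: int, strand: str,
                         slot: int) -> list[int]:
    """Forward positions (in coding order) of codon ``slot`` of an ORF."""
    if strand == "+":
        p = call_start + 3 * slot
        return [p, p + 1, p + 2]
    p = call_end - 3 * slot - 3
    return [p + 2, p + 1, p]


def _force_codon(asm: _Assembly, fwd_positions: list[int], strand: str,
                 targets: list[str]) -> bool:
    """Rewrite one target codon (coding-strand) at the given positions.

    A position may be FREE (any base), fixed (base must already match), or
    part of a host gene codon, in which case the whole host codon may swap
    to any synonymous codon consistent with the required bases. First
    feasible target wins.
    """
    L = len(asm)
    for t in targets:
        need = [(fwd_positions[k] % L,
                 t[k] if strand == "+" else _COMP[t[k]]) for k in range(3)]
        writes: list[tuple[int, str]] = []
        host_req: dict[tuple[int, int], list[tuple[int, str]]] = {}
        ok = True
        for p, b in need:
            h = asm.host[p]
            if h is not None:
                host_req.setdefault(h, []).append((p, b))
            elif asm.free[p]:
                writes.append((p, b))
            elif asm.bases[p] != b:
                ok = False
                break
        if not ok:
            continue
        for h, reqs in host_req.items():
            aa, hstrand, fpos = asm.codons[h]
            for cand in CODONS_BY_AA[aa]:
                fwd = [c if hstrand == "+" else _COMP[c] for c in cand]
                # fpos is in coding order, so fwd[k] belongs at fpos[k]
                if all(fwd[fpos.index(p)] == b for p, b in reqs):
                    writes.extend(zip(fpos, fwd))
                    break
            else:
                ok = False
                break
        if ok:
            for p, b in writes:
                asm.bases[p] = b
            return True
    return False


def _break_orf(asm: _Assembly, call, rng: np.random.Generator,
               max_slot: int | None = None) -> bool:
    """Insert an in-frame stop into an unwanted ORF, or spoil its start.

    Slot order is randomized: edits can open new chance ORFs elsewhere, and
    a deterministic first-fit choice can cycle between two states.
    """
    n = call.n_codons
    last = n if max_slot is None else min(n, max_slot)
    slots = list(range(1, last))
    rng.shuffle(slots)
    for slot in slots:
        if _force_codon(asm, _codon_fwd_positions(call.start, call.end,
                                                  call.strand, slot),
                        call.strand, list(STOPS)):
            return True
    # fall back: rewrite the start codon to any non-start (stops preferred)
    pos = _codon_fwd_positions(call.start, call.end, call.strand, 0)
    cur = "".join(
        asm.bases[p % len(asm)] if call.strand == "+"
        else _COMP[asm.bases[p % len(asm)]] for p in pos)
    targets = list(STOPS) + [c for c in _ALL_CODONS
                             if c not in _START_SET and c not in STOPS and c != cur]
    return _force_codon(asm, pos, call.strand, targets)


def _reshuffle_region(asm: _Assembly, rng: np.random.Generator, call) -> bool:
    """Re-pick synonymous codons across a stubborn ORF's span.

    Used when no targeted single-codon edit can break the ORF; a fresh
    synonym draw usually plants a stop in its frame by chance, and the
    repair loop re-checks afterwards.
    """
    L = len(asm)
    touched = set()
    for off in range(call.span):
        h = asm.host[(call.start + off) % L]
        if h is None or h in touched:
            continue
        touched.add(h)
        aa, hstrand, fpos = asm.codons[h]
        options = CODONS_BY_AA[aa]
        cand = options[int(rng.integers(len(options)))]
        fwd = [c if hstrand == "+" else _COMP[c] for c in cand]
        for p, b in zip(fpos, fwd):
            asm.bases[p] = b
    # free spacer positions inside the span are re-drawn too
    changed = bool(touched)
    for off in range(call.span):
        p = (call.start + off) % L
        if asm.free[p]:
            asm.bases[p] = "ACGT"[int(rng.integers(4))]
            changed = True
    return changed


def _host_window(asm: _Assembly, call) -> tuple[int, int, int] | None:
    """(gene idx, codon lo, codon hi) of host codons under a stubborn ORF."""
    L = len(asm)
    per_gene: dict[int, list[int]] = {}
    for off in range(call.span):
        h = asm.host[(call.start + off) % L]
        if h is not None:
            per_gene.setdefault(h[0], []).append(h[1])
    if not per_gene:
        return None
    gi = max(per_gene, key=lambda g: len(per_gene[g]))
    return gi, min(per_gene[gi]), max(per_gene[gi])


def _finalize_replicon(asm: _Assembly, rng: np.random.Generator, rep_id: str,
                       planted: list[TruthGene], params: OrfParams,
                       max_iter: int = 40) -> str:
    """Repair pass: break every non-planted ORF; verify planted starts."""
    L = len(asm)
    planted_keys = {(g.strand, g.start % L, g.end - g.start) for g in planted}

    def stop_key(strand: str, start: int, end: int) -> tuple:
        return (strand, end % L) if strand == "+" else (strand, start % L)

    planted_stops = {stop_key(g.strand, g.start, g.end): g for g in planted}
    prev_bad: set | None = None
    same_count = 0
    for _ in range(max_iter):
        seq = CircularSequence(rep_id, "".join(asm.bases))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls = find_orfs(seq, params)
        bad = [c for c in calls
               if (c.strand, c.start % L, c.span) not in planted_keys]
        if not bad:
            missing = planted_keys - {
                (c.strand, c.start % L, c.span) for c in calls}
            if missing:
                raise RepliconInfeasible(f"{rep_id}: planted gene lost {missing}")
            return seq.residues
        bad_keys = {(c.strand, c.start % L, c.span) for c in bad}
        same_count = same_count + 1 if bad_keys == prev_bad else 0
        if same_count >= 3:
            # targeted edits and reshuffling both keep leaving the same
            # ORFs: their openness is fixed by the amino-acid sequence
            stuck = [w for c in bad if (w := _host_window(asm, c))]
            raise RepliconInfeasible(f"{rep_id}: rigid chance ORFs", stuck)
        prev_bad = bad_keys
        for call in bad:
            sk = stop_key(call.strand, call.start, call.end)
            if sk in planted_stops:
                # same stop as a planted gene but a different chosen start:
                # a longer upstream competitor won the SD tie; spoil the
                # stretch between the competitor start and the planted start
                g = planted_stops[sk]
                extra = (call.span - (g.end - g.start)) // 3
                ok = _break_orf(asm, call, rng, max_slot=extra)
            else:
                ok = _break_orf(asm, call, rng)
            if not ok:
                ok = _reshuffle_region(asm, rng, call)
            if not ok:
                stuck = [w] if (w := _host_window(asm, call)) else []
                raise RepliconInfeasible(
                    f"{rep_id}: cannot break ORF at {call.start}", stuck)
    stuck = [w for c in (bad or []) if (w := _host_window(asm, c))]
    raise RepliconInfeasible(f"{rep_id}: repair did not converge", stuck)


# ---------------------------------------------------------------------------
# top-level generation

def _build_replicon(cfg: SynthConfig, rng: np.random.Generator, rep_id: str,
                    genes: list[tuple[str, str]], subfamily: int,
                    params: OrfParams) -> tuple[CircularSequence, RepliconTruth]:
    """genes: list of (family_id, member protein) in final gene order."""
    lo, hi = cfg.intergenic_len_range
    n_genes = len(genes)
    if n_genes < 3:
        raise RepliconInfeasible(rep_id)
    # replication cassette (core genes) kept on the forward strand, right
    # after the large ori-bearing intergenic region
    strands = ["+", "+"] + ["+" if rng.random() < 0.65 else "-"
                            for _ in range(n_genes - 2)]
    start_codons = [("ATG", "GTG", "TTG")[rng.choice(3, p=[0.7, 0.2, 0.1])]
                    for _ in range(n_genes)]
    stop_codons = [STOPS[rng.choice(3, p=[0.5, 0.3, 0.2])]
                   for _ in range(n_genes)]
    ori_len = int(rng.integers(*cfg.ori_region_range))
    spacers = [int(rng.integers(lo, hi + 1)) for _ in range(n_genes - 1)] + [
        int(rng.integers(lo, hi + 1))]
    spans = [3 * (len(p) + 1) for _, p in genes]
    total = ori_len + sum(spans) + sum(spacers)
    # pad spacers up to the realistic size floor
    i = 0
    while total < cfg.min_length:
        grow = min(hi - spacers[i % len(spacers)], cfg.min_length - total)
        if grow > 0:
            spacers[i % len(spacers)] += grow
            total += grow
        i += 1
        if i > 10 * len(spacers):
            raise RepliconInfeasible(f"{rep_id}: cannot reach minimum length")
    ori = ori_len // 2
    half = total // 2

    asm = _Assembly()
    _emit_spacer(asm, rng, ori_len, ori, half, total, cfg)
    if cfg.repeat_near_ori and ori_len >= 150:
        unit = "".join(rng.choice(list("ACGT"), size=cfg.repeat_len))
        _stamp(asm, 20, unit)
        _stamp(asm, ori_len - 40 - cfg.repeat_len, unit)
    truth_genes: list[TruthGene] = []
    for gi, ((fid, protein), strand) in enumerate(zip(genes, strands)):
        if strand == "+":
            # SD motif ends sd_offset bp upstream of the start codon
            _stamp(asm, len(asm) - cfg.sd_offset - 6, "AGGAGG")
        start = len(asm)
        _emit_gene(asm, rng, gi, protein, strand, start_codons[gi],
                   stop_codons[gi], ori, half, total, cfg.ori_bias)
        end = len(asm)
        truth_genes.append(TruthGene(f"{rep_id}_g{gi + 1}", start, end,
                                     strand, fid, protein))
        _emit_spacer(asm, rng, spacers[gi], ori, half, total, cfg)
        if strand == "-":
            # coding-strand SD lies downstream on the forward strand
            _stamp(asm, end + cfg.sd_offset, "CCTCCT")
    assert len(asm) == total, (len(asm), total)
    residues = _finalize_replicon(asm, rng, rep_id, truth_genes, params)
    # rotate into a random coordinate frame; truth follows
    k = int(rng.integers(total))
    seq = CircularSequence(rep_id, residues[k:] + residues[:k], True)
    rotated = [
        TruthGene(g.protein_id, (g.start - k) % total,
                  (g.start - k) % total + (g.end - g.start),
                  g.strand, g.family_id, g.protein)
        for g in truth_genes
    ]
    rotated.sort(key=lambda g: g.start)
    return seq, RepliconTruth(ori_pos=(ori - k) % total, subfamily=subfamily,
                              genes=rotated)


# residue pairs tried, in order, when repairing an ancestor window that
# guarantees an unbreakable chance ORF; all are common residues whose codon
# families open stop possibilities on other frames/strands
_REPAIR_PAIRS = ("LI", "LK", "SL", "LN", "IS", "KL")


def generate_set(cfg: SynthConfig = SynthConfig(),
                 params: OrfParams = OrfParams()
                 ) -> tuple[list[CircularSequence], SyntheticTruth]:
    """Generate a full plasmid set plus planted truth; seed-deterministic.

    Built in rounds: if a replicon reports a rigid chance ORF (one whose
    openness is guaranteed by a host gene's amino acids), the family
    ancestor is edited inside the stuck window and the whole set is
    regenerated, so family structure stays consistent across replicons.
    """
    rng = np.random.default_rng(cfg.seed)
    replicon_ids = [f"synthP{i + 1:02d}" for i in range(cfg.n_replicons)]
    members, ancestors, classes = _plan_families(cfg, rng, replicon_ids)
    for round_no in range(6):
        member_protein: dict[tuple[str, str], str] = {}
        for fid in sorted(members):
            for r in members[fid]:
                member_protein[(fid, r)] = _mutate_protein(
                    rng, ancestors[fid], cfg.intra_family_divergence)
        seqs: list[CircularSequence] = []
        truth_reps: dict[str, RepliconTruth] = {}
        stuck_windows: list[tuple[str, int, int]] = []
        for ri, rep_id in enumerate(replicon_ids):
            fams = [fid for fid in members if rep_id in members[fid]]
            core = [f for f in fams if f.startswith("core_")]
            rest = [f for f in fams if not f.startswith("core_")]
            subfam = 0 if ri < cfg.subfamily_split[0] else 1
            built = None
            for attempt in range(3):
                sub = np.random.default_rng(rng.integers(2 ** 31))
                order = core + list(sub.permutation(rest))
                genes = [(fid, member_protein[(fid, rep_id)]) for fid in order]
                try:
                    built = _build_replicon(cfg, sub, rep_id, genes, subfam, params)
                    break
                except RepliconInfeasible as exc:
                    for gi, lo, hi in exc.stuck:
                        stuck_windows.append((order[gi], lo, hi))
            if built is None:
                break
            seq, rt = built
            seqs.append(seq)
            truth_reps[rep_id] = rt
        else:
            return seqs, SyntheticTruth(truth_reps, classes)
        if not stuck_windows:
            continue  # plain bad luck; new round redraws members
        pair = _REPAIR_PAIRS[round_no % len(_REPAIR_PAIRS)]
        for fid, lo, hi in stuck_windows:
            anc = list(ancestors[fid])
            pos = max(1, min((lo + hi) // 2, len(anc) - 3))
            anc[pos], anc[pos + 1] = pair[0], pair[1]
            ancestors[fid] = "".join(anc)
    raise RepliconInfeasible("set generation failed after ancestor repairs")


def generate_decoy_proteome(n: int, family_reps: list[tuple[str, str]],
                            fraction_shared: float, divergence: float,
                            seed: int) -> tuple[list[tuple[str, str]],
                                                dict[str, str | None]]:
    """A PAV1-style decoy proteome: a fraction of diverged family copies
    among composition-matched random proteins.

    Returns (proteins as (id, seq), truth mapping id -> source family or
    None for decoys).
    """
    if not 0 <= fraction_shared <= 1:
        raise ValueError("fraction_shared must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = round(n * fraction_shared)
    pick = rng.choice(len(family_reps), size=n_shared,
                      replace=n_shared > len(family_reps))
    lengths = [len(seq) for _, seq in family_reps] or [200]
    proteins: list[tuple[str, str]] = []
    truth: dict[str, str | None] = {}
    for i in range(n):
        pid = f"virusORF{i + 1}"
        if i < n_shared:
            fid, anc = family_reps[int(pick[i])]
            proteins.append((pid, _mutate_protein(rng, anc, divergence)))
            truth[pid] = fid
        else:
            ln = int(lengths[rng.integers(len(lengths))])
            proteins.append((pid, _random_protein(rng, ln)))
            truth[pid] = None
    order = rng.permutation(n)
    proteins = [proteins[i] for i in order]
    return proteins, truth
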