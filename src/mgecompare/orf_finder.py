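"""ORF prediction on circular DNA with Shine-Dalgarno start adjustment.

Open reading frames are called in all six frames with a minimum length of
39 codons, start codons ATG/GTG/TTG and stops TAA/TAG/TGA. Where several
in-frame starts share a stop, the reported start is chosen by ribosome-
binding-site evidence: a purine-rich Shine-Dalgarno (SD) match (consensus
AGGAGG) a few bp upstream of the start wins over mere ORF length. This
automates the start curation that is otherwise done by eye.

Origin-spanning ORFs on circular sequences are found by scanning the
doubled sequence and deduplicating modulo length; coordinates of reported
calls are on the forward strand, 0-based half-open, with ``end > length``
denoting a wrapped interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .seq_io import CircularSequence, revcomp

log = logging.getLogger(__name__)

STOP_DEFAULT = frozenset({"TAA", "TAG", "TGA"})
START_DEFAULT = frozenset({"ATG", "GTG", "TTG"})


@dataclass(frozen=True)
class OrfParams:
    """Calling criteria; defaults follow small-archaeal-replicon practice."""

    min_codons: int = 39
    start_codons: frozenset = START_DEFAULT
    stop_codons: frozenset = STOP_DEFAULT
    sd_consensus: str = "AGGAGG"
    sd_window: tuple[int, int] = (4, 20)  # offsets upstream of the start codon
    sd_min_match: int = 4

    def __post_init__(self):
        if self.min_codons < 1:
            raise ValueError("min_codons must be >= 1")
        lo, hi = self.sd_window
        if not 0 <= lo < hi:
            raise ValueError("sd_window must satisfy 0 <= low < high")


@dataclass(frozen=True)
class OrfCall:
    seq_id: str
    start: int  # forward-strand frame of reference, 0-based
    end: int    # half-open; > length means wrap on a circular sequence
    strand: str
    start_codon: str
    n_codons: int  # start codon .. last sense codon (stop excluded)
    sd_score: int
    sd_offset: int | None
    protein: str

    @property
    def span(self) -> int:
        return self.end - self.start


def translate(dna: str, as_start: bool = False, table: int = 11) -> str:
    """Translate a CDS (without stop) to protein; alternative starts give M."""
    if len(dna) % 3:
        raise ValueError("CDS length not divisible by 3")
    prot = str(Seq(dna).translate(table=table))
    if "*" in prot:
        raise ValueError(f"internal stop codon at codon {prot.index('*')}")
    if as_start and prot:
        prot = "M" + prot[1:]
    return prot


def _sd_best_match(window: str, consensus: str, hi: int) -> tuple[int, int | None]:
    """Longest contiguous exact match between window and consensus.

    Returns (score, offset of the match 3' end from the start codon); among
    equally long matches the one nearest the start codon wins.
    """
    n = len(consensus)
    for k in range(n, 0, -1):
        best_off = None
        for i in range(n - k + 1):
            sub = consensus[i:i + k]
            j = window.find(sub)
            while j != -1:
                off = hi - (j + k)  # distance from match end to start codon
                if best_off is None or off < best_off:
                    best_off = off
                j = window.find(sub, j + 1)
        if best_off is not None:
            return k, best_off
    return 0, None


def score_sd_on_strand(coding: str, pos: int, circular: bool,
                       params: OrfParams) -> tuple[int, int | None]:
    """SD score for a start at ``pos`` on its coding strand string."""
    lo, hi = params.sd_window
    L = len(coding)
    if circular:
        window = "".join(coding[(pos - off) % L] for off in range(hi, lo, -1))
    else:
        a, b = max(0, pos - hi), max(0, pos - lo)
        window = coding[a:b]
    return _sd_best_match(window, params.sd_consensus, hi)


def score_sd(seq: CircularSequence, start: int, strand: str,
             params: OrfParams = OrfParams()) -> tuple[int, int | None]:
    """SD score/offset for a forward-frame start coordinate on either strand.

    ``start`` is the leftmost forward-strand coordinate of the start codon
    for '+' ORFs, or of the codon's last base + 1 site for '-' ORFs (i.e.
    the wrapped forward `end` of the ORF); for '-' the position is converted
    to the coding (reverse-complement) strand first.
    """
    L = seq.length
    if strand == "+":
        return score_sd_on_strand(seq.residues, start, seq.circular, params)
    coding = revcomp(seq.residues)
    return score_sd_on_strand(coding, (L - start) % L, seq.circular, params)


def choose_start(candidates: list[int], sd_scores: list[int],
                 params: OrfParams = OrfParams()) -> int:
    """Pick the reported start among in-frame candidates sharing a stop.

    Candidates are positions on the coding strand (ascending = downstream,
    i.e. shorter ORF). With any SD support >= sd_min_match the candidate
    maximizing (sd_score, ORF length) wins; otherwise the most upstream
    (longest) candidate; ties break to the smaller coordinate.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if max(sd_scores) >= params.sd_min_match:
        # longer ORF = smaller coding-strand position among shared-stop starts
        return min(zip(candidates, sd_scores), key=lambda cs: (-cs[1], cs[0]))[0]
    return min(candidates)


def _scan_strand(seq: CircularSequence, coding: str, strand: str,
                 params: OrfParams) -> list[OrfCall]:
    """Scan one coding strand (replicated for circular sequences).

    Two copies suffice when L is divisible by 3 (each frame is its own
    L-codon cycle); otherwise the codon walk closes only after three laps,
    and a frame-cycle with a single stop has a run approaching 3L that is
    stop-bounded only in a four-copy scan. A few tail bases cover stops
    starting in the last codon of a copy.
    """
    L = seq.length
    if seq.circular:
        copies = 2 if L % 3 == 0 else 4
        scan = coding * copies + coding[:4]
    else:
        scan = coding
    stops, starts = params.stop_codons, params.start_codons
    calls: dict[tuple, OrfCall] = {}
    stop_free_warned = False
    for frame in range(3):
        run_start = frame
        bounded_left = not seq.circular  # scan edge is a real boundary only
        p = frame                        # on linear sequences
        while p + 3 <= len(scan):
            codon = scan[p:p + 3]
            is_stop = codon in stops
            has_n = "N" in codon
            if is_stop or has_n:
                if is_stop and bounded_left:
                    _emit_run(seq, coding, strand, run_start, p, scan, params, calls)
                # runs truncated by N are discarded entirely; on circular
                # sequences a scan-edge run is a truncated copy of a run
                # seen intact later in the doubled sequence
                run_start = p + 3
                bounded_left = True
            p += 3
        if seq.circular and run_start == frame and p >= L + frame:
            # no stop met in a full lap: stop-free circular frame
            if not stop_free_warned:
                warnings.warn(
                    f"{seq.id}: stop-free reading frame on strand {strand}; "
                    "no ORF reported for it", stacklevel=2)
                stop_free_warned = True
    return list(calls.values())


def _emit_run(seq: CircularSequence, coding: str, strand: str,
              run_start: int, stop_pos: int, scan: str,
              params: OrfParams, calls: dict) -> None:
    """Report the SD-chosen ORF for one (frame, stop) run, deduplicated."""
    L = seq.length
    span_limit = L
    cands = []
    for c in range(run_start, stop_pos, 3):
        n_codons = (stop_pos - c) // 3
        if n_codons < params.min_codons:
            break  # further candidates are shorter still
        if stop_pos + 3 - c > span_limit:
            continue  # ORF cannot be longer than the circle
        if scan[c:c + 3] in params.start_codons:
            cands.append(c)
    if not cands:
        return
    sd = [score_sd_on_strand(coding, c % L, seq.circular, params)
          for c in cands]
    chosen = choose_start(cands, [s for s, _ in sd], params)
    sd_score, sd_offset = sd[cands.index(chosen)]
    a = chosen % L
    span = stop_pos + 3 - chosen
    # forward-strand frame of reference
    if strand == "+":
        start_f, end_f = a, a + span
    else:
        start_f = (L - (a + span)) % L
        end_f = start_f + span
    key = (strand, start_f % L, span)
    if key in calls:
        return
    cds = scan[chosen:stop_pos]
    calls[key] = OrfCall(
        seq_id=seq.id, start=start_f, end=end_f, strand=strand,
        start_codon=scan[chosen:chosen + 3],
        n_codons=(stop_pos - chosen) // 3,
        sd_score=sd_score, sd_offset=sd_offset,
        protein=translate(cds, as_start=True),
    )


def find_orfs(seq: CircularSequence, params: OrfParams = OrfParams()) -> list[OrfCall]:
    """All SD-adjusted ORF calls on both strands, sorted by start coordinate.

    Overlapping and nested ORFs are not filtered.
    """
    if seq.length < 3:
        raise ValueError("sequence shorter than one codon")
    calls = (_scan_strand(seq, seq.residues, "+", params)
             + _scan_strand(seq, revcomp(seq.residues), "-", params))
    calls.sort(key=lambda o: (o.start, o.end, o.strand))
    return calls


def extract_cds(seq: CircularSequence, orf: OrfCall) -> str:
    """Re-extract the coding sequence (without stop) of a call."""
    dna = seq.fetch(orf.start, orf.end)
    if orf.strand == "-":
        dna = revcomp(dna)
    return dna[:-3]


def number_proteins(orfs: list[OrfCall]) -> list[tuple[str, str]]:
    """Protein FASTA ids '<seq_id>_gp<n>', numbered clockwise from 0."""
    out = []
    for i, o in enumerate(sorted(orfs, key=lambda o: (o.start, o.end)), start=1):
        out.append((f"{o.seq_id}_gp{i}", o.protein))
    return out
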