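"""Sequence I/O and per-replicon statistics for small circular replicons.

Coordinate convention: 0-based half-open throughout. On a circular sequence
an interval may wrap past the origin; this is encoded as ``end > length``
with ``end - start <= length``. GFF3/BED emission converts at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class CircularSequence:
    """A DNA sequence with explicit (default circular) topology.

    Residues are case-normalized to upper on construction and restricted to
    the {A,C,G,T,N} alphabet.
    """

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-DNA characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Wrap-aware slice [start, end) with end possibly > length."""
        L = self.length
        if end <= L:
            return self.residues[start:end]
        if not self.circular:
            raise IndexError(f"interval [{start},{end}) beyond linear sequence")
        if end - start > L:
            raise IndexError("interval longer than the sequence")
        return self.residues[start:] + self.residues[: end - L]

    def rotate(self, k: int) -> "CircularSequence":
        """Rotate the circular coordinate frame so old position k becomes 0."""
        if not self.circular:
            raise ValueError("cannot rotate a linear sequence")
        k %= self.length
        return CircularSequence(self.id, self.residues[k:] + self.residues[:k], True)

    def reverse_complement(self) -> "CircularSequence":
        return CircularSequence(self.id, revcomp(self.residues), self.circular)


@dataclass
class AnnotatedFeature:
    """A located feature; CDS features feed the coding-density statistic."""

    seq_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"feature {self.label!r}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.label!r}: strand must be + or -")

    @property
    def span(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path, circular: bool = True) -> list[CircularSequence]:
    """Read FASTA into CircularSequence records.

    ``circular`` sets the default topology; a per-record header token
    ``circular=false`` (or ``linear``) overrides it.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.lower()
        circ = circular
        if "circular=false" in desc or " linear" in f" {desc}":
            circ = False
        elif "circular=true" in desc or " circular" in f" {desc}":
            circ = True
        records.append(CircularSequence(rec.id, str(rec.seq), circ))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, seqs: Iterable[CircularSequence]) -> None:
    recs = [
        SeqRecord(Seq(s.residues), id=s.id,
                  description=f"circular={'true' if s.circular else 'false'}")
        for s in seqs
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_protein_fasta(path: str | Path, proteins: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(p), id=pid, description="") for pid, p in proteins]
    SeqIO.write(recs, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    out = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def read_genbank(path: str | Path, circular: bool = True
                 ) -> tuple[CircularSequence, list[AnnotatedFeature]]:
    """Read a GenBank flat file: sequence plus CDS features.

    Locations are converted to the 0-based half-open convention; a two-part
    join() spanning the origin of a circular record is mapped to a single
    wrapped interval with end > length. Features whose locations cannot be
    interpreted are skipped with a logged warning.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
        residues = str(rec.seq)
    except Exception as exc:  # noqa: BLE001 - map all biopython failures
        raise ParseError(f"{path}: cannot parse GenBank record ({exc})") from exc
    if not residues or set(residues) == {"?"}:
        raise ParseError(f"{path}: GenBank record has no ORIGIN sequence")
    topo = rec.annotations.get("topology", "").lower()
    if topo:
        circular = topo == "circular"
    seq = CircularSequence(rec.id, residues, circular)
    L = seq.length
    feats: list[AnnotatedFeature] = []
    for f in rec.features:
        if f.type != "CDS":
            continue
        label = f.qualifiers.get("locus_tag", f.qualifiers.get("gene", ["CDS"]))[0]
        strand = "+" if (f.location.strand or 1) >= 0 else "-"
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        try:
            if len(parts) == 1:
                start, end = int(parts[0].start), int(parts[0].end)
            elif (len(parts) == 2 and seq.circular
                    and int(parts[1].end) == L and int(parts[0].start) == 0):
                # origin-spanning join: (high part, then low part)
                start = int(parts[1].start)
                end = L + int(parts[0].end)
            else:
                raise ValueError("unsupported compound location")
            if end - start > L:
                raise ValueError("feature longer than the sequence")
            feats.append(AnnotatedFeature(seq.id, start, end, strand, "CDS", label))
        except ValueError as exc:
            log.warning("%s: skipping feature %s (%s)", path.name, label, exc)
    return seq, feats


def gc_content(seq: CircularSequence) -> float:
    """G+C fraction over non-N residues."""
    counts = {b: seq.residues.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError(f"{seq.id}: all-N sequence, G+C undefined")
    return (counts["G"] + counts["C"]) / denom


def _coverage_mask(seq: CircularSequence, features: Sequence[AnnotatedFeature],
                   kinds: tuple[str, ...] = ("CDS",)) -> np.ndarray:
    L = seq.length
    mask = np.zeros(L, dtype=bool)
    for f in features:
        if f.kind not in kinds:
            continue
        if f.end > 2 * L or f.end - f.start > L:
            raise ValueError(f"feature {f.label!r} extends beyond end+length")
        if f.end <= L:
            mask[f.start:f.end] = True
        else:
            if not seq.circular:
                raise ValueError(f"wrapped feature {f.label!r} on linear sequence")
            mask[f.start:] = True
            mask[: f.end - L] = True
    return mask


def coding_density(seq: CircularSequence, features: Sequence[AnnotatedFeature],
                   mode: str = "union") -> float:
    """Fraction of the replicon covered by CDS features.

    ``union`` (default) counts overlapping positions once; ``sum`` divides
    total CDS length by sequence length (may exceed 1 on heavy overlap).
    """
    if mode == "sum":
        return sum(f.span for f in features if f.kind == "CDS") / seq.length
    if mode != "union":
        raise ValueError(f"unknown coding-density mode {mode!r}")
    return float(_coverage_mask(seq, features).sum()) / seq.length


def replicon_statistics(pairs: Iterable[tuple[CircularSequence, Sequence[AnnotatedFeature]]],
                        mode: str = "union") -> pd.DataFrame:
    """Per-replicon summary: length, CDS count, coding %, G+C %."""
    rows = []
    for seq, feats in pairs:
        cds = [f for f in feats if f.kind == "CDS"]
        rows.append({
            "replicon": seq.id,
            "length_bp": seq.length,
            "cds": len(cds),
            "coding_pct": round(100.0 * coding_density(seq, cds, mode=mode), 1),
            "gc_pct": round(100.0 * gc_content(seq), 1),
        })
    return pd.DataFrame(rows).set_index("replicon")


# ---------------------------------------------------------------------------
# emission helpers (GFF3 1-based inclusive; BED 0-based half-open)

def orfs_to_gff3(orfs, length_by_seq: dict[str, int] | None = None) -> str:
    lines = ["##gff-version 3"]
    for i, o in enumerate(orfs, start=1):
        attrs = f"ID={o.seq_id}_gp{i};start_codon={o.start_codon};n_codons={o.n_codons}"
        if o.sd_score:
            attrs += f";sd_score={o.sd_score};sd_offset={o.sd_offset}"
        L = (length_by_seq or {}).get(o.seq_id)
        note = ""
        if L is not None and o.end > L:
            # wrapped CDS kept as one line with raw end, flagged for consumers
            note = ";wraps_origin=true"
        lines.append("\t".join([
            o.seq_id, "mge-compare:orf", "CDS", str(o.start + 1), str(o.end),
            ".", o.strand, "0", attrs + note,
        ]))
    return "\n".join(lines) + "\n"


def ori_to_bed(seq_id: str, predictions, length: int) -> str:
    lines = []
    for p in predictions:
        a, b = p.region
        lines.append("\t".join([
            seq_id, str(a), str(min(b, length)), f"ori_candidate_rank{p.rank}",
            str(p.rank), ".",
        ]))
        if b > length:  # wrapped tail as a second BED line
            lines.append("\t".join([
                seq_id, "0", str(b - length), f"ori_candidate_rank{p.rank}_wrap",
                str(p.rank), ".",
            ]))
    return "\n".join(lines) + ("\n" if lines else "")
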