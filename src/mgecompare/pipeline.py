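"""End-to-end comparative analysis over a set of circular replicons.

Runs the stages in order — statistics, ORF calling (or trusted GenBank
annotations), skew/ori prediction, all-vs-all homology, pan-genome
matrix/tree/classes, optional cross-screen of an external proteome — and
writes every artifact plus a JSON report and MANIFEST to an output
directory. Every number in the report is recomputable from inputs and
config alone.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .homology import (AlignParams, ProteinRecord, all_vs_all,
                       cluster_families, cross_screen, family_of, hits_to_tsv)
from .orf_finder import OrfCall, OrfParams, find_orfs
from .pangenome import (classify_conservation, delineate_subfamilies,
                        gene_content_distance, nj_tree, presence_matrix,
                        root_with_outgroup, to_phylip, CLASS_COLORS)
from .seq_io import (AnnotatedFeature, CircularSequence, orfs_to_gff3,
                     ori_to_bed, read_fasta, read_genbank, read_protein_fasta,
                     replicon_statistics, write_protein_fasta)
from .skew_ori import cumulative_skew, find_repeats, intergenic_regions, predict_ori

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta_paths: list[str] = field(default_factory=list)
    genbank_paths: list[str] = field(default_factory=list)
    trust_annotations: bool = False
    orf: OrfParams = field(default_factory=OrfParams)
    align: AlignParams = field(default_factory=AlignParams)
    skew_window: int = 100
    repeat_min_len: int = 12
    intergenic_min_len: int = 150
    distance_method: str = "jaccard"
    subfamily_k: int = 2
    outgroup: str | None = None
    screen_fasta: str | None = None
    out_dir: str = "mge_compare_out"
    seed: int = 0
    coding_density_mode: str = "union"


@dataclass
class Report:
    version: str
    config: dict
    statistics: dict
    orfs: dict
    ori: dict
    families: dict
    matrix: dict
    distances: dict
    newick: str | None
    subfamilies: dict
    conservation: dict
    screen: dict | None


def _orf_from_feature(seq: CircularSequence, f: AnnotatedFeature) -> OrfCall:
    """Wrap a trusted CDS annotation in the OrfCall container."""
    from .orf_finder import extract_cds, translate
    dummy = OrfCall(seq.id, f.start, f.end, f.strand, "ATG",
                    (f.end - f.start) // 3 - 1, 0, None, "")
    try:
        protein = translate(extract_cds(seq, dummy), as_start=True)
    except ValueError:
        protein = ""
    return OrfCall(seq.id, f.start, f.end, f.strand, seq.fetch(f.start, f.start + 3)
                   if f.strand == "+" else "", (f.end - f.start) // 3 - 1,
                   0, None, protein)


def run_compare(cfg: RunConfig) -> Report:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def save(name: str, text: str) -> None:
        (out / name).write_text(text)
        manifest.append(name)

    replicons: list[tuple[CircularSequence, list[AnnotatedFeature]]] = []
    for p in cfg.fasta_paths:
        for seq in read_fasta(p):
            replicons.append((seq, []))
    for p in cfg.genbank_paths:
        seq, feats = read_genbank(p)
        replicons.append((seq, feats))
    if not replicons:
        raise ValueError("no input replicons")

    # --- per-replicon: ORFs, skew, ori ---------------------------------
    orf_calls: dict[str, list[OrfCall]] = {}
    ori_preds: dict[str, list] = {}
    lengths: dict[str, int] = {}
    proteins: list[ProteinRecord] = []
    for seq, feats in replicons:
        lengths[seq.id] = seq.length
        if cfg.trust_annotations and feats:
            calls = [_orf_from_feature(seq, f) for f in feats if f.kind == "CDS"]
        else:
            calls = find_orfs(seq, cfg.orf)
        orf_calls[seq.id] = calls
        for i, o in enumerate(sorted(calls, key=lambda o: (o.start, o.end)),
                              start=1):
            if o.protein:
                proteins.append(ProteinRecord(f"{seq.id}_gp{i}", seq.id, o.protein))
        profile = cumulative_skew(seq, window=cfg.skew_window)
        repeats = find_repeats(seq, min_len=cfg.repeat_min_len)
        regions = intergenic_regions(seq, calls, min_len=cfg.intergenic_min_len)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                preds = predict_ori(seq, profile, regions, repeats)
        except ValueError as exc:
            log.warning("%s: %s", seq.id, exc)
            preds = []
        ori_preds[seq.id] = preds
        save(f"{seq.id}.ori.bed", ori_to_bed(seq.id, preds, seq.length))
        save(f"{seq.id}.repeats.tsv", "\n".join(
            f"{r.kind}\t{r.pos1}\t{r.pos2}\t{r.rep_len}\t{r.seq}"
            for r in repeats) + "\n")

    all_calls = [o for calls in orf_calls.values() for o in calls]
    save("orfs.gff3", orfs_to_gff3(sorted(all_calls, key=lambda o: (o.seq_id, o.start)),
                                   lengths))
    write_protein_fasta(out / "proteins.faa",
                        [(p.protein_id, p.seq) for p in proteins])
    manifest.append("proteins.faa")

    # --- statistics -----------------------------------------------------
    stats_feats = []
    for seq, feats in replicons:
        if feats:
            cds = feats
        else:
            cds = [AnnotatedFeature(seq.id, o.start, o.end, o.strand, "CDS")
                   for o in orf_calls[seq.id]]
        stats_feats.append((seq, cds))
    stats = replicon_statistics(stats_feats, mode=cfg.coding_density_mode)
    save("statistics.tsv", stats.to_csv(sep="\t"))

    # --- homology and pan-genome ---------------------------------------
    families = []
    matrix = None
    dists = None
    newick = None
    labels: dict[str, int] = {}
    classes: dict[str, str] = {}
    if len(proteins) >= 2:
        hits = all_vs_all(proteins, cfg.align)
        save("hits.tsv", hits_to_tsv(hits))
        families = cluster_families(hits, proteins)
        fam_lines = ["family\treplicon\tprotein"]
        for f in families:
            for rep, pid in sorted(f.members):
                fam_lines.append(f"{f.family_id}\t{rep}\t{pid}")
        save("families.tsv", "\n".join(fam_lines) + "\n")
        matrix = presence_matrix(families, [s.id for s, _ in replicons])
        save("presence_matrix.tsv", matrix.to_csv(sep="\t"))
        if matrix.shape[0] >= 2:
            dists = gene_content_distance(matrix, method=cfg.distance_method)
            save("distances.phylip", to_phylip(dists))
        if dists is not None and matrix.shape[0] >= 3:
            tree = nj_tree(dists)
            root = (root_with_outgroup(tree, cfg.outgroup)
                    if cfg.outgroup in dists.index else tree.root)
            newick = root.newick()
            save("gene_content_tree.nwk", newick + "\n")
            labels = delineate_subfamilies(dists, k=cfg.subfamily_k)
            cc = classify_conservation(matrix, labels)
            classes = {fid: c.value for fid, c in cc.items()}
            cls_lines = ["family\tclass\tcolor"]
            for fid, c in cc.items():
                cls_lines.append(f"{fid}\t{c.value}\t{CLASS_COLORS[c]}")
            save("conservation.tsv", "\n".join(cls_lines) + "\n")
        else:
            log.warning("fewer than 3 replicons: tree stage skipped")

    # --- optional cross-screen ------------------------------------------
    screen = None
    if cfg.screen_fasta:
        queries = read_protein_fasta(cfg.screen_fasta)
        res = cross_screen(queries, families, proteins, cfg.align)
        fam = family_of(families)
        screen = {
            "assignments": {
                q: {"subject": h.subject_id, "family": fam.get(h.subject_id),
                    "score": h.score, "identity": round(h.identity, 3),
                    "coverage_short": round(h.coverage_short, 3)}
                for q, h in res.assignments.items()},
            "orphans": res.orphans,
        }
        save("cross_screen.json", json.dumps(screen, indent=1, sort_keys=True))

    report = Report(
        version=__version__,
        config={**{k: v for k, v in asdict(cfg).items()},
                "orf": asdict(cfg.orf) if not isinstance(cfg.orf, dict) else cfg.orf},
        statistics=json.loads(stats.to_json(orient="index")),
        orfs={sid: [asdict(o) for o in calls] for sid, calls in orf_calls.items()},
        ori={sid: [asdict(p) for p in preds] for sid, preds in ori_preds.items()},
        families={f.family_id: sorted(pid for _, pid in f.members)
                  for f in families},
        matrix=(json.loads(matrix.to_json(orient="index"))
                if matrix is not None else {}),
        distances=(json.loads(dists.to_json(orient="index"))
                   if dists is not None else {}),
        newick=newick,
        subfamilies=labels,
        conservation=classes,
        screen=screen,
    )
    def _stable(obj):
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return str(obj)

    save("report.json", json.dumps(asdict(report), indent=1, sort_keys=True,
                                   default=_stable))
    (out / "MANIFEST").write_text("\n".join(["COMPLETE"] + sorted(manifest)) + "\n")
    return report
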