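# Methods

## Coordinates and circular topology

All intervals are 0-based half-open. On a circular sequence of length L a
feature may wrap the origin; this is encoded as `end > L` with
`end − start ≤ L`, so interval arithmetic stays ordinary and GFF3/BED
emission converts at the boundary. GenBank two-part `join()` locations
that span the origin are folded into this representation on input.

## ORF prediction

Criteria: minimum 39 codons counted from the start codon through the last
sense codon (the stop is excluded; `(end − start) = 3·(n_codons+1)`),
start codons ATG/GTG/TTG (alternative starts translate as Met), stop
codons TAA/TAG/TGA, translation table 11. All six frames are scanned; on
circular sequences the doubled sequence is scanned and calls are
deduplicated modulo L. A run of sense codons is only converted into a
call when it is bounded by a real barrier (stop codon, or a codon
containing N) on both sides — a run truncated by the scan edge is a
partial copy of a run that appears intact elsewhere in the doubled
sequence. Frames of a circle that contain no stop at all are reported as
a warning, not as a call. Codons containing N terminate an ORF and the
truncated ORF is discarded. Overlapping and nested calls are not
filtered: for these gene-dense replicons any overlap filter would be a
curation decision, not a property of the sequence.

Where several in-frame starts share a stop, the reported start maximizes
(SD score, ORF length), falling back to the most upstream start when no
candidate reaches the minimum SD match of 4; ties break to the smaller
coordinate. The SD score is the length of the longest contiguous exact
match between the consensus `AGGAGG` and the window 4–20 bp upstream of
the start codon on the coding strand (offsets measured from the match 3′
end to the start codon; nearest match wins ties). This is a deliberately
auditable rule — no free-energy model — and the consensus, window and
threshold are all parameters. Published annotations of such plasmids
adjust starts by eye against SD motifs; the rule automates that step and
will not reproduce manual curation exactly.

## Cumulative GC skew and ori prediction

The per-position increment is +1 for G, −1 for C, 0 otherwise. The mean
increment is subtracted before cumulation, so the circular walk closes at
zero and the location of extrema is equivariant under rotation of the
coordinate frame; the raw (uncentered) walk of a circle depends on the
arbitrary start point, which makes "the minimum" ill-defined. A moving
average (default width 100 bp, circular) smooths the walk. Candidate ori
positions are local minima with topographic prominence ≥ 0.1 of the
profile range (suppressing noise valleys; the fraction is a parameter).

Large intergenic regions (complement of the ORF union, gaps ≥ 150 bp)
are scored by circular distance to the nearest candidate minimum (zero
when a minimum falls inside), with the count of repeat pairs fully inside
the region and the minimum's prominence as tie-breaks. *All* regions are
reported with ranks: profiles with two genuine valleys are a documented
real-world case, and the tool must surface the ambiguity rather than
resolve it. Repeats are maximal exact pairs (direct and inverted), found
by seed-and-extend over exact 12-mers, wrap-aware, ranked by length;
"significance" is length rank — no statistical model, because the search
spaces are a few kilobases.

## Homology, families, and screening

Pairwise comparison is optimal local alignment (Smith–Waterman) under
BLOSUM62 with affine gaps: a gap of length k costs 11 + (k−1)·1. Identity
is counted over aligned residue pairs; coverage is aligned residue pairs
divided by the length of the *shorter* protein, matching how domain-level
relationships are conventionally reported ("x% identity over N aa").
A hit requires raw score ≥ 75, identity ≥ 0.30 and coverage ≥ 0.25; hits
with coverage ≥ 0.70 are *full*, the rest *partial* (domain-level). The
score floor sits far above the random-alignment tail for proteins of
80–900 aa under this matrix (random pairs top out near score ~55 at these
lengths, with shallow coverage) and far below any genuine homologue
signal down to ~40% residue divergence, where full-length hits score in
the hundreds. There is no E-value model: the database here is a fixed
handful of replicons, not a growing archive.

Families are the single-linkage transitive closure over full hits only;
partial hits never merge families (a shared domain does not make two
modular replicases the same gene), but they drive the modular-map report,
which partitions a protein's axis into segments supported by hits to
distinct partner families. Family ids hash the sorted member list, so the
partition and ids are invariant to input order. Cross-screening aligns
each external query to every family representative (optionally every
member) and reports the best hit above the partial thresholds; queries
with none are orphans.

These thresholds are a declared decision: the original analyses of such
data used profile-based searches (PSI-BLAST, HHpred) whose remote-homology
hits a direct pairwise method cannot recover. Profile methods are out of
scope; the thresholds are configurable and echoed in every report.

## Pan-genome analysis

Presence/absence is binary (paralogs collapse; a count matrix is kept as
a sidecar). Two gene-content distances are implemented because the
original tool's formula is not public: Jaccard (default) and
−ln(|A∩B|/min(|A|,|B|)) with empty intersections mapped to a ceiling
(default 5.0). The tree is Saitou–Nei neighbor joining with the standard
Q criterion, deterministic lowest-(i,j) tie-break, and negative branch
lengths clamped to zero with the deficit shifted to the sister branch; NJ
is exact on additive matrices, which the tests exploit. Optional rooting
splits a named outgroup's pendant edge at its midpoint. Subfamily
delineation is single-linkage agglomerative clustering of the distance
matrix cut to k clusters (default 2) via `cut_tree`, which returns
exactly k clusters even under tied merge heights; labels are renumbered
by first appearance, making the output deterministic. Conservation
classes partition families: core (all replicons), semi-conserved (≥1
replicon of each subfamily, not all), group-specific (≥2 replicons of
exactly one subfamily), singleton (exactly one replicon).

## Synthetic data generator

The generator emulates the observed regime of small archaeal plasmids:
8–14 kb circular replicons carrying ~9–13 genes each, two subfamilies of
four replicons, and a family structure of 2 core families (one large
600–900 aa replicase-like protein and one small 80–150 aa regulator),
3 semi-conserved families placed in 1–2 members of *each* subfamily,
4 group-specific families per subfamily carried by nearly every group
member (membership probability 0.85, and never fewer than two group
families per replicon, so each subfamily forms a coherent shared-gene
block rather than a diffuse one), plus ≥2 private singletons per replicon
(topped up so every replicon reaches 9 genes). Family members derive from
an i.i.d. ancestor (hyperthermophile-leaning amino-acid background) by
point substitutions at the configured divergence (default 0.10); there
are no indels, so identity and coverage have exact expectations.

Genes are back-translated with table 11. Strand-composition bias is
injected only where it cannot change a protein: free intergenic bases and
synonymous third positions prefer G on the leading strand (and C on the
lagging strand) at the configured bias (default 0.7), switching at the
planted ori (middle of the large intergenic region before the replication
cassette) and at its antipode (the terminus; single-ori model). A 25 bp
direct repeat pair is planted inside the ori region. `AGGAGG` is stamped
ending 8 bp upstream of every start codon on the coding strand. The
whole-replicon G+C fraction lands at 0.45 ± 0.03 via the codon-choice
weights and spacer composition.

Making the planted genes the *exact* ORF complement of each replicon — a
property the recovery tests rely on — requires actively suppressing
chance ORFs: ~10 kb of coding DNA otherwise carries dozens of ≥39-codon
reading frames on other strands and frames. Three mechanisms cooperate:
synonymous codon choice is biased (weight 3) toward codons whose reverse
complements are stops (TTA, CTA, TCA); a repair pass rescans each
assembled replicon and breaks every non-planted call by rewriting host
codons synonymously to introduce an in-frame stop (or to spoil the chance
start), with randomized edit order to avoid cycles; and every generated
protein carries a Leu or Ser in each 25-residue block, because those are
the only residues whose codons can place a stop on the reverse strand in
the same phase. When a chance ORF's openness is forced by the amino-acid
sequence itself (no synonymous assignment can break it), the family
ancestor is edited inside the stuck window and the whole set is rebuilt,
keeping family structure consistent. Generation is deterministic per
seed.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: indels and rate heterogeneity,
recombination and horizontal transfer within the set, overlapping genes,
multi-ori replication, profile-detectable remote homology, and the
manual-curation component of real annotations.

## Problem sizes

The validation suite uses the sizes the analyses are reported at: 100
random 600 bp circles for ORF-oracle equivalence, 200 random ≤50 aa pairs
for the alignment DP oracle, 25 additive matrices for each NJ oracle, 50
single-replicon sets for ori recovery (success = rank-1 region contains
the planted ori and |skew minimum − ori| ≤ 250 bp, required in ≥90%),
20 eight-replicon sets for pan-genome recovery (family partition at
adjusted Rand index 1.0, correct 2-way split, every conservation class
correct, required in ≥95%), and a 12-protein half-homologous decoy
proteome at 40% divergence for cross-screening (exactly 6 mapped, 6
orphans).

## Known limitations

SD-based start adjustment is a heuristic and will differ from manual
curation at some loci. Ori prediction assumes a single bidirectional-ish
compositional switch; rolling-circle replicons with weak skew will rank
poorly. Pairwise alignment cannot see profile-level remote homology, so
family maps of real data are conservative relative to published curated
maps. The gene-content distance of the original analysis is not public;
topology-level agreement is the only meaningful comparison for real
trees. Single-linkage subfamily delineation inherits single linkage's
chaining sensitivity; the configurable threshold cut is provided for
borderline data.
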