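#!/usr/bin/env python
"""Generate the synthetic plasmid study set.

Writes an 8-replicon circular plasmid set (two planted subfamilies of
four, core/semi-conserved/group-specific/singleton gene families, skewed
ori with nearby direct repeat, SD motifs) plus its ground truth under
results/synthetic/. The set drives analyses 02-04.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mgecompare.seq_io import write_fasta
from mgecompare.synthetic import SynthConfig, generate_set

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(seed=SEED)
    seqs, truth = generate_set(cfg)
    write_fasta(OUT / "replicons.fasta", seqs)
    payload = {
        "seed": SEED,
        "family_class": truth.family_class,
        "replicons": {
            rid: {"ori_pos": rt.ori_pos, "subfamily": rt.subfamily,
                  "genes": [vars(g) for g in rt.genes]}
            for rid, rt in truth.replicons.items()},
    }
    (OUT / "truth.json").write_text(json.dumps(payload, indent=1))
    lengths = [s.length for s in seqs]
    genes = [len(truth.replicons[s.id].genes) for s in seqs]
    print(f"wrote {len(seqs)} replicons "
          f"({min(lengths)}-{max(lengths)} bp, {min(genes)}-{max(genes)} genes) "
          f"to {OUT}")


if __name__ == "__main__":
    main()
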