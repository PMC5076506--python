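#!/usr/bin/env python
"""Curate the raw sequence set: drop fragments, collapse near-duplicates.

Reads results/inputs/msa_raw.fasta, applies the 0.7 fraction-of-median
length filter and the 95% identity redundancy prune, and reports how the
removals compare with the generator's ground truth.
"""

import json
from pathlib import Path

from allokin.curation import curate, read_fasta, write_fasta

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    seqs = read_fasta(ROOT / "inputs" / "msa_raw.fasta")
    truth = json.loads((ROOT / "inputs" / "msa_truth.json").read_text())

    kept, report = curate(seqs, identity_threshold=0.95, min_length_fraction=0.7)
    write_fasta(kept, ROOT / "msa_curated.fasta")
    report.to_json(ROOT / "curation_report.json")

    kept_ids = {s.id for s in kept}
    dup_removed = len(set(truth["redundant_ids"]) - kept_ids)
    frag_removed = len(set(truth["fragment_ids"]) - kept_ids)
    print(f"input {report.n_input} -> kept {report.n_output} "
          f"(fragments removed {report.n_removed_fragment}, "
          f"redundant removed {report.n_removed_redundant})")
    print(f"ground truth: {dup_removed}/{len(truth['redundant_ids'])} injected "
          f"duplicates and {frag_removed}/{len(truth['fragment_ids'])} fragments "
          "removed")


if __name__ == "__main__":
    main()
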