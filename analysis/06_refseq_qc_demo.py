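#!/usr/bin/env python
"""Reference-sequence curation demo on a generated candidate set.

Builds a small synthetic batch of SSU reference candidates spanning the
culling boundaries (ambiguous bases, homopolymers, domain-conditional
lengths, duplicate records), runs the full curation chain, and writes the
kept/rejected artifacts under results/refseq_qc/.
"""
from pathlib import Path

import numpy as np

from nukaflow.refseq_qc import (
    ReferenceSeq,
    cull_seqs,
    dereplicate_uniq,
    filter_by_length_and_taxon,
    rejected_to_tsv,
    write_reference_seqs,
)
from nukaflow.tables_io import Lineage

OUT = Path(__file__).resolve().parent.parent / "results" / "refseq_qc"


def synthetic_candidates(n: int = 60, seed: int = 5) -> list[ReferenceSeq]:
    """Random 16S/18S-length candidates; every few records carry a QC defect
    (degenerate stretch, homopolymer, short length, or duplication)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out = []
    domains = ["Bacteria", "Archaea", "Eukaryota"]
    for i in range(n):
        domain = domains[i % 3]
        length = {"Bacteria": 1250, "Archaea": 950, "Eukaryota": 1450}[domain]
        if i % 5 == 1:
            length -= 80  # below the domain minimum
        seq = "".join(rng.choice(bases, size=length))
        if i % 5 == 2:
            seq = seq[:50] + "N" * 6 + seq[56:]  # degenerate stretch
        if i % 5 == 3:
            seq = seq[:100] + "A" * 9 + seq[109:]  # long homopolymer
        lineage = Lineage((f"d__{domain}", "p__P", "c__C", "o__O", "f__F",
                           f"g__Genus{i % 7}"))
        out.append(ReferenceSeq.create(f"ref{i:03d}", seq, lineage))
        if i % 10 == 4:  # exact duplicate record
            out.append(ReferenceSeq.create(f"ref{i:03d}dup", seq, lineage))
    return out


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    candidates = synthetic_candidates()
    kept, culled = cull_seqs(candidates)
    kept, short = filter_by_length_and_taxon(kept)
    unique = dereplicate_uniq(kept)
    write_reference_seqs(unique, OUT / "curated.fasta")
    rejected_to_tsv(culled + short, OUT / "rejected.tsv")
    print(f"{len(candidates)} candidates -> culled {len(culled)} "
          f"(degenerates/homopolymers), {len(short)} too short, "
          f"{len(kept) - len(unique)} duplicates removed")
    print(f"curated set: {len(unique)} sequences")


if __name__ == "__main__":
    main()
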