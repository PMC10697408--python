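"""Reference-sequence curation filters for classifier-database building.

Mirrors the standard SSU reference curation recipe: cull sequences with too
many degenerate (ambiguous) bases or long homopolymers, apply
domain-conditional minimum lengths (16S for archaea/bacteria, 18S for
eukaryotes), and deduplicate in "uniq" mode, where identical sequences with
different taxonomic lineages are all retained.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .tables_io import Lineage

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")

DOMAIN_LABELS = ("archaea_16S", "bacteria_16S", "eukaryote_18S", "unknown")


def _resolve_domain(lineage: Optional[Lineage]) -> str:
    if lineage is None or not lineage.ranks:
        return "unknown"
    domain = lineage.rank_name(0).lower()
    if "archaea" in domain:
        return "archaea_16S"
    if "bacteria" in domain:
        return "bacteria_16S"
    if "eukary" in domain:
        return "eukaryote_18S"
    return "unknown"


@dataclass(frozen=True)
class ReferenceSeq:
    """A candidate database sequence with its lineage and resolved domain.

    Sequences are upper-cased and U is normalized to T on ingest, so all
    downstream checks see a DNA alphabet.
    """

    id: str
    sequence: str
    lineage: Optional[Lineage] = None
    domain_label: str = "unknown"

    @classmethod
    def create(cls, id: str, sequence: str, lineage: Optional[Lineage] = None):
        seq = sequence.upper().replace("U", "T")
        if not seq:
            raise FormatError(f"sequence {id!r} is empty")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"sequence {id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        return cls(id=id, sequence=seq, lineage=lineage,
                   domain_label=_resolve_domain(lineage))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RefSeqQCParams:
    """Culling thresholds; the defaults follow the usual curation recipe:
    reject at >= 5 ambiguous bases or a homopolymer run of >= 8, and require
    900/1200/1400 bp for archaeal 16S / bacterial 16S / eukaryotic 18S."""

    max_degenerates_exclusive: int = 5
    min_homopolymer_reject: int = 8
    min_length_by_domain: dict = field(
        default_factory=lambda: {
            "archaea_16S": 900,
            "bacteria_16S": 1200,
            "eukaryote_18S": 1400,
        }
    )

    def __post_init__(self):
        if self.max_degenerates_exclusive <= 0 or self.min_homopolymer_reject <= 0:
            raise ValueError("thresholds must be positive")
        if any(v <= 0 for v in self.min_length_by_domain.values()):
            raise ValueError("length minima must be positive")


@dataclass(frozen=True)
class RejectedSeq:
    seq: ReferenceSeq
    reasons: tuple[str, ...]
    values: tuple[int, ...]


def count_degenerate_bases(sequence: str) -> int:
    """Number of IUPAC degeneracy codes (anything outside A/C/G/T; U counts
    as T, i.e. an RNA alphabet is tolerated, not penalized)."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise FormatError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return sum(1 for c in seq if c not in UNAMBIGUOUS)


def longest_homopolymer(sequence: str) -> int:
    """Length of the longest run of one identical character."""
    if not sequence:
        return 0
    best = run = 1
    prev = sequence[0]
    for c in sequence[1:]:
        run = run + 1 if c == prev else 1
        prev = c
        if run > best:
            best = run
    return best


def cull_seqs(
    seqs: Iterable[ReferenceSeq], params: RefSeqQCParams = RefSeqQCParams()
) -> tuple[list[ReferenceSeq], list[RejectedSeq]]:
    """Reject sequences with too many degenerate bases or too-long runs.

    A sequence is rejected iff its degenerate-base count reaches
    ``max_degenerates_exclusive`` or its longest homopolymer reaches
    ``min_homopolymer_reject``; a record failing both rules carries both
    reasons.  kept + rejected partition the input in order.
    """
    kept: list[ReferenceSeq] = []
    rejected: list[RejectedSeq] = []
    for s in seqs:
        degen = count_degenerate_bases(s.sequence)
        homo = longest_homopolymer(s.sequence)
        reasons: list[str] = []
        values: list[int] = []
        if degen >= params.max_degenerates_exclusive:
            reasons.append("degenerates")
            values.append(degen)
        if homo >= params.min_homopolymer_reject:
            reasons.append("homopolymer")
            values.append(homo)
        if reasons:
            rejected.append(RejectedSeq(s, tuple(reasons), tuple(values)))
        else:
            kept.append(s)
    return kept, rejected


def filter_by_length_and_taxon(
    seqs: Iterable[ReferenceSeq], params: RefSeqQCParams = RefSeqQCParams()
) -> tuple[list[ReferenceSeq], list[RejectedSeq]]:
    """Keep sequences meeting their domain's minimum length.

    Sequences whose domain cannot be resolved from the lineage pass with a
    warning reason of "unknown_domain" attached nowhere — they are kept
    conservatively, since no rule exists for them.
    """
    import logging

    logger = logging.getLogger(__name__)
    kept: list[ReferenceSeq] = []
    rejected: list[RejectedSeq] = []
    for s in seqs:
        minimum = params.min_length_by_domain.get(s.domain_label)
        if minimum is None:
            logger.warning(
                "sequence %s: unknown domain, length filter skipped", s.id
            )
            kept.append(s)
            continue
        if len(s) >= minimum:
            kept.append(s)
        else:
            rejected.append(RejectedSeq(s, ("length",), (len(s),)))
    return kept, rejected


def dereplicate_uniq(seqs: Sequence[ReferenceSeq]) -> list[ReferenceSeq]:
    """Uniq-mode deduplication: collapse identical (sequence, lineage) pairs.

    Identical sequences that carry *different* lineages are all retained —
    the classifier needs the conflicting labels.  First occurrence wins;
    output order is deterministic.
    """
    seen: set[tuple] = set()
    out: list[ReferenceSeq] = []
    for s in seqs:
        ranks = s.lineage.ranks if s.lineage is not None else ()
        key = (s.sequence, ranks)
        if key in seen:
            continue
        seen.add(key)
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# FASTA / TSV IO
# ---------------------------------------------------------------------------

def read_reference_seqs(
    fasta_path: str | Path, lineage_tsv: Optional[str | Path] = None
) -> list[ReferenceSeq]:
    """Load sequences from FASTA, optionally joining lineages from a
    Feature ID / Taxon TSV (same layout as the feature-taxonomy file)."""
    lineages: dict[str, Lineage] = {}
    if lineage_tsv is not None:
        from .tables_io import read_taxonomy

        tax = read_taxonomy(lineage_tsv)
        lineages = {fid: tax[fid] for fid in tax}
    out = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        out.append(
            ReferenceSeq.create(
                id=record.id, sequence=str(record.seq), lineage=lineages.get(record.id)
            )
        )
    return out


def write_reference_seqs(seqs: Iterable[ReferenceSeq], fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def rejected_to_tsv(rejected: Iterable[RejectedSeq], path: str | Path) -> None:
    rows = [
        {
            "id": r.seq.id,
            "reasons": ";".join(r.reasons),
            "values": ";".join(str(v) for v in r.values),
        }
        for r in rejected
    ]
    pd.DataFrame(rows, columns=["id", "reasons", "values"]).to_csv(
        path, sep="\t", index=False
    )
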