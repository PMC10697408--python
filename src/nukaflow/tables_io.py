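"""Feature tables, sample metadata, and taxonomy: types, readers, writers.

The central object is :class:`FeatureTable`, an integer ASV-count matrix with
features as rows and samples as columns — the orientation common among
amplicon exporters.  Relative abundances live in a distinct type
(:class:`RelativeAbundanceTable`) so that threshold-based operations can never
be applied to raw counts by mistake.

All on-disk formats are plain UTF-8 TSV:

* feature table — first column ``feature_id`` (plain dialect) or ``#OTU ID``
  after an optional single ``#``-comment line (``biom_tsv`` dialect);
* metadata — header ``sample-id  subject  substrate  day  timepoint  phase``;
* taxonomy — header ``Feature ID  Taxon  Confidence`` with semicolon-separated
  lineages carrying the usual ``d__/p__/.../g__/s__`` rank prefixes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, UniquenessError, VocabularyError

logger = logging.getLogger(__name__)

SUBSTRATES = ("nukadoko", "skin")
PHASES = ("contact", "no_contact")

#: last study day of the daily-stirring (contact) phase
CONTACT_LAST_DAY = 14

RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTable:
    """Integer ASV counts, features x samples.

    ``data`` is a pandas DataFrame indexed by feature id with sample ids as
    columns; values must be non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        # a zero-feature table can arise from aggressive filtering and stays
        # representable; a table without samples cannot
        if df.shape[1] < 1:
            raise FormatError("feature table must have at least one sample")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or not np.all(values == np.floor(values)):
                raise FormatError("feature table counts must be integers")
            object.__setattr__(self, "data", df.astype(np.int64))
            values = self.data.to_numpy()
        if (values < 0).any():
            raise FormatError("feature table counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample_counts(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(sample_ids)])

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(feature_ids), :])

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)


@dataclass(frozen=True)
class RelativeAbundanceTable:
    """Per-sample relative abundances; every column sums to 1 (±1e-9)."""

    data: pd.DataFrame

    def __post_init__(self):
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any() or (values > 1 + 1e-12).any():
            raise FormatError("relative abundances must lie in [0, 1]")
        sums = values.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
        if bad.size:
            raise FormatError(
                f"sample {self.data.columns[bad[0]]!r} abundances sum to "
                f"{sums[bad[0]]:.12f}, not 1"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample_abundances(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's annotations; pairing logic is driven entirely by these."""

    sample_id: str
    subject: str
    substrate: str
    day: int
    timepoint_label: str
    phase: str

    def __post_init__(self):
        if self.substrate not in SUBSTRATES:
            raise VocabularyError(
                f"unknown substrate {self.substrate!r} for sample {self.sample_id!r}; "
                f"expected one of {SUBSTRATES}"
            )
        if self.phase not in PHASES:
            raise VocabularyError(
                f"unknown phase {self.phase!r} for sample {self.sample_id!r}; "
                f"expected one of {PHASES}"
            )
        if self.day < 0:
            raise VocabularyError(f"negative day for sample {self.sample_id!r}")
        expected = "contact" if self.day <= CONTACT_LAST_DAY else "no_contact"
        if self.phase != expected:
            raise VocabularyError(
                f"sample {self.sample_id!r}: day {self.day} implies phase "
                f"{expected!r}, got {self.phase!r}"
            )


class SampleMetadataSet:
    """Ordered collection of :class:`SampleMetadata` with uniqueness checks."""

    def __init__(self, records: Iterable[SampleMetadata]):
        self.records: list[SampleMetadata] = list(records)
        seen_keys: set[tuple] = set()
        seen_ids: set[str] = set()
        for r in self.records:
            key = (r.subject, r.substrate, r.timepoint_label)
            if key in seen_keys:
                raise UniquenessError(
                    f"duplicate (subject, substrate, timepoint) {key!r}"
                )
            if r.sample_id in seen_ids:
                raise UniquenessError(f"duplicate sample id {r.sample_id!r}")
            seen_keys.add(key)
            seen_ids.add(r.sample_id)
        self._by_id = {r.sample_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def get(self, sample_id: str) -> SampleMetadata:
        return self._by_id[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadataSet":
        wanted = set(sample_ids)
        return SampleMetadataSet(r for r in self.records if r.sample_id in wanted)

    def sorted(self) -> "SampleMetadataSet":
        """Normalized order: (subject, substrate, day, timepoint_label)."""
        return SampleMetadataSet(
            sorted(
                self.records,
                key=lambda r: (r.subject, r.substrate, r.day, r.timepoint_label),
            )
        )


@dataclass(frozen=True)
class Lineage:
    """An ordered taxonomy lineage, at most 7 ranks (domain..species).

    Rank labels keep their ``d__``-style prefixes so they can be matched
    verbatim; :meth:`genus` strips the prefix for display and aggregation.
    """

    ranks: tuple[str, ...]
    confidence: Optional[float] = None

    def __post_init__(self):
        if len(self.ranks) > 7:
            raise FormatError(f"lineage has {len(self.ranks)} ranks; at most 7 allowed")

    @property
    def is_unassigned(self) -> bool:
        return len(self.ranks) == 1 and self.ranks[0].strip().lower() == "unassigned"

    @staticmethod
    def _strip_prefix(label: str) -> str:
        for p in RANK_PREFIXES:
            if label.startswith(p):
                return label[len(p):]
        return label

    def rank_name(self, index: int) -> str:
        """Prefix-stripped label at ``index``, '' if absent."""
        if index >= len(self.ranks):
            return ""
        return self._strip_prefix(self.ranks[index]).strip()

    @property
    def genus(self) -> str:
        return self.rank_name(5)

    @property
    def lowest_named_rank(self) -> str:
        for label in reversed(self.ranks):
            name = self._strip_prefix(label).strip()
            if name:
                return name
        return ""


class TaxonomyMap(Mapping[str, Lineage]):
    """feature id -> :class:`Lineage`."""

    def __init__(self, assignments: Mapping[str, Lineage]):
        self._assignments = dict(assignments)

    def __getitem__(self, feature_id: str) -> Lineage:
        return self._assignments[feature_id]

    def __iter__(self):
        return iter(self._assignments)

    def __len__(self) -> int:
        return len(self._assignments)

    def genus_of(self, feature_id: str, default: str = "") -> str:
        lin = self._assignments.get(feature_id)
        return lin.genus if lin is not None else default


@dataclass(frozen=True)
class Dataset:
    """A validated, id-consistent bundle of table + metadata + taxonomy."""

    table: FeatureTable
    meta: SampleMetadataSet
    tax: TaxonomyMap
    unassigned_features: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, dialect: str = "plain") -> FeatureTable:
    """Read a features x samples TSV into a validated :class:`FeatureTable`.

    ``dialect='biom_tsv'`` additionally accepts one leading ``#``-prefixed
    comment line (e.g. ``# Constructed from biom file``) and the ``#OTU ID``
    first-column header used by BIOM TSV exports.
    """
    if dialect not in ("plain", "biom_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if dialect == "biom_tsv" and lines and lines[0].startswith("#") \
            and not lines[0].startswith("#OTU ID"):
        lines = lines[1:]
    if not lines:
        raise FormatError(f"{path}: empty feature table")
    header = lines[0].split("\t")
    first_col = header[0]
    if dialect == "biom_tsv":
        if first_col != "#OTU ID" and first_col != "feature_id":
            raise FormatError(
                f"{path}: biom_tsv dialect expects '#OTU ID' header, got {first_col!r}"
            )
    elif first_col != "feature_id":
        raise FormatError(f"{path}: expected first column 'feature_id', got {first_col!r}")
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns")
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample id {s!r}")
        seen.add(s)
    feature_ids: list[str] = []
    rows: list[list[int]] = []
    seen_f: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        fid = cells[0]
        if fid in seen_f:
            raise FormatError(f"{path}: duplicate feature id {fid!r}")
        seen_f.add(fid)
        row: list[int] = []
        for s, cell in zip(sample_ids, cells[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric count {cell!r} in sample {s!r}"
                ) from None
            if value < 0 or value != int(value):
                raise FormatError(
                    f"{path}:{lineno}: count {cell!r} in sample {s!r} is not a "
                    "non-negative integer"
                )
            row.append(int(value))
        feature_ids.append(fid)
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: feature table has no feature rows")
    df = pd.DataFrame(rows, index=feature_ids, columns=sample_ids, dtype=np.int64)
    df.index.name = "feature_id"
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a plain-dialect TSV; re-reading reproduces the table exactly."""
    for fid in table.feature_ids:
        if "\t" in fid or "\n" in fid:
            raise FormatError(f"feature id {fid!r} contains a delimiter character")
    for sid in table.sample_ids:
        if "\t" in sid or "\n" in sid:
            raise FormatError(f"sample id {sid!r} contains a delimiter character")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(table.sample_ids) + "\n")
        for fid, row in table.data.iterrows():
            fh.write(fid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


METADATA_COLUMNS = ["sample-id", "subject", "substrate", "day", "timepoint", "phase"]


def read_metadata(path: str | Path) -> SampleMetadataSet:
    """Read the sample-annotation TSV into a validated metadata set."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            day = int(row["day"])
        except ValueError:
            raise FormatError(
                f"{path}: non-integer day {row['day']!r} for sample {row['sample-id']!r}"
            ) from None
        records.append(
            SampleMetadata(
                sample_id=row["sample-id"],
                subject=row["subject"],
                substrate=row["substrate"],
                day=day,
                timepoint_label=row["timepoint"],
                phase=row["phase"],
            )
        )
    return SampleMetadataSet(records)


def write_metadata(meta: SampleMetadataSet, path: str | Path) -> None:
    rows = [
        {
            "sample-id": r.sample_id,
            "subject": r.subject,
            "substrate": r.substrate,
            "day": r.day,
            "timepoint": r.timepoint_label,
            "phase": r.phase,
        }
        for r in meta
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a ``Feature ID / Taxon / Confidence`` TSV into a TaxonomyMap.

    Lineages are split on ';' and whitespace-trimmed; rank prefixes are kept.
    An empty Confidence cell leaves the confidence unset.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "Feature ID" not in df.columns or "Taxon" not in df.columns:
        raise FormatError(f"{path}: taxonomy TSV needs 'Feature ID' and 'Taxon' columns")
    has_conf = "Confidence" in df.columns
    assignments: dict[str, Lineage] = {}
    for _, row in df.iterrows():
        ranks = tuple(part.strip() for part in row["Taxon"].split(";"))
        conf: Optional[float] = None
        if has_conf and row["Confidence"].strip():
            conf = float(row["Confidence"])
        assignments[row["Feature ID"]] = Lineage(ranks=ranks, confidence=conf)
    return TaxonomyMap(assignments)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    rows = [
        {
            "Feature ID": fid,
            "Taxon": "; ".join(tax[fid].ranks),
            "Confidence": "" if tax[fid].confidence is None else tax[fid].confidence,
        }
        for fid in tax
    ]
    pd.DataFrame(rows, columns=["Feature ID", "Taxon", "Confidence"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# alignment and normalization
# ---------------------------------------------------------------------------

def align_dataset(
    table: FeatureTable, meta: SampleMetadataSet, tax: TaxonomyMap
) -> Dataset:
    """Reconcile the three inputs into one validated :class:`Dataset`.

    Samples in the table but absent from the metadata are an error; metadata
    rows without a table column are ignored with a warning.  Features missing
    from the taxonomy are retained and flagged (the organelle/unassigned
    filter removes them downstream).  Sample order is normalized to
    (subject, substrate, day, timepoint).
    """
    table_samples = set(table.sample_ids)
    meta_samples = set(meta.sample_ids)
    missing_meta = sorted(table_samples - meta_samples)
    if missing_meta:
        raise AlignmentError(
            f"samples missing from metadata: {', '.join(missing_meta)}"
        )
    overlap = table_samples & meta_samples
    if not overlap:
        raise AlignmentError("no overlapping samples between table and metadata")
    extra = sorted(meta_samples - table_samples)
    if extra:
        logger.warning("metadata samples absent from table ignored: %s", ", ".join(extra))
    meta_aligned = meta.subset(overlap).sorted()
    table_aligned = table.select_samples(meta_aligned.sample_ids)
    unassigned = frozenset(f for f in table.feature_ids if f not in tax)
    return Dataset(
        table=table_aligned, meta=meta_aligned, tax=tax, unassigned_features=unassigned
    )


def to_relative(table: FeatureTable, drop_empty: bool = False) -> RelativeAbundanceTable:
    """Convert counts to per-sample relative abundances.

    All-zero samples are an error unless ``drop_empty`` is set, in which case
    they are removed with a logged warning.
    """
    totals = table.sample_totals()
    zero = totals[totals == 0]
    df = table.data
    if len(zero):
        if not drop_empty:
            raise FormatError(
                f"sample {zero.index[0]!r} has zero total count "
                "(pass drop_empty=True to remove it)"
            )
        logger.warning("dropping all-zero samples: %s", ", ".join(zero.index))
        df = df.drop(columns=list(zero.index))
        if df.shape[1] == 0:
            raise FormatError("all samples were empty")
        totals = totals.drop(zero.index)
    rel = df.astype(float) / totals
    return RelativeAbundanceTable(rel)
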