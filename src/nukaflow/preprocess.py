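"""Taxonomy-driven filtering and genus-level aggregation.

Chloroplast- and mitochondria-derived 16S reads, and ASVs with no taxonomic
assignment, are removed before any community statistic; the removal is fully
accounted for per sample.  Relative tables then collapse to genus and to a
top-N + remainder presentation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .tables_io import FeatureTable, RelativeAbundanceTable, TaxonomyMap

logger = logging.getLogger(__name__)

REMAINDER_LABEL = "remainder"

FILTER_REASONS = ("chloroplast", "mitochondria", "unassigned")


@dataclass
class FilterReport:
    """Which features were removed, why, and how many reads that cost.

    Each removed feature carries exactly one reason (the first matching rule
    wins: chloroplast, then mitochondria, then unassigned), and per-sample
    read accounting balances exactly: retained + removed = original totals.
    """

    removed: dict[str, list[str]] = field(
        default_factory=lambda: {r: [] for r in FILTER_REASONS}
    )
    reads_removed: pd.Series = field(default_factory=lambda: pd.Series(dtype="int64"))
    reads_retained: pd.Series = field(default_factory=lambda: pd.Series(dtype="int64"))

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def reason_of(self, feature_id: str) -> str | None:
        for reason, ids in self.removed.items():
            if feature_id in ids:
                return reason
        return None

    def to_feature_tsv(self, path: str | Path) -> None:
        rows = [
            {"feature_id": fid, "reason": reason}
            for reason in FILTER_REASONS
            for fid in self.removed[reason]
        ]
        pd.DataFrame(rows, columns=["feature_id", "reason"]).to_csv(
            path, sep="\t", index=False
        )

    def to_accounting_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "reads_removed": self.reads_removed,
                "reads_retained": self.reads_retained,
            }
        )
        df.index.name = "sample-id"
        df.to_csv(path, sep="\t")


def _classify(feature_id: str, tax: TaxonomyMap) -> str | None:
    """First matching removal reason for a feature, or None to retain."""
    lin = tax.get(feature_id)
    if lin is not None:
        labels = [r.lower() for r in lin.ranks]
        if any("chloroplast" in r for r in labels):
            return "chloroplast"
        if any("mitochondri" in r for r in labels):
            return "mitochondria"
        if lin.is_unassigned:
            return "unassigned"
        return None
    return "unassigned"


def filter_organelle_unassigned(
    table: FeatureTable, tax: TaxonomyMap, min_resolved_ranks: int | None = None
) -> tuple[FeatureTable, FilterReport]:
    """Remove chloroplast, mitochondrial, and unassigned features.

    A feature is removed iff (a) any lineage rank contains "chloroplast"
    (case-insensitive); else (b) any rank contains "mitochondri"; else (c) it
    has no taxonomy record or its whole lineage is the single label
    "Unassigned".  Lineages resolved only to higher ranks (e.g. domain alone)
    are kept by default; ``min_resolved_ranks`` optionally also removes
    features with fewer named ranks, recorded under the "unassigned" reason.
    """
    report = FilterReport()
    keep: list[str] = []
    for fid in table.feature_ids:
        reason = _classify(fid, tax)
        if reason is None and min_resolved_ranks is not None:
            lin = tax[fid]
            named = sum(1 for i in range(len(lin.ranks)) if lin.rank_name(i))
            if named < min_resolved_ranks:
                reason = "unassigned"
        if reason is None:
            keep.append(fid)
        else:
            report.removed[reason].append(fid)
    removed_ids = [f for r in FILTER_REASONS for f in report.removed[r]]
    totals = table.sample_totals()
    removed_counts = table.data.loc[removed_ids].sum(axis=0).astype("int64")
    report.reads_removed = removed_counts
    report.reads_retained = (totals - removed_counts).astype("int64")
    if not keep:
        logger.warning("organelle/unassigned filter removed every feature")
    filtered = table.select_features(keep)
    return filtered, report


def _genus_key(feature_id: str, tax: TaxonomyMap) -> str:
    lin = tax.get(feature_id)
    if lin is None:
        return "Unclassified_Unassigned"
    genus = lin.genus
    if genus:
        return genus
    lowest = lin.lowest_named_rank
    return f"Unclassified_{lowest}" if lowest else "Unclassified_Unassigned"


def collapse_genus(
    rel: RelativeAbundanceTable, tax: TaxonomyMap
) -> RelativeAbundanceTable:
    """Sum relative abundances into genus rows.

    Rows are keyed by the prefix-stripped genus name; features without a named
    genus fall into ``Unclassified_<lowest named rank>`` buckets.  Column sums
    are preserved.
    """
    keys = [_genus_key(fid, tax) for fid in rel.feature_ids]
    collapsed = rel.data.groupby(pd.Index(keys, name="genus"), sort=True).sum()
    return RelativeAbundanceTable(collapsed)


def top_n_summary(
    genus_table: RelativeAbundanceTable, n: int = 15
) -> RelativeAbundanceTable:
    """Keep the top-``n`` genera by mean abundance; sum the rest as remainder.

    Ranking is by mean relative abundance across all samples of the table,
    ties broken lexicographically; the ``remainder`` row is always present
    (all zeros when ``n`` covers every genus).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    means = genus_table.data.mean(axis=1)
    order = sorted(means.index, key=lambda g: (-means[g], g))
    top = order[:n]
    rest = order[n:]
    out = genus_table.data.loc[top].copy()
    out.loc[REMAINDER_LABEL] = genus_table.data.loc[rest].sum(axis=0)
    return RelativeAbundanceTable(out)
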