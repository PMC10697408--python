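"""The shared-ASV transmission statistic.

A source (rice-bran bed) sample and a sink (palm skin) sample from the same
subject form a pair; an ASV is *shared* when its relative abundance strictly
exceeds a threshold (default 1%) in **both** members of the pair.  The
per-pair transmission signal is the summed sink-side relative abundance of
the shared ASVs, reported as a percent.

Pairing follows the study's two rules: during the daily-stirring (contact)
phase each skin sample is paired with the same day's bed sample; after
stirring stops, every skin sample is paired with the bed sample from a fixed
source day (the last stirred day, 14, by default).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import AlignmentError
from .tables_io import (
    RelativeAbundanceTable,
    SampleMetadataSet,
    TaxonomyMap,
)

DEFAULT_THRESHOLD = 0.01


@dataclass(frozen=True)
class PairingScheme:
    """Contact phase: same-day pairing; no-contact phase: fixed source day."""

    source_day: int = 14

    def __post_init__(self):
        if self.source_day < 0:
            raise ValueError("source_day must be non-negative")


@dataclass(frozen=True)
class SamplePair:
    subject: str
    source_sample_id: str
    sink_sample_id: str
    day: int
    timepoint_label: str
    phase: str


@dataclass(frozen=True)
class UnpairedSink:
    """A skin sample for which no partner bed sample exists; kept explicit."""

    subject: str
    sink_sample_id: str
    day: int
    timepoint_label: str
    phase: str
    reason: str


@dataclass
class SharedAsvResult:
    pair: SamplePair
    threshold: float
    shared_feature_ids: frozenset[str]
    sink_abundance: dict[str, float] = field(default_factory=dict)

    @property
    def shared_proportion(self) -> float:
        """Percent of the sink community carried by shared ASVs."""
        return 100.0 * sum(self.sink_abundance.values())


def build_pairs(
    meta: SampleMetadataSet, scheme: PairingScheme = PairingScheme()
) -> tuple[list[SamplePair], list[UnpairedSink]]:
    """Pair every skin sample with its source bed sample under the scheme.

    Skin samples lacking a partner (no bed sample on the required day) are
    returned as explicit :class:`UnpairedSink` records, never dropped.
    """
    source_by_key = {
        (r.subject, r.day): r
        for r in meta
        if r.substrate == "nukadoko"
    }
    sinks = [r for r in meta.sorted() if r.substrate == "skin"]
    if not sinks or not source_by_key:
        raise AlignmentError("metadata must contain both nukadoko and skin samples")
    pairs: list[SamplePair] = []
    unpaired: list[UnpairedSink] = []
    for sink in sinks:
        wanted_day = sink.day if sink.phase == "contact" else scheme.source_day
        source = source_by_key.get((sink.subject, wanted_day))
        if source is None:
            unpaired.append(
                UnpairedSink(
                    subject=sink.subject,
                    sink_sample_id=sink.sample_id,
                    day=sink.day,
                    timepoint_label=sink.timepoint_label,
                    phase=sink.phase,
                    reason=f"no nukadoko sample for subject {sink.subject} on day {wanted_day}",
                )
            )
            continue
        pairs.append(
            SamplePair(
                subject=sink.subject,
                source_sample_id=source.sample_id,
                sink_sample_id=sink.sample_id,
                day=sink.day,
                timepoint_label=sink.timepoint_label,
                phase=sink.phase,
            )
        )
    return pairs, unpaired


def find_shared_asvs(
    source_rel: pd.Series,
    sink_rel: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
    strict: bool = True,
) -> frozenset[str]:
    """Features whose relative abundance exceeds ``threshold`` in both samples.

    The comparison is strict (">") by default, matching the study's "> 1%"
    definition: a feature at exactly the threshold is not shared.  Pass
    ``strict=False`` for ">=" sensitivity analyses.
    """
    if set(source_rel.index) != set(sink_rel.index):
        raise AlignmentError("source and sink vectors use different feature universes")
    sink_aligned = sink_rel.reindex(source_rel.index)
    if strict:
        mask = (source_rel > threshold) & (sink_aligned > threshold)
    else:
        mask = (source_rel >= threshold) & (sink_aligned >= threshold)
    return frozenset(source_rel.index[mask])


def shared_proportion(sink_rel: pd.Series, shared: Iterable[str]) -> float:
    """Percent of sink reads belonging to the shared set."""
    shared = list(shared)
    missing = [f for f in shared if f not in sink_rel.index]
    if missing:
        raise AlignmentError(f"shared features absent from sink vector: {missing}")
    return float(100.0 * sink_rel.loc[shared].sum())


def shared_timecourse(
    rel: RelativeAbundanceTable,
    meta: SampleMetadataSet,
    scheme: PairingScheme = PairingScheme(),
    threshold: float = DEFAULT_THRESHOLD,
    strict: bool = True,
) -> tuple[list[SharedAsvResult], list[UnpairedSink]]:
    """Per-pair shared-ASV results across the whole study, in metadata order.

    The table must already be organelle-filtered and relative.  Unpaired skin
    samples come back as explicit gap records.
    """
    pairs, unpaired = build_pairs(meta, scheme)
    results: list[SharedAsvResult] = []
    for pair in pairs:
        source_vec = rel.sample_abundances(pair.source_sample_id)
        sink_vec = rel.sample_abundances(pair.sink_sample_id)
        shared = find_shared_asvs(source_vec, sink_vec, threshold, strict=strict)
        results.append(
            SharedAsvResult(
                pair=pair,
                threshold=threshold,
                shared_feature_ids=shared,
                sink_abundance={f: float(sink_vec[f]) for f in sorted(shared)},
            )
        )
    return results, unpaired


def timecourse_frame(
    results: list[SharedAsvResult], unpaired: Optional[list[UnpairedSink]] = None
) -> pd.DataFrame:
    """Tidy per-pair table; unpaired sinks appear with NA proportions."""
    rows = []
    for r in results:
        rows.append(
            {
                "subject": r.pair.subject,
                "day": r.pair.day,
                "timepoint": r.pair.timepoint_label,
                "phase": r.pair.phase,
                "source_sample": r.pair.source_sample_id,
                "sink_sample": r.pair.sink_sample_id,
                "threshold": r.threshold,
                "n_shared": len(r.shared_feature_ids),
                "shared_proportion_percent": r.shared_proportion,
            }
        )
    for u in unpaired or []:
        rows.append(
            {
                "subject": u.subject,
                "day": u.day,
                "timepoint": u.timepoint_label,
                "phase": u.phase,
                "source_sample": "",
                "sink_sample": u.sink_sample_id,
                "threshold": float("nan"),
                "n_shared": pd.NA,
                "shared_proportion_percent": float("nan"),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "subject", "day", "timepoint", "phase", "source_sample",
            "sink_sample", "threshold", "n_shared", "shared_proportion_percent",
        ],
    )
    return df.sort_values(
        ["subject", "day", "timepoint"], kind="stable"
    ).reset_index(drop=True)


def persistence_summary(results: list[SharedAsvResult]) -> pd.DataFrame:
    """Last no-contact day per subject with a nonempty shared set.

    Subjects whose entire no-contact phase has empty shared sets report
    "none" — the shedding signal never outlived the contact phase.
    """
    by_subject: dict[str, Optional[int]] = {}
    for r in results:
        by_subject.setdefault(r.pair.subject, None)
        if r.pair.phase != "no_contact":
            continue
        if r.shared_proportion > 0:
            prev = by_subject[r.pair.subject]
            by_subject[r.pair.subject] = r.pair.day if prev is None else max(prev, r.pair.day)
    rows = [
        {"subject": s, "last_detection_day": "none" if d is None else d}
        for s, d in sorted(by_subject.items())
    ]
    return pd.DataFrame(rows, columns=["subject", "last_detection_day"])


def shared_taxa_breakdown(
    result: SharedAsvResult, tax: TaxonomyMap
) -> dict[str, float]:
    """Split a pair's shared proportion by genus.

    Shared ASVs with no taxonomy record or no named genus fall into the
    "Unassigned" bucket; contributions sum to the pair's shared proportion.
    """
    out: dict[str, float] = {}
    for fid in sorted(result.shared_feature_ids):
        genus = tax.genus_of(fid, default="")
        if not genus:
            genus = "Unassigned"
        out[genus] = out.get(genus, 0.0) + 100.0 * result.sink_abundance[fid]
    return out


def breakdown_frame(
    results: list[SharedAsvResult], tax: TaxonomyMap
) -> pd.DataFrame:
    rows = []
    for r in results:
        for genus, pct in sorted(shared_taxa_breakdown(r, tax).items()):
            rows.append(
                {
                    "subject": r.pair.subject,
                    "day": r.pair.day,
                    "timepoint": r.pair.timepoint_label,
                    "genus": genus,
                    "contribution_percent": pct,
                }
            )
    return pd.DataFrame(
        rows, columns=["subject", "day", "timepoint", "genus", "contribution_percent"]
    )


def write_timecourse_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
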