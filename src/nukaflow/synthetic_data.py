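"""Study-shaped synthetic data with known ground truth.

Emulates the transmission study's design: each subject maintains a rice-bran
bed whose community is near-constant and dominated by one lactic-acid
bacterium (~69-79% of reads), while their palm-skin community is
subject-specific and, by default, disjoint from the bed's feature universe.
Daily stirring transfers a fraction *f* of the bed community onto the palm;
transferred material decays exponentially (half-life in days), and every
sample is sequenced as a multinomial draw at a realistic read depth
(13 000-42 000 by default).

The generator is the test bed for the whole pipeline: it returns the exact
(pre-sampling) community profiles and the closed-form expected shared-ASV
proportion at every timepoint, so recovery tests can compare pipeline output
against analytic truth.

Model choices (documented, deliberately simple):

* transfer is one mixing event per stir; each contact-phase sample reflects
  only the most recent stir, with the 6 h stir-to-swab gap absorbed as a
  0.25-day shedding step.  Residue from earlier stirs is assumed fully shed
  (an excellent approximation when the half-life is much shorter than the
  3-day stir-to-sample interval);
* the day-0 pre-interaction sample ("0") has no transfer at all; the
  6-hours-post sample ("0'") carries the first deposit;
* the no-contact phase decays the day-14 deposit: elapsed time for a skin
  sample on day d >= 15 is (d - 14) + 0.25 days since the last stir.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .tables_io import (
    FeatureTable,
    Lineage,
    SampleMetadata,
    SampleMetadataSet,
    TaxonomyMap,
)

SOURCE_DAYS = (0, 3, 6, 9, 12, 14)
SKIN_TIMEPOINTS = ("0", "0'", "3", "6", "9", "12", "14", "15", "18", "21", "24", "27", "29")

DOMINANT_GENUS = "Loigolactibacillus"
OVERLAP_GENUS = "Allorhizobium-Neorhizobium-Pararhizobium-Rhizobium"
SOURCE_GENERA = (
    "Pantoea", "Xanthomonas", "Staphylococcus", "Weissella",
    "Lactiplantibacillus", "Leuconostoc", "Halomonas", "Pediococcus",
)
SINK_GENERA = (
    "Cutibacterium", "Pseudomonas", "Staphylococcus", "Acinetobacter",
    "Kocuria", "Corynebacterium", "Streptococcus", "Micrococcus",
)

#: organelle / unassigned reads present in every raw sample when
#: ``contaminant_fraction`` > 0; the preprocessing filter removes all four
CONTAMINANT_IDS = (
    "contam_chloroplast", "contam_mitochondria",
    "contam_norecord", "contam_unassigned",
)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the generator.

    ``dominant_mass=None`` draws each subject's dominant-ASV share uniformly
    in [0.69, 0.79], the range the bed communities occupy; pass a float to
    pin it.  ``overlap_abundance`` > 0 plants one feature in both universes
    at that relative abundance, modelling ambient background sharing (the
    pre-interaction signal one subject can show); the default is fully
    disjoint universes so every detection is attributable to transfer.
    """

    n_subjects: int = 3
    n_source_asvs: int = 60
    n_sink_asvs: int = 80
    dominant_mass: Optional[float] = None
    dominant_mass_range: tuple[float, float] = (0.69, 0.79)
    source_noise_concentration: float = 500.0
    transfer_fraction: float = 0.10
    shedding_half_life: float = 0.5
    depth_range: tuple[int, int] = (13_000, 42_000)
    stir_to_swab_days: float = 0.25
    overlap_abundance: float = 0.0
    contaminant_fraction: float = 0.0
    threshold: float = 0.01
    master_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.transfer_fraction < 1):
            raise ValueError("transfer_fraction must lie in [0, 1)")
        if self.dominant_mass is not None and not (0 < self.dominant_mass < 1):
            raise ValueError("dominant_mass must lie in (0, 1)")
        if self.shedding_half_life <= 0:
            raise ValueError("shedding_half_life must be positive")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must be positive and ordered")
        if not (0 <= self.overlap_abundance < 1):
            raise ValueError("overlap_abundance must lie in [0, 1)")
        if not (0 <= self.contaminant_fraction < 1):
            raise ValueError("contaminant_fraction must lie in [0, 1)")


@dataclass
class SubjectTruth:
    subject: str
    dominant_mass: float
    transferred_feature_ids: list[str]
    #: timepoint label -> {"f_effective", "expected_shared_proportion_percent",
    #:                     "expected_shared_ids"}
    expected: dict = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    """Ground truth: transfer parameters and analytic expectations."""

    transfer_fraction: float
    shedding_half_life: float
    threshold: float
    master_seed: int
    subjects: dict[str, SubjectTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "transfer_fraction": self.transfer_fraction,
            "shedding_half_life": self.shedding_half_life,
            "threshold": self.threshold,
            "master_seed": self.master_seed,
            "subjects": {s: asdict(t) for s, t in self.subjects.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def _rng(master_seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic substream: one master seed, structured spawn keys."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=spawn_key)
    )


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _source_feature_ids(subject: str, n: int) -> list[str]:
    return [f"sub{subject}_src{i:03d}" for i in range(n)]


def _sink_feature_ids(subject: str, n: int) -> list[str]:
    return [f"sub{subject}_skn{i:03d}" for i in range(n)]


def _base_source_profile(
    params: SimulationParams, subject_index: int
) -> tuple[pd.Series, float]:
    """Dominant ASV at its mass, optional overlap ASV, Dirichlet remainder."""
    subject = str(subject_index + 1)
    rng = _rng(params.master_seed, subject_index, 0)
    if params.dominant_mass is None:
        lo, hi = params.dominant_mass_range
        dm = float(rng.uniform(lo, hi))
    else:
        dm = params.dominant_mass
    ids = _source_feature_ids(subject, params.n_source_asvs)
    values = np.zeros(len(ids))
    values[0] = dm
    rest_mass = 1.0 - dm
    start = 1
    if params.overlap_abundance > 0:
        values[1] = params.overlap_abundance
        rest_mass -= params.overlap_abundance
        start = 2
    tail = rng.dirichlet(np.ones(len(ids) - start))
    values[start:] = rest_mass * tail
    return pd.Series(values, index=ids), dm


def simulate_source_series(
    params: SimulationParams, subject_index: int
) -> tuple[FeatureTable, dict[int, pd.Series], float]:
    """One subject's bed community across the stirring schedule.

    Returns the sampled count table (one column per bed sampling day), the
    exact per-day relative profiles, and the dominant-ASV mass used.  With
    ``source_noise_concentration=inf`` every day shares the base profile
    exactly (the perfectly conservative limit).
    """
    subject = str(subject_index + 1)
    base, dm = _base_source_profile(params, subject_index)
    profiles: dict[int, pd.Series] = {}
    columns: dict[str, np.ndarray] = {}
    for di, day in enumerate(SOURCE_DAYS):
        if np.isinf(params.source_noise_concentration):
            profile = base.copy()
        else:
            rng = _rng(params.master_seed, subject_index, 1, di)
            alpha = params.source_noise_concentration * base.to_numpy()
            profile = pd.Series(rng.dirichlet(alpha), index=base.index)
        profiles[day] = profile
        rng_counts = _rng(params.master_seed, subject_index, 3, di)
        depth = int(rng_counts.integers(params.depth_range[0], params.depth_range[1] + 1))
        draw = _with_contaminants(profile, params)
        columns[f"sub{subject}_nuka_d{day:02d}"] = pd.Series(
            rng_counts.multinomial(depth, draw.to_numpy()), index=draw.index
        )
    df = pd.DataFrame(columns, dtype=np.int64).fillna(0).astype(np.int64)
    df.index.name = "feature_id"
    return FeatureTable(df), profiles, dm


def simulate_sink_baseline(params: SimulationParams, subject_index: int) -> pd.Series:
    """Subject-specific skin community over the sink feature universe.

    Disjoint from the bed's features unless ``overlap_abundance`` > 0, in
    which case the bed's designated overlap ASV is planted at that abundance.
    """
    subject = str(subject_index + 1)
    rng = _rng(params.master_seed, subject_index, 2)
    ids = _sink_feature_ids(subject, params.n_sink_asvs)
    values = rng.dirichlet(np.ones(len(ids)))
    profile = pd.Series(values, index=ids)
    if params.overlap_abundance > 0:
        overlap_id = _source_feature_ids(subject, 2)[1]
        profile = profile * (1.0 - params.overlap_abundance)
        profile[overlap_id] = params.overlap_abundance
    return profile


def apply_shedding(f: float, elapsed: float, half_life: float) -> float:
    """Effective transfer fraction after ``elapsed`` days of exponential loss."""
    if elapsed < 0:
        raise ValueError("elapsed must be non-negative")
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    return f * 2.0 ** (-elapsed / half_life)


def apply_transfer(
    sink_profile: pd.Series, source_profile: pd.Series, f: float
) -> pd.Series:
    """Mix a source deposit into the sink: (1-f)*sink + f*source.

    Profiles are aligned on the union of their features (missing = 0); the
    result sums to 1.
    """
    if not (0 <= f < 1):
        raise ValueError("f must lie in [0, 1)")
    union = sink_profile.index.union(source_profile.index)
    sink = sink_profile.reindex(union, fill_value=0.0)
    source = source_profile.reindex(union, fill_value=0.0)
    return (1.0 - f) * sink + f * source


def _with_contaminants(profile: pd.Series, params: SimulationParams) -> pd.Series:
    """Dilute a clean profile with a uniform organelle/unassigned component.

    The filter removes the contaminant reads again downstream, so in
    expectation the filtered relative abundances equal the clean profile.
    """
    c = params.contaminant_fraction
    if c <= 0:
        return profile
    contam = pd.Series(c / len(CONTAMINANT_IDS), index=list(CONTAMINANT_IDS))
    return pd.concat([(1.0 - c) * profile, contam])


def _skin_day(label: str) -> int:
    return int(label.rstrip("'"))


def _effective_fraction(params: SimulationParams, label: str) -> float:
    """Transfer fraction present in the skin sample at a given timepoint."""
    day = _skin_day(label)
    if label == "0":  # pre-interaction: no deposit yet
        return 0.0
    if day <= 14:
        elapsed = params.stir_to_swab_days
    else:
        elapsed = (day - 14) + params.stir_to_swab_days
    return apply_shedding(params.transfer_fraction, elapsed, params.shedding_half_life)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

_FILLER = ("d__Bacteria", "p__Firmicutes", "c__Bacilli", "o__Lactobacillales",
           "f__Lactobacillaceae")


def _lineage_for(genus: str) -> Lineage:
    return Lineage(ranks=_FILLER + (f"g__{genus}", ""))


def _genusless_lineage(family: str) -> Lineage:
    return Lineage(
        ranks=("d__Bacteria", "p__Proteobacteria", "c__Alphaproteobacteria",
               "o__Rhizobiales", f"f__{family}", "", "")
    )


def _build_taxonomy(params: SimulationParams) -> TaxonomyMap:
    """Assign genera: the dominant bed ASV gets its distinctive LAB genus,
    the optional overlap ASV the rhizobium group; every 7th other feature is
    left genus-less to exercise the Unassigned/Unclassified paths."""
    assignments: dict[str, Lineage] = {}
    for si in range(params.n_subjects):
        subject = str(si + 1)
        src = _source_feature_ids(subject, params.n_source_asvs)
        snk = _sink_feature_ids(subject, params.n_sink_asvs)
        for i, fid in enumerate(src):
            if i == 0:
                assignments[fid] = _lineage_for(DOMINANT_GENUS)
            elif i == 1:
                assignments[fid] = _lineage_for(OVERLAP_GENUS)
            elif i % 7 == 3:
                assignments[fid] = _genusless_lineage("Rhizobiaceae")
            else:
                assignments[fid] = _lineage_for(SOURCE_GENERA[i % len(SOURCE_GENERA)])
        for i, fid in enumerate(snk):
            if i % 7 == 3:
                assignments[fid] = _genusless_lineage("Beijerinckiaceae")
            else:
                assignments[fid] = _lineage_for(SINK_GENERA[i % len(SINK_GENERA)])
    if params.contaminant_fraction > 0:
        assignments["contam_chloroplast"] = Lineage(
            ("d__Bacteria", "p__Cyanobacteria", "c__Cyanobacteriia",
             "o__Chloroplast", "", "", "")
        )
        assignments["contam_mitochondria"] = Lineage(
            ("d__Bacteria", "p__Proteobacteria", "c__Alphaproteobacteria",
             "o__Rickettsiales", "f__Mitochondria", "", "")
        )
        assignments["contam_unassigned"] = Lineage(("Unassigned",))
        # contam_norecord deliberately has no taxonomy entry
    return TaxonomyMap(assignments)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def generate_study(
    params: SimulationParams = SimulationParams(),
) -> tuple[FeatureTable, SampleMetadataSet, TaxonomyMap, SyntheticTruth]:
    """Generate the full study-shaped dataset plus its ground truth.

    Deterministic given ``params.master_seed``: the same parameters produce a
    bit-identical dataset.
    """
    truth = SyntheticTruth(
        transfer_fraction=params.transfer_fraction,
        shedding_half_life=params.shedding_half_life,
        threshold=params.threshold,
        master_seed=params.master_seed,
    )
    all_feature_ids: list[str] = []
    for si in range(params.n_subjects):
        subject = str(si + 1)
        all_feature_ids += _source_feature_ids(subject, params.n_source_asvs)
        all_feature_ids += _sink_feature_ids(subject, params.n_sink_asvs)
    if params.contaminant_fraction > 0:
        all_feature_ids += list(CONTAMINANT_IDS)

    columns: dict[str, pd.Series] = {}
    meta_records: list[SampleMetadata] = []

    for si in range(params.n_subjects):
        subject = str(si + 1)
        source_table, source_profiles, dm = simulate_source_series(params, si)
        baseline = simulate_sink_baseline(params, si)
        subj_truth = SubjectTruth(
            subject=subject,
            dominant_mass=dm,
            transferred_feature_ids=list(source_profiles[0].index),
        )
        for sid in source_table.sample_ids:
            day = int(sid.rsplit("_d", 1)[1])
            columns[sid] = source_table.sample_counts(sid)
            meta_records.append(
                SampleMetadata(
                    sample_id=sid,
                    subject=subject,
                    substrate="nukadoko",
                    day=day,
                    timepoint_label=str(day),
                    phase="contact" if day <= 14 else "no_contact",
                )
            )
        for ti, label in enumerate(SKIN_TIMEPOINTS):
            day = _skin_day(label)
            f_t = _effective_fraction(params, label)
            source_day = day if day <= 14 else 14
            source_profile = source_profiles[source_day]
            mixed = apply_transfer(baseline, source_profile, f_t)
            rng = _rng(params.master_seed, si, 4, ti)
            depth = int(rng.integers(params.depth_range[0], params.depth_range[1] + 1))
            draw = _with_contaminants(mixed, params)
            counts = rng.multinomial(depth, draw.to_numpy())
            sample_id = "sub{}_skin_{}".format(subject, label.replace("'", "p"))
            columns[sample_id] = pd.Series(counts, index=draw.index)
            meta_records.append(
                SampleMetadata(
                    sample_id=sample_id,
                    subject=subject,
                    substrate="skin",
                    day=day,
                    timepoint_label=label,
                    phase="contact" if day <= 14 else "no_contact",
                )
            )
            shared_ids = sorted(
                fid
                for fid in source_profile.index
                if source_profile[fid] > params.threshold
                and mixed.get(fid, 0.0) > params.threshold
            )
            subj_truth.expected[label] = {
                "f_effective": f_t,
                "expected_shared_ids": shared_ids,
                "expected_shared_sink_abundance": {
                    fid: float(mixed[fid]) for fid in shared_ids
                },
                "expected_shared_proportion_percent": float(
                    100.0 * sum(mixed[fid] for fid in shared_ids)
                ),
            }
        truth.subjects[subject] = subj_truth

    df = pd.DataFrame(0, index=pd.Index(all_feature_ids, name="feature_id"),
                      columns=list(columns), dtype=np.int64)
    for sid, series in columns.items():
        df.loc[series.index, sid] = series.astype(np.int64)
    table = FeatureTable(df)
    meta = SampleMetadataSet(meta_records).sorted()
    tax = _build_taxonomy(params)
    return table, meta, tax, truth
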