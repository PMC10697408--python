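import numpy as np
import pandas as pd
import pytest

from nukaflow.errors import AlignmentError
from nukaflow.preprocess import filter_organelle_unassigned
from nukaflow.shared_asv import (
    PairingScheme,
    SharedAsvResult,
    SamplePair,
    breakdown_frame,
    build_pairs,
    find_shared_asvs,
    persistence_summary,
    shared_proportion,
    shared_taxa_breakdown,
    shared_timecourse,
    timecourse_frame,
)
from nukaflow.synthetic_data import SimulationParams, generate_study
from nukaflow.tables_io import (
    Lineage,
    SampleMetadata,
    SampleMetadataSet,
    TaxonomyMap,
    to_relative,
)


def brute_force_shared(source: pd.Series, sink: pd.Series, threshold: float):
    """Independent oracle: per-feature double scan."""
    out = set()
    for f in source.index:
        if source[f] > threshold and sink[f] > threshold:
            out.add(f)
    return frozenset(out)


class TestBuildPairs:
    def test_study_layout_yields_13_pairs_per_subject(self, study_layout_meta):
        pairs, unpaired = build_pairs(study_layout_meta, PairingScheme(source_day=14))
        assert unpaired == []
        for subject in ("1", "2", "3"):
            mine = [p for p in pairs if p.subject == subject]
            assert len(mine) == 13
            contact = [p for p in mine if p.phase == "contact"]
            no_contact = [p for p in mine if p.phase == "no_contact"]
            assert len(contact) == 7  # 0, 0', 3, 6, 9, 12, 14
            assert {p.timepoint_label for p in contact} == {
                "0", "0'", "3", "6", "9", "12", "14"
            }
            assert len(no_contact) == 6

    def test_no_contact_skin_maps_to_source_day_14(self, study_layout_meta):
        pairs, _ = build_pairs(study_layout_meta, PairingScheme(source_day=14))
        day15 = next(p for p in pairs if p.subject == "1" and p.day == 15)
        assert day15.source_sample_id == "sub1_nuka_d14"
        for p in pairs:
            if p.phase == "no_contact":
                assert p.source_sample_id.endswith("d14")

    def test_subjects_always_match_within_pairs(self, study_layout_meta):
        pairs, _ = build_pairs(study_layout_meta)
        for p in pairs:
            assert p.source_sample_id.startswith(f"sub{p.subject}_")
            assert p.sink_sample_id.startswith(f"sub{p.subject}_")

    def test_missing_source_day_reported_unpaired(self):
        records = [
            SampleMetadata("nuka0", "1", "nukadoko", 0, "0", "contact"),
            SampleMetadata("skin0", "1", "skin", 0, "0", "contact"),
            SampleMetadata("skin3", "1", "skin", 3, "3", "contact"),
        ]
        pairs, unpaired = build_pairs(SampleMetadataSet(records))
        assert [p.sink_sample_id for p in pairs] == ["skin0"]
        assert len(unpaired) == 1
        assert unpaired[0].sink_sample_id == "skin3"
        assert "day 3" in unpaired[0].reason

    def test_alternate_source_day(self, study_layout_meta):
        pairs, unpaired = build_pairs(study_layout_meta, PairingScheme(source_day=12))
        for p in pairs:
            if p.phase == "no_contact":
                assert p.source_sample_id.endswith("d12")


class TestFindSharedAsvs:
    def test_spec_example_only_mutually_abundant(self):
        universe = ["A", "B", "C", "D"]
        source = pd.Series({"A": 0.70, "B": 0.05, "C": 0.002, "D": 0.248})[universe]
        sink = pd.Series({"A": 0.03, "B": 0.005, "C": 0.065, "D": 0.90})[universe]
        # A passes both; B fails sink; C fails source; D passes both here
        assert find_shared_asvs(source, sink, 0.01) == frozenset({"A", "D"})
        sink2 = sink.copy()
        sink2["D"] = 0.0
        sink2["C"] += 0.90
        assert find_shared_asvs(source, sink2, 0.01) == frozenset({"A"})

    def test_threshold_zero_gives_support_intersection(self):
        source = pd.Series({"A": 0.5, "B": 0.5, "C": 0.0})
        sink = pd.Series({"A": 0.9, "B": 0.0, "C": 0.1})
        assert find_shared_asvs(source, sink, 0.0) == frozenset({"A"})

    def test_identical_vectors_share_everything_above_threshold(self):
        v = pd.Series({"A": 0.6, "B": 0.3, "C": 0.1, "D": 0.0})
        assert find_shared_asvs(v, v, 0.25) == frozenset({"A", "B"})

    def test_strict_inequality_at_exact_threshold(self):
        v = pd.Series({"A": 0.01, "B": 0.99})
        assert "A" not in find_shared_asvs(v, v, 0.01)
        assert "A" in find_shared_asvs(v, v, 0.01, strict=False)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(AlignmentError):
            find_shared_asvs(pd.Series({"A": 1.0}), pd.Series({"B": 1.0}))

    def test_equals_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            k = int(rng.integers(20, 201))
            ids = [f"F{i}" for i in range(k)]
            source = pd.Series(rng.dirichlet(np.full(k, 0.3)), index=ids)
            sink = pd.Series(rng.dirichlet(np.full(k, 0.3)), index=ids)
            thr = float(rng.choice([0.001, 0.01, 0.05]))
            assert find_shared_asvs(source, sink, thr) == brute_force_shared(
                source, sink, thr
            )

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(23)
        k = 50
        ids = [f"F{i}" for i in range(k)]
        source = pd.Series(rng.dirichlet(np.ones(k)), index=ids)
        sink = pd.Series(rng.dirichlet(np.ones(k)), index=ids)
        prev = None
        prev_prop = None
        for thr in (0.0, 0.005, 0.01, 0.02, 0.05, 0.2):
            shared = find_shared_asvs(source, sink, thr)
            prop = shared_proportion(sink, shared)
            if prev is not None:
                assert shared <= prev
                assert prop <= prev_prop + 1e-12
            prev, prev_prop = shared, prop

    def test_membership_symmetric_proportion_is_not(self):
        rng = np.random.default_rng(29)
        k = 40
        ids = [f"F{i}" for i in range(k)]
        source = pd.Series(rng.dirichlet(np.ones(k) * 0.2), index=ids)
        sink = pd.Series(rng.dirichlet(np.ones(k) * 0.2), index=ids)
        fwd = find_shared_asvs(source, sink, 0.01)
        rev = find_shared_asvs(sink, source, 0.01)
        assert fwd == rev
        if fwd:
            assert shared_proportion(sink, fwd) != pytest.approx(
                shared_proportion(source, fwd)
            )

    def test_disjoint_supports_never_share(self):
        source = pd.Series({"A": 0.5, "B": 0.5, "C": 0.0, "D": 0.0})
        sink = pd.Series({"A": 0.0, "B": 0.0, "C": 0.5, "D": 0.5})
        for thr in (0.001, 0.01, 0.3):
            assert find_shared_asvs(source, sink, thr) == frozenset()


class TestSharedProportion:
    def test_single_feature_percent(self):
        sink = pd.Series({"A": 0.03, "B": 0.97})
        assert shared_proportion(sink, {"A"}) == pytest.approx(3.0)

    def test_empty_set_is_zero(self):
        assert shared_proportion(pd.Series({"A": 1.0}), set()) == 0.0

    def test_all_features_is_hundred(self):
        sink = pd.Series({"A": 0.25, "B": 0.75})
        assert shared_proportion(sink, {"A", "B"}) == pytest.approx(100.0, abs=1e-7)


def _run_timecourse(params):
    table, meta, tax, truth = generate_study(params)
    filtered, _ = filter_organelle_unassigned(table, tax)
    rel = to_relative(filtered)
    results, unpaired = shared_timecourse(rel, meta, threshold=params.threshold)
    return results, unpaired, truth


class TestTimecourse:
    def test_null_transfer_gives_all_zero_proportions(self):
        results, unpaired, _ = _run_timecourse(
            SimulationParams(transfer_fraction=0.0, master_seed=3)
        )
        assert unpaired == []
        assert len(results) == 39
        assert all(r.shared_proportion == 0.0 for r in results)

    def test_contact_day_proportion_near_analytic_expectation(self):
        """f=0.10 of a source ASV at known abundance should land within
        multinomial tolerance of the analytic mixture expectation."""
        params = SimulationParams(
            transfer_fraction=0.10,
            dominant_mass=0.75,
            shedding_half_life=0.5,
            depth_range=(30_000, 30_000),
            master_seed=5,
        )
        results, _, truth = _run_timecourse(params)
        for r in results:
            if r.pair.phase != "contact":
                continue
            expected = truth.subjects[r.pair.subject].expected[
                r.pair.timepoint_label
            ]["expected_shared_proportion_percent"]
            p = expected / 100.0
            se = 100.0 * np.sqrt(max(p * (1 - p), 1e-9) / 30_000)
            assert abs(r.shared_proportion - expected) < 5 * se + 0.05

    def test_frame_keeps_unpaired_as_gaps(self):
        records = [
            SampleMetadata("nuka0", "1", "nukadoko", 0, "0", "contact"),
            SampleMetadata("skin0", "1", "skin", 0, "0", "contact"),
            SampleMetadata("skin3", "1", "skin", 3, "3", "contact"),
        ]
        meta = SampleMetadataSet(records)
        df = pd.DataFrame(
            {"nuka0": [90, 10], "skin0": [50, 50], "skin3": [20, 80]},
            index=["A", "B"],
        )
        from nukaflow.tables_io import FeatureTable

        rel = to_relative(FeatureTable(df))
        results, unpaired = shared_timecourse(rel, meta)
        frame = timecourse_frame(results, unpaired)
        assert len(frame) == 2
        gap = frame[frame["sink_sample"] == "skin3"].iloc[0]
        assert gap["source_sample"] == ""
        assert np.isnan(gap["shared_proportion_percent"])


class TestPersistence:
    def _result(self, subject, day, label, phase, proportion):
        pair = SamplePair(subject, f"src{day}", f"snk{day}", day, label, phase)
        shared = frozenset({"X"}) if proportion > 0 else frozenset()
        return SharedAsvResult(
            pair=pair,
            threshold=0.01,
            shared_feature_ids=shared,
            sink_abundance={"X": proportion / 100.0} if proportion > 0 else {},
        )

    def test_last_nonzero_no_contact_day(self):
        results = [
            self._result("1", 14, "14", "contact", 5.0),
            self._result("1", 15, "15", "no_contact", 0.5),
            self._result("1", 18, "18", "no_contact", 0.0),
        ]
        out = persistence_summary(results)
        assert out.set_index("subject").loc["1", "last_detection_day"] == 15

    def test_all_zero_no_contact_reports_none(self):
        results = [
            self._result("2", 15, "15", "no_contact", 0.0),
            self._result("2", 18, "18", "no_contact", 0.0),
        ]
        out = persistence_summary(results)
        assert out.set_index("subject").loc["2", "last_detection_day"] == "none"

    def test_contact_phase_detection_does_not_count(self):
        results = [self._result("3", 14, "14", "contact", 9.0)]
        out = persistence_summary(results)
        assert out.set_index("subject").loc["3", "last_detection_day"] == "none"


class TestBreakdown:
    def _result(self, abundances):
        pair = SamplePair("1", "src", "snk", 3, "3", "contact")
        return SharedAsvResult(
            pair=pair,
            threshold=0.01,
            shared_feature_ids=frozenset(abundances),
            sink_abundance=dict(abundances),
        )

    def test_same_genus_contributions_add(self):
        tax = TaxonomyMap(
            {
                "A": Lineage(("d__B", "p", "c", "o", "f", "g__Loigolactobacillus")),
                "B": Lineage(("d__B", "p", "c", "o", "f", "g__Loigolactobacillus")),
            }
        )
        result = self._result({"A": 0.01, "B": 0.02})
        out = shared_taxa_breakdown(result, tax)
        assert out == {"Loigolactobacillus": pytest.approx(3.0)}

    def test_missing_taxonomy_goes_to_unassigned(self):
        result = self._result({"A": 0.05})
        out = shared_taxa_breakdown(result, TaxonomyMap({}))
        assert out == {"Unassigned": pytest.approx(5.0)}

    def test_contributions_sum_to_shared_proportion(self, default_study):
        table, meta, tax, truth = default_study
        filtered, _ = filter_organelle_unassigned(table, tax)
        rel = to_relative(filtered)
        results, _ = shared_timecourse(rel, meta)
        for r in results:
            out = shared_taxa_breakdown(r, tax)
            assert sum(out.values()) == pytest.approx(r.shared_proportion, abs=1e-9)
        frame = breakdown_frame(results, tax)
        assert set(frame.columns) == {
            "subject", "day", "timepoint", "genus", "contribution_percent",
        }
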