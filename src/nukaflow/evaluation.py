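"""Recovery experiments: run the pipeline over simulated studies and compare
against the generator's analytic ground truth.

These drivers exist so that calibration checks (null behaviour, transfer
recovery, shedding-rate recovery) are computed one way, whether invoked from
the test suite, the analysis scripts, or the acceptance script.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .preprocess import filter_organelle_unassigned
from .shared_asv import SharedAsvResult, shared_timecourse
from .synthetic_data import SimulationParams, SyntheticTruth, generate_study
from .tables_io import to_relative


def run_shared_pipeline(
    params: SimulationParams,
) -> tuple[list[SharedAsvResult], SyntheticTruth]:
    """Simulate one study and push it through filter -> relative -> shared-ASV."""
    table, meta, tax, truth = generate_study(params)
    filtered, _ = filter_organelle_unassigned(table, tax)
    rel = to_relative(filtered)
    results, _ = shared_timecourse(rel, meta, threshold=params.threshold)
    return results, truth


def contact_recovery(
    base_params: SimulationParams, seeds: list[int]
) -> pd.DataFrame:
    """Measured vs expected contact-phase shared proportions over many runs.

    One row per (seed, subject, contact timepoint) with the pipeline's
    measured proportion, the closed-form expectation, the sequencing depth's
    binomial standard error, and whether every strongly deposited ASV
    (exact post-transfer sink abundance > 1.5x the 1% threshold) was
    recovered as shared.
    """
    depth = base_params.depth_range[0]
    rows = []
    for seed in seeds:
        params = replace(base_params, master_seed=seed)
        results, truth = run_shared_pipeline(params)
        for r in results:
            if r.pair.phase != "contact":
                continue
            exp = truth.subjects[r.pair.subject].expected[r.pair.timepoint_label]
            expected = exp["expected_shared_proportion_percent"]
            p = expected / 100.0
            strong = {
                fid
                for fid, ab in exp["expected_shared_sink_abundance"].items()
                if ab > 1.5 * base_params.threshold
            }
            rows.append(
                {
                    "seed": seed,
                    "subject": r.pair.subject,
                    "timepoint": r.pair.timepoint_label,
                    "measured": r.shared_proportion,
                    "expected": expected,
                    "binomial_se": 100.0 * math.sqrt(max(p * (1 - p), 0.0) / depth),
                    "n_strong": len(strong),
                    "n_strong_detected": len(strong & set(r.shared_feature_ids)),
                }
            )
    return pd.DataFrame(rows)


def noiseless_shedding_slopes(params: SimulationParams) -> list[float]:
    """Log-linear decay slopes of the *expected* (infinite-depth) shared
    proportion over the no-contact phase, one per subject.

    With exponential shedding these equal -log(2)/half_life exactly wherever
    at least two no-contact timepoints stay above the detection threshold.
    """
    _, _, _, truth = generate_study(params)
    slopes = []
    for st in truth.subjects.values():
        days, logs = [], []
        for label, exp in st.expected.items():
            day = int(label.rstrip("'"))
            if day <= 14 or exp["expected_shared_proportion_percent"] <= 0:
                continue
            days.append(day)
            logs.append(math.log(exp["expected_shared_proportion_percent"]))
        if len(days) >= 2:
            slopes.append(float(np.polyfit(days, logs, 1)[0]))
    return slopes


def measured_shedding_slopes(
    base_params: SimulationParams, seeds: list[int], min_points: int = 3
) -> list[float]:
    """Finite-depth decay slopes from the pipeline's measured proportions."""
    slopes = []
    for seed in seeds:
        params = replace(base_params, master_seed=seed)
        results, _ = run_shared_pipeline(params)
        per_subject: dict[str, list[tuple[int, float]]] = {}
        for r in results:
            if r.pair.phase != "no_contact" or r.shared_proportion <= 0:
                continue
            per_subject.setdefault(r.pair.subject, []).append(
                (r.pair.day, r.shared_proportion)
            )
        for points in per_subject.values():
            if len(points) < min_points:
                continue
            days = [d for d, _ in points]
            logs = [math.log(p) for _, p in points]
            slopes.append(float(np.polyfit(days, logs, 1)[0]))
    return slopes


def bootstrap_ci(
    values: list[float], n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of ``values``."""
    rng = np.random.default_rng(seed)
    arr = np.asarray(values)
    means = rng.choice(arr, size=(n_boot, arr.size), replace=True).mean(axis=1)
    alpha = (1 - level) / 2
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha))
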