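"""Alpha diversity and rarefaction.

Shannon index (base 2 by default), observed-feature counts, exact
without-replacement subsampling, and mean rarefaction curves over a read-depth
grid (the study design sweeps depths 0..10 000).

Rarefaction draws use ``numpy``'s multivariate hypergeometric sampler, which
is an exact draw of ``depth`` reads without replacement.  Randomness is
derived from a single master seed through per-(sample, depth, iteration)
``SeedSequence`` substreams, so curves are bitwise reproducible regardless of
evaluation order.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

METRICS = ("shannon", "observed_features")


def shannon(abundances, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i over positive entries.

    ``abundances`` may be raw counts or proportions; they are normalized to
    sum to one.  An all-zero vector has no defined diversity.
    """
    if base <= 1:
        raise ValueError("log base must be > 1")
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed_features(counts) -> int:
    """Number of features with strictly positive count."""
    x = np.asarray(counts)
    return int((x > 0).sum())


def rarefy(counts, depth: int, seed) -> np.ndarray:
    """Subsample ``depth`` reads without replacement from a count vector.

    The result sums to ``depth`` and never exceeds ``counts`` elementwise.
    ``seed`` may be an int or a ``numpy`` Generator/SeedSequence.
    """
    x = np.asarray(counts, dtype=np.int64)
    if depth < 1:
        raise ValueError("depth must be positive")
    total = int(x.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(x, depth)


@dataclass(frozen=True)
class RarefactionCurve:
    """Mean metric value per sample across a depth grid.

    ``values`` is samples x depths; a cell is NaN where the depth exceeds the
    sample's total read count (no extrapolation).  Depth 0 is reported as 0
    by convention so curves start at the origin.
    """

    metric: str
    depths: tuple[int, ...]
    values: pd.DataFrame
    iterations: int
    seed: int

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.depths, self.depths[1:])):
            raise ValueError("depths must be strictly increasing")

    def to_long(self) -> pd.DataFrame:
        long = (
            self.values.reset_index(names="sample-id")
            .melt(id_vars="sample-id", var_name="depth", value_name="mean_value")
            .dropna(subset=["mean_value"])
        )
        long["metric"] = self.metric
        long["iterations"] = self.iterations
        long["seed"] = self.seed
        return long.sort_values(["sample-id", "depth"], kind="stable").reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def _metric_fn(metric: str):
    if metric == "shannon":
        return shannon
    if metric == "observed_features":
        return lambda v: float(observed_features(v))
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def rarefaction_curve(
    table,
    metric: str = "shannon",
    max_depth: int = 10_000,
    step: int = 500,
    iterations: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Mean rarefaction curve for every sample of a feature table.

    At each depth d in {0, step, 2*step, ... <= max_depth} the metric is
    averaged over ``iterations`` independent without-replacement draws.
    Depths larger than a sample's total are left absent for that sample.
    """
    if step < 1 or iterations < 1:
        raise ValueError("step and iterations must be >= 1")
    fn = _metric_fn(metric)
    depths = tuple(range(0, max_depth + 1, step))
    totals = table.sample_totals()
    out = pd.DataFrame(
        np.nan, index=pd.Index(table.sample_ids, name="sample-id"), columns=list(depths)
    )
    for si, sid in enumerate(table.sample_ids):
        counts = table.sample_counts(sid).to_numpy()
        total = int(totals[sid])
        for di, depth in enumerate(depths):
            if depth == 0:
                out.loc[sid, depth] = 0.0
                continue
            if depth > total:
                continue
            acc = 0.0
            for it in range(iterations):
                ss = np.random.SeedSequence(entropy=seed, spawn_key=(si, di, it))
                acc += fn(rarefy(counts, depth, np.random.default_rng(ss)))
            out.loc[sid, depth] = acc / iterations
    return RarefactionCurve(
        metric=metric, depths=depths, values=out, iterations=iterations, seed=seed
    )


def alpha_diversity_table(table, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon index and observed features, one row per sample."""
    rows = []
    for sid in table.sample_ids:
        counts = table.sample_counts(sid).to_numpy()
        rows.append(
            {
                "sample-id": sid,
                "shannon": shannon(counts, base=base),
                "observed_features": observed_features(counts),
            }
        )
    return pd.DataFrame(rows)
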