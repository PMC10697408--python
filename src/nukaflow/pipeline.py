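"""End-to-end pipeline: config validation, stage orchestration, TSV reports.

``run_pipeline`` binds the stages — read & align, organelle/unassigned
filtering, genus composition, alpha diversity, rarefaction, shared-ASV
timecourse — into one deterministic run.  All outputs are tidy TSVs with a
provenance header comment (tool version and a config hash, never a
timestamp), so identical configs over identical inputs produce byte-identical
files.
"""
from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError, ValidationError
from . import diversity, preprocess, shared_asv, tables_io

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RarefactionSettings:
    max_depth: int = 10_000
    step: int = 500
    iterations: int = 10
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    table: str
    taxonomy: str
    metadata: str
    out_dir: str = "pipeline_out"
    threshold: float = 0.01
    source_day: int = 14
    top_n: int = 15
    table_dialect: str = "plain"
    rarefaction: RarefactionSettings = field(default_factory=RarefactionSettings)
    provenance: str = ""

    def __post_init__(self):
        if not (0 < self.threshold < 1):
            raise ValidationError(
                f"threshold must lie in (0, 1), got {self.threshold}"
            )
        if self.top_n < 1:
            raise ValidationError(f"top_n must be >= 1, got {self.top_n}")
        if self.source_day < 0:
            raise ValidationError("source_day must be non-negative")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant fields (the output location is not
        part of the analysis, so moving a run does not change its hash)."""
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


_KNOWN_KEYS = {
    "table", "taxonomy", "metadata", "out_dir", "threshold", "source_day",
    "top_n", "table_dialect", "rarefaction", "provenance",
}
_RAREFACTION_KEYS = {"max_depth", "step", "iterations", "seed"}


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config.

    Unknown keys are rejected with a closest-match suggestion (typo safety);
    ranges are checked; defaults fill anything omitted.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    for key in raw:
        if key not in _KNOWN_KEYS:
            hint = difflib.get_close_matches(key, _KNOWN_KEYS, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValidationError(f"{path}: unknown config key {key!r}{suffix}")
    for required in ("table", "taxonomy", "metadata"):
        if required not in raw:
            raise ValidationError(f"{path}: missing required key {required!r}")
    rare_raw = raw.pop("rarefaction", {}) or {}
    for key in rare_raw:
        if key not in _RAREFACTION_KEYS:
            hint = difflib.get_close_matches(key, _RAREFACTION_KEYS, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValidationError(
                f"{path}: unknown rarefaction key {key!r}{suffix}"
            )
    try:
        rare = RarefactionSettings(**{k: int(v) for k, v in rare_raw.items()})
        return PipelineConfig(rarefaction=rare, **raw)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


@dataclass
class ReportBundle:
    """In-memory pipeline results; ``write`` emits every table as TSV."""

    config: PipelineConfig
    filter_report: preprocess.FilterReport
    genus_composition: tables_io.RelativeAbundanceTable
    top_n_composition: tables_io.RelativeAbundanceTable
    alpha: pd.DataFrame
    rarefaction_shannon: diversity.RarefactionCurve
    timecourse: pd.DataFrame
    breakdown: pd.DataFrame
    persistence: pd.DataFrame
    results: list
    unpaired: list

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = (
            f"# nukaflow {__version__} config={self.config.config_hash()}\n"
        )

        def emit(df: pd.DataFrame, name: str, index: bool = False):
            path = out / name
            with path.open("w", encoding="utf-8") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=index)

        self.filter_report.to_feature_tsv(out / "filter_report.tsv")
        self.filter_report.to_accounting_tsv(out / "filter_accounting.tsv")
        emit(self.genus_composition.data, "composition_genus.tsv", index=True)
        emit(self.top_n_composition.data, "composition_top_n.tsv", index=True)
        emit(self.alpha, "alpha_diversity.tsv")
        emit(self.rarefaction_shannon.to_long(), "rarefaction_shannon.tsv")
        emit(self.timecourse, "shared_timecourse.tsv")
        emit(self.breakdown, "shared_breakdown.tsv")
        emit(self.persistence, "persistence.tsv")
        (out / "config_echo.json").write_text(
            json.dumps(asdict(self.config), indent=2, sort_keys=True)
        )


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage label."""
    class _Ctx:
        def __enter__(self):
            logger.info("=== stage: %s ===", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, write: bool = True) -> ReportBundle:
    """Run every stage and (optionally) write the report bundle.

    Any stage failure aborts with a stage-labeled :class:`PipelineError`;
    nothing is written unless every stage succeeded, so there are no partial
    outputs to clean up.
    """
    with _stage("read"):
        table = tables_io.read_feature_table(config.table, dialect=config.table_dialect)
        meta = tables_io.read_metadata(config.metadata)
    with _stage("taxonomy"):
        tax = tables_io.read_taxonomy(config.taxonomy)
    with _stage("align"):
        dataset = tables_io.align_dataset(table, meta, tax)
        logger.info("aligned %d features x %d samples",
                    len(dataset.table.feature_ids), len(dataset.table.sample_ids))
    with _stage("filter"):
        filtered, report = preprocess.filter_organelle_unassigned(dataset.table, tax)
        logger.info("removed %d features (%d reads)", report.n_removed,
                    int(report.reads_removed.sum()))
    with _stage("relative"):
        rel = tables_io.to_relative(filtered)
    with _stage("composition"):
        genus = preprocess.collapse_genus(rel, tax)
        top = preprocess.top_n_summary(genus, n=config.top_n)
    with _stage("diversity"):
        alpha = diversity.alpha_diversity_table(filtered)
        curve = diversity.rarefaction_curve(
            filtered,
            metric="shannon",
            max_depth=config.rarefaction.max_depth,
            step=config.rarefaction.step,
            iterations=config.rarefaction.iterations,
            seed=config.rarefaction.seed,
        )
    with _stage("shared_asv"):
        scheme = shared_asv.PairingScheme(source_day=config.source_day)
        results, unpaired = shared_asv.shared_timecourse(
            rel, dataset.meta, scheme, threshold=config.threshold
        )
        logger.info("built %d pairs (%d unpaired sinks)", len(results), len(unpaired))
        timecourse = shared_asv.timecourse_frame(results, unpaired)
        breakdown = shared_asv.breakdown_frame(results, tax)
        persistence = shared_asv.persistence_summary(results)
    bundle = ReportBundle(
        config=config,
        filter_report=report,
        genus_composition=genus,
        top_n_composition=top,
        alpha=alpha,
        rarefaction_shannon=curve,
        timecourse=timecourse,
        breakdown=breakdown,
        persistence=persistence,
        results=results,
        unpaired=unpaired,
    )
    if write:
        with _stage("write"):
            bundle.write(config.out_dir)
    return bundle
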