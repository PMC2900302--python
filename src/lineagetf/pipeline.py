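"""End-to-end analysis pipeline.

Stages: annotation catalog -> transcription-factor selection -> log2
ratios versus the shared control -> per-lineage behavior classification
-> cross-lineage contingency table -> phase assignment -> gene-family
enrichment per phase -> lineage-switch candidates. All stage outputs are
written as TSV/JSON under the configured output directory together with a
machine-readable run report; a stage failure aborts the run with the
stage name and removes partial outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .behavior import (
    ADIPOCYTE,
    OSTEOBLAST,
    Behavior,
    ClassificationParams,
    candidate_switch_genes,
    classify_all,
    compute_ratios,
    count_changed,
    cross_tabulate,
)
from .catalog import (
    FamilyDefinition,
    bhlh_family,
    family_members,
    load_catalog,
    select_transcription_factors,
    symbols_by_id,
)
from .enrichment import DEFAULT_ALPHA, enrich_all, enrichment_frame
from .errors import DataError, UsageError
from .io import load_expression, load_metadata, write_behavior_calls
from .phases import (
    PhaseWindow,
    assign_phases,
    cluster_genes,
    default_windows,
    phase_report,
    standardize_profile,
)
from .simulate import (
    Dataset,
    SimulationConfig,
    build_reference_fixture,
    generate_dataset,
    write_dataset,
)

logger = logging.getLogger(__name__)

LINEAGES = (OSTEOBLAST, ADIPOCYTE)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; exactly one of ``inputs``/``simulate``.

    ``inputs`` maps 'expression' (list of TSV paths), 'metadata' and
    'annotation' to files; ``simulate`` is either the string 'fixture' or
    a :class:`SimulationConfig`.
    """

    inputs: Mapping[str, Any] | None = None
    simulate: str | SimulationConfig | None = None
    classification: ClassificationParams = ClassificationParams()
    windows: Mapping[str, Sequence[PhaseWindow]] | None = None
    families: Sequence[FamilyDefinition] = (bhlh_family(),)
    alpha: float = DEFAULT_ALPHA
    continuity_correction: bool = False
    bonferroni: bool = False
    output_dir: str | Path = "lineagetf_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise UsageError("exactly one of inputs/simulate must be configured")
        if not (0 < self.alpha < 1):
            raise UsageError("alpha must lie in (0, 1)")


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    return config_from_mapping(raw)


def config_from_mapping(raw: Mapping[str, Any]) -> PipelineConfig:
    kwargs: dict[str, Any] = {}
    if "inputs" in raw:
        kwargs["inputs"] = raw["inputs"]
    if "simulate" in raw:
        sim = raw["simulate"]
        if isinstance(sim, str):
            kwargs["simulate"] = sim
        else:
            sim = dict(sim)
            kind = sim.pop("kind", "background")
            if kind == "fixture":
                kwargs["simulate"] = "fixture"
            else:
                kwargs["simulate"] = SimulationConfig(**sim)
    if "classification" in raw:
        kwargs["classification"] = ClassificationParams(**raw["classification"])
    if "windows" in raw:
        kwargs["windows"] = {
            lineage: _windows_from_list(lineage, spec)
            for lineage, spec in raw["windows"].items()
        }
    if "families" in raw:
        kwargs["families"] = tuple(
            FamilyDefinition(
                name=f["name"],
                interpro_id=f.get("interpro_id"),
                explicit_members=frozenset(f.get("explicit_members", ())),
            )
            for f in raw["families"]
        )
    for key in ("alpha", "continuity_correction", "bonferroni", "output_dir", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


def _windows_from_list(lineage: str, spec: Sequence[Mapping[str, Any]]) -> list[PhaseWindow]:
    windows = []
    for i, w in enumerate(spec):
        windows.append(
            PhaseWindow(
                lineage=lineage,
                label=str(w["label"]),
                start_hours=float(w["start_hours"]),
                end_hours=float(w["end_hours"]),
                end_inclusive=bool(w.get("end_inclusive", i == len(spec) - 1)),
            )
        )
    return windows


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    versions: dict
    n_genes: int
    n_transcription_factors: int
    n_changed: int
    contingency: dict
    phase_counts: dict
    enrichment_significant: list
    switch_candidates: list
    output_files: list
    log_path: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_echo(config: PipelineConfig) -> dict:
    echo: dict[str, Any] = {
        "classification": dataclasses.asdict(config.classification),
        "alpha": config.alpha,
        "continuity_correction": config.continuity_correction,
        "bonferroni": config.bonferroni,
        "seed": config.seed,
        "output_dir": str(config.output_dir),
    }
    if config.simulate is not None:
        echo["simulate"] = (
            config.simulate if isinstance(config.simulate, str)
            else dataclasses.asdict(config.simulate)
        )
    else:
        echo["inputs"] = {k: str(v) for k, v in (config.inputs or {}).items()}
    return echo


class _Stage:
    """Context that names the failing stage and removes partial outputs."""

    def __init__(self, name: str, written: list[Path]):
        self.name = name
        self.written = written

    def __enter__(self):
        logger.info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is None:
            return False
        for path in self.written:
            path.unlink(missing_ok=True)
        if isinstance(exc, UsageError):
            return False
        raise DataError(f"stage {self.name!r} failed: {exc}") from exc


def _acquire_dataset(config: PipelineConfig, out_dir: Path) -> Dataset:
    if config.simulate is not None:
        if config.simulate == "fixture":
            dataset = build_reference_fixture()
        else:
            dataset = generate_dataset(config.simulate)
        write_dataset(dataset, out_dir / "dataset")
        return dataset
    inputs = dict(config.inputs or {})
    try:
        expression_paths = inputs["expression"]
        metadata_path = inputs["metadata"]
        annotation_path = inputs["annotation"]
    except KeyError as exc:
        raise UsageError(f"inputs block lacks key {exc}") from exc
    if isinstance(expression_paths, (str, Path)):
        expression_paths = [expression_paths]
    return Dataset(
        catalog=load_catalog(annotation_path),
        expression=load_expression(expression_paths),
        metadata=load_metadata(metadata_path),
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all outputs; returns the run report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lineagetf")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    written: list[Path] = []
    try:
        return _run(config, out_dir, written, log_path)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path, written: list[Path], log_path: Path) -> RunReport:
    params = config.classification
    logger.info(
        "defaults in effect: fold_threshold=%g, sd_multiplier=%g (array-wide "
        "per-time-point mean±k·sd bounds), alpha=%g, continuity_correction=%s, "
        "bonferroni=%s, seed=%d",
        params.fold_threshold, params.sd_multiplier, config.alpha,
        config.continuity_correction, config.bonferroni, config.seed,
    )

    with _Stage("load-data", written):
        dataset = _acquire_dataset(config, out_dir)
        symbols = symbols_by_id(dataset.catalog)

    with _Stage("tf-selection", written):
        tf_ids = select_transcription_factors(dataset.catalog)
        tf_ids &= set(dataset.expression.index)
        if not tf_ids:
            raise DataError("no transcription factors selected from the catalog")
        logger.info("selected %d transcription factors", len(tf_ids))

    with _Stage("ratios", written):
        tables = {
            lineage: compute_ratios(dataset.expression, dataset.metadata, lineage)
            for lineage in LINEAGES
        }

    with _Stage("classification", written):
        calls = {
            lineage: classify_all(tables[lineage], params, gene_ids=sorted(tf_ids))
            for lineage in LINEAGES
        }
        path = out_dir / "behavior_calls.tsv"
        write_behavior_calls(calls[OSTEOBLAST], calls[ADIPOCYTE], symbols, path)
        written.append(path)

    with _Stage("contingency", written):
        table = cross_tabulate(calls[OSTEOBLAST], calls[ADIPOCYTE])
        changed = count_changed(table)
        path = out_dir / "contingency.tsv"
        table.to_frame().to_csv(path, sep="\t")
        written.append(path)
        path = out_dir / "contingency.json"
        path.write_text(json.dumps(table.to_dict(), indent=1))
        written.append(path)
        logger.info("%d of %d TFs changed in at least one lineage",
                    changed, table.grand_total)

    with _Stage("switch-candidates", written):
        switch = candidate_switch_genes(calls[OSTEOBLAST], calls[ADIPOCYTE])
        path = out_dir / "switch_candidates.tsv"
        pd.DataFrame(
            {"gene_id": switch, "symbol": [symbols.get(g, g) for g in switch]}
        ).to_csv(path, sep="\t", index=False)
        written.append(path)

    with _Stage("phases", written):
        windows = {
            lineage: list((config.windows or {}).get(lineage) or default_windows(lineage))
            for lineage in LINEAGES
        }
        for lineage in LINEAGES:
            logger.info("%s windows: %s", lineage,
                        ", ".join(w.label for w in windows[lineage]))
        assignments = {
            lineage: assign_phases(calls[lineage], tables[lineage], windows[lineage])
            for lineage in LINEAGES
        }
        reports_up = {
            lineage: phase_report(assignments[lineage], windows[lineage], Behavior.UP)
            for lineage in LINEAGES
        }
        for lineage in LINEAGES:
            full = phase_report(assignments[lineage], windows[lineage])
            path = out_dir / f"phase_membership_{lineage}.tsv"
            full.to_frame(symbols).to_csv(path, sep="\t", index=False)
            written.append(path)

    with _Stage("clustering", written):
        order = _heatmap_order(tables, sorted(tf_ids))
        path = out_dir / "gene_order.txt"
        path.write_text("\n".join(order) + ("\n" if order else ""))
        written.append(path)

    with _Stage("enrichment", written):
        background = {r.gene_id for r in dataset.catalog}
        families = [(f, family_members(dataset.catalog, f)) for f in config.families]
        results = enrich_all(
            list(reports_up.values()),
            families,
            background,
            alpha=config.alpha,
            continuity_correction=config.continuity_correction,
            bonferroni=config.bonferroni,
        )
        path = out_dir / "enrichment.tsv"
        enrichment_frame(results).to_csv(path, sep="\t", index=False)
        written.append(path)

    report = RunReport(
        config=_config_echo(config),
        versions={
            "lineagetf": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        n_genes=int(dataset.expression.shape[0]),
        n_transcription_factors=len(tf_ids),
        n_changed=changed,
        contingency=table.to_dict(),
        phase_counts={
            lineage: {
                g.window.label: g.count for g in reports_up[lineage].groups
            }
            for lineage in LINEAGES
        },
        enrichment_significant=[
            {"lineage": r.lineage, "window": r.phase_label, "family": r.family_name,
             "chi2": r.chi2, "p_value": r.p_value}
            for r in results if r.significant
        ],
        switch_candidates=switch,
        output_files=sorted(p.name for p in written),
        log_path=log_path.name,
    )
    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=1))
    return report


def _heatmap_order(tables, tf_ids: list[str]) -> list[str]:
    """Deterministic heat-map gene order over concatenated z-scored profiles.

    Genes whose concatenated profile is constant (no variation in either
    lineage) are appended after the clustered genes, unclustered.
    """
    profiles = []
    flat: list[str] = []
    for gene_id in tf_ids:
        concat: list[float] = []
        for lineage in LINEAGES:
            series = standardize_profile(tables[lineage].series(gene_id))
            concat.extend(series.values)
        if np.std(concat) == 0:
            flat.append(gene_id)
        else:
            profiles.append((gene_id, concat))
    if len(profiles) < 2:
        return [g for g, _ in profiles] + flat
    frame = pd.DataFrame([v for _, v in profiles], index=[g for g, _ in profiles])
    result = cluster_genes(frame, distance="correlation", linkage="average")
    return list(result.gene_order) + flat
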