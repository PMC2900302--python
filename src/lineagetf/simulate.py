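"""Synthetic two-lineage differentiation time-course datasets.

Two generators:

* :func:`build_reference_fixture` — a deterministic, noiseless dataset
  whose 110 transcription factors realise the curated reference phase
  lists (:mod:`lineagetf.reference_lists`): each gene's osteoblast
  profile plateaus at +2.0 log2 across its labelled phase window and sits
  at baseline elsewhere; the eleven bHLH genes additionally realise their
  curated adipocyte behavior (down plateaus of -2.0 in the labelled
  cluster window, an up plateau for Clock, small +-0.2 wiggles for the
  unchanged three); osteoblast up-and-down genes carry a late -1.5 dip.
  Run through the analysis pipeline this reproduces the curated phase
  counts (46, 29, 4, 7, 24), behavior arrows and the switch-candidate
  set exactly.

* :func:`generate_dataset` — a seeded simulation adding an unchanged
  background population (per-sample offsets uniform within +-0.2 log2,
  optional Gaussian noise on the log2 scale) with a chosen number of
  bHLH-tagged background genes, and (by default) the fixture appended.

What this emulates: RMA-normalised log2 microarray intensities for one
shared uninduced control and two induced time courses, with clean
phase-structured regulation. What it does not emulate: probe-level
effects, per-gene baseline-dependent variance, correlated noise, or
partially-regulated genes near the thresholds.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference_lists as ref
from .behavior import ADIPOCYTE, OSTEOBLAST, Behavior, TimeGrid
from .catalog import BHLH_INTERPRO, GeneRecord, write_catalog
from .errors import DataError
from .io import (
    CONTROL_SAMPLE_ID,
    load_expression,
    load_metadata,
    write_expression,
    write_metadata,
)
from .phases import (
    DEFAULT_ADIPOCYTE_TIMES,
    DEFAULT_OSTEOBLAST_TIMES,
    PhaseWindow,
    default_windows,
)

#: GO accession every fixture gene carries (transcription factor activity).
FIXTURE_GO_ID = "GO:0003700"
#: Generic GO accession carried by background (non-TF) genes.
BACKGROUND_GO_ID = "GO:0008150"

_BASELINE_LOG2 = 8.0


@dataclass(frozen=True)
class FixtureSpec:
    """The curated lists the reference fixture encodes."""

    osteoblast_phase_genes: dict[str, tuple[str, ...]]
    bhlh_genes: dict[str, tuple[str, str, str, str | None]]
    bold_switch_genes: frozenset[str]

    def __post_init__(self) -> None:
        all_phase = [g for genes in self.osteoblast_phase_genes.values() for g in genes]
        if len(all_phase) != len(set(all_phase)):
            raise DataError("phase lists are not disjoint")
        if not self.bold_switch_genes <= set(self.bhlh_genes):
            raise DataError("switch genes must be bHLH genes")


def fixture_spec() -> FixtureSpec:
    """The packaged curated lists."""
    return FixtureSpec(
        osteoblast_phase_genes=dict(ref.OSTEOBLAST_PHASE_GENES),
        bhlh_genes=dict(ref.BHLH_GENES),
        bold_switch_genes=ref.BOLD_SWITCH_GENES,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    Amplitudes are log2 ratios versus the control: ``peak_amplitude_log2``
    (default 2.0, i.e. four-fold, comfortably beyond both the two-fold
    rule and the "two-fold or greater" switch criterion),
    ``updown_amplitude_log2`` for the downward excursion of up-and-down
    genes (1.5), and ``unchanged_amplitude_log2`` bounding background
    wiggle (0.2, safely sub-threshold). ``noise_sd_log2`` adds Gaussian
    noise to every measurement including the control. A fixed seed gives
    byte-identical output.
    """

    n_background_genes: int = 20000
    n_family_background: int = 100
    peak_amplitude_log2: float = 2.0
    updown_amplitude_log2: float = 1.5
    unchanged_amplitude_log2: float = 0.2
    noise_sd_log2: float = 0.0
    seed: int = 0
    include_fixture: bool = True

    def __post_init__(self) -> None:
        if self.n_background_genes < 0 or self.n_family_background < 0:
            raise DataError("gene counts must be non-negative")
        if self.n_family_background > self.n_background_genes:
            raise DataError("family background exceeds background size")
        if min(self.peak_amplitude_log2, self.updown_amplitude_log2) <= 0:
            raise DataError("amplitudes must be positive")
        if not (0 < self.unchanged_amplitude_log2 < 1.0):
            raise DataError("unchanged amplitude must stay below the fold threshold")
        if self.noise_sd_log2 < 0:
            raise DataError("noise sd must be non-negative")


@dataclass
class Dataset:
    """A catalog plus a combined expression matrix and sample metadata.

    ``expression`` holds log2 intensities, genes x samples, including the
    shared time-0 control column.
    """

    catalog: list[GeneRecord]
    expression: pd.DataFrame
    metadata: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.catalog]


def _sample_id(lineage: str, t: float) -> str:
    prefix = {OSTEOBLAST: "ob", ADIPOCYTE: "ad"}[lineage]
    return f"{prefix}_{t:g}h"


def _metadata_frame(
    osteo_times: tuple[float, ...], adipo_times: tuple[float, ...]
) -> pd.DataFrame:
    rows = [{"sample_id": CONTROL_SAMPLE_ID, "lineage": "control",
             "time_hours": 0.0, "is_control": 1}]
    for lineage, times in ((OSTEOBLAST, osteo_times), (ADIPOCYTE, adipo_times)):
        for t in times:
            rows.append({"sample_id": _sample_id(lineage, t), "lineage": lineage,
                         "time_hours": float(t), "is_control": 0})
    return pd.DataFrame(rows, columns=["sample_id", "lineage", "time_hours", "is_control"])


def _window_times(window: PhaseWindow, times: tuple[float, ...]) -> list[float]:
    inside = [t for t in times if window.contains(t)]
    if not inside:
        raise DataError(f"window {window.label!r} contains no sampling time")
    return inside


def build_reference_fixture() -> Dataset:
    """The deterministic noiseless reference dataset (110 genes).

    Osteoblast profiles plateau at +peak amplitude over the gene's
    labelled phase window; curated up-and-down genes add a -1.5 plateau
    over the last window. Adipocyte profiles realise the curated arrows:
    down/up plateaus of the peak amplitude over the labelled cluster
    window, alternating +-0.2 wiggles for the curated unchanged genes,
    flat baseline for everything else. All genes carry a TF GO accession;
    the eleven bHLH genes carry the bHLH InterPro accession.
    """
    spec = fixture_spec()
    amplitude = SimulationConfig().peak_amplitude_log2
    dip = SimulationConfig().updown_amplitude_log2
    wiggle = SimulationConfig().unchanged_amplitude_log2

    osteo_grid = TimeGrid(OSTEOBLAST, DEFAULT_OSTEOBLAST_TIMES)
    adipo_grid = TimeGrid(ADIPOCYTE, DEFAULT_ADIPOCYTE_TIMES)
    osteo_windows = {w.label: w for w in default_windows(OSTEOBLAST)}
    adipo_windows = {w.label: w for w in default_windows(ADIPOCYTE)}
    last_osteo = default_windows(OSTEOBLAST)[-1]

    genes: list[str] = []
    records: list[GeneRecord] = []
    osteo_rows: list[np.ndarray] = []
    adipo_rows: list[np.ndarray] = []

    for phase_label, symbols in spec.osteoblast_phase_genes.items():
        window = osteo_windows[phase_label]
        up_times = set(_window_times(window, osteo_grid.times))
        for i, symbol in enumerate(symbols):
            bhlh = spec.bhlh_genes.get(symbol)
            osteo = np.zeros(len(osteo_grid))
            for j, t in enumerate(osteo_grid.times):
                if t in up_times:
                    osteo[j] = amplitude
            if bhlh is not None and bhlh[0] == "UP_DOWN":
                for j, t in enumerate(osteo_grid.times):
                    if last_osteo.contains(t) and t not in up_times:
                        osteo[j] = -dip

            # Unregulated adipocyte profiles carry a deterministic
            # sub-threshold +-wiggle (alternating sign) rather than exact
            # zeros, so the array-wide sd never collapses at time points
            # where no gene is regulated (which would make the adaptive
            # mean +- k*sd bound fire on the wiggle itself).
            adipo = np.array(
                [wiggle * (1 if (len(genes) + j) % 2 == 0 else -1)
                 for j in range(len(adipo_grid))]
            )
            if bhlh is not None:
                _, adipo_behavior, _, adipo_label = bhlh
                if adipo_behavior in ("UP", "DOWN"):
                    sign = 1.0 if adipo_behavior == "UP" else -1.0
                    down_window = adipo_windows[adipo_label]
                    for j, t in enumerate(adipo_grid.times):
                        adipo[j] = sign * amplitude if down_window.contains(t) else 0.0

            genes.append(symbol)
            interpro = frozenset({BHLH_INTERPRO}) if bhlh is not None else frozenset()
            records.append(
                GeneRecord(gene_id=symbol, symbol=symbol,
                           go_ids=frozenset({FIXTURE_GO_ID}), interpro_ids=interpro)
            )
            osteo_rows.append(osteo)
            adipo_rows.append(adipo)

    expression = _assemble_expression(
        genes,
        baselines=np.full(len(genes), _BASELINE_LOG2),
        osteo=np.array(osteo_rows),
        adipo=np.array(adipo_rows),
        osteo_times=osteo_grid.times,
        adipo_times=adipo_grid.times,
    )
    metadata = _metadata_frame(osteo_grid.times, adipo_grid.times)
    return Dataset(catalog=records, expression=expression, metadata=metadata)


def _assemble_expression(
    genes: list[str],
    baselines: np.ndarray,
    osteo: np.ndarray,
    adipo: np.ndarray,
    osteo_times: tuple[float, ...],
    adipo_times: tuple[float, ...],
) -> pd.DataFrame:
    columns = {CONTROL_SAMPLE_ID: baselines}
    for j, t in enumerate(osteo_times):
        columns[_sample_id(OSTEOBLAST, t)] = baselines + osteo[:, j]
    for j, t in enumerate(adipo_times):
        columns[_sample_id(ADIPOCYTE, t)] = baselines + adipo[:, j]
    frame = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    return frame


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Seeded synthetic dataset: unchanged background, optional fixture.

    Background genes carry per-sample offsets uniform within the unchanged
    amplitude (so they classify UNCHANGED without noise); the first
    ``n_family_background`` of them are tagged with the bHLH InterPro
    accession but no TF GO term. Gaussian noise (``noise_sd_log2``) is
    added to every measurement, control included. Output is byte-identical
    for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_background_genes
    n_os, n_ad = len(DEFAULT_OSTEOBLAST_TIMES), len(DEFAULT_ADIPOCYTE_TIMES)

    width = max(6, len(str(max(n, 1))))
    gene_ids = [f"bg{i:0{width}d}" for i in range(1, n + 1)]
    records = [
        GeneRecord(
            gene_id=g,
            symbol=g,
            go_ids=frozenset({BACKGROUND_GO_ID}),
            interpro_ids=(
                frozenset({BHLH_INTERPRO}) if i < config.n_family_background
                else frozenset()
            ),
        )
        for i, g in enumerate(gene_ids)
    ]
    baselines = rng.uniform(6.0, 12.0, size=n)
    amp = config.unchanged_amplitude_log2
    osteo = rng.uniform(-amp, amp, size=(n, n_os))
    adipo = rng.uniform(-amp, amp, size=(n, n_ad))
    expression = _assemble_expression(
        gene_ids, baselines, osteo, adipo,
        DEFAULT_OSTEOBLAST_TIMES, DEFAULT_ADIPOCYTE_TIMES,
    )

    catalog = records
    if config.include_fixture:
        fixture = build_reference_fixture()
        expression = pd.concat([expression, fixture.expression], axis=0)
        catalog = records + fixture.catalog

    if config.noise_sd_log2 > 0:
        noise = rng.normal(0.0, config.noise_sd_log2, size=expression.shape)
        expression = expression + noise

    metadata = _metadata_frame(DEFAULT_OSTEOBLAST_TIMES, DEFAULT_ADIPOCYTE_TIMES)
    return Dataset(catalog=catalog, expression=expression, metadata=metadata)


def write_dataset(dataset: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write a dataset as TSV files; returns the written paths.

    Emits one expression matrix per lineage (each including the shared
    control column), the sample metadata sidecar and the annotation
    catalog, in the formats the loaders read back losslessly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = dataset.metadata
    paths: dict[str, Path] = {}
    for lineage, key in ((OSTEOBLAST, "expression_osteoblast"),
                         (ADIPOCYTE, "expression_adipocyte")):
        samples = [CONTROL_SAMPLE_ID] + [
            s for s in meta.loc[meta["lineage"] == lineage, "sample_id"]
        ]
        samples = [s for s in samples if s in dataset.expression.columns]
        path = directory / f"{key}.tsv"
        write_expression(dataset.expression[samples], path)
        paths[key] = path
    paths["metadata"] = write_metadata(meta, directory / "sample_metadata.tsv")
    paths["annotation"] = write_catalog(dataset.catalog, directory / "annotation.tsv")
    return paths


def load_dataset(
    expression_paths: list[str | Path],
    metadata_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reload expression (merged across files) and metadata."""
    expression = load_expression(expression_paths)
    metadata = load_metadata(metadata_path)
    return expression, metadata
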