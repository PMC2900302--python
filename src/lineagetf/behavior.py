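"""Time-course behavior classification of gene expression.

Each gene's expression over one differentiation time course is summarised
as log2 ratios versus the shared time-0 (uninduced) control, then
classified into one of four behaviors:

* ``UP`` — the up-regulation criterion fires at >=1 time point, the
  down-regulation criterion never fires;
* ``DOWN`` — the mirror image;
* ``UP_DOWN`` — both criteria fire, at distinct time points;
* ``UNCHANGED`` — neither fires anywhere.

A time point fires upward when the log2 ratio exceeds the fold threshold
(default 1.0, i.e. two-fold) OR exceeds the array-adaptive upper bound
mean + k*sd taken across all genes at that time point (default k = 3,
population sd). Downward firing is symmetric with the negated threshold
and the lower bound mean - k*sd. Comparisons are strict: a ratio exactly
at the threshold does not fire.

The per-time-point mean +- k*sd bounds are computed across all genes on
the array for that sample (an array-wide outlier criterion), so the rule
is an absolute fold cutoff OR an array-adaptive cutoff, computable
without replicates. This reference population is configurable in spirit:
callers may supply their own ``bounds`` to :func:`classify_gene`.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

#: Largest value plausibly on the log2 scale; anything above suggests
#: linear-scale intensities, which are rejected rather than auto-converted.
_MAX_LOG2_INTENSITY = 50.0

OSTEOBLAST = "osteoblast"
ADIPOCYTE = "adipocyte"


class Behavior(str, enum.Enum):
    """Four-way time-course behavior category."""

    UP = "UP"
    DOWN = "DOWN"
    UP_DOWN = "UP_DOWN"
    UNCHANGED = "UNCHANGED"

    @property
    def arrow(self) -> str:
        return {"UP": "↑", "DOWN": "↓", "UP_DOWN": "↑↓", "UNCHANGED": "≈"}[self.value]


#: Fixed category order used in every tabulated output.
BEHAVIOR_ORDER: tuple[Behavior, ...] = (
    Behavior.UP,
    Behavior.DOWN,
    Behavior.UP_DOWN,
    Behavior.UNCHANGED,
)


@dataclass(frozen=True)
class TimeGrid:
    """Ordered post-induction sampling times (hours) of one lineage."""

    lineage: str
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.times:
            raise DataError(f"{self.lineage}: empty time grid")
        if any(t <= 0 for t in self.times):
            raise DataError(f"{self.lineage}: sampling times must be > 0 (control excluded)")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise DataError(f"{self.lineage}: sampling times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RatioSeries:
    """One gene's log2 ratios versus the time-0 control, on one grid."""

    gene_id: str
    lineage: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.values)):
            raise DataError(f"{self.gene_id}/{self.lineage}: non-finite ratio values")


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds of the up/down rule.

    fold_threshold: absolute log2-ratio cutoff (1.0 = two-fold).
    sd_multiplier: k of the array-adaptive mean +- k*sd cutoff.
    """

    fold_threshold: float = 1.0
    sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0 or self.sd_multiplier <= 0:
            raise DataError("classification thresholds must be positive")


@dataclass(frozen=True)
class BehaviorCall:
    """Classification of one gene in one lineage, with firing times."""

    gene_id: str
    lineage: str
    call: Behavior
    up_times: tuple[float, ...] = ()
    down_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        expected = _derive_behavior(bool(self.up_times), bool(self.down_times))
        if self.call is not expected:
            raise DataError(
                f"{self.gene_id}/{self.lineage}: call {self.call.value} inconsistent "
                f"with firing times (expected {expected.value})"
            )


def _derive_behavior(up_fired: bool, down_fired: bool) -> Behavior:
    if up_fired and down_fired:
        return Behavior.UP_DOWN
    if up_fired:
        return Behavior.UP
    if down_fired:
        return Behavior.DOWN
    return Behavior.UNCHANGED


@dataclass(frozen=True)
class RatioTable:
    """All genes' ratio series of one lineage, aligned to one grid.

    ``values`` is a genes x times DataFrame (index gene_id, columns the
    sampling times in hours).
    """

    grid: TimeGrid
    values: pd.DataFrame

    def series(self, gene_id: str) -> RatioSeries:
        if gene_id not in self.values.index:
            raise DataError(f"gene {gene_id!r} absent from ratio table")
        return RatioSeries(
            gene_id=gene_id,
            lineage=self.grid.lineage,
            values=tuple(float(v) for v in self.values.loc[gene_id]),
        )

    def __iter__(self):
        for gene_id in self.values.index:
            yield self.series(gene_id)


def compute_ratios(
    expression: pd.DataFrame, metadata: pd.DataFrame, lineage: str
) -> RatioTable:
    """Log2 ratios of one lineage's samples versus the time-0 control.

    ``expression`` holds log2 intensities (genes x samples); ``metadata``
    has columns sample_id, lineage, time_hours, is_control. Exactly one
    control sample (shared by both lineages) is required. Values are
    already on the log2 scale, so the ratio is a plain subtraction;
    linear-scale input is rejected, not auto-detected.
    """
    if float(np.nanmax(expression.to_numpy())) > _MAX_LOG2_INTENSITY:
        raise DataError(
            "expression values exceed the plausible log2 range; "
            "supply log2-transformed intensities"
        )
    controls = metadata.loc[metadata["is_control"].astype(int) == 1, "sample_id"]
    if len(controls) != 1:
        raise DataError(f"expected exactly one control sample, found {len(controls)}")
    control_id = str(controls.iloc[0])
    if control_id not in expression.columns:
        raise DataError(f"control sample {control_id!r} missing from expression matrix")

    rows = metadata[
        (metadata["lineage"] == lineage) & (metadata["is_control"].astype(int) == 0)
    ].copy()
    if rows.empty:
        raise DataError(f"no samples for lineage {lineage!r}")
    rows["time_hours"] = rows["time_hours"].astype(float)
    dup = rows["time_hours"].duplicated()
    if dup.any():
        t = rows.loc[dup, "time_hours"].iloc[0]
        raise DataError(f"duplicate sample for ({lineage}, {t} h)")
    rows = rows.sort_values("time_hours")
    missing = [s for s in rows["sample_id"] if s not in expression.columns]
    if missing:
        raise DataError(f"samples in metadata but not expression: {', '.join(missing)}")

    grid = TimeGrid(lineage=lineage, times=tuple(float(t) for t in rows["time_hours"]))
    ratios = expression[list(rows["sample_id"])].to_numpy(dtype=float)
    ratios = ratios - expression[control_id].to_numpy(dtype=float)[:, None]
    frame = pd.DataFrame(ratios, index=expression.index, columns=list(grid.times))
    return RatioTable(grid=grid, values=frame)


def per_timepoint_bounds(
    all_ratios_at_time: Sequence[float] | np.ndarray, k: float
) -> tuple[float, float]:
    """(mean - k*sd, mean + k*sd) across all genes at one time point.

    sd is the population standard deviation (ddof=0). Requires >=2 values.
    """
    values = np.asarray(all_ratios_at_time, dtype=float)
    if values.size < 2:
        raise DataError("per-time-point bounds need at least 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    return (mean - k * sd, mean + k * sd)


def table_bounds(table: RatioTable, k: float) -> list[tuple[float, float]]:
    """Array-adaptive bounds for every time point of a ratio table."""
    return [
        per_timepoint_bounds(table.values[t].to_numpy(), k) for t in table.grid.times
    ]


def classify_gene(
    series: RatioSeries,
    bounds_per_time: Sequence[tuple[float, float]],
    params: ClassificationParams = ClassificationParams(),
    times: Sequence[float] | None = None,
) -> BehaviorCall:
    """Apply the up/down rule to one ratio series.

    A time point fires upward iff value > fold_threshold OR value > the
    upper bound at that point; downward iff value < -fold_threshold OR
    value < the lower bound. Strict inequalities throughout.
    """
    if len(series.values) != len(bounds_per_time):
        raise DataError(
            f"{series.gene_id}: {len(series.values)} ratios vs "
            f"{len(bounds_per_time)} bounds"
        )
    if times is None:
        times = tuple(range(1, len(series.values) + 1))
    up, down = [], []
    for t, v, (lo, hi) in zip(times, series.values, bounds_per_time):
        if v > params.fold_threshold or v > hi:
            up.append(float(t))
        if v < -params.fold_threshold or v < lo:
            down.append(float(t))
    return BehaviorCall(
        gene_id=series.gene_id,
        lineage=series.lineage,
        call=_derive_behavior(bool(up), bool(down)),
        up_times=tuple(up),
        down_times=tuple(down),
    )


def classify_all(
    table: RatioTable,
    params: ClassificationParams = ClassificationParams(),
    gene_ids: Iterable[str] | None = None,
) -> dict[str, BehaviorCall]:
    """Classify every gene of a ratio table (or a subset).

    Bounds are computed across ALL genes of the table at each time point,
    even when classification is restricted to a subset, so the
    array-adaptive criterion always references the full array.
    """
    bounds = table_bounds(table, params.sd_multiplier)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    values = table.values.to_numpy(dtype=float)
    times = np.asarray(table.grid.times, dtype=float)
    up_mask = (values > params.fold_threshold) | (values > hi)
    down_mask = (values < -params.fold_threshold) | (values < lo)

    subset = table.values.index if gene_ids is None else list(gene_ids)
    index_of = {g: i for i, g in enumerate(table.values.index)}
    calls: dict[str, BehaviorCall] = {}
    for gene_id in subset:
        if gene_id not in index_of:
            raise DataError(f"gene {gene_id!r} absent from ratio table")
        i = index_of[gene_id]
        up = tuple(float(t) for t in times[up_mask[i]])
        down = tuple(float(t) for t in times[down_mask[i]])
        calls[gene_id] = BehaviorCall(
            gene_id=gene_id,
            lineage=table.grid.lineage,
            call=_derive_behavior(bool(up), bool(down)),
            up_times=up,
            down_times=down,
        )
    return calls


@dataclass(frozen=True)
class ContingencyTable4:
    """4x4 cross-lineage behavior counts, (adipocyte call, osteoblast call).

    Rows and columns follow :data:`BEHAVIOR_ORDER`.
    """

    cells: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.cells)
        if arr.shape != (4, 4) or (arr < 0).any():
            raise DataError("contingency table must be 4x4 with non-negative counts")

    def cell(self, adipocyte: Behavior, osteoblast: Behavior) -> int:
        return self.cells[BEHAVIOR_ORDER.index(adipocyte)][BEHAVIOR_ORDER.index(osteoblast)]

    @property
    def row_totals(self) -> tuple[int, ...]:
        return tuple(int(sum(row)) for row in self.cells)

    @property
    def col_totals(self) -> tuple[int, ...]:
        return tuple(int(sum(col)) for col in zip(*self.cells))

    @property
    def grand_total(self) -> int:
        return int(sum(self.row_totals))

    def to_frame(self) -> pd.DataFrame:
        labels = [b.value for b in BEHAVIOR_ORDER]
        frame = pd.DataFrame(list(self.cells), index=labels, columns=labels)
        frame.index.name = "adipocyte"
        frame.columns.name = "osteoblast"
        frame["Total"] = list(self.row_totals)
        frame.loc["Total"] = list(self.col_totals) + [self.grand_total]
        return frame

    def to_dict(self) -> dict:
        return {
            "order": [b.value for b in BEHAVIOR_ORDER],
            "cells": [list(row) for row in self.cells],
            "row_totals": list(self.row_totals),
            "col_totals": list(self.col_totals),
            "grand_total": self.grand_total,
        }


def cross_tabulate(
    calls_osteo: Mapping[str, BehaviorCall] | Iterable[BehaviorCall],
    calls_adipo: Mapping[str, BehaviorCall] | Iterable[BehaviorCall],
) -> ContingencyTable4:
    """Cross-tabulate per-gene behavior across the two lineages."""
    osteo = _as_call_map(calls_osteo)
    adipo = _as_call_map(calls_adipo)
    only = set(osteo) ^ set(adipo)
    if only:
        raise DataError(
            f"gene(s) classified in one lineage only: {', '.join(sorted(only)[:5])}"
        )
    counts = np.zeros((4, 4), dtype=int)
    for gene_id, ocall in osteo.items():
        a = BEHAVIOR_ORDER.index(adipo[gene_id].call)
        o = BEHAVIOR_ORDER.index(ocall.call)
        counts[a, o] += 1
    return ContingencyTable4(cells=tuple(tuple(int(c) for c in row) for row in counts))


def _as_call_map(calls) -> dict[str, BehaviorCall]:
    if isinstance(calls, Mapping):
        return dict(calls)
    return {c.gene_id: c for c in calls}


def count_changed(table: ContingencyTable4) -> int:
    """Genes regulated in at least one lineage: total minus the (≈, ≈) cell."""
    return table.grand_total - table.cell(Behavior.UNCHANGED, Behavior.UNCHANGED)


def candidate_switch_genes(
    calls_osteo: Mapping[str, BehaviorCall] | Iterable[BehaviorCall],
    calls_adipo: Mapping[str, BehaviorCall] | Iterable[BehaviorCall],
    direction: tuple[str, str] = ("UP", "DOWN"),
) -> list[str]:
    """Genes with opposite pure calls in the two lineages.

    ``direction`` is (osteoblast call, adipocyte call); only exact pure
    matches qualify (UP_DOWN never does). Sorted by gene_id.
    """
    if tuple(direction) not in {("UP", "DOWN"), ("DOWN", "UP")}:
        raise DataError(f"direction must be (UP,DOWN) or (DOWN,UP), got {direction}")
    osteo = _as_call_map(calls_osteo)
    adipo = _as_call_map(calls_adipo)
    only = set(osteo) ^ set(adipo)
    if only:
        raise DataError(
            f"gene(s) classified in one lineage only: {', '.join(sorted(only)[:5])}"
        )
    want_o, want_a = Behavior(direction[0]), Behavior(direction[1])
    return sorted(
        g for g in osteo if osteo[g].call is want_o and adipo[g].call is want_a
    )
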