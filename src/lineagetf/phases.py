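"""Temporal phase structure of differentiation time courses.

Two complementary tools:

* Hierarchical clustering of gene profiles (for heat-map ordering) and of
  sample columns (to detect blocks of similar consecutive time points —
  the temporal phases of the differentiation course).
* An explicit, testable phase-assignment rule: each regulated gene is
  binned into the phase window containing the time of its strongest
  regulation (argmax of the ratio over the time points where the up
  criterion fired; argmin for the down direction; earliest time wins
  ties).

Default windows reproduce the five osteoblast phases (1 h; 6-24 h;
30-48 h; 4-6 d; 8-14 d) and four adipocyte phases (2 d; 4 d; 8 d;
10-14 d) of a two-week ST2 differentiation course; both are configurable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .behavior import (
    ADIPOCYTE,
    OSTEOBLAST,
    Behavior,
    BehaviorCall,
    RatioSeries,
    RatioTable,
    TimeGrid,
)
from .errors import DataError

logger = logging.getLogger(__name__)

#: Default sampling grids (hours) for the synthetic two-week course:
#: 15 osteoblast and 7 adipocyte time points plus the shared 0 h control.
DEFAULT_OSTEOBLAST_TIMES: tuple[float, ...] = (
    1, 3, 6, 12, 18, 24, 30, 36, 48, 96, 120, 144, 192, 240, 336,
)
DEFAULT_ADIPOCYTE_TIMES: tuple[float, ...] = (2, 24, 48, 96, 168, 240, 336)

_DISTANCES = {"correlation", "euclidean"}
_LINKAGES = {"average", "complete"}


@dataclass(frozen=True)
class PhaseWindow:
    """A contiguous time interval of one lineage's course.

    The interval is [start_hours, end_hours); the last window of a lineage
    is closed on the right (``end_inclusive=True``) so the windows can
    partition the whole sampled range.
    """

    lineage: str
    label: str
    start_hours: float
    end_hours: float
    end_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.start_hours > self.end_hours:
            raise DataError(f"window {self.label!r}: start > end")

    def contains(self, time_hours: float) -> bool:
        if self.end_inclusive:
            return self.start_hours <= time_hours <= self.end_hours
        return self.start_hours <= time_hours < self.end_hours


def default_windows(lineage: str) -> list[PhaseWindow]:
    """The default phase windows of a lineage."""
    if lineage == OSTEOBLAST:
        spec = [("1hr", 0.5, 3), ("6-24hr", 3, 27), ("30-48hr", 27, 60),
                ("4-6d", 60, 168), ("8-14d", 168, 336)]
    elif lineage == ADIPOCYTE:
        spec = [("2d", 1, 60), ("4d", 60, 120), ("8d", 120, 216), ("10-14d", 216, 336)]
    else:
        raise DataError(f"no default windows for lineage {lineage!r}")
    last = len(spec) - 1
    return [
        PhaseWindow(lineage, label, float(a), float(b), end_inclusive=(i == last))
        for i, (label, a, b) in enumerate(spec)
    ]


def validate_windows(windows: Sequence[PhaseWindow], grid: TimeGrid) -> None:
    """Check that windows are ordered, disjoint and cover every grid time."""
    if not windows:
        raise DataError("empty window list")
    for a, b in zip(windows, windows[1:]):
        if a.end_hours > b.start_hours or (a.end_inclusive and a.end_hours >= b.start_hours):
            raise DataError(f"windows {a.label!r} and {b.label!r} overlap or are unordered")
    for t in grid.times:
        if not any(w.contains(t) for w in windows):
            raise DataError(f"sampling time {t} h of {grid.lineage} not covered by any window")


@dataclass(frozen=True)
class PhaseAssignment:
    """One regulated gene placed in the phase window of its peak regulation."""

    gene_id: str
    lineage: str
    direction: Behavior
    window: PhaseWindow
    peak_time_hours: float
    peak_value: float

    def __post_init__(self) -> None:
        if self.direction not in (Behavior.UP, Behavior.DOWN):
            raise DataError("assignment direction must be UP or DOWN")
        if not self.window.contains(self.peak_time_hours):
            raise DataError(
                f"{self.gene_id}: peak time {self.peak_time_hours} h outside "
                f"window {self.window.label!r}"
            )
        if self.direction is Behavior.UP and self.peak_value <= 0:
            raise DataError(f"{self.gene_id}: UP assignment with non-positive peak")
        if self.direction is Behavior.DOWN and self.peak_value >= 0:
            raise DataError(f"{self.gene_id}: DOWN assignment with non-negative peak")


@dataclass(frozen=True)
class ClusteringResult:
    """Deterministic agglomerative clustering of gene profiles."""

    gene_order: tuple[str, ...]
    merge_tree: tuple[tuple[int, int, float, int], ...]  # scipy linkage rows
    distance_name: str
    linkage_name: str

    @property
    def linkage_matrix(self) -> np.ndarray:
        return np.asarray(self.merge_tree, dtype=float)


def standardize_profile(series: RatioSeries) -> RatioSeries:
    """Z-score a profile across its time points (population sd).

    A constant profile maps to all zeros (with a logged note) so it can
    still enter euclidean clustering.
    """
    values = np.asarray(series.values, dtype=float)
    if values.size < 2:
        raise DataError(f"{series.gene_id}: standardization needs >=2 time points")
    sd = values.std(ddof=0)
    if sd == 0:
        logger.info("constant profile for %s/%s standardized to zeros",
                    series.gene_id, series.lineage)
        z = np.zeros_like(values)
    else:
        z = (values - values.mean()) / sd
    return RatioSeries(gene_id=series.gene_id, lineage=series.lineage,
                       values=tuple(float(v) for v in z))


def _profiles_to_matrix(
    profiles: Iterable[RatioSeries] | pd.DataFrame,
) -> tuple[list[str], np.ndarray]:
    if isinstance(profiles, pd.DataFrame):
        return [str(g) for g in profiles.index], profiles.to_numpy(dtype=float)
    profiles = list(profiles)
    lengths = {len(p.values) for p in profiles}
    if len(lengths) > 1:
        raise DataError("profiles are not aligned to a common grid")
    return [p.gene_id for p in profiles], np.array([p.values for p in profiles], float)


def cluster_genes(
    profiles: Iterable[RatioSeries] | pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusteringResult:
    """Agglomerative clustering of gene profiles for heat-map ordering.

    The gene order is the left-to-right leaf traversal of the merge tree.
    scipy's linkage on the condensed distance matrix is deterministic for
    a fixed input order; equal merge distances resolve toward the
    smallest leaf index.
    """
    if distance not in _DISTANCES:
        raise DataError(f"unknown distance {distance!r}; choose from {sorted(_DISTANCES)}")
    if linkage not in _LINKAGES:
        raise DataError(f"unknown linkage {linkage!r}; choose from {sorted(_LINKAGES)}")
    gene_ids, matrix = _profiles_to_matrix(profiles)
    if len(gene_ids) < 2:
        raise DataError("clustering needs at least 2 profiles")
    if not np.isfinite(matrix).all():
        raise DataError("NaN or infinite value in profiles")
    if distance == "correlation" and (matrix.std(axis=1, ddof=0) == 0).any():
        raise DataError("constant profile: correlation distance undefined")
    condensed = pdist(matrix, metric=distance)
    condensed = np.clip(condensed, 0.0, None)  # guard tiny negative rounding
    tree = sch.linkage(condensed, method=linkage)
    order = sch.leaves_list(tree)
    return ClusteringResult(
        gene_order=tuple(gene_ids[i] for i in order),
        merge_tree=tuple(
            (int(a), int(b), float(d), int(n)) for a, b, d, n in tree
        ),
        distance_name=distance,
        linkage_name=linkage,
    )


def assign_phases(
    calls: Mapping[str, BehaviorCall] | Iterable[BehaviorCall],
    profiles: RatioTable,
    windows: Sequence[PhaseWindow],
) -> list[PhaseAssignment]:
    """Bin each regulated gene into the window of its peak regulation.

    Reads raw (unstandardized) ratios. Each fired direction yields exactly
    one assignment: UP uses the argmax of the ratio over the up-fired time
    points, DOWN the argmin over the down-fired points; the earliest time
    wins ties. UNCHANGED genes yield nothing; UP_DOWN genes yield two
    assignments.
    """
    validate_windows(windows, profiles.grid)
    if not isinstance(calls, Mapping):
        calls = {c.gene_id: c for c in calls}
    times = list(profiles.grid.times)
    assignments: list[PhaseAssignment] = []
    for gene_id, call in calls.items():
        if call.call is Behavior.UNCHANGED:
            continue
        series = profiles.series(gene_id)
        by_time = dict(zip(times, series.values))
        for direction, fired in (
            (Behavior.UP, call.up_times),
            (Behavior.DOWN, call.down_times),
        ):
            if not fired:
                continue
            if direction is Behavior.UP:
                peak_t = min(fired, key=lambda t: (-by_time[t], t))
            else:
                peak_t = min(fired, key=lambda t: (by_time[t], t))
            window = next((w for w in windows if w.contains(peak_t)), None)
            if window is None:
                raise DataError(
                    f"{gene_id}: peak time {peak_t} h outside all windows"
                )
            assignments.append(
                PhaseAssignment(
                    gene_id=gene_id,
                    lineage=profiles.grid.lineage,
                    direction=direction,
                    window=window,
                    peak_time_hours=float(peak_t),
                    peak_value=float(by_time[peak_t]),
                )
            )
    return assignments


def _format_hours(t: float) -> str:
    return f"{t / 24:g}d" if t >= 48 else f"{t:g}h"


def detect_phase_windows(
    sample_values: pd.DataFrame,
    times: Sequence[float],
    lineage: str,
    max_phases: int = 6,
) -> list[PhaseWindow]:
    """Detect temporal phases from sample-column similarity.

    Clusters the sample columns (correlation distance, average linkage),
    chooses the number of clusters k <= max_phases at the largest jump in
    merge height, then converts the labelling into contiguous-in-time
    groups: a cut crossing non-adjacent times is repaired by merging the
    most similar adjacent runs until at most max_phases windows remain.
    Window boundaries fall halfway between adjacent groups; the first
    window opens at half the first sampling time and the last closes at
    the final time (inclusive), so the windows partition the grid.
    """
    times = [float(t) for t in times]
    if sample_values.shape[1] != len(times):
        raise DataError("sample_values columns and times are misaligned")
    if len(times) < 2:
        raise DataError("phase detection needs >=2 samples")
    order = np.argsort(times)
    times = [times[i] for i in order]
    matrix = sample_values.to_numpy(dtype=float)[:, order].T  # samples x genes
    if not np.isfinite(matrix).all():
        raise DataError("NaN or infinite value in sample matrix")

    if (matrix.std(axis=1, ddof=0) == 0).any():
        raise DataError("constant sample column: correlation distance undefined")
    condensed = np.clip(pdist(matrix, metric="correlation"), 0.0, None)
    tree = sch.linkage(condensed, method="average")
    heights = tree[:, 2]
    n = len(times)
    # gap(k) = height of the merge that reduces k clusters to k-1, minus the
    # last merge still present at k clusters; large gap => natural cut at k.
    best_k, best_gap = 1, 0.0
    for k in range(2, min(max_phases, n) + 1):
        gap = heights[n - k] - (heights[n - k - 1] if n - k - 1 >= 0 else 0.0)
        if gap > best_gap + 1e-12:
            best_k, best_gap = k, gap
    if best_gap <= 1e-12:
        labels = np.ones(n, dtype=int)
    else:
        labels = sch.fcluster(tree, t=best_k, criterion="maxclust")

    runs: list[list[int]] = [[0]]
    for i in range(1, n):
        if labels[i] == labels[i - 1]:
            runs[-1].append(i)
        else:
            runs.append([i])
    dist_sq = squareform(condensed)
    while len(runs) > max_phases:
        # merge the adjacent pair of runs with the smallest mean distance
        best_i = min(
            range(len(runs) - 1),
            key=lambda i: float(dist_sq[np.ix_(runs[i], runs[i + 1])].mean()),
        )
        runs[best_i] = runs[best_i] + runs.pop(best_i + 1)

    windows: list[PhaseWindow] = []
    for i, run in enumerate(runs):
        first, last = times[run[0]], times[run[-1]]
        start = times[0] / 2 if i == 0 else (times[runs[i - 1][-1]] + first) / 2
        is_last = i == len(runs) - 1
        end = last if is_last else (last + times[runs[i + 1][0]]) / 2
        label = _format_hours(first) if first == last else (
            f"{_format_hours(first)}-{_format_hours(last)}"
        )
        windows.append(
            PhaseWindow(lineage, label, float(start), float(end), end_inclusive=is_last)
        )
    return windows


@dataclass(frozen=True)
class PhaseGroup:
    """One window's members, sorted by peak time then gene id."""

    window: PhaseWindow
    members: tuple[PhaseAssignment, ...]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PhaseReport:
    """Ordered per-window membership summary."""

    lineage: str
    direction: Behavior | None
    groups: tuple[PhaseGroup, ...]

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(g.count for g in self.groups)

    def to_frame(self, symbols: Mapping[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for group in self.groups:
            for a in group.members:
                rows.append(
                    {
                        "lineage": a.lineage,
                        "window_label": group.window.label,
                        "gene_id": a.gene_id,
                        "symbol": (symbols or {}).get(a.gene_id, a.gene_id),
                        "direction": a.direction.value,
                        "peak_time_hours": a.peak_time_hours,
                        "peak_log2_ratio": a.peak_value,
                    }
                )
        columns = ["lineage", "window_label", "gene_id", "symbol", "direction",
                   "peak_time_hours", "peak_log2_ratio"]
        return pd.DataFrame(rows, columns=columns)


def phase_report(
    assignments: Iterable[PhaseAssignment],
    windows: Sequence[PhaseWindow] | None = None,
    direction: Behavior | str | None = None,
) -> PhaseReport:
    """Group assignments per window, sorted by peak time then gene id.

    ``direction`` filters to UP or DOWN assignments (e.g. the up-regulated
    phase lists). With ``windows=None`` the windows present in the
    assignments are used, in start-time order; passing explicit windows
    also reports empty ones.
    """
    assignments = list(assignments)
    if direction is not None:
        direction = Behavior(direction)
        assignments = [a for a in assignments if a.direction is direction]
    lineages = {a.lineage for a in assignments}
    if len(lineages) > 1:
        raise DataError("assignments span multiple lineages; report one at a time")
    if windows is None:
        seen = {a.window for a in assignments}
        windows = sorted(seen, key=lambda w: w.start_hours)
    lineage = assignments[0].lineage if assignments else (
        windows[0].lineage if windows else ""
    )
    groups = []
    for window in windows:
        members = sorted(
            (a for a in assignments if a.window == window),
            key=lambda a: (a.peak_time_hours, a.gene_id),
        )
        groups.append(PhaseGroup(window=window, members=tuple(members)))
    return PhaseReport(lineage=lineage, direction=direction, groups=tuple(groups))
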