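"""Chi-square tests of gene-family over-representation within a phase.

The question: is membership of a gene family (e.g. the bHLH superfamily)
independent of membership of a differentiation phase, against the full
gene background? Each (phase, family) pair yields a 2x2 contingency table

    a  in-phase & in-family     b  in-phase & out-of-family
    c  out-of-phase & in-family d  out-of-phase & out-of-family

tested with the uncorrected Pearson chi-square statistic at df = 1,

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),   N = a+b+c+d,

and the upper-tail chi-square(1) p-value. Yates continuity correction is
off by default (a flag); no multiple-testing adjustment is applied across
phases and families by default (a Bonferroni flag exists) — each test is
reported at the configured alpha as-is.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .catalog import FamilyDefinition
from .errors import DataError
from .phases import PhaseReport

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class TwoByTwoTable:
    """2x2 family-by-phase contingency counts."""

    a: int  # in-phase & in-family
    b: int  # in-phase & out-of-family
    c: int  # out-of-phase & in-family
    d: int  # out-of-phase & out-of-family

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("negative contingency count")
        if self.n == 0:
            raise DataError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one family-by-phase independence test (df = 1)."""

    family_name: str
    phase_label: str
    lineage: str
    table: TwoByTwoTable
    chi2: float
    p_value: float
    alpha: float
    df: int = 1

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def chi_square_independence(
    table: TwoByTwoTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table.

    Closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) at df = 1; with
    ``continuity_correction`` the Yates form replaces |ad-bc| by
    max(|ad-bc| - N/2, 0). A zero marginal makes the expected counts
    degenerate and is a hard error.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = table.marginals
    if 0 in (r1, r2, c1, c2):
        raise DataError("degenerate table: zero marginal")
    n = table.n
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff * diff / (float(r1) * r2 * c1 * c2)
    p = float(chi2_dist.sf(chi2, df=1))
    return float(chi2), p


def enrich(
    phase_members: set[str],
    family: set[str],
    background: set[str],
    alpha: float = DEFAULT_ALPHA,
    family_name: str = "family",
    phase_label: str = "phase",
    lineage: str = "",
    continuity_correction: bool = False,
) -> EnrichmentResult:
    """Test one family against one phase over a gene background."""
    stray_phase = phase_members - background
    stray_family = family - background
    if stray_phase or stray_family:
        offenders = sorted(stray_phase | stray_family)[:5]
        raise DataError(
            f"ids outside the background universe: {', '.join(offenders)}"
        )
    a = len(phase_members & family)
    b = len(phase_members - family)
    c = len(family - phase_members)
    d = len(background) - a - b - c
    table = TwoByTwoTable(a=a, b=b, c=c, d=d)
    chi2, p = chi_square_independence(table, continuity_correction)
    return EnrichmentResult(
        family_name=family_name,
        phase_label=phase_label,
        lineage=lineage,
        table=table,
        chi2=chi2,
        p_value=p,
        alpha=alpha,
    )


def enrich_all(
    phase_reports: Iterable[PhaseReport],
    families: Sequence[tuple[FamilyDefinition, set[str]]],
    background: set[str],
    alpha: float = DEFAULT_ALPHA,
    continuity_correction: bool = False,
    bonferroni: bool = False,
) -> list[EnrichmentResult]:
    """One test per (phase, family), ordered by lineage, window, family.

    ``families`` pairs each definition with its resolved member id set
    (see :func:`lineagetf.catalog.family_members`). With ``bonferroni``
    the per-test alpha is divided by the number of tests; by default each
    test is judged at the raw alpha. Degenerate pairs (an empty phase, an
    empty family, or a family spanning the whole background) cannot be
    tested and are skipped with a logged note.
    """
    reports = list(phase_reports)
    n_tests = sum(len(r.groups) for r in reports) * len(families)
    effective_alpha = alpha / n_tests if (bonferroni and n_tests) else alpha
    results: list[EnrichmentResult] = []
    for report in sorted(reports, key=lambda r: r.lineage):
        for group in report.groups:
            members = {a.gene_id for a in group.members}
            for definition, member_ids in families:
                degenerate = (
                    not members
                    or members >= background
                    or not member_ids
                    or member_ids >= background
                )
                if degenerate:
                    logger.info(
                        "skipping untestable pair (%s/%s, %s): zero marginal",
                        report.lineage, group.window.label, definition.name,
                    )
                    continue
                results.append(
                    enrich(
                        phase_members=members,
                        family=member_ids,
                        background=background,
                        alpha=effective_alpha,
                        family_name=definition.name,
                        phase_label=group.window.label,
                        lineage=report.lineage,
                        continuity_correction=continuity_correction,
                    )
                )
    return results


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results for TSV output."""
    rows = [
        {
            "lineage": r.lineage,
            "window_label": r.phase_label,
            "family": r.family_name,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "chi2": r.chi2,
            "df": r.df,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for r in results
    ]
    columns = ["lineage", "window_label", "family", "a", "b", "c", "d",
               "chi2", "df", "p_value", "significant"]
    return pd.DataFrame(rows, columns=columns)
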