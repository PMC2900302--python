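"""Gene annotation catalog: transcription-factor selection and gene families.

A catalog is a flat table of genes, each carrying GO and InterPro
accessions. Transcription factors are the genes annotated with at least
one GO term from a transcription-related term set (the packaged default
is the 39-term set of GO release 2009-01-25 used for mouse TF
cataloguing). Gene families (e.g. the bHLH superfamily) are defined by an
InterPro domain accession, an explicit member list, or both.

GO accessions are matched exactly, with no ontology-graph propagation to
descendant terms: the term set is a flat ID list by design.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

GO_PATTERN = re.compile(r"^GO:\d{7}$")
INTERPRO_PATTERN = re.compile(r"^IPR\d{6}$")

#: InterPro accession of the basic helix-loop-helix domain.
BHLH_INTERPRO = "IPR001092"

_CATALOG_COLUMNS = ("gene_id", "symbol", "go_ids", "interpro_ids")


@dataclass(frozen=True)
class GeneRecord:
    """One gene with its identifiers and annotation accessions."""

    gene_id: str
    symbol: str
    go_ids: frozenset[str] = frozenset()
    interpro_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for acc in self.go_ids:
            if not GO_PATTERN.match(acc):
                raise DataError(f"malformed GO accession {acc!r} on gene {self.gene_id!r}")
        for acc in self.interpro_ids:
            if not INTERPRO_PATTERN.match(acc):
                raise DataError(
                    f"malformed InterPro accession {acc!r} on gene {self.gene_id!r}"
                )


@dataclass(frozen=True)
class GOTermSet:
    """A named flat set of GO accessions."""

    go_ids: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.go_ids:
            raise DataError(f"GO term set {self.label!r} is empty")
        for acc in self.go_ids:
            if not GO_PATTERN.match(acc):
                raise DataError(f"malformed GO accession {acc!r} in term set {self.label!r}")


@dataclass(frozen=True)
class FamilyDefinition:
    """A gene family defined by an InterPro domain and/or an explicit list."""

    name: str
    interpro_id: str | None = None
    explicit_members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.interpro_id is None and not self.explicit_members:
            raise DataError(
                f"family {self.name!r} needs an interpro_id or explicit members"
            )
        if self.interpro_id is not None and not INTERPRO_PATTERN.match(self.interpro_id):
            raise DataError(
                f"malformed InterPro accession {self.interpro_id!r} for family {self.name!r}"
            )


def default_tf_terms() -> GOTermSet:
    """The packaged transcription-related GO term set (39 accessions)."""
    text = (resources.files("lineagetf") / "data" / "go_tf_terms.txt").read_text()
    ids = frozenset(line.strip() for line in text.splitlines() if line.strip())
    return GOTermSet(go_ids=ids, label="transcription-related GO terms")


def _split_multivalue(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(part.strip() for part in text.split(";") if part.strip())


def load_catalog(path: str | Path) -> list[GeneRecord]:
    """Load a gene annotation catalog from a TSV file.

    Expected columns: ``gene_id``, ``symbol``, ``go_ids``, ``interpro_ids``;
    multi-valued cells are semicolon-delimited, blanks yield empty sets.

    Raises
    ------
    DataError
        On duplicate gene ids (the duplicate id is named) or a malformed
        accession (the 1-based data row number is named).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"catalog file not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"catalog {path} lacks required columns: {', '.join(missing)}")

    records: list[GeneRecord] = []
    seen: set[str] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        gene_id = str(row.gene_id).strip()
        if gene_id in seen:
            raise DataError(f"duplicate gene_id {gene_id!r} in catalog {path}")
        seen.add(gene_id)
        try:
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    symbol=str(row.symbol).strip(),
                    go_ids=_split_multivalue(row.go_ids),
                    interpro_ids=_split_multivalue(row.interpro_ids),
                )
            )
        except DataError as exc:
            raise DataError(f"row {row_number} of {path}: {exc}") from exc
    return records


def write_catalog(records: Iterable[GeneRecord], path: str | Path) -> Path:
    """Write a catalog to TSV in the format :func:`load_catalog` reads."""
    path = Path(path)
    rows = [
        {
            "gene_id": r.gene_id,
            "symbol": r.symbol,
            "go_ids": ";".join(sorted(r.go_ids)),
            "interpro_ids": ";".join(sorted(r.interpro_ids)),
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(_CATALOG_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)
    return path


def select_transcription_factors(
    catalog: Iterable[GeneRecord], terms: GOTermSet | None = None
) -> set[str]:
    """Gene ids whose GO annotation intersects the term set.

    With ``terms=None`` the packaged default transcription-related set is
    used. Monotone in ``terms``: adding accessions never removes a gene.
    """
    if terms is None:
        terms = default_tf_terms()
    return {rec.gene_id for rec in catalog if rec.go_ids & terms.go_ids}


def family_members(catalog: Iterable[GeneRecord], family: FamilyDefinition) -> set[str]:
    """Gene ids belonging to a family, restricted to the catalog.

    Union of InterPro-matched genes and explicit members; explicit members
    absent from the catalog are ignored with a logged warning.
    """
    catalog = list(catalog)
    ids = {rec.gene_id for rec in catalog}
    members: set[str] = set()
    if family.interpro_id is not None:
        members |= {rec.gene_id for rec in catalog if family.interpro_id in rec.interpro_ids}
    for member in family.explicit_members:
        if member in ids:
            members.add(member)
        else:
            logger.warning(
                "family %s explicit member %r absent from catalog; ignored",
                family.name,
                member,
            )
    return members


def symbols_by_id(catalog: Iterable[GeneRecord]) -> Mapping[str, str]:
    """gene_id -> symbol lookup."""
    return {rec.gene_id: rec.symbol for rec in catalog}


def bhlh_family(explicit_members: Sequence[str] = ()) -> FamilyDefinition:
    """The bHLH superfamily (InterPro basic helix-loop-helix domain)."""
    return FamilyDefinition(
        name="bHLH",
        interpro_id=BHLH_INTERPRO,
        explicit_members=frozenset(explicit_members),
    )
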