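"""Matching of genome-project registry records against a taxonomy.

Before strains are selected for sequencing, strains whose genomes are
already targeted, in progress or finished elsewhere have to be recognised.
Registry records (GOLD-style rows with organism / species / project-name /
strain / culture-collection fields and a project status) are compared with
a taxonomy that maps each accepted species name to its synonyms and to the
known culture-collection deposits of its type strain.

Species names are matched by exact string equality against the synonym
lists (misspellings are rare enough in practice that fuzzy matching buys
little and risks false merges).  Strain names are too short and too
variably written for exact matching, so equality is relaxed in three ways:

1. case-insensitive comparison;
2. a trailing "T" (commonly appended to mark a type strain) is ignored;
3. characters other than letters, digits and underscores (spaces, hyphens,
   dots, ...) are ignored.

Every record receives exactly one of four statuses: ``species_not_found``,
``strains_not_found``, ``found_incomplete`` or ``found_complete``.  The
first two mark the record's strain as a potential sequencing candidate;
the last two mean the genome is already covered elsewhere.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .errors import TableFormatError

__all__ = [
    "ProjectStatus",
    "MatchStatus",
    "ProjectRecord",
    "TaxonomyEntry",
    "MatchResult",
    "normalize_strain_name",
    "strain_keys",
    "strains_equal",
    "extract_species_names",
    "extract_strain_names",
    "match_record",
    "match_registry",
    "candidate_filter",
    "read_registry_tsv",
    "read_taxonomy_tsv",
    "write_matches_tsv",
]

logger = logging.getLogger(__name__)


class ProjectStatus(str, Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"


class MatchStatus(str, Enum):
    SPECIES_NOT_FOUND = "species_not_found"
    STRAINS_NOT_FOUND = "strains_not_found"
    FOUND_INCOMPLETE = "found_incomplete"
    FOUND_COMPLETE = "found_complete"

    @property
    def is_candidate(self) -> bool:
        return self in (MatchStatus.SPECIES_NOT_FOUND, MatchStatus.STRAINS_NOT_FOUND)


@dataclass(frozen=True)
class ProjectRecord:
    record_id: str
    organism_name: str = ""
    species_field: str = ""
    ncbi_project_name: str = ""
    strain_field: str = ""
    culture_collection: str = ""
    project_status: ProjectStatus = ProjectStatus.INCOMPLETE

    def __post_init__(self):
        if not any(
            (
                self.organism_name,
                self.species_field,
                self.ncbi_project_name,
                self.strain_field,
                self.culture_collection,
            )
        ):
            raise ValueError(f"record {self.record_id!r} has no name field")


@dataclass(frozen=True)
class TaxonomyEntry:
    accepted_species: str
    synonyms: frozenset[str] = field(default_factory=frozenset)
    type_strain_deposits: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.accepted_species:
            raise ValueError("accepted_species must be non-empty")
        # the accepted name is always its own synonym
        object.__setattr__(
            self, "synonyms", frozenset(self.synonyms) | {self.accepted_species}
        )


@dataclass(frozen=True)
class MatchResult:
    record_id: str
    status: MatchStatus
    matched_species: Optional[str] = None
    matched_deposit: Optional[str] = None


# ---------------------------------------------------------------------------
# Strain-name normalization
# ---------------------------------------------------------------------------

_NON_WORD = re.compile(r"[^A-Za-z0-9_]+")


def normalize_strain_name(name: str) -> str:
    """Canonical form of a strain name under the three relaxation rules.

    Characters other than letters, digits and underscores are removed, the
    result is lowercased, and one trailing "t" (the type-strain marker) is
    stripped when something remains before it.  Equality testing should use
    :func:`strains_equal`, which also accepts the unstripped form.
    """
    stripped = _NON_WORD.sub("", name)
    if not stripped:
        raise ValueError(f"strain name {name!r} is empty after normalization")
    lowered = stripped.lower()
    if lowered.endswith("t") and len(lowered) >= 2:
        return lowered[:-1]
    return lowered


def strain_keys(name: str) -> frozenset[str]:
    """Both equivalence keys of a strain name: with and without a trailing 't'."""
    stripped = _NON_WORD.sub("", name)
    if not stripped:
        raise ValueError(f"strain name {name!r} is empty after normalization")
    lowered = stripped.lower()
    keys = {lowered}
    if lowered.endswith("t") and len(lowered) >= 2:
        keys.add(lowered[:-1])
    return frozenset(keys)


def strains_equal(a: str, b: str) -> bool:
    return bool(strain_keys(a) & strain_keys(b))


# ---------------------------------------------------------------------------
# Name extraction
# ---------------------------------------------------------------------------

_BINOMIAL = re.compile(r"^([A-Z][A-Za-z]*)\s+([a-z][a-z\-]+)")


def extract_species_names(record: ProjectRecord) -> list[str]:
    """Candidate species names from the organism, species and project-name fields.

    Each full field value is a candidate, and so is its leading "Genus
    species" binomial (organism names commonly carry a strain suffix, e.g.
    "Ktedonobacter racemifer SOSP1-21").
    """
    names: list[str] = []
    for value in (record.organism_name, record.species_field, record.ncbi_project_name):
        value = value.strip()
        if not value:
            continue
        if value not in names:
            names.append(value)
        m = _BINOMIAL.match(value)
        if m:
            binomial = f"{m.group(1)} {m.group(2)}"
            if binomial not in names:
                names.append(binomial)
    return names


def extract_strain_names(record: ProjectRecord, matched_species: str = "") -> list[str]:
    """Candidate strain names from all five name fields.

    Whole field values, comma/semicolon-separated chunks, and — for fields
    that start with the matched species name — the remaining suffix are all
    candidates.
    """
    names: list[str] = []

    def add(value: str) -> None:
        value = value.strip()
        if value and value not in names:
            names.append(value)

    fields = (
        record.strain_field,
        record.culture_collection,
        record.organism_name,
        record.species_field,
        record.ncbi_project_name,
    )
    for value in fields:
        value = value.strip()
        if not value:
            continue
        add(value)
        for chunk in re.split(r"[,;]", value):
            add(chunk)
        if matched_species and value.lower().startswith(matched_species.lower()):
            add(value[len(matched_species):])
    return names


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def match_record(record: ProjectRecord, taxonomy: Iterable[TaxonomyEntry]) -> MatchResult:
    """Assign one of the four statuses to a registry record.

    Species names extracted from the record are matched exactly against all
    synonyms; if none hits, the status is ``species_not_found``.  Otherwise
    the record's strain names are compared, under the relaxed equivalence,
    with the matched species' type-strain deposits; no hit gives
    ``strains_not_found``, a hit gives ``found_complete`` or
    ``found_incomplete`` according to the record's project status.  A record
    matching several taxonomy entries resolves to the first in file order.
    """
    taxonomy = list(taxonomy)
    if not taxonomy:
        raise ValueError("taxonomy must be non-empty")
    species_names = extract_species_names(record)

    matched_entry: Optional[TaxonomyEntry] = None
    matched_name = None
    hits = []
    for entry in taxonomy:
        if any(name in entry.synonyms for name in species_names):
            hits.append(entry)
    if hits:
        matched_entry = hits[0]
        matched_name = matched_entry.accepted_species
        if len({h.accepted_species for h in hits}) > 1:
            logger.warning(
                "record %s matches several species (%s); using %s",
                record.record_id,
                ", ".join(sorted({h.accepted_species for h in hits})),
                matched_name,
            )
    if matched_entry is None:
        return MatchResult(record.record_id, MatchStatus.SPECIES_NOT_FOUND)

    strain_names = extract_strain_names(record, matched_species=matched_name)
    deposit_keys = {}
    for deposit in matched_entry.type_strain_deposits:
        try:
            for key in strain_keys(deposit):
                deposit_keys.setdefault(key, deposit)
        except ValueError:
            continue
    for candidate in strain_names:
        try:
            keys = strain_keys(candidate)
        except ValueError:
            continue
        for key in keys:
            if key in deposit_keys:
                status = (
                    MatchStatus.FOUND_COMPLETE
                    if record.project_status is ProjectStatus.COMPLETE
                    else MatchStatus.FOUND_INCOMPLETE
                )
                return MatchResult(record.record_id, status, matched_name, deposit_keys[key])
    return MatchResult(record.record_id, MatchStatus.STRAINS_NOT_FOUND, matched_name)


def match_registry(
    records: Iterable[ProjectRecord], taxonomy: Iterable[TaxonomyEntry]
) -> list[MatchResult]:
    taxonomy = list(taxonomy)
    return [match_record(r, taxonomy) for r in records]


def candidate_filter(results: Iterable[MatchResult]) -> set[str]:
    """Record ids still worth targeting: species or strain unknown to the registry."""
    return {r.record_id for r in results if r.status.is_candidate}


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_REGISTRY_COLUMNS = [
    "record_id",
    "organism_name",
    "species",
    "ncbi_project_name",
    "strain",
    "culture_collection",
    "status",
]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{what} is missing column(s): {', '.join(missing)}")


def read_registry_tsv(path) -> list[ProjectRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _REGISTRY_COLUMNS, "registry table")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ProjectRecord(
                record_id=row.record_id,
                organism_name=row.organism_name,
                species_field=row.species,
                ncbi_project_name=row.ncbi_project_name,
                strain_field=row.strain,
                culture_collection=row.culture_collection,
                project_status=ProjectStatus(row.status),
            )
        )
    return records


def read_taxonomy_tsv(path) -> list[TaxonomyEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df, ["accepted_species", "synonyms", "type_strain_deposits"], "taxonomy table"
    )
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            TaxonomyEntry(
                accepted_species=row.accepted_species,
                synonyms=frozenset(s for s in row.synonyms.split(";") if s),
                type_strain_deposits=frozenset(
                    s for s in row.type_strain_deposits.split(";") if s
                ),
            )
        )
    return entries


def write_matches_tsv(results: Iterable[MatchResult], path) -> None:
    results = list(results)
    df = pd.DataFrame(
        {
            "record_id": [r.record_id for r in results],
            "status": [r.status.value for r in results],
            "matched_species": [r.matched_species or "" for r in results],
            "matched_deposit": [r.matched_deposit or "" for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
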