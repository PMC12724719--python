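"""Assembly of validated table rows into an in-memory protein universe.

The universe is the counting substrate of the screen: one record per
protein carrying its taxon, length, transmembrane label, the *set* of
domains annotated on it (a protein contributes at most once per domain to
any count — the frequencies count proteins, not domain instances), and an
optional orthogroup id. Most proteins in a realistic corpus have no
orthogroup; that is a legal state.

Subspecies are resolved to their parent species by exactly one parent step;
deeper chains under rank SUBSPECIES are treated as an input error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io_formats import (
    DomainAnnotationRow,
    OrthogroupAssignmentRow,
    ProteinTableRow,
    Rank,
    TaxonomyRow,
    TMStatus,
)
from . import ortho_filter

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class ProteinRecord:
    accession: str
    taxon_id: int
    length_aa: int
    tm_status: TMStatus
    domain_ids: set[str] = field(default_factory=set)
    orthogroup_id: Optional[str] = None


@dataclass(slots=True)
class BuildLog:
    """Bookkeeping from universe assembly: what was joined and what was dropped."""

    n_proteins: int = 0
    n_domain_rows: int = 0
    n_domain_rows_unknown_accession: int = 0
    n_assignments_in: int = 0
    n_assignments_unknown_accession: int = 0
    n_assignments_taxon_mismatch: int = 0
    n_assignments_single_species_og: int = 0
    n_assignments_kept: int = 0


class ProteinUniverse:
    """All proteins under study, with species-resolved taxa.

    ``species_of`` maps every taxon id to its species-level taxon id
    (identity for species, one parent step for subspecies).
    """

    def __init__(self, records: Iterable[ProteinRecord], species_of: dict[int, int]):
        self._by_accession: dict[str, ProteinRecord] = {}
        for rec in records:
            if rec.accession in self._by_accession:
                raise ValueError(f"duplicate accession {rec.accession!r} in universe")
            self._by_accession[rec.accession] = rec
        self.species_of = species_of
        self.build_log: Optional[BuildLog] = None

    def __len__(self) -> int:
        return len(self._by_accession)

    def __iter__(self):
        return iter(self._by_accession.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._by_accession[accession]

    @property
    def records(self) -> list[ProteinRecord]:
        return list(self._by_accession.values())

    def species(self, record: ProteinRecord) -> int:
        return self.species_of.get(record.taxon_id, record.taxon_id)


def resolve_species(taxonomy: Sequence[TaxonomyRow]) -> dict[int, int]:
    """Map each taxon to its species-level taxon (subspecies -> parent)."""
    rank_of = {t.taxon_id: t.rank for t in taxonomy}
    species_of: dict[int, int] = {}
    for t in taxonomy:
        if t.rank is Rank.SUBSPECIES:
            if rank_of.get(t.parent_id) is Rank.SUBSPECIES:
                raise ValueError(
                    f"taxon {t.taxon_id}: subspecies parent {t.parent_id} is itself a "
                    "subspecies; chains deeper than one step are not supported"
                )
            species_of[t.taxon_id] = t.parent_id
        else:
            species_of[t.taxon_id] = t.taxon_id
    return species_of


def apply_length_filter(
    records: Sequence[ProteinTableRow], max_length_aa: int
) -> tuple[list[ProteinTableRow], int]:
    """Drop proteins strictly longer than ``max_length_aa`` amino acids.

    "Exceeded" is read as strictly greater: a protein of exactly the
    threshold length is kept.
    """
    kept = [r for r in records if r.length_aa <= max_length_aa]
    return kept, len(records) - len(kept)


def build_universe(
    proteins: Sequence[ProteinTableRow],
    domains: Sequence[DomainAnnotationRow],
    orthogroup_assignments: Sequence[OrthogroupAssignmentRow],
    taxonomy: Sequence[TaxonomyRow],
    *,
    filter_assignments: bool = True,
    collapse_subspecies: bool = True,
) -> ProteinUniverse:
    """Join domains and (filtered) orthogroup assignments onto proteins.

    Domain rows referencing unknown accessions are dropped with a logged
    count, never fatally. Orthogroup assignments pass through the
    taxon-consistency and single-species filters unless
    ``filter_assignments`` is False (the rows are then attached verbatim).
    ``collapse_subspecies`` controls whether the single-species rule counts
    subspecies as their parent species.
    """
    species_of = resolve_species(taxonomy)
    log = BuildLog(n_proteins=len(proteins), n_domain_rows=len(domains))

    records = {
        p.accession: ProteinRecord(p.accession, p.taxon_id, p.length_aa, p.tm_status)
        for p in proteins
    }
    for row in domains:
        rec = records.get(row.accession)
        if rec is None:
            log.n_domain_rows_unknown_accession += 1
            continue
        rec.domain_ids.add(row.domain_id)
    if log.n_domain_rows_unknown_accession:
        logger.info(
            "dropped %d domain row(s) for unknown accessions",
            log.n_domain_rows_unknown_accession,
        )

    assignments = [a for a in orthogroup_assignments if a.accession in records]
    log.n_assignments_in = len(orthogroup_assignments)
    log.n_assignments_unknown_accession = len(orthogroup_assignments) - len(assignments)
    if log.n_assignments_unknown_accession:
        logger.info(
            "dropped %d orthogroup assignment(s) for unknown accessions",
            log.n_assignments_unknown_accession,
        )

    if filter_assignments:
        protein_taxa = {a.accession: records[a.accession].taxon_id for a in assignments}
        kept, n_mismatch = ortho_filter.filter_taxon_consistency(
            assignments, protein_taxa, taxonomy
        )
        log.n_assignments_taxon_mismatch = n_mismatch
        resolver = species_of if collapse_subspecies else {t: t for t in species_of}
        kept, n_single = ortho_filter.drop_single_species_orthogroups(
            kept, protein_taxa, resolver
        )
        log.n_assignments_single_species_og = n_single
        assignments = kept
    log.n_assignments_kept = len(assignments)

    for a in assignments:
        records[a.accession].orthogroup_id = a.orthogroup_id

    universe = ProteinUniverse(records.values(), species_of)
    universe.build_log = log
    return universe
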