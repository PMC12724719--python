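"""Quality filters on orthogroup assignments.

Orthology mappers occasionally assign a protein to an orthogroup under a
taxon that disagrees with the protein's own taxonomic annotation, and some
orthogroups end up represented by a single species, which carries no
cross-species conservation signal. Two filters remove both cases:

1. taxon consistency — the protein's taxon must equal the taxon claimed by
   the orthology resource, or be a subspecies whose parent is that taxon;
2. single-species removal — an orthogroup must span >= 2 distinct species
   after subspecies are collapsed to their parent species.

Consistency runs first: its drops can turn a multi-species orthogroup into
a single-species one, so the single-species rule is evaluated on the
surviving assignments. The ordered pass is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import OrthogroupAssignmentRow, Rank, TaxonomyRow


@dataclass(slots=True)
class FilteredAssignments:
    kept: list[OrthogroupAssignmentRow]
    dropped_taxon_mismatch: int
    dropped_single_species_og: int


def filter_taxon_consistency(
    assignments: Sequence[OrthogroupAssignmentRow],
    protein_taxa: Mapping[str, int],
    taxonomy: Sequence[TaxonomyRow],
) -> tuple[list[OrthogroupAssignmentRow], int]:
    """Keep assignments whose protein taxon matches the resource's taxon.

    Kept iff protein taxon == og_taxon_id, or the protein taxon has rank
    SUBSPECIES and its parent is og_taxon_id.
    """
    rank_of = {t.taxon_id: t.rank for t in taxonomy}
    parent_of = {t.taxon_id: t.parent_id for t in taxonomy}
    kept: list[OrthogroupAssignmentRow] = []
    for a in assignments:
        if a.accession not in protein_taxa:
            raise KeyError(f"accession {a.accession!r} missing from protein taxa map")
        taxon = protein_taxa[a.accession]
        if taxon == a.og_taxon_id:
            kept.append(a)
        elif rank_of.get(taxon) is Rank.SUBSPECIES and parent_of.get(taxon) == a.og_taxon_id:
            kept.append(a)
    return kept, len(assignments) - len(kept)


def drop_single_species_orthogroups(
    assignments: Sequence[OrthogroupAssignmentRow],
    protein_taxa: Mapping[str, int],
    species_of: Mapping[int, int],
) -> tuple[list[OrthogroupAssignmentRow], int]:
    """Remove all assignments of orthogroups spanning fewer than two species.

    Species are counted after resolving each member's (protein-side) taxon
    through ``species_of``; two subspecies of one species count as one.
    """
    species_in_og: dict[str, set[int]] = {}
    for a in assignments:
        taxon = protein_taxa[a.accession]
        species_in_og.setdefault(a.orthogroup_id, set()).add(species_of.get(taxon, taxon))
    kept = [a for a in assignments if len(species_in_og[a.orthogroup_id]) >= 2]
    return kept, len(assignments) - len(kept)


def apply_filters(
    assignments: Sequence[OrthogroupAssignmentRow],
    protein_taxa: Mapping[str, int],
    taxonomy: Sequence[TaxonomyRow],
    species_of: Mapping[int, int],
) -> FilteredAssignments:
    """Run both filters in the fixed order: consistency, then single-species."""
    kept, n_mismatch = filter_taxon_consistency(assignments, protein_taxa, taxonomy)
    kept, n_single = drop_single_species_orthogroups(kept, protein_taxa, species_of)
    return FilteredAssignments(kept, n_mismatch, n_single)
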