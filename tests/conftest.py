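"""Shared builders for hand-crafted universes and table rows."""

from __future__ import annotations

import pytest

from mbtrscreen import (
    OrthogroupAssignmentRow,
    ProteinRecord,
    ProteinTableRow,
    ProteinUniverse,
    Rank,
    TaxonomyRow,
    TMStatus,
)

HUMAN, MOUSE, ZEBRAFISH = 9606, 10090, 7955
HUMAN_SUBSP = 95001

BASE_TAXONOMY = [
    TaxonomyRow(HUMAN, 0, Rank.SPECIES),
    TaxonomyRow(MOUSE, 0, Rank.SPECIES),
    TaxonomyRow(ZEBRAFISH, 0, Rank.SPECIES),
    TaxonomyRow(HUMAN_SUBSP, HUMAN, Rank.SUBSPECIES),
]

SPECIES_OF = {HUMAN: HUMAN, MOUSE: MOUSE, ZEBRAFISH: ZEBRAFISH, HUMAN_SUBSP: HUMAN}


def record(acc, taxon=HUMAN, status=TMStatus.NON_TM, domains=(), og=None, length=500):
    return ProteinRecord(acc, taxon, length, status, set(domains), og)


def universe_of(*records):
    """A ProteinUniverse over the base taxonomy, bypassing assignment filters."""
    return ProteinUniverse(records, dict(SPECIES_OF))


def protein_row(acc, taxon=HUMAN, length=500, status=TMStatus.NON_TM):
    return ProteinTableRow(acc, taxon, length, status)


def assignment(acc, og, og_taxon=HUMAN):
    return OrthogroupAssignmentRow(acc, og, og_taxon)


@pytest.fixture
def base_taxonomy():
    return list(BASE_TAXONOMY)
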