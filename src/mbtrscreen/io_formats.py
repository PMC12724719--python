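"""Readers and writers for the screen's tabular dialects.

Every table the pipeline touches is header-bearing, tab-separated, UTF-8,
unquoted — the native dialect of the upstream tools whose outputs feed the
screen (UniProt dumps, eggNOG-mapper, InterProScan). Parsers validate each
row against the type invariants and report 1-based line numbers (header =
line 1) in every error; row order is preserved. Unknown columns are ignored
with a logged warning so real annotation dumps with extra columns pass
through unchanged.

A secondary reader accepts the InterProScan tab-separated dialect and keeps
only Pfam signature hits (accessions matching ``PF`` + 5 digits).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

PFAM_ACCESSION_RE = re.compile(r"^PF\d{5}$")


class TMStatus(str, Enum):
    """Per-protein transmembrane label from an external topology predictor."""

    TM = "TM"
    NON_TM = "NON_TM"
    UNASSIGNED = "UNASSIGNED"


class Rank(str, Enum):
    SPECIES = "SPECIES"
    SUBSPECIES = "SUBSPECIES"
    OTHER = "OTHER"


class SchemaError(ValueError):
    """A required column is missing from a table header."""


class TableValidationError(ValueError):
    """A row violates a type invariant; message carries the 1-based line."""


@dataclass(frozen=True, slots=True)
class ProteinTableRow:
    accession: str
    taxon_id: int
    length_aa: int
    tm_status: TMStatus


@dataclass(frozen=True, slots=True)
class DomainAnnotationRow:
    accession: str
    domain_id: str
    start: Optional[int] = None
    end: Optional[int] = None


@dataclass(frozen=True, slots=True)
class OrthogroupAssignmentRow:
    accession: str
    orthogroup_id: str
    og_taxon_id: int


@dataclass(frozen=True, slots=True)
class TaxonomyRow:
    taxon_id: int
    parent_id: int  # 0 = root
    rank: Rank


def _open_reader(path: str | Path, required: Sequence[str]) -> tuple[csv.DictReader, object]:
    handle = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(handle, delimiter="\t")
    header = reader.fieldnames
    if header is None:
        handle.close()
        raise SchemaError(f"{path}: empty file, expected header with {list(required)}")
    missing = [c for c in required if c not in header]
    if missing:
        handle.close()
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in header if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    return reader, handle


def _parse_int(value: str, field: str, line: int, minimum: int) -> int:
    try:
        parsed = int(value)
    except (TypeError, ValueError):
        raise TableValidationError(f"line {line}: {field} {value!r} is not an integer")
    if parsed < minimum:
        raise TableValidationError(f"line {line}: {field} {parsed} < {minimum}")
    return parsed


def read_protein_table(path: str | Path) -> list[ProteinTableRow]:
    """Read the canonical protein table (accession, taxon_id, length_aa, tm_status)."""
    reader, handle = _open_reader(path, ["accession", "taxon_id", "length_aa", "tm_status"])
    rows: list[ProteinTableRow] = []
    seen: dict[str, int] = {}
    with handle:
        for line_no, raw in enumerate(reader, start=2):
            acc = (raw["accession"] or "").strip()
            if not acc:
                raise TableValidationError(f"line {line_no}: empty accession")
            if acc in seen:
                raise TableValidationError(
                    f"line {line_no}: duplicate accession {acc!r} (first seen line {seen[acc]})"
                )
            seen[acc] = line_no
            try:
                status = TMStatus(raw["tm_status"])
            except ValueError:
                raise TableValidationError(
                    f"line {line_no}: tm_status {raw['tm_status']!r} not one of "
                    f"{[s.value for s in TMStatus]}"
                )
            rows.append(
                ProteinTableRow(
                    accession=acc,
                    taxon_id=_parse_int(raw["taxon_id"], "taxon_id", line_no, 1),
                    length_aa=_parse_int(raw["length_aa"], "length_aa", line_no, 1),
                    tm_status=status,
                )
            )
    return rows


def read_domain_table(path: str | Path) -> list[DomainAnnotationRow]:
    """Read the canonical domain table; start/end are optional per row."""
    reader, handle = _open_reader(path, ["accession", "domain_id", "start", "end"])
    rows: list[DomainAnnotationRow] = []
    seen: set[tuple] = set()
    with handle:
        for line_no, raw in enumerate(reader, start=2):
            acc = (raw["accession"] or "").strip()
            dom = (raw["domain_id"] or "").strip()
            if not acc or not dom:
                raise TableValidationError(f"line {line_no}: empty accession or domain_id")
            start = raw["start"].strip() if raw["start"] else ""
            end = raw["end"].strip() if raw["end"] else ""
            start_i = _parse_int(start, "start", line_no, 1) if start else None
            end_i = _parse_int(end, "end", line_no, 1) if end else None
            if start_i is not None and end_i is not None and start_i > end_i:
                raise TableValidationError(f"line {line_no}: start {start_i} > end {end_i}")
            key = (acc, dom, start_i, end_i)
            if key in seen:
                raise TableValidationError(f"line {line_no}: duplicate annotation {key}")
            seen.add(key)
            rows.append(DomainAnnotationRow(acc, dom, start_i, end_i))
    return rows


def read_interproscan_table(path: str | Path) -> tuple[list[DomainAnnotationRow], int]:
    """Read InterProScan TSV output, keeping Pfam signature hits only.

    Columns (1-based): 1 protein accession, 4 analysis, 5 signature accession,
    7 start, 8 stop. Rows whose signature accession does not match the Pfam
    pattern are dropped; the drop count is returned and logged.
    InterProScan output has no header.
    """
    rows: list[DomainAnnotationRow] = []
    dropped = 0
    seen: set[tuple] = set()
    with open(path, newline="", encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise TableValidationError(
                    f"line {line_no}: expected >= 8 tab-separated columns, got {len(fields)}"
                )
            signature = fields[4].strip()
            if not PFAM_ACCESSION_RE.match(signature):
                dropped += 1
                continue
            start_i = _parse_int(fields[6], "start", line_no, 1)
            end_i = _parse_int(fields[7], "end", line_no, 1)
            if start_i > end_i:
                raise TableValidationError(f"line {line_no}: start {start_i} > end {end_i}")
            key = (fields[0].strip(), signature, start_i, end_i)
            if key in seen:
                continue
            seen.add(key)
            rows.append(DomainAnnotationRow(*key))
    if dropped:
        logger.info("%s: dropped %d non-Pfam signature row(s)", path, dropped)
    return rows, dropped


def read_orthogroup_table(path: str | Path) -> list[OrthogroupAssignmentRow]:
    reader, handle = _open_reader(path, ["accession", "orthogroup_id", "og_taxon_id"])
    rows: list[OrthogroupAssignmentRow] = []
    seen: dict[str, int] = {}
    with handle:
        for line_no, raw in enumerate(reader, start=2):
            acc = (raw["accession"] or "").strip()
            og = (raw["orthogroup_id"] or "").strip()
            if not acc or not og:
                raise TableValidationError(f"line {line_no}: empty accession or orthogroup_id")
            if acc in seen:
                raise TableValidationError(
                    f"line {line_no}: accession {acc!r} assigned to a second orthogroup "
                    f"(first seen line {seen[acc]})"
                )
            seen[acc] = line_no
            rows.append(
                OrthogroupAssignmentRow(acc, og, _parse_int(raw["og_taxon_id"], "og_taxon_id", line_no, 1))
            )
    return rows


def read_taxonomy_table(path: str | Path) -> list[TaxonomyRow]:
    """Read the taxonomy table and check parent chains are acyclic."""
    reader, handle = _open_reader(path, ["taxon_id", "parent_id", "rank"])
    rows: list[TaxonomyRow] = []
    seen: dict[int, int] = {}
    with handle:
        for line_no, raw in enumerate(reader, start=2):
            taxon = _parse_int(raw["taxon_id"], "taxon_id", line_no, 1)
            parent = _parse_int(raw["parent_id"], "parent_id", line_no, 0)
            if taxon == parent:
                raise TableValidationError(f"line {line_no}: taxon {taxon} is its own parent")
            if taxon in seen:
                raise TableValidationError(
                    f"line {line_no}: duplicate taxon_id {taxon} (first seen line {seen[taxon]})"
                )
            seen[taxon] = line_no
            try:
                rank = Rank(raw["rank"])
            except ValueError:
                raise TableValidationError(f"line {line_no}: rank {raw['rank']!r} unknown")
            rows.append(TaxonomyRow(taxon, parent, rank))
    parent_of = {r.taxon_id: r.parent_id for r in rows}
    for r in rows:
        slow, node = r.taxon_id, r.taxon_id
        visited = set()
        while node in parent_of and parent_of[node] != 0:
            if node in visited:
                raise TableValidationError(f"taxonomy cycle involving taxon {slow}")
            visited.add(node)
            node = parent_of[node]
    return rows


def lengths_from_fasta(path: str | Path) -> dict[str, int]:
    """Sequence lengths (non-whitespace residue counts) keyed by record id."""
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise TableValidationError(f"duplicate FASTA id {record.id!r}")
        n = len(str(record.seq).replace(" ", "").replace("\t", ""))
        if n == 0:
            raise TableValidationError(f"FASTA record {record.id!r} has an empty sequence")
        lengths[record.id] = n
    return lengths


# --- writers (canonical dialect: header, tab-separated, no quoting) ---------


def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE)
        writer.writerow(header)
        writer.writerows(rows)


def write_protein_table(rows: Iterable[ProteinTableRow], path: str | Path) -> None:
    _write_tsv(
        path,
        ["accession", "taxon_id", "length_aa", "tm_status"],
        ((r.accession, r.taxon_id, r.length_aa, r.tm_status.value) for r in rows),
    )


def write_domain_table(rows: Iterable[DomainAnnotationRow], path: str | Path) -> None:
    _write_tsv(
        path,
        ["accession", "domain_id", "start", "end"],
        (
            (r.accession, r.domain_id, r.start if r.start is not None else "", r.end if r.end is not None else "")
            for r in rows
        ),
    )


def write_orthogroup_table(rows: Iterable[OrthogroupAssignmentRow], path: str | Path) -> None:
    _write_tsv(
        path,
        ["accession", "orthogroup_id", "og_taxon_id"],
        ((r.accession, r.orthogroup_id, r.og_taxon_id) for r in rows),
    )


def write_taxonomy_table(rows: Iterable[TaxonomyRow], path: str | Path) -> None:
    _write_tsv(
        path,
        ["taxon_id", "parent_id", "rank"],
        ((r.taxon_id, r.parent_id, r.rank.value) for r in rows),
    )


PAIR_REPORT_COLUMNS = [
    "domain_id",
    "orthogroup_id",
    "n_total_og",
    "n_tm_og",
    "f_all",
    "f_og",
    "score",
    "f_all_full",
    "f_og_full",
    "score_full",
]


def write_pair_report(pairs: Iterable, path: str | Path) -> None:
    """Write the ranked pair table.

    Frequencies and the score are rendered at 2 decimals (the precision the
    candidate tables are reported at) with full-precision shortest-repr
    values in parallel ``*_full`` columns, so re-reading reproduces the
    floats exactly.
    """

    def render(p):
        return (
            p.domain_id,
            p.orthogroup_id,
            p.n_total_og,
            p.n_tm_og,
            f"{p.f_all:.2f}",
            f"{p.f_og:.2f}",
            f"{p.score:.2f}",
            repr(float(p.f_all)),
            repr(float(p.f_og)),
            repr(float(p.score)),
        )

    _write_tsv(path, PAIR_REPORT_COLUMNS, (render(p) for p in pairs))


def read_pair_report(path: str | Path) -> list[dict]:
    """Re-read a pair report; full-precision columns come back as exact floats."""
    reader, handle = _open_reader(path, PAIR_REPORT_COLUMNS)
    out = []
    with handle:
        for raw in reader:
            out.append(
                {
                    "domain_id": raw["domain_id"],
                    "orthogroup_id": raw["orthogroup_id"],
                    "n_total_og": int(raw["n_total_og"]),
                    "n_tm_og": int(raw["n_tm_og"]),
                    "f_all": float(raw["f_all_full"]),
                    "f_og": float(raw["f_og_full"]),
                    "score": float(raw["score_full"]),
                }
            )
    return out
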