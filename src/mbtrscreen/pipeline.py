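"""End-to-end orchestration: ingest -> length filter -> assembly -> screen -> report.

One reproducible run over the four canonical tables, with a machine-readable
run summary mirroring the screen's filtering funnel (input counts, length
exclusions, assignment drops, and the pair counts after each cascade stage).
Counting is two-pass (global, then per-orthogroup) over dictionaries keyed by
domain and (domain, orthogroup), so memory scales with the number of distinct
keys rather than the protein count.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io_formats
from .io_formats import TMStatus, write_pair_report, _write_tsv
from .screen import ScreenConfig, ScreenFunnel, run_screen_on_universe
from .universe import apply_length_filter, build_universe

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class RunSummary:
    """Machine-readable provenance and funnel counts for one screen run."""

    n_proteins_read: int = 0
    n_overlength_excluded: int = 0
    n_tm: int = 0
    n_non_tm: int = 0
    n_tm_unassigned: int = 0
    n_domain_rows_read: int = 0
    n_domain_rows_unknown_accession: int = 0
    n_assignments_read: int = 0
    n_assignments_unknown_accession: int = 0
    n_assignments_taxon_mismatch: int = 0
    n_assignments_single_species_og: int = 0
    n_assignments_kept: int = 0
    n_orthogroups_kept: int = 0
    n_pairs_scored: int = 0
    n_pairs_after_min_tm: int = 0
    n_pairs_after_cutoff: int = 0
    n_pairs_after_required_taxa: int = 0
    input_digests: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)

    def as_rows(self) -> list[tuple[str, str]]:
        rows: list[tuple[str, str]] = []
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if isinstance(value, dict):
                rows.extend((f"{name}.{k}", str(v)) for k, v in sorted(value.items()))
            else:
                rows.append((name, str(value)))
        return rows

    def write(self, path: str | Path) -> None:
        _write_tsv(path, ["key", "value"], self.as_rows())


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_screen(
    proteins_path: str | Path,
    domains_path: str | Path,
    orthogroups_path: str | Path,
    taxonomy_path: str | Path,
    out_report: str | Path,
    config: Optional[ScreenConfig] = None,
    out_summary: Optional[str | Path] = None,
    fasta_path: Optional[str | Path] = None,
) -> tuple[ScreenFunnel, RunSummary]:
    """Run the full screen and write the ranked pair report.

    If ``fasta_path`` is given, missing lengths are irrelevant — the protein
    table is authoritative here — but the FASTA digest is still recorded.
    Partial outputs are removed if any stage fails.
    """
    config = config or ScreenConfig()
    outputs = [Path(out_report)] + ([Path(out_summary)] if out_summary else [])
    try:
        summary = RunSummary()
        for name, p in [
            ("proteins", proteins_path),
            ("domains", domains_path),
            ("orthogroups", orthogroups_path),
            ("taxonomy", taxonomy_path),
        ] + ([("fasta", fasta_path)] if fasta_path else []):
            summary.input_digests[name] = _sha256(p)
        summary.config_echo = {
            "min_tm_in_pair": config.min_tm_in_pair,
            "log10_cutoff": config.log10_cutoff,
            "required_taxa": ",".join(str(t) for t in sorted(config.required_taxa)),
            "require_domain_in_required_taxon": config.require_domain_in_required_taxon,
            "max_length_aa": config.max_length_aa,
            "count_unassigned_tm": config.count_unassigned_tm,
            "min_tm_counts_domain_carriers": config.min_tm_counts_domain_carriers,
        }

        try:
            protein_rows = io_formats.read_protein_table(proteins_path)
            domain_rows = io_formats.read_domain_table(domains_path)
            og_rows = io_formats.read_orthogroup_table(orthogroups_path)
            taxonomy_rows = io_formats.read_taxonomy_table(taxonomy_path)
        except Exception as exc:
            raise RuntimeError(f"[ingest] {exc}") from exc

        summary.n_proteins_read = len(protein_rows)
        protein_rows, n_excluded = apply_length_filter(protein_rows, config.max_length_aa)
        summary.n_overlength_excluded = n_excluded
        summary.n_tm = sum(r.tm_status is TMStatus.TM for r in protein_rows)
        summary.n_non_tm = sum(r.tm_status is TMStatus.NON_TM for r in protein_rows)
        summary.n_tm_unassigned = sum(r.tm_status is TMStatus.UNASSIGNED for r in protein_rows)

        try:
            universe = build_universe(protein_rows, domain_rows, og_rows, taxonomy_rows)
        except Exception as exc:
            raise RuntimeError(f"[assemble] {exc}") from exc
        log = universe.build_log
        summary.n_domain_rows_read = log.n_domain_rows
        summary.n_domain_rows_unknown_accession = log.n_domain_rows_unknown_accession
        summary.n_assignments_read = log.n_assignments_in
        summary.n_assignments_unknown_accession = log.n_assignments_unknown_accession
        summary.n_assignments_taxon_mismatch = log.n_assignments_taxon_mismatch
        summary.n_assignments_single_species_og = log.n_assignments_single_species_og
        summary.n_assignments_kept = log.n_assignments_kept
        summary.n_orthogroups_kept = len(
            {r.orthogroup_id for r in universe if r.orthogroup_id is not None}
        )

        try:
            funnel, _domain_stats = run_screen_on_universe(universe, config)
        except Exception as exc:
            raise RuntimeError(f"[screen] {exc}") from exc
        summary.n_pairs_scored = funnel.n_input
        summary.n_pairs_after_min_tm = funnel.n_after_min_tm
        summary.n_pairs_after_cutoff = funnel.n_after_cutoff
        summary.n_pairs_after_required_taxa = funnel.n_after_required_taxa

        try:
            write_pair_report(funnel.pairs, out_report)
            if out_summary:
                summary.write(out_summary)
        except Exception as exc:
            raise RuntimeError(f"[report] {exc}") from exc

        for key, value in summary.as_rows():
            logger.info("%s=%s", key, value)
        return funnel, summary
    except Exception:
        for path in outputs:
            path.unlink(missing_ok=True)
        raise
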