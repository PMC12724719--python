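"""Broad-taxa domain expansion.

Given a target domain (e.g. the NDT80/PhoG-like DNA-binding domain), select
every transmembrane protein carrying it while excluding proteins that also
carry any disqualifying domain (e.g. the MYRF ICA and MYRF C-terminal
domains, to keep canonical MYRF orthologs out of the candidate set), and
summarize per-orthogroup transmembrane frequencies over the carriers. The
universe here may be broader than the screen's (the expansion is typically
run across all eukaryotes rather than vertebrates only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .io_formats import TMStatus
from .screen import PairStats
from .universe import ProteinRecord, ProteinUniverse

logger = logging.getLogger(__name__)

UNASSIGNED_OG = "UNASSIGNED"


@dataclass(frozen=True)
class ExpansionQuery:
    target_domain: str
    exclude_domains: frozenset[str] = field(default_factory=frozenset)
    require_tm: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "exclude_domains", frozenset(self.exclude_domains))
        if self.target_domain in self.exclude_domains:
            raise ValueError(f"target domain {self.target_domain!r} cannot also be excluded")


def run_expansion(
    universe: ProteinUniverse, query: ExpansionQuery
) -> tuple[list[ProteinRecord], list[PairStats]]:
    """Select matching proteins and summarize per-orthogroup frequencies.

    A protein matches iff it carries the target domain, carries none of the
    excluded domains, and (when ``require_tm``) is transmembrane. The
    per-orthogroup summary counts every exclusion-surviving carrier of the
    target domain with an assigned TM label (TM or NON_TM) regardless of
    ``require_tm`` — so f_OG is the within-orthogroup TM frequency of the
    domain, comparable to the screen's pair statistics. Carriers without an
    orthogroup are grouped under the sentinel id "UNASSIGNED".
    """
    matches: list[ProteinRecord] = []
    summary: dict[str, PairStats] = {}
    seen_target = False
    for rec in universe:
        if query.target_domain not in rec.domain_ids:
            continue
        seen_target = True
        if rec.domain_ids & query.exclude_domains:
            continue
        if not query.require_tm or rec.tm_status is TMStatus.TM:
            matches.append(rec)
        if rec.tm_status is TMStatus.UNASSIGNED:
            continue
        og = rec.orthogroup_id if rec.orthogroup_id is not None else UNASSIGNED_OG
        entry = summary.get(og)
        if entry is None:
            entry = summary[og] = PairStats(query.target_domain, og, 0, 0)
        entry.n_total_og += 1
        if rec.tm_status is TMStatus.TM:
            entry.n_tm_og += 1
    if not seen_target:
        logger.warning("target domain %s absent from the universe", query.target_domain)
    ranked = sorted(summary.values(), key=lambda p: (-p.f_og, -p.n_tm_og, p.orthogroup_id))
    return matches, ranked
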