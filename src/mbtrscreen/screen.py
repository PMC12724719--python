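"""The conservation-to-frequency screen.

For each domain X, the global transmembrane frequency is

    f_all(X) = n(TM proteins with X) / n(proteins with X)

computed over the whole universe, and within each orthogroup OG

    f_OG(X, OG) = n(TM proteins with X in OG) / n(proteins with X in OG).

The ranking statistic is the conservation-to-frequency ratio
f_OG / f_all: a domain that rarely co-occurs with a transmembrane segment
globally (low f_all) but does so consistently within one orthologous
family (high f_OG) scores high, which is the signature of a membrane-bound
transcriptional regulator whose domain combination is rare but conserved.

Candidates are then filtered: pairs backed by fewer than 10 transmembrane
proteins are removed (small orthogroups produce spuriously large ratios),
the score must strictly exceed 10^0.3 (~1.995), and the orthogroup must
contain at least one protein from a required reference species (human or
mouse by default) so the candidate is experimentally actionable.

Proteins with an UNASSIGNED transmembrane label are evidence for neither
class; by default they are excluded from both numerator and denominator of
every frequency (``count_unassigned_tm=True`` instead counts them in
denominators only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Mapping, Optional, Sequence

from .io_formats import TMStatus
from .universe import ProteinUniverse


@dataclass(slots=True)
class DomainStats:
    """Global TM/total counts and f_all for one domain."""

    domain_id: str
    n_total: int
    n_tm: int

    @property
    def f_all(self) -> float:
        return self.n_tm / self.n_total

    @property
    def excluded(self) -> bool:
        """Domains never paired with a transmembrane segment are excluded."""
        return self.n_tm == 0


@dataclass(slots=True)
class PairStats:
    """Per-(domain, orthogroup) counts, f_OG, and the ratio score."""

    domain_id: str
    orthogroup_id: str
    n_total_og: int
    n_tm_og: int
    f_all: float = math.nan
    score: float = math.nan

    @property
    def f_og(self) -> float:
        return self.n_tm_og / self.n_total_og


@dataclass
class ScreenConfig:
    """All thresholds and reference-taxon requirements of the filter cascade.

    min_tm_in_pair
        Minimum transmembrane proteins backing a pair (default 10).
    log10_cutoff
        Score must strictly exceed ``10**log10_cutoff`` (default 0.3, i.e.
        ~1.995; the comparison uses the full-precision power, not the
        rounded constant).
    required_taxa
        Species-level taxon ids of which at least one must be represented
        in the orthogroup (default human 9606 and mouse 10090).
    require_domain_in_required_taxon
        If True (default), the required-taxon protein must itself carry the
        pair's domain; if False, mere orthogroup membership suffices.
    max_length_aa
        Length filter applied upstream (default 8300 aa).
    count_unassigned_tm
        If True, UNASSIGNED-status proteins enter frequency denominators
        (never numerators); default False excludes them from both.
    min_tm_counts_domain_carriers
        If True (default), the >=10-TM filter counts TM proteins carrying
        the domain inside the orthogroup (n_tm_og); if False it counts all
        TM proteins in the orthogroup.
    """

    min_tm_in_pair: int = 10
    log10_cutoff: float = 0.3
    required_taxa: frozenset[int] = dataclass_field(default_factory=lambda: frozenset({9606, 10090}))
    require_domain_in_required_taxon: bool = True
    max_length_aa: int = 8300
    count_unassigned_tm: bool = False
    min_tm_counts_domain_carriers: bool = True

    def __post_init__(self) -> None:
        if self.min_tm_in_pair < 1:
            raise ValueError("min_tm_in_pair must be >= 1")
        if not math.isfinite(self.log10_cutoff):
            raise ValueError("log10_cutoff must be finite")
        self.required_taxa = frozenset(self.required_taxa)

    @property
    def score_cutoff(self) -> float:
        return 10.0 ** self.log10_cutoff


def _counts_denominator(status: TMStatus, config: ScreenConfig) -> bool:
    if status is TMStatus.UNASSIGNED:
        return config.count_unassigned_tm
    return True


def compute_f_all(
    universe: ProteinUniverse, config: Optional[ScreenConfig] = None
) -> dict[str, DomainStats]:
    """Global per-domain TM frequencies over the whole universe.

    Orthogroup membership is irrelevant here: the denominator is every
    protein carrying the domain, assigned or not.
    """
    config = config or ScreenConfig()
    if len(universe) == 0:
        raise ValueError("cannot compute f_all over an empty universe")
    stats: dict[str, DomainStats] = {}
    for rec in universe:
        if not _counts_denominator(rec.tm_status, config):
            continue
        is_tm = rec.tm_status is TMStatus.TM
        for domain in rec.domain_ids:
            entry = stats.get(domain)
            if entry is None:
                entry = stats[domain] = DomainStats(domain, 0, 0)
            entry.n_total += 1
            if is_tm:
                entry.n_tm += 1
    return stats


def compute_pair_stats(
    universe: ProteinUniverse, config: Optional[ScreenConfig] = None
) -> list[PairStats]:
    """Per-(domain, orthogroup) counts; proteins without an orthogroup contribute nothing."""
    config = config or ScreenConfig()
    pairs: dict[tuple[str, str], PairStats] = {}
    for rec in universe:
        if rec.orthogroup_id is None or not _counts_denominator(rec.tm_status, config):
            continue
        is_tm = rec.tm_status is TMStatus.TM
        for domain in rec.domain_ids:
            key = (domain, rec.orthogroup_id)
            entry = pairs.get(key)
            if entry is None:
                entry = pairs[key] = PairStats(domain, rec.orthogroup_id, 0, 0)
            entry.n_total_og += 1
            if is_tm:
                entry.n_tm_og += 1
    return list(pairs.values())


def score_pairs(
    pairs: Sequence[PairStats], domain_stats: Mapping[str, DomainStats]
) -> list[PairStats]:
    """Attach score = f_OG / f_all; pairs of excluded domains are omitted."""
    scored: list[PairStats] = []
    for pair in pairs:
        stats = domain_stats.get(pair.domain_id)
        if stats is None or stats.excluded:
            continue
        if stats.n_tm == 0:  # pragma: no cover - guarded by excluded above
            raise RuntimeError(f"domain {pair.domain_id} reached scoring with f_all = 0")
        pair.f_all = stats.f_all
        pair.score = pair.f_og / stats.f_all
        scored.append(pair)
    return scored


@dataclass(slots=True)
class ScreenFunnel:
    """Ranked surviving pairs plus the per-filter funnel counts."""

    pairs: list[PairStats]
    n_input: int
    n_after_min_tm: int
    n_after_cutoff: int
    n_after_required_taxa: int


def _required_taxon_ogs(
    universe: ProteinUniverse, config: ScreenConfig
) -> tuple[dict[str, bool], dict[str, set[str]]]:
    """Per-orthogroup: any required-taxon member; required-taxon domain carriers."""
    og_has_member: dict[str, bool] = {}
    og_domains: dict[str, set[str]] = {}
    for rec in universe:
        if rec.orthogroup_id is None:
            continue
        if universe.species(rec) in config.required_taxa:
            og_has_member[rec.orthogroup_id] = True
            og_domains.setdefault(rec.orthogroup_id, set()).update(rec.domain_ids)
    return og_has_member, og_domains


def apply_filter_cascade(
    pairs: Sequence[PairStats], config: ScreenConfig, universe: ProteinUniverse
) -> ScreenFunnel:
    """Apply the three pair filters and rank the survivors.

    The three predicates form a pure conjunction, so the surviving set is
    order-independent; the funnel counts are logged in the fixed order
    min-TM -> score cutoff -> required taxa. Survivors are sorted by score
    descending, ties broken by (domain_id, orthogroup_id) ascending.
    """
    if config.min_tm_counts_domain_carriers:
        tm_backing = {id(p): p.n_tm_og for p in pairs}
    else:
        og_tm_total: dict[str, int] = {}
        for rec in universe:
            if rec.orthogroup_id is not None and rec.tm_status is TMStatus.TM:
                og_tm_total[rec.orthogroup_id] = og_tm_total.get(rec.orthogroup_id, 0) + 1
        tm_backing = {id(p): og_tm_total.get(p.orthogroup_id, 0) for p in pairs}

    after_tm = [p for p in pairs if tm_backing[id(p)] >= config.min_tm_in_pair]
    cutoff = config.score_cutoff
    after_cutoff = [p for p in after_tm if p.score > cutoff]

    og_has_member, og_domains = _required_taxon_ogs(universe, config)
    if config.require_domain_in_required_taxon:
        after_taxa = [
            p for p in after_cutoff if p.domain_id in og_domains.get(p.orthogroup_id, ())
        ]
    else:
        after_taxa = [p for p in after_cutoff if og_has_member.get(p.orthogroup_id, False)]

    ranked = sorted(after_taxa, key=lambda p: (-p.score, p.domain_id, p.orthogroup_id))
    return ScreenFunnel(
        pairs=ranked,
        n_input=len(pairs),
        n_after_min_tm=len(after_tm),
        n_after_cutoff=len(after_cutoff),
        n_after_required_taxa=len(after_taxa),
    )


def run_screen_on_universe(
    universe: ProteinUniverse, config: Optional[ScreenConfig] = None
) -> tuple[ScreenFunnel, dict[str, DomainStats]]:
    """Full screen on an assembled universe: f_all, pair stats, scores, cascade."""
    config = config or ScreenConfig()
    domain_stats = compute_f_all(universe, config)
    pairs = compute_pair_stats(universe, config)
    scored = score_pairs(pairs, domain_stats)
    return apply_filter_cascade(scored, config, universe), domain_stats
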