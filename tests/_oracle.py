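"""Independent brute-force reference for the whole screen.

Everything here is re-derived with plain nested loops over the raw table
rows — no counting code is shared with the package — so tests can compare
the pipeline's output against a second, dumb-but-obviously-correct route.
Float arithmetic uses the same operand order (count / count, then ratio of
the two frequencies) so agreement is exact, not approximate.
"""

from __future__ import annotations

from mbtrscreen.io_formats import Rank, TMStatus


def oracle_screen(proteins, domains, assignments, taxonomy, config):
    """Full pipeline by enumeration.

    Returns (scored, ranked): ``scored`` maps (domain, og) -> dict of
    counts/frequencies/score for every scored pair, ``ranked`` is the list
    of (domain, og) keys surviving the cascade in rank order.
    """
    # length filter
    kept = [p for p in proteins if p.length_aa <= config.max_length_aa]
    taxon_of = {p.accession: p.taxon_id for p in kept}
    status_of = {p.accession: p.tm_status for p in kept}

    # taxonomy maps
    rank_of = {t.taxon_id: t.rank for t in taxonomy}
    parent_of = {t.taxon_id: t.parent_id for t in taxonomy}

    def species(taxon):
        if rank_of.get(taxon) is Rank.SUBSPECIES:
            return parent_of[taxon]
        return taxon

    # assignment filters: taxon consistency, then single-species removal
    consistent = []
    for a in assignments:
        if a.accession not in taxon_of:
            continue
        taxon = taxon_of[a.accession]
        if taxon == a.og_taxon_id:
            consistent.append(a)
        elif rank_of.get(taxon) is Rank.SUBSPECIES and parent_of.get(taxon) == a.og_taxon_id:
            consistent.append(a)
    og_species = {}
    for a in consistent:
        og_species.setdefault(a.orthogroup_id, set()).add(species(taxon_of[a.accession]))
    surviving = [a for a in consistent if len(og_species[a.orthogroup_id]) >= 2]
    og_of = {a.accession: a.orthogroup_id for a in surviving}

    # per-protein domain sets (unknown accessions dropped)
    domains_of = {p.accession: set() for p in kept}
    for row in domains:
        if row.accession in domains_of:
            domains_of[row.accession].add(row.domain_id)

    def counts_in_denominator(acc):
        if status_of[acc] is TMStatus.UNASSIGNED:
            return config.count_unassigned_tm
        return True

    all_domains = sorted({d for s in domains_of.values() for d in s})
    all_ogs = sorted(set(og_of.values()))

    f_all = {}
    for d in all_domains:
        n_total = n_tm = 0
        for p in kept:
            if d in domains_of[p.accession] and counts_in_denominator(p.accession):
                n_total += 1
                if p.tm_status is TMStatus.TM:
                    n_tm += 1
        if n_total:
            f_all[d] = (n_total, n_tm)

    scored = {}
    for d in all_domains:
        for og in all_ogs:
            n_total = n_tm = 0
            for p in kept:
                if (
                    og_of.get(p.accession) == og
                    and d in domains_of[p.accession]
                    and counts_in_denominator(p.accession)
                ):
                    n_total += 1
                    if p.tm_status is TMStatus.TM:
                        n_tm += 1
            if n_total == 0:
                continue
            g_total, g_tm = f_all[d]
            if g_tm == 0:  # domain never pairs with TM: excluded
                continue
            f_og = n_tm / n_total
            score = f_og / (g_tm / g_total)
            scored[(d, og)] = {
                "n_total_og": n_total,
                "n_tm_og": n_tm,
                "f_og": f_og,
                "f_all": g_tm / g_total,
                "score": score,
            }

    # filter cascade
    og_tm_total = {}
    for p in kept:
        og = og_of.get(p.accession)
        if og is not None and p.tm_status is TMStatus.TM:
            og_tm_total[og] = og_tm_total.get(og, 0) + 1
    required_domains_in_og = {}
    required_member_og = set()
    for p in kept:
        og = og_of.get(p.accession)
        if og is not None and species(p.taxon_id) in config.required_taxa:
            required_member_og.add(og)
            required_domains_in_og.setdefault(og, set()).update(domains_of[p.accession])

    survivors = []
    cutoff = 10.0 ** config.log10_cutoff
    for (d, og), row in scored.items():
        backing = row["n_tm_og"] if config.min_tm_counts_domain_carriers else og_tm_total.get(og, 0)
        if backing < config.min_tm_in_pair:
            continue
        if not row["score"] > cutoff:
            continue
        if config.require_domain_in_required_taxon:
            if d not in required_domains_in_og.get(og, set()):
                continue
        elif og not in required_member_og:
            continue
        survivors.append((d, og))
    ranked = sorted(survivors, key=lambda key: (-scored[key]["score"], key[0], key[1]))
    return scored, ranked
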