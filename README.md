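# mbtrscreen

A screen for **membrane-bound transcriptional regulators (MBTRs)** —
proteins such as SREBP, ATF6, MYRF or PREB that are anchored in a membrane
by a transmembrane (TM) segment yet carry a domain normally associated with
transcriptional regulation. Such domain combinations are *rare* across a
protein corpus but *conserved* within the orthologous families that
genuinely use them, and that contrast is the signal this package ranks on.

It is aimed at computational biologists who have, for a large protein set:
per-protein TM labels (from a topology predictor such as TMbed), Pfam
domain annotations, orthogroup assignments (e.g. eggNOG-mapper output) and
a taxonomy table — and who want a ranked, reproducible candidate list.

## The statistic

For each domain *X*, over the whole universe of proteins:

```
f_all(X) = n(TM proteins with X) / n(proteins with X)
```

and within each orthogroup *OG*:

```
f_OG(X, OG) = n(TM proteins with X in OG) / n(proteins with X in OG)
```

Each [domain, orthogroup] pair is scored by the
**conservation-to-frequency ratio** `f_OG / f_all`. Candidates must
survive three filters: at least 10 TM proteins backing the pair (small
orthogroups give spuriously large ratios), a score strictly above
`10^0.3 ≈ 1.995`, and at least one human (9606) or mouse (10090) protein
carrying the domain in the orthogroup, so the candidate is experimentally
actionable. Upstream, proteins longer than 8,300 aa are excluded, and
orthogroup assignments are dropped when the protein's taxon disagrees with
the orthology resource's taxon (subspecies of the claimed species are
accepted) or when the orthogroup spans a single species.

## Worked example

Simulate a universe with one planted PREB-like family — a domain
(`PF90001`) carried by 600 non-TM proteins globally but by 30 mostly-TM
members of one orthogroup — then screen it:

```
$ mbtr-screen simulate --spec spec.yaml --out-dir sim
$ mbtr-screen screen --proteins sim/proteins.tsv --domains sim/domains.tsv \
      --orthogroups sim/orthogroups.tsv --taxonomy sim/taxonomy.tsv \
      --out report.tsv --summary summary.tsv
...
INFO mbtrscreen.pipeline: n_pairs_scored=64
INFO mbtrscreen.pipeline: n_pairs_after_min_tm=1
INFO mbtrscreen.pipeline: n_pairs_after_cutoff=1
INFO mbtrscreen.pipeline: n_pairs_after_required_taxa=1
1 candidate pair(s) written to report.tsv

$ cut -f1-7 report.tsv
domain_id  orthogroup_id  n_total_og  n_tm_og  f_all  f_og  score
PF90001    OGP0001        30          26       0.04   0.87  21.00
```

Of 64 scored pairs only the planted one survives the cascade: 26 of its 30
orthogroup members are TM (`f_og = 0.87`) while globally only 26 of 630
carriers are (`f_all = 0.04`), giving a ratio of 21 — exactly
`(members + decoys) / members`, the value the generator's closed form
predicts. The summary TSV records the full funnel (proteins read, length
exclusions, assignment drops, pair counts per filter) plus input digests.

Other subcommands: `query-domain` runs the broad-taxa expansion (all TM
carriers of a target domain minus proteins carrying disqualifying domains,
with per-orthogroup f_OG — the NDT80/MYRF-style analysis) and `validate`
checks input tables against the format invariants. Everything is also a
library (`mbtrscreen.build_universe`, `run_screen_on_universe`,
`run_expansion`, `generate`, ...).

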