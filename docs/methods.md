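# Methods

## The screen

The unit of annotation is presence/absence of a Pfam-style domain on a
protein: multiple copies of a domain count once, because both frequencies
count proteins, not domain instances. For a domain *X* the global TM
frequency is `f_all = n_tm / n_total` over **every** protein in the
universe carrying *X* (orthogroup membership is irrelevant to the
denominator — the global rate is the reference the within-family rate is
compared against). Within an orthogroup, `f_OG` is the same ratio over the
orthogroup's carriers of *X*. The ranking statistic is `f_OG / f_all`,
computed at full floating precision with no intermediate rounding; report
files render 2-decimal display columns alongside shortest-repr
full-precision columns so a re-read reproduces every float exactly.

Domains never observed on a TM protein have `f_all` numerator zero; they
are flagged excluded and never scored (the ratio would be undefined or
infinite, and such a domain cannot have a conserved TM combination by
definition).

### Filter cascade

Three pure-conjunction predicates, applied after scoring:

1. **min_tm_in_pair = 10** — the pair must be backed by ≥ 10 TM proteins.
   By default this counts TM proteins *carrying the domain inside the
   orthogroup* (`n_tm_og`), which is the quantity the ratio is actually
   estimated from; `min_tm_counts_domain_carriers=False` switches to
   counting all TM proteins in the orthogroup, for users who read the
   backing requirement orthogroup-wide.
2. **score > 10^0.3** — strict inequality against the full-precision power
   (≈ 1.99526), not its 3-decimal rounding 1.995; the rounded constant is
   a display form, not the definition.
3. **required taxa** — the orthogroup must contain ≥ 1 protein whose
   species-resolved taxon is human (9606) or mouse (10090). By default
   that protein must itself carry the pair's domain (the stricter reading:
   the candidate is actionable in a model organism);
   `require_domain_in_required_taxon=False` relaxes this to mere
   orthogroup membership.

Because the cascade is a conjunction, the surviving set is independent of
predicate order; the logged funnel counts use the fixed order min-TM →
cutoff → taxa. Survivors are ranked by score descending with ties broken
lexicographically by (domain_id, orthogroup_id), making the output a total
order: identical inputs in any row order produce byte-identical reports.

### Universe assembly and upstream filters

* **Length filter**: proteins longer than `max_length_aa = 8300` amino
  acids are excluded; "exceeds" is strict, so a protein of exactly 8,300
  aa is kept. The filter is idempotent.
* **TM label**: a pre-computed per-protein label (TM / NON_TM /
  UNASSIGNED). UNASSIGNED proteins (a residual fraction in any real
  corpus, ~0.008%) are evidence for neither class and are excluded from
  both numerator and denominator of every frequency by default;
  `count_unassigned_tm=True` instead counts them in denominators only.
  They remain in the universe for all other bookkeeping.
* **Taxon consistency**: an orthogroup assignment is kept iff the
  protein's taxon equals the resource's claimed taxon, or is a SUBSPECIES
  whose parent is that taxon. Subspecies resolution walks exactly one
  parent step; a subspecies whose parent is itself a subspecies is an
  input error.
* **Single-species orthogroups** are removed *after* the consistency
  filter (consistency drops can collapse a multi-species orthogroup to one
  species), counting species after subspecies collapse — two subspecies of
  one species provide no cross-species conservation signal. The ordered
  pass is idempotent.

### Domain expansion query

`run_expansion` selects every TM carrier of a target domain that carries
none of a set of disqualifying domains (presence anywhere in the protein;
no positional logic), and summarizes per-orthogroup `n_total / n_tm /
f_OG` over all exclusion-surviving carriers with an assigned TM label —
the TM requirement applies to the returned matches, not to the summary
denominators, so the summary's f_OG is directly comparable to the screen's
pair statistics. Carriers without an orthogroup are grouped under the
sentinel id `UNASSIGNED`.

## Synthetic universes

The generator emulates the structure the screen assumes: several species
(human and mouse always first, so the required-taxa filter is exercised;
each species carries one subspecies with probability 1/3), a catalog of
background domains each with its own TM co-occurrence rate drawn uniformly
from [0.05, 0.5], background orthogroups of 4–12 members sharing one or
two domains (a conserved architecture), ~30% of proteins without any
orthogroup, a 2% rate of taxon-inconsistent assignments to exercise the
assignment filters, lengths uniform on [100, 2000] aa with an optional
count of deliberately over-length proteins, and a realistic trace rate of
UNASSIGNED TM labels (8 × 10⁻⁵).

A **planted family** is one orthogroup whose `n_members` members all carry
a dedicated domain and are TM with probability `tm_given_member` (~0.95),
plus `global_decoys` non-TM orthogroup-less carriers of the same domain.
The defaults (30 members, 600 decoys = 20×) reproduce the signature of a
genuine hit: `f_all` low because the corpus-wide carrier pool is
dominated by non-TM proteins, `f_OG` high inside the family. The ground
truth table recounts every planted pair's realized `n_tm_og`, `f_OG`,
`f_all` and score directly from the emitted rows.

`expected_score` returns the ratio of expectations
`E[f_OG] / E[f_all] = (n_members + global_decoys) / n_members` — not the
expectation of the realized ratio in general. However, when the planted
domain occurs only on members and decoys and decoys are never TM, the TM
carrier count cancels between numerator and denominator, so the realized
score equals this value exactly whenever at least one member is TM; the
Monte-Carlo agreement checks therefore pass with zero error rather than
merely within tolerance, which is a property of the planted design, not a
loosened test.

What the generator does **not** emulate: sequence content, realistic
domain-architecture grammars (co-occurrence of domain families along a
protein), unequal species representation, or annotation noise correlated
with protein family size. Passing tests demonstrate the counting,
filtering and ranking machinery is exact and the screen recovers planted
rare-but-conserved signals under the stated conditions; they say nothing
about the biological completeness of any real-corpus candidate list,
which depends on annotation and orthology quality.

All randomness flows through one numpy `Generator` in a fixed generation
order, so spec + seed determine the output byte for byte.

## Verification design

Every counting path has a second, independent route: a brute-force
enumerator (plain nested loops over raw table rows, in `tests/_oracle.py`)
re-derives the entire pipeline — length filter, assignment filters,
frequencies, scores, cascade, ranking — and is compared exactly (float
equality, achieved by using the same operand order: count/count, then the
ratio of the two frequencies). The oracle-equivalence check runs on 50
random universes of ≤ 500 proteins with randomized filter configurations;
planted-family recovery uses 20 seeds at the default study conditions;
closed-form agreement uses 200 seeds at 50 members / 1000 decoys. These
problem sizes keep each check well under a couple of minutes while leaving
the assertions exact.

## Known limitations

* The screen has no null model: the `10^0.3` cutoff is a heuristic on the
  score distribution, and no p-values or multiple-testing correction are
  produced.
* Accessions are opaque strings; UniProt isoform suffixes are not
  normalized.
* Orthology is taken as given; no inference, tree building or
  representative selection is performed.
* The expansion query takes raw domain accessions; no display-name →
  accession mapping ships with the package.
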