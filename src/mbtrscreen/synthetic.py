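"""Parameterized synthetic protein universes with planted ground truth.

The generator emulates the statistical structure the screen assumes: a
multi-species corpus with a catalog of background domains, each with its
own background probability of co-occurring with a transmembrane segment;
orthogroup structure across species (with optional subspecies and a small
rate of taxon-inconsistent assignments, so the assignment filters have
work to do); a pool of orthogroup-less proteins; and planted
"MBTR-like" families — orthogroups in which a globally rare domain/TM
combination is highly conserved, the signature the screen is built to
detect. Global non-TM decoy carriers of the planted domain drive its
f_all down, mirroring how a genuinely rare combination looks against a
20-million-protein corpus at desk scale.

All randomness flows through one numpy Generator in a fixed generation
order (taxonomy, background rates, orthogroups, unassigned pool, planted
families, over-length extras), so a given spec + seed reproduces the
emitted files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    DomainAnnotationRow,
    OrthogroupAssignmentRow,
    ProteinTableRow,
    Rank,
    TaxonomyRow,
    TMStatus,
    write_domain_table,
    write_orthogroup_table,
    write_protein_table,
    write_taxonomy_table,
    _write_tsv,
)

REQUIRED_SPECIES = (9606, 10090)  # human, mouse — the screen's default reference taxa


@dataclass(frozen=True)
class PlantedFamily:
    """One rare-but-conserved domain/TM family planted as ground truth.

    ``global_decoys`` non-TM, orthogroup-less proteins carry the same
    domain, keeping its global TM frequency low; ``tm_given_member`` is the
    per-member probability of a transmembrane segment inside the family's
    orthogroup (high, ~0.95, for a conserved combination).
    """

    family_id: str
    domain_id: str
    orthogroup_id: str
    n_members: int = 30
    tm_given_member: float = 0.95
    global_decoys: int = 600
    includes_required_taxon: bool = True

    def validate(self) -> None:
        if self.n_members < 2:
            raise ValueError(f"{self.family_id}: n_members must be >= 2")
        if not 0.0 <= self.tm_given_member <= 1.0:
            raise ValueError(f"{self.family_id}: tm_given_member outside [0, 1]")
        if self.global_decoys < 0:
            raise ValueError(f"{self.family_id}: global_decoys must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated universe.

    Defaults describe a small but structured corpus: a handful of
    vertebrate-like species (human and mouse always included, a third of
    species carrying one subspecies), a few dozen background domains whose
    TM co-occurrence rates span rare to common, orthogroups of 4-12
    members, ~30% of proteins without any orthogroup, and realistic
    protein lengths.
    """

    n_species: int = 6
    n_background_orthogroups: int = 40
    og_size_range: tuple[int, int] = (4, 12)
    n_background_domains: int = 30
    background_tm_given_domain: tuple[float, float] = (0.05, 0.5)
    fraction_unassigned_og: float = 0.3
    planted_families: tuple[PlantedFamily, ...] = ()
    length_range: tuple[int, int] = (100, 2000)
    seed: int = 0
    subspecies_prob: float = 1.0 / 3.0
    unassigned_status_rate: float = 8e-5
    taxon_mismatch_rate: float = 0.02
    n_overlength: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2 (single-species universes carry no signal)")
        if self.n_background_orthogroups < 0 or self.n_background_domains < 1:
            raise ValueError("background counts out of range")
        for name in ("og_size_range", "length_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or lo > hi:
                raise ValueError(f"{name} must satisfy 1 <= min <= max")
        lo, hi = self.background_tm_given_domain
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("background_tm_given_domain must be a sub-range of [0, 1]")
        for prob_name in ("fraction_unassigned_og", "subspecies_prob",
                          "unassigned_status_rate", "taxon_mismatch_rate"):
            p = getattr(self, prob_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{prob_name} outside [0, 1]")
        if self.fraction_unassigned_og >= 1.0:
            raise ValueError("fraction_unassigned_og must be < 1")
        if self.n_overlength < 0:
            raise ValueError("n_overlength must be >= 0")
        seen = set()
        for fam in self.planted_families:
            fam.validate()
            key = (fam.domain_id, fam.orthogroup_id)
            if key in seen:
                raise ValueError(f"duplicate planted pair {key}")
            seen.add(key)


@dataclass(slots=True)
class GroundTruthRow:
    """Realized statistics of one planted pair, recounted from the emitted rows."""

    family_id: str
    domain_id: str
    orthogroup_id: str
    n_total_og: int
    n_tm_og: int
    f_og: float
    f_all: float
    score: float


@dataclass
class SyntheticUniverse:
    proteins: list[ProteinTableRow]
    domains: list[DomainAnnotationRow]
    orthogroups: list[OrthogroupAssignmentRow]
    taxonomy: list[TaxonomyRow]
    ground_truth: list[GroundTruthRow]
    spec: SyntheticSpec

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": out / "proteins.tsv",
            "domains": out / "domains.tsv",
            "orthogroups": out / "orthogroups.tsv",
            "taxonomy": out / "taxonomy.tsv",
            "ground_truth": out / "ground_truth.tsv",
        }
        write_protein_table(self.proteins, paths["proteins"])
        write_domain_table(self.domains, paths["domains"])
        write_orthogroup_table(self.orthogroups, paths["orthogroups"])
        write_taxonomy_table(self.taxonomy, paths["taxonomy"])
        _write_tsv(
            paths["ground_truth"],
            ["family_id", "domain_id", "orthogroup_id", "n_total_og", "n_tm_og",
             "f_og", "f_all", "score"],
            (
                (g.family_id, g.domain_id, g.orthogroup_id, g.n_total_og, g.n_tm_og,
                 repr(g.f_og), repr(g.f_all), repr(g.score))
                for g in self.ground_truth
            ),
        )
        return paths


def expected_score(family: PlantedFamily, spec: Optional[SyntheticSpec] = None) -> float:
    """Closed-form expectation ratio E[f_OG] / E[f_all] for a planted pair.

    E[f_OG] = tm_given_member; E[f_all] = n_members * tm_given_member /
    (n_members + global_decoys), since decoys are never transmembrane. The
    ratio of expectations, (n_members + global_decoys) / n_members, is not
    the expectation of the realized ratio, but when the planted domain
    occurs on members and decoys only the two coincide exactly whenever at
    least one member is transmembrane.
    """
    if family.n_members < 1:
        raise ValueError("degenerate family: no members")
    if family.tm_given_member == 0.0:
        raise ValueError("degenerate family: tm_given_member = 0 gives an excluded domain")
    e_f_all = (family.n_members * family.tm_given_member) / (
        family.n_members + family.global_decoys
    )
    return family.tm_given_member / e_f_all


def _species_ids(n_species: int) -> list[int]:
    ids = list(REQUIRED_SPECIES[:n_species])
    ids.extend(90001 + i for i in range(n_species - len(ids)))
    return ids


def generate(spec: SyntheticSpec) -> SyntheticUniverse:
    """Generate one universe; identical spec (incl. seed) gives identical rows."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    len_lo, len_hi = spec.length_range

    # taxonomy: species, plus at most one subspecies per species
    species = _species_ids(spec.n_species)
    taxonomy = [TaxonomyRow(s, 0, Rank.SPECIES) for s in species]
    subspecies_of: dict[int, int] = {}
    for i, s in enumerate(species):
        if rng.random() < spec.subspecies_prob:
            sub = 500001 + i
            subspecies_of[s] = sub
            taxonomy.append(TaxonomyRow(sub, s, Rank.SUBSPECIES))

    background_domains = [f"PF{10000 + i}" for i in range(spec.n_background_domains)]
    lo, hi = spec.background_tm_given_domain
    tm_rate = {d: float(rng.uniform(lo, hi)) for d in background_domains}

    proteins: list[ProteinTableRow] = []
    domain_rows: list[DomainAnnotationRow] = []
    og_rows: list[OrthogroupAssignmentRow] = []
    counter = 0

    def new_protein(taxon: int, length: int, status: TMStatus,
                    domains: Sequence[str], og: Optional[tuple[str, int]]) -> None:
        nonlocal counter
        counter += 1
        acc = f"P{counter:07d}"
        proteins.append(ProteinTableRow(acc, taxon, length, status))
        for d in domains:
            domain_rows.append(DomainAnnotationRow(acc, d))
        if og is not None:
            og_rows.append(OrthogroupAssignmentRow(acc, og[0], og[1]))

    def draw_status(p_tm: float) -> TMStatus:
        if rng.random() < spec.unassigned_status_rate:
            return TMStatus.UNASSIGNED
        return TMStatus.TM if rng.random() < p_tm else TMStatus.NON_TM

    def draw_member_taxon() -> tuple[int, int]:
        """(protein taxon, species) — occasionally the species' subspecies."""
        sp = int(species[rng.integers(0, len(species))])
        if sp in subspecies_of and rng.random() < 0.25:
            return subspecies_of[sp], sp
        return sp, sp

    # background orthogroups: members share the group's domain architecture
    n_assigned_background = 0
    for i in range(spec.n_background_orthogroups):
        og_id = f"OG{i:05d}"
        n_dom = int(rng.integers(1, 3))
        dom_idx = rng.choice(len(background_domains), size=n_dom, replace=False)
        og_domains = [background_domains[int(j)] for j in sorted(dom_idx)]
        p_tm = float(np.mean([tm_rate[d] for d in og_domains]))
        size = int(rng.integers(spec.og_size_range[0], spec.og_size_range[1] + 1))
        for _ in range(size):
            taxon, sp = draw_member_taxon()
            og_taxon = sp
            if rng.random() < spec.taxon_mismatch_rate:
                others = [s for s in species if s != sp]
                og_taxon = int(others[rng.integers(0, len(others))])
            length = int(rng.integers(len_lo, len_hi + 1))
            new_protein(taxon, length, draw_status(p_tm), og_domains, (og_id, og_taxon))
            n_assigned_background += 1

    # orthogroup-less background pool
    frac = spec.fraction_unassigned_og
    n_unassigned = int(round(n_assigned_background * frac / (1.0 - frac)))
    for _ in range(n_unassigned):
        taxon, _sp = draw_member_taxon()
        n_dom = int(rng.integers(1, 3))
        dom_idx = rng.choice(len(background_domains), size=n_dom, replace=False)
        doms = [background_domains[int(j)] for j in sorted(dom_idx)]
        p_tm = float(np.mean([tm_rate[d] for d in doms]))
        length = int(rng.integers(len_lo, len_hi + 1))
        new_protein(taxon, length, draw_status(p_tm), doms, None)

    # planted families: conserved domain/TM combination inside one orthogroup,
    # plus global non-TM decoy carriers that keep the domain's f_all low
    for fam in spec.planted_families:
        for k in range(fam.n_members):
            if k == 0 and fam.includes_required_taxon:
                taxon = sp = REQUIRED_SPECIES[0]
            else:
                taxon, sp = draw_member_taxon()
            status = TMStatus.TM if rng.random() < fam.tm_given_member else TMStatus.NON_TM
            length = int(rng.integers(len_lo, len_hi + 1))
            new_protein(taxon, length, status, [fam.domain_id], (fam.orthogroup_id, sp))
        for _ in range(fam.global_decoys):
            taxon, _sp = draw_member_taxon()
            length = int(rng.integers(len_lo, len_hi + 1))
            new_protein(taxon, length, TMStatus.NON_TM, [fam.domain_id], None)

    # deliberately over-length proteins, to exercise the length filter
    for _ in range(spec.n_overlength):
        taxon, _sp = draw_member_taxon()
        dom = background_domains[int(rng.integers(0, len(background_domains)))]
        length = 8301 + int(rng.integers(0, 500))
        new_protein(taxon, length, TMStatus.NON_TM, [dom], None)

    ground_truth = _recount_ground_truth(spec, proteins, domain_rows, og_rows)
    return SyntheticUniverse(proteins, domain_rows, og_rows, taxonomy, ground_truth, spec)


def _recount_ground_truth(
    spec: SyntheticSpec,
    proteins: Sequence[ProteinTableRow],
    domain_rows: Sequence[DomainAnnotationRow],
    og_rows: Sequence[OrthogroupAssignmentRow],
) -> list[GroundTruthRow]:
    """Realized per-planted-pair statistics, recounted from the emitted rows."""
    domains_of: dict[str, set[str]] = {}
    for row in domain_rows:
        domains_of.setdefault(row.accession, set()).add(row.domain_id)
    og_of = {row.accession: row.orthogroup_id for row in og_rows}

    out: list[GroundTruthRow] = []
    for fam in spec.planted_families:
        n_total = n_tm = n_total_og = n_tm_og = 0
        for p in proteins:
            if p.tm_status is TMStatus.UNASSIGNED:
                continue
            if fam.domain_id not in domains_of.get(p.accession, ()):
                continue
            is_tm = p.tm_status is TMStatus.TM
            n_total += 1
            n_tm += int(is_tm)
            if og_of.get(p.accession) == fam.orthogroup_id:
                n_total_og += 1
                n_tm_og += int(is_tm)
        f_all = n_tm / n_total if n_total else float("nan")
        f_og = n_tm_og / n_total_og if n_total_og else float("nan")
        score = f_og / f_all if n_total and n_tm else float("nan")
        out.append(
            GroundTruthRow(fam.family_id, fam.domain_id, fam.orthogroup_id,
                           n_total_og, n_tm_og, f_og, f_all, score)
        )
    return out
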