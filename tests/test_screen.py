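"""Core screen: f_all, f_OG, the ratio score, and the filter cascade."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from mbtrscreen import (
    PairStats,
    ScreenConfig,
    TMStatus,
    apply_filter_cascade,
    compute_f_all,
    compute_pair_stats,
    score_pairs,
)
from mbtrscreen.universe import ProteinUniverse

from conftest import HUMAN, MOUSE, ZEBRAFISH, record, universe_of

CUTOFF = 10.0 ** 0.3


def random_universe(seed, n=200, n_domains=12, n_ogs=8, p_og=0.6):
    rng = np.random.default_rng(seed)
    taxa = [HUMAN, MOUSE, ZEBRAFISH]
    records = []
    for i in range(n):
        domains = {
            f"PF{int(d):05d}" for d in rng.choice(n_domains, size=int(rng.integers(0, 4)), replace=False)
        }
        status = [TMStatus.TM, TMStatus.NON_TM, TMStatus.UNASSIGNED][
            int(rng.choice(3, p=[0.3, 0.65, 0.05]))
        ]
        og = f"OG{int(rng.integers(0, n_ogs))}" if rng.random() < p_og else None
        records.append(record(f"P{i}", taxa[int(rng.integers(0, 3))], status, domains, og))
    return universe_of(*records)


class TestFAll:
    def test_direct_ratio(self):
        records = [
            record(f"P{i}", status=TMStatus.TM if i < 2 else TMStatus.NON_TM, domains={"PF00001"})
            for i in range(10)
        ]
        stats = compute_f_all(universe_of(*records))
        assert stats["PF00001"].f_all == 0.2
        assert stats["PF00001"].n_total == 10 and stats["PF00001"].n_tm == 2

    def test_domain_never_tm_is_excluded_from_scoring(self):
        universe = universe_of(
            record("P1", status=TMStatus.NON_TM, domains={"PF00001"}, og="OG1"),
            record("P2", status=TMStatus.NON_TM, domains={"PF00001"}, og="OG1"),
        )
        stats = compute_f_all(universe)
        assert stats["PF00001"].excluded
        pairs = compute_pair_stats(universe)
        assert score_pairs(pairs, stats) == []

    def test_unassigned_status_counts_in_neither_side_by_default(self):
        universe = universe_of(
            record("P1", status=TMStatus.TM, domains={"PF00001"}),
            record("P2", status=TMStatus.NON_TM, domains={"PF00001"}),
            record("P3", status=TMStatus.UNASSIGNED, domains={"PF00001"}),
        )
        assert compute_f_all(universe)["PF00001"].n_total == 2
        relaxed = compute_f_all(universe, ScreenConfig(count_unassigned_tm=True))
        assert relaxed["PF00001"].n_total == 3 and relaxed["PF00001"].n_tm == 1

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            compute_f_all(universe_of())

    @pytest.mark.parametrize("seed", range(4))
    def test_random_universe_matches_brute_force_recount(self, seed):
        universe = random_universe(seed, n=500, n_domains=40)
        stats = compute_f_all(universe)
        records = universe.records
        domains = {d for r in records for d in r.domain_ids}
        for domain in domains:
            carriers = [
                r for r in records
                if domain in r.domain_ids and r.tm_status is not TMStatus.UNASSIGNED
            ]
            if not carriers:
                assert domain not in stats
                continue
            assert stats[domain].n_total == len(carriers)
            assert stats[domain].n_tm == sum(r.tm_status is TMStatus.TM for r in carriers)


class TestPairStats:
    def test_unanimous_tm_gives_f_og_one(self):
        records = [
            record(f"P{i}", status=TMStatus.TM, domains={"PF00001"}, og="OG1") for i in range(5)
        ]
        (pair,) = compute_pair_stats(universe_of(*records))
        assert pair.f_og == 1.0 and pair.n_total_og == 5

    def test_protein_without_orthogroup_contributes_nothing(self):
        universe = universe_of(record("P1", status=TMStatus.TM, domains={"PF00001"}))
        assert compute_pair_stats(universe) == []

    @pytest.mark.parametrize("seed", [10, 11])
    def test_counts_match_group_by_oracle(self, seed):
        universe = random_universe(seed, n=300, n_ogs=20)
        pairs = {(p.domain_id, p.orthogroup_id): p for p in compute_pair_stats(universe)}
        expected = {}
        for r in universe:
            if r.orthogroup_id is None or r.tm_status is TMStatus.UNASSIGNED:
                continue
            for d in r.domain_ids:
                key = (d, r.orthogroup_id)
                total, tm = expected.get(key, (0, 0))
                expected[key] = (total + 1, tm + (r.tm_status is TMStatus.TM))
        assert set(pairs) == set(expected)
        for key, (total, tm) in expected.items():
            assert (pairs[key].n_total_og, pairs[key].n_tm_og) == (total, tm)

    def test_conservation_of_tm_counts_across_orthogroups(self):
        universe = random_universe(21, n=400, n_ogs=10, p_og=1.0)
        stats = compute_f_all(universe)
        pairs = compute_pair_stats(universe)
        per_domain_og_tm = {}
        for p in pairs:
            per_domain_og_tm[p.domain_id] = per_domain_og_tm.get(p.domain_id, 0) + p.n_tm_og
        for domain, total in per_domain_og_tm.items():
            assert total <= stats[domain].n_tm
        # every protein is orthogroup-assigned here, so equality must hold
        for domain, stat in stats.items():
            assert per_domain_og_tm.get(domain, 0) == stat.n_tm


class TestScoring:
    def test_exact_ratio_and_identity(self):
        pair = PairStats("PF00001", "OG1", 4, 2)  # f_og = 0.5
        from mbtrscreen.screen import DomainStats

        (scored,) = score_pairs([pair], {"PF00001": DomainStats("PF00001", 8, 2)})  # f_all = 0.25
        assert scored.score == 2.0
        same = PairStats("PF00001", "OG1", 8, 2)
        (scored,) = score_pairs([same], {"PF00001": DomainStats("PF00001", 8, 2)})
        assert scored.score == 1.0

    def test_high_scoring_rare_conserved_pair_passes_cutoff(self):
        # the SREBP-like signature: f_og 0.58 over a rare domain gives ~46.93
        f_all = 0.58 / 46.93
        n_total = 50
        pair = PairStats("PF00010", "OG1", n_total, 29, f_all=f_all)  # f_og = 0.58
        pair.score = pair.f_og / f_all
        assert pair.score == pytest.approx(46.93)
        universe = universe_of(
            record("H1", HUMAN, TMStatus.TM, {"PF00010"}, "OG1"),
        )
        funnel = apply_filter_cascade([pair], ScreenConfig(min_tm_in_pair=10), universe)
        assert funnel.pairs == [pair]


def cascade_universe():
    """OG1 has a human carrier of PF00001; OGZ is zebrafish-only."""
    return universe_of(
        record("H1", HUMAN, TMStatus.TM, {"PF00001"}, "OG1"),
        record("Z1", ZEBRAFISH, TMStatus.TM, {"PF00001"}, "OGZ"),
        record("H2", HUMAN, TMStatus.NON_TM, {"PF00002"}, "OG1"),
    )


def make_pair(og="OG1", domain="PF00001", n_tm=20, n_total=20, score=5.0, f_all=0.1):
    pair = PairStats(domain, og, n_total, n_tm, f_all=f_all)
    pair.score = score
    return pair


class TestFilterCascade:
    def test_min_tm_boundary_nine_dropped_ten_kept(self):
        universe = cascade_universe()
        config = ScreenConfig()
        nine = make_pair(n_tm=9, n_total=9)
        ten = make_pair(n_tm=10, n_total=10)
        assert apply_filter_cascade([nine], config, universe).pairs == []
        assert apply_filter_cascade([ten], config, universe).pairs == [ten]

    def test_score_exactly_at_cutoff_dropped_strictly_above_kept(self):
        universe = cascade_universe()
        config = ScreenConfig()
        at = make_pair(score=CUTOFF)
        above = make_pair(score=math.nextafter(CUTOFF, math.inf))
        assert apply_filter_cascade([at], config, universe).pairs == []
        assert apply_filter_cascade([above], config, universe).pairs == [above]

    def test_orthogroup_without_required_taxon_dropped(self):
        universe = cascade_universe()
        pair = make_pair(og="OGZ")
        assert apply_filter_cascade([pair], ScreenConfig(), universe).pairs == []

    def test_required_taxon_must_carry_the_domain_by_default(self):
        universe = cascade_universe()
        # OG1's human proteins carry PF00001/PF00002 but not PF00099
        pair = make_pair(domain="PF00099")
        strict = ScreenConfig()
        relaxed = ScreenConfig(require_domain_in_required_taxon=False)
        assert apply_filter_cascade([pair], strict, universe).pairs == []
        assert apply_filter_cascade([pair], relaxed, universe).pairs == [pair]

    def test_min_tm_can_count_all_tm_in_orthogroup(self):
        universe = universe_of(
            *[record(f"H{i}", HUMAN, TMStatus.TM, {"PF00001"}, "OG1") for i in range(12)],
            record("M1", MOUSE, TMStatus.TM, {"PF00002"}, "OG1"),
        )
        # PF00002 is backed by 1 TM carrier but sits in an OG with 13 TM proteins
        pair = make_pair(domain="PF00002", n_tm=1, n_total=1)
        strict = ScreenConfig()
        og_wide = ScreenConfig(min_tm_counts_domain_carriers=False)
        assert apply_filter_cascade([pair], strict, universe).pairs == []
        assert apply_filter_cascade([pair], og_wide, universe).pairs == [pair]

    def test_cascade_is_conjunction_and_idempotent(self):
        universe = cascade_universe()
        config = ScreenConfig()
        rng = np.random.default_rng(2)
        pairs = [
            make_pair(
                og=["OG1", "OGZ"][int(rng.integers(0, 2))],
                n_tm=int(rng.integers(0, 30)),
                score=float(rng.uniform(0.1, 5.0)),
            )
            for _ in range(60)
        ]
        funnel = apply_filter_cascade(pairs, config, universe)
        expected = {
            id(p)
            for p in pairs
            if p.n_tm_og >= 10 and p.score > CUTOFF and p.orthogroup_id == "OG1"
        }
        assert {id(p) for p in funnel.pairs} == expected
        again = apply_filter_cascade(funnel.pairs, config, universe)
        assert again.pairs == funnel.pairs
        assert funnel.n_input >= funnel.n_after_min_tm >= funnel.n_after_cutoff >= funnel.n_after_required_taxa

    def test_ranking_is_a_total_order_independent_of_input_order(self):
        universe = cascade_universe()
        config = ScreenConfig(min_tm_in_pair=1)
        pairs = [
            make_pair(domain=f"PF{i:05d}", score=score)
            for i, score in enumerate([3.0, 7.0, 3.0, 5.5, 7.0])
        ]
        universe["H1"].domain_ids.update(p.domain_id for p in pairs)
        baseline = apply_filter_cascade(pairs, config, universe).pairs
        assert [p.score for p in baseline] == [7.0, 7.0, 5.5, 3.0, 3.0]
        for seed in range(5):
            shuffled = pairs[:]
            random.Random(seed).shuffle(shuffled)
            assert apply_filter_cascade(shuffled, config, universe).pairs == baseline


class TestScreenIdentities:
    def test_whole_universe_single_orthogroup_gives_score_one(self):
        universe = random_universe(33, n=120, p_og=0.0)
        for rec in universe:
            rec.orthogroup_id = "OGALL"
        stats = compute_f_all(universe)
        scored = score_pairs(compute_pair_stats(universe), stats)
        assert scored, "expected at least one scorable pair"
        for pair in scored:
            assert pair.score == 1.0

    def test_flipping_one_carrier_to_tm_strictly_increases_score(self):
        records = [
            record(f"P{i}", status=TMStatus.TM if i < 3 else TMStatus.NON_TM,
                   domains={"PF00001"}, og="OG1")
            for i in range(8)
        ]
        universe = universe_of(*records)
        stats = compute_f_all(universe)  # held fixed
        (before,) = score_pairs(compute_pair_stats(universe), stats)
        universe["P5"].tm_status = TMStatus.TM
        (after,) = score_pairs(compute_pair_stats(universe), stats)
        assert after.f_og > before.f_og
        assert after.score > before.score
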