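"""Non-paralog selection, ranking, permutation testing, characterization."""

import numpy as np
import pandas as pd
import pytest

from ribocompare.profile_processing import DEFAULT_PARAMS, ProfileRejection
from ribocompare.ranking import (
    RankTable,
    align_nonparalog,
    characterize_rank_groups,
    eligible_nonparalogs,
    permutation_test_per_rank,
    random_control,
    rank_pair,
    run_trials,
    select_nonparalogs,
)


class TestEligibility:
    def test_exclusion_rules(self, small_pairs, small_pool):
        pair = small_pairs[0]
        da, db = pair.entry_a.domain, pair.entry_b.domain
        ref_len = da.n_residues
        eligible = eligible_nonparalogs(pair, small_pool)
        ids = {e.domain_id for e in eligible}
        assert pair.entry_a.domain_id not in ids
        assert pair.entry_b.domain_id not in ids
        for e in eligible:
            d = e.domain
            assert d.family not in (da.family, db.family)
            assert d.superfamily not in (da.superfamily, db.superfamily)
            assert d.scop_class not in (da.scop_class, db.scop_class)
            assert abs(d.n_residues - ref_len) <= 25
            assert d.n_residues >= 100 and e.coverage >= 0.70

    def test_family_member_excluded(self, small_pairs, small_pool):
        pair = small_pairs[0]
        family = pair.entry_a.domain.family
        eligible = eligible_nonparalogs(pair, small_pool)
        assert all(e.domain.family != family for e in eligible)

    def test_length_window_boundary(self, small_pairs, small_pool):
        pair = small_pairs[0]
        ref = pair.entry_a.domain.n_residues
        eligible = eligible_nonparalogs(pair, small_pool, length_tolerance=0)
        assert all(e.domain.n_residues == ref for e in eligible)


class TestAlignNonparalog:
    def test_truncation_to_reference_length(self, small_pool):
        entry = next(e for e in small_pool if e.trimmed is not None)
        n = len(entry.trimmed.counts)
        out = align_nonparalog(entry, n - 10)
        assert len(out) == n - 10
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_exact_length_kept(self, small_pool):
        entry = next(e for e in small_pool if e.trimmed is not None)
        n = len(entry.trimmed.counts)
        assert len(align_nonparalog(entry, n)) == n

    def test_too_short_signalled(self, small_pool):
        entry = next(e for e in small_pool if e.trimmed is not None)
        n = len(entry.trimmed.counts)
        with pytest.raises(ProfileRejection, match="too_short"):
            align_nonparalog(entry, n + 1)


class TestRankPair:
    def test_maximum_gets_rank_one(self):
        assert rank_pair(0.9, [0.1] * 19, np.random.default_rng(0)) == 1

    def test_fifth_smallest_gets_rank_16(self):
        others = [i / 100 for i in range(1, 21) if i != 5]  # pair sits 5th-smallest of 20
        assert rank_pair(0.05, others, np.random.default_rng(0)) == 16

    def test_tie_split_uniform(self):
        rng = np.random.default_rng(1)
        ranks = [
            rank_pair(0.5, [0.5] + [0.1] * 18, rng) for _ in range(4000)
        ]
        counts = np.bincount(ranks)
        assert set(np.nonzero(counts)[0]) == {1, 2}
        assert abs(counts[1] - 2000) < 4 * np.sqrt(1000)


class TestRunTrials:
    def test_rows_sum_to_pairs_evaluated(self, small_pairs, small_pool):
        table = run_trials(small_pairs, small_pool, n_trials=3, seed=0)
        assert (table.counts.sum(axis=1) <= len(small_pairs)).all()
        assert (table.counts.sum(axis=1) == (table.assignments > 0).sum(axis=1)).all()

    def test_seeded_determinism(self, small_pairs, small_pool):
        t1 = run_trials(small_pairs, small_pool, n_trials=3, seed=5)
        t2 = run_trials(small_pairs, small_pool, n_trials=3, seed=5)
        np.testing.assert_array_equal(t1.counts, t2.counts)
        np.testing.assert_array_equal(t1.assignments, t2.assignments)

    def test_strong_signal_concentrates_rank_one(self, small_pairs, small_pool):
        """rho=0.9 at depth 80: most pairs beat their competitors."""
        table = run_trials(small_pairs, small_pool, n_trials=3, seed=1)
        assert table.mean_per_rank[0] > 3 * table.expected_per_rank

    def test_expected_per_rank(self):
        table = RankTable(np.zeros((2, 20), dtype=int), 664, np.zeros((2, 0), int))
        assert table.expected_per_rank == pytest.approx(33.20)


class TestSelectNonparalogs:
    def test_without_replacement(self, small_pairs, small_pool):
        pair = small_pairs[0]
        chosen = select_nonparalogs(
            pair, small_pool, n=10, rng=np.random.default_rng(2)
        )
        ids = [e.domain_id for e, _ in chosen]
        assert len(ids) == len(set(ids)) == 10

    def test_pool_exhaustion_names_pair(self, small_pairs, small_pool):
        pair = small_pairs[0]
        with pytest.raises(RuntimeError, match=pair.pair_id):
            select_nonparalogs(
                pair, small_pool, n=10_000, rng=np.random.default_rng(3)
            )


class TestPermutationTest:
    def _table(self, counts):
        return RankTable(counts, int(counts[0].sum()), np.zeros((len(counts), 0), int))

    def test_identical_tables_give_p_one(self):
        rng = np.random.default_rng(4)
        counts = rng.multinomial(100, np.ones(20) / 20, size=20)
        res = permutation_test_per_rank(
            self._table(counts), self._table(counts), n_perm=500, seed=0
        )
        assert (res.p_value == 1.0).all()

    def test_extreme_separation_reaches_floor(self):
        a = np.zeros((20, 20), dtype=int)
        a[:, 0] = 100
        b = np.zeros((20, 20), dtype=int)
        b[:, 19] = 100
        n_perm = 2000
        res = permutation_test_per_rank(
            self._table(a), self._table(b), n_perm=n_perm, seed=1
        )
        assert res.p_value.iloc[0] == pytest.approx(1 / (1 + n_perm))
        assert res.significant.iloc[0]

    def test_unequal_trials_rejected(self):
        a = self._table(np.zeros((20, 20), dtype=int))
        b = self._table(np.zeros((10, 20), dtype=int))
        with pytest.raises(ValueError, match="trials"):
            permutation_test_per_rank(a, b, n_perm=10)


class TestRandomControl:
    def test_zero_pairs_is_empty_and_error_free(self, small_pool):
        table, pairs = random_control(small_pool, n_pairs=0, n_trials=2, seed=0)
        assert pairs == [] and table.counts.sum() == 0

    def test_seeded_determinism(self, small_pool):
        t1, p1 = random_control(small_pool, n_pairs=3, n_trials=2, seed=6)
        t2, p2 = random_control(small_pool, n_pairs=3, n_trials=2, seed=6)
        np.testing.assert_array_equal(t1.counts, t2.counts)
        assert [p.pair_id for p in p1] == [p.pair_id for p in p2]


class TestCharacterizeRankGroups:
    def test_composition_fractions_sum_to_one(self, small_pairs, small_pool):
        table = run_trials(small_pairs, small_pool, n_trials=2, seed=7)
        summary = characterize_rank_groups(table, small_pairs)
        for _, row in summary.aa_composition.iterrows():
            if row.sum() > 0:
                assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_groups_partition_evaluated_pairs(self, small_pairs, small_pool):
        table = run_trials(small_pairs, small_pool, n_trials=2, seed=7)
        summary = characterize_rank_groups(table, small_pairs)
        n_eval = int((table.assignments[0] > 0).sum())
        assert len(summary.pairs) == n_eval
        assert set(summary.pairs.group) <= {"rank1", "other"}

    def test_uniform_composition_recovered(self, small_pairs, small_pool):
        """Generator draws residues uniformly: composition ~ 1/20 per amino acid."""
        table = run_trials(small_pairs, small_pool, n_trials=1, seed=8)
        summary = characterize_rank_groups(table, small_pairs)
        total = summary.aa_composition.loc["rank1"] + summary.aa_composition.loc["other"]
        # pooled over groups; each fraction near 0.05
        pooled = total / total.sum()
        n_res = sum(
            len(p.entry_a.protein) + len(p.entry_b.protein) for p in small_pairs
        )
        se = np.sqrt(0.05 * 0.95 / n_res)
        assert np.all(np.abs(pooled - 0.05) < 5 * se)
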