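"""Homolog selection, reduced-alphabet entropies, and the two evolutionary scores."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xtalface.constants import MURPHY10
from xtalface.evolution import (BIO, NOPRED, XTAL, HomologHit,
                                SelectionParams, column_entropy,
                                core_rim_score, core_surface_score,
                                entropy_profile, filter_homologs,
                                map_reference, reduce_redundancy)


def hit(i, seq="A" * 50, identity=0.9, coverage=0.9):
    return HomologHit(id=f"h{i:03d}", sequence=seq, identity=identity,
                      coverage=coverage)


class TestReferenceMapping:
    def test_identical_sequences(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        m = map_reference(seq, seq)
        assert m.ok and m.identity == 1.0 and m.coverage == 1.0
        assert m.mismatches == set()
        assert m.mapping == {i: i for i in range(len(seq))}

    def test_two_substitutions_in_hundred(self):
        rng = np.random.default_rng(1)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        ref = "".join(rng.choice(letters, size=100))
        mutant = list(ref)
        mutant[10] = "W" if ref[10] != "W" else "Y"
        mutant[60] = "W" if ref[60] != "W" else "Y"
        m = map_reference("".join(mutant), ref)
        assert m.ok
        assert m.identity == pytest.approx(0.98)
        assert m.mismatches == {10, 60}

    def test_unrelated_sequences_give_no_reference(self):
        m = map_reference("AGAGAGAGAGAGAGAGAGAG", "WYWYWYWYWYWYWYWYWYWY")
        assert not m.ok
        assert m.mapping == {}


class TestHomologFiltering:
    def test_soft_cutoff_satisfied_directly(self):
        hits = [hit(i, identity=0.65) for i in range(12)]
        res = filter_homologs(hits)
        assert res.sufficient and len(res.accepted) == 12
        assert res.effective_cutoff == pytest.approx(0.60)

    def test_relaxation_to_fifty_five_percent(self):
        hits = ([hit(i, identity=0.62) for i in range(4)] +
                [hit(10 + i, identity=0.57) for i in range(7)])
        res = filter_homologs(hits)
        assert res.sufficient and len(res.accepted) == 11
        assert res.effective_cutoff == pytest.approx(0.55)

    def test_insufficient_below_hard_floor(self):
        hits = [hit(i, identity=0.52) for i in range(9)]
        res = filter_homologs(hits)
        assert not res.sufficient
        assert len(res.accepted) == 9

    def test_coverage_filter_applies_first(self):
        hits = ([hit(i, identity=0.9, coverage=0.5) for i in range(20)] +
                [hit(100 + i, identity=0.9, coverage=0.9) for i in range(5)])
        res = filter_homologs(hits)
        assert len(res.accepted) == 5 and not res.sufficient

    def test_lowering_soft_cutoff_is_monotone(self):
        rng = np.random.default_rng(2)
        hits = [hit(i, identity=float(x))
                for i, x in enumerate(rng.uniform(0.4, 1.0, size=40))]
        counts = [len(filter_homologs(
            hits, SelectionParams(soft_identity=s, hard_identity=0.50)
        ).accepted) for s in (0.60, 0.55, 0.50)]
        assert counts == sorted(counts)


class TestRedundancyReduction:
    def test_identical_sequences_collapse(self):
        hits = [hit(0, "MKTAYIAKQR"), hit(1, "MKTAYIAKQR")]
        assert len(reduce_redundancy(hits)) == 1

    def test_diverse_set_unchanged_at_98(self):
        def fake_identity(s1, s2):
            return 0.5
        hits = [hit(i, f"SEQ{i}") for i in range(50)]
        assert len(reduce_redundancy(hits, identity_fn=fake_identity)) == 50

    def test_tight_cluster_collapses_to_one(self):
        def fake_identity(s1, s2):
            return 0.99
        hits = [hit(i, f"SEQ{i}", identity=0.7 + 0.001 * i)
                for i in range(150)]
        reps = reduce_redundancy(hits, identity_fn=fake_identity)
        assert len(reps) == 1
        assert reps[0].id == "h149"   # highest identity to the query

    def test_threshold_steps_down_to_reach_maximum(self):
        # identity 0.95 between consecutive ids only: single linkage chains
        def fake_identity(s1, s2):
            i, j = int(s1[3:]), int(s2[3:])
            return 0.95 if abs(i - j) == 1 else 0.1
        hits = [hit(i, f"SEQ{i:03d}") for i in range(120)]
        reps = reduce_redundancy(hits, SelectionParams(max_sequences=100),
                                 identity_fn=fake_identity)
        assert len(reps) <= 100

    def test_order_stable_and_idempotent(self):
        def fake_identity(s1, s2):
            return 0.99 if s1[:4] == s2[:4] else 0.2
        hits = [hit(i, f"GRP{i % 7}_{i}", identity=0.6 + 0.002 * i)
                for i in range(30)]
        reps = reduce_redundancy(hits, identity_fn=fake_identity)
        rng = np.random.default_rng(0)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert reduce_redundancy(shuffled, identity_fn=fake_identity) == reps
        assert reduce_redundancy(reps, identity_fn=fake_identity) == reps


class TestColumnEntropy:
    @pytest.mark.parametrize("column,expected", [
        ("LLLL", 0.0),
        ("LLVV", 0.0),                        # same hydrophobic class
        ("AAGG", math.log(2)),
        ("LCAGSPFEKH", math.log(10)),         # one of each class
    ])
    def test_exact_values(self, column, expected):
        assert column_entropy(column) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("column", ["----", "L---", "XX--", ""])
    def test_degenerate_columns_are_undefined(self, column):
        assert math.isnan(column_entropy(column))

    def test_entropy_bounds(self):
        rng = np.random.default_rng(0)
        letters = list("ACDEFGHIKLMNPQRSTVWY-")
        for _ in range(50):
            col = "".join(rng.choice(letters, size=30))
            e = column_entropy(col)
            if not math.isnan(e):
                assert 0.0 <= e <= math.log(10) + 1e-12

    @given(st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
                    min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_class_collapse_invariance(self, column, rnd):
        classes = {}
        for letter, cls in MURPHY10.items():
            classes.setdefault(cls, []).append(letter)
        swapped = [rnd.choice(classes[MURPHY10[c]]) for c in column]
        assert column_entropy(swapped) == pytest.approx(
            column_entropy(column), abs=1e-12)


class TestEntropyProfile:
    def test_identical_rows_give_zero_everywhere(self):
        aln = [("query", "MKTAYI"), ("h1", "MKTAYI"), ("h2", "MKTAYI")]
        prof = entropy_profile(aln, "query", 6)
        np.testing.assert_allclose(prof.entropies, 0.0)

    def test_uncovered_residue_is_undefined(self):
        aln = [("query", "MKT"), ("h1", "MKT")]
        prof = entropy_profile(aln, "query", 5)
        assert np.isfinite(prof.entropies[:3]).all()
        assert np.isnan(prof.entropies[3:]).all()

    def test_gap_column_in_query_is_skipped(self):
        aln = [("query", "MK-T"), ("h1", "MKAT")]
        prof = entropy_profile(aln, "query", 3)
        assert np.isfinite(prof.entropies).all()

    def test_row_order_invariance(self):
        aln = [("query", "MKTAYI"), ("h1", "MLTAYI"), ("h2", "MKSAYI")]
        prof1 = entropy_profile(aln, "query", 6)
        prof2 = entropy_profile([aln[0], aln[2], aln[1]], "query", 6)
        np.testing.assert_allclose(prof1.entropies, prof2.entropies)

    def test_missing_query_raises(self):
        with pytest.raises(KeyError):
            entropy_profile([("h1", "MKT")], "query", 3)


class TestCoreRimScore:
    def test_conserved_core_scores_bio(self):
        ratio, call = core_rim_score([0.5] * 10, [1.0] * 10)
        assert ratio == pytest.approx(0.5)
        assert call == BIO

    def test_boundary_ratio_is_crystal(self):
        ratio, call = core_rim_score([0.75] * 10, [1.0] * 10)
        assert ratio == pytest.approx(0.75)
        assert call == XTAL

    def test_exactly_eight_core_residues_is_nopred(self):
        ratio, call = core_rim_score([0.1] * 8, [1.0] * 5)
        assert ratio is None and call == NOPRED

    def test_degenerate_rim_is_nopred(self):
        assert core_rim_score([0.1] * 10, [0.0] * 5) == (None, NOPRED)
        assert core_rim_score([0.1] * 10, []) == (None, NOPRED)


class TestCoreSurfaceScore:
    def test_conserved_core_scores_strongly_negative(self):
        rng = np.random.default_rng(0)
        surface = list(rng.uniform(0.5, 1.5, size=100))
        score, call = core_surface_score([0.0] * 12, surface, seed=1)
        assert score < -3 and call == BIO

    def test_pool_smaller_than_core_is_nopred(self):
        score, call = core_surface_score([0.5] * 10, [0.5] * 9, seed=1)
        assert score is None and call == NOPRED

    def test_constant_pool_is_nopred(self):
        score, call = core_surface_score([0.5] * 10, [1.0] * 50, seed=1)
        assert score is None and call == NOPRED

    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(2)
        surface = list(rng.uniform(0, 2, size=80))
        core = list(rng.uniform(0, 2, size=12))
        s1, _ = core_surface_score(core, surface, seed=77)
        s2, _ = core_surface_score(core, surface, seed=77)
        assert s1 == s2

    def test_sampling_noise_across_seeds_is_small(self):
        rng = np.random.default_rng(3)
        surface = list(rng.uniform(0, 2, size=200))
        core = list(rng.uniform(0, 2, size=15))
        scores = [core_surface_score(core, surface, seed=s)[0]
                  for s in range(12)]
        assert np.std(scores) < 0.05


class TestParameterRecovery:
    def test_planted_conservation_is_recovered(self):
        """Planted low-entropy cores give cr < 1 and cs < 0 in >95% of seeds."""
        from xtalface.synthetic import FixtureSpec, make_msa_fixture
        wins = 0
        n_seeds = 100
        core_pos = list(range(10))
        rim_pos = list(range(10, 25))
        surface_pos = list(range(25, 72))
        for seed in range(n_seeds):
            spec = FixtureSpec(seed=seed,
                               conserved_positions=frozenset(core_pos))
            aln, _ = make_msa_fixture(spec)
            prof = entropy_profile(aln, "query", spec.chain_length)
            core = [prof.entropies[i] for i in core_pos]
            rim = [prof.entropies[i] for i in rim_pos]
            surface = [prof.entropies[i] for i in surface_pos]
            cr, _ = core_rim_score(core, rim, min_core=8)
            cs, _ = core_surface_score(core, surface, n_samples=2000,
                                       seed=seed)
            if cr is not None and cs is not None and cr < 1 and cs < 0:
                wins += 1
        assert wins > 95
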