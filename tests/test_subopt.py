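"""The enumeration core: refinement, pruning modes, oracle equivalence."""

import random
import warnings

import pytest

from subfold import (
    ConstraintSet,
    EnumerationCapExceeded,
    FoldOptions,
    brute_force_enumerate,
    enumerate_suboptimal,
    eval_structure,
    fill_matrices,
    lonely_pair_prunable,
    refine_state,
)
from subfold.subopt import PartialState, SafetyCapWarning, V, W, root_state
from conftest import (
    brute_force_window_set,
    has_lonely_pair,
    max_branches_in_closed_pairs,
    random_sequence,
)


def enum_set(seq, cs=None, opts=None, params=None):
    return {st.to_dotbracket() for st in enumerate_suboptimal(seq, cs, opts, params)}


class TestRefineState:
    def test_unpairable_root_chains_to_open_structure(self, params):
        seq = "AAAA"
        m = fill_matrices(seq, params)
        kids = refine_state(root_state(m), m, seq, ConstraintSet.empty(4), FoldOptions(), params)
        assert len(kids) == 1
        assert kids[0].sigma == ((1, 3, W),)
        assert not kids[0].pairs

    def test_zero_window_leaves_are_mfe_structures(self, params):
        rng = random.Random(3)
        for _ in range(6):
            seq = random_sequence(rng, rng.randint(8, 14))
            m = fill_matrices(seq, params)
            got = list(enumerate_suboptimal(seq, opts=FoldOptions(window=0.0), params=params))
            assert got, seq
            for st in got:
                assert round(st.energy * 10) == m.mfe_deci

    def test_full_expansion_of_14mer_yields_119_leaves(self, seq14, params):
        assert len(enum_set(seq14, params=params)) == 119


class TestLonelyPairPrunable:
    def test_mutually_stacked_pairs_not_prunable(self):
        s = PartialState(sigma=(), pairs=frozenset({(1, 10), (2, 9)}))
        assert not lonely_pair_prunable(s)

    def test_lonely_pair_with_empty_sigma_prunable(self):
        s = PartialState(sigma=(), pairs=frozenset({(1, 10)}))
        assert lonely_pair_prunable(s)

    def test_interior_interval_can_rescue(self):
        s = PartialState(sigma=((3, 12, V),), pairs=frozenset({(3, 12)}))
        assert not lonely_pair_prunable(s, seq="GGGGGAAAACCCCC")
        plain = PartialState(sigma=((4, 11, W),), pairs=frozenset({(3, 12)}))
        assert not lonely_pair_prunable(plain, seq="GGGGGAAAACCCCC")


class TestOracleEquivalence:
    """Exact set equality against brute-force enumerate + evaluate + filter."""

    @pytest.mark.parametrize("trial", range(12))
    def test_windowed_enumeration_matches_oracle(self, trial, params):
        rng = random.Random(100 + trial)
        seq = random_sequence(rng, rng.randint(8, 16))
        window = rng.choice([0.0, 1.5, 4.0, 10.0, None])
        opts = FoldOptions(window=window)
        got = enum_set(seq, opts=opts, params=params)
        brute = brute_force_enumerate(seq)
        if window is None:
            want = {st.to_dotbracket() for st in brute}
        else:
            want = brute_force_window_set(seq, brute, params, window)
        assert got == want, (seq, window)

    def test_no_lonely_pairs_equals_filtered_oracle(self, params):
        rng = random.Random(41)
        for _ in range(6):
            seq = random_sequence(rng, rng.randint(8, 14))
            opts = FoldOptions(no_lonely_pairs=True)
            got = enum_set(seq, opts=opts, params=params)
            want = {
                st.to_dotbracket()
                for st in brute_force_enumerate(seq)
                if not has_lonely_pair(st)
            }
            assert got == want, seq

    def test_lonely_pairs_appear_without_the_pruning(self, params):
        """Regression for the motivating defect: with a large window and no
        pruning, isolated pairs are emitted; the flag removes all of them."""
        seq = "GCUCUAAAAGAGAG"
        plain = list(enumerate_suboptimal(seq, opts=FoldOptions(window=30.0), params=params))
        assert any(has_lonely_pair(st) for st in plain)
        pruned = list(
            enumerate_suboptimal(
                seq, opts=FoldOptions(window=30.0, no_lonely_pairs=True), params=params
            )
        )
        assert pruned and not any(has_lonely_pair(st) for st in pruned)

    def test_no_multibranch_structures_are_hairpin_series(self, params):
        rng = random.Random(43)
        for _ in range(5):
            seq = random_sequence(rng, rng.randint(10, 16))
            opts = FoldOptions(no_multibranch=True)
            got = {st.to_dotbracket() for st in enumerate_suboptimal(seq, opts=opts, params=params)}
            want = {
                st.to_dotbracket()
                for st in brute_force_enumerate(seq)
                if max_branches_in_closed_pairs(st) <= 1
            }
            assert got == want, seq

    def test_no_duplicates_and_energy_cross_check(self, params):
        rng = random.Random(47)
        seq = random_sequence(rng, 14)
        out = list(enumerate_suboptimal(seq, params=params))
        dbs = [st.to_dotbracket() for st in out]
        assert len(dbs) == len(set(dbs))
        for st in out:
            assert eval_structure(seq, st, params) == pytest.approx(st.energy, abs=1e-3)

    def test_count_grows_monotonically_and_fast_with_window(self, params):
        seq = "GGCGCAAUAAGCGCCAAGGCC"
        counts = []
        for w in (0.0, 2.0, 4.0, 8.0, 16.0):
            n = sum(1 for _ in enumerate_suboptimal(seq, opts=FoldOptions(window=w), params=params))
            counts.append(n)
        assert counts == sorted(counts)
        # superlinear growth: the largest window step adds the most structures
        assert counts[-1] - counts[-2] > counts[1] - counts[0]


class TestLowMemoryMode:
    def test_sorted_output_identical_to_standard(self, params):
        rng = random.Random(53)
        for _ in range(4):
            seq = random_sequence(rng, rng.randint(10, 15))
            std = sorted(
                (st.to_dotbracket(), round(st.energy * 10))
                for st in enumerate_suboptimal(seq, opts=FoldOptions(), params=params)
            )
            low = sorted(
                (st.to_dotbracket(), round(st.energy * 10))
                for st in enumerate_suboptimal(seq, opts=FoldOptions(low_memory=True), params=params)
            )
            assert std == low

    def test_first_emission_retains_linear_state(self, params):
        """Frames held before the first leaf is reached stay O(N)."""
        from subfold.subopt import _enumerate_low_memory

        seq = "GC" * 20 + "AAAA" + "GC" * 20
        m = fill_matrices(seq, params)
        gen = _enumerate_low_memory(
            root_state(m), m, seq, ConstraintSet.empty(len(seq)), FoldOptions(), params, None
        )
        next(gen)  # force work up to the first emission
        # the generator's frame stack is bounded by the refinement depth,
        # which is at most one frame per nucleotide
        frames = gen.gi_frame.f_locals["frames"]
        assert len(frames) <= len(seq)


def test_safety_cap_warning_and_cap(params):
    seq14 = "GCUCUAAAAGAGAG"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        next(enumerate_suboptimal(seq14, opts=FoldOptions(max_structures=50), params=params))
    # combinatorial run projected beyond the cap warns up front ...
    assert any(issubclass(w.category, SafetyCapWarning) for w in caught)
    # ... and emission past the cap raises
    with pytest.raises(EnumerationCapExceeded), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        list(enumerate_suboptimal(seq14, opts=FoldOptions(max_structures=50), params=params))
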