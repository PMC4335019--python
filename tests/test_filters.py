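"""Helix detection, the helix filter and landscape metrics."""

import random

import pytest
from hypothesis import given, strategies as st

from subfold import (
    HelixFilterSpec,
    SecondaryStructure,
    ValidationError,
    base_pair_distance,
    find_helices,
    helix_filter_pass,
    landscape_summary,
    nucleotide_difference,
)
from conftest import random_sequence


def _random_structure(rng: random.Random, n: int) -> SecondaryStructure:
    """Independent random non-crossing pair sets (interval recursion)."""
    pairs = []

    def build(a, b):
        if b - a < 4:
            return
        if rng.random() < 0.5:
            j = rng.randint(a + 4, b)
            i = rng.randint(a, j - 4)
            pairs.append((i, j))
            build(i + 1, j - 1)
            build(a, i - 1)

    build(1, n)
    return SecondaryStructure(n=n, pairs=frozenset(pairs))


class TestFindHelices:
    def test_perfect_stack_is_one_helix(self):
        st_ = SecondaryStructure(n=12, pairs={(1, 12), (2, 11), (3, 10), (4, 9)})
        helices = find_helices(st_, 0)
        assert len(helices) == 1
        assert helices[0].length == 4
        assert helices[0].mismatches == 0

    def test_one_by_one_interruption_extends_with_tolerance(self):
        pairs = {(1, 14), (2, 13), (4, 11), (5, 10)}
        st_ = SecondaryStructure(n=14, pairs=pairs)
        with_tol = find_helices(st_, 1)
        assert len(with_tol) == 1
        assert with_tol[0].length == 4
        assert with_tol[0].mismatches == 1
        without = find_helices(st_, 0)
        assert sorted(h.length for h in without) == [2, 2]

    def test_bulge_terminates_helix(self):
        # (2,13) -> (4,12) skips one nucleotide on one side only: a bulge
        st_ = SecondaryStructure(n=15, pairs={(1, 14), (2, 13), (4, 12), (5, 11)})
        assert len(find_helices(st_, 3)) == 2

    def test_empty_structure(self):
        assert find_helices(SecondaryStructure(n=9), 2) == []

    def test_partition_is_exact(self):
        rng = random.Random(61)
        for _ in range(20):
            st_ = _random_structure(rng, 40)
            helices = find_helices(st_, 2)
            emitted = [p for h in helices for p in h.pair_run]
            assert sorted(emitted) == sorted(st_.pairs)


class TestHelixFilterPass:
    def test_count_and_length_thresholds(self):
        st_ = SecondaryStructure(
            n=22, pairs={(i, 22 - i + 1) for i in range(1, 10)}
        )  # one 9-pair helix
        assert helix_filter_pass(st_, HelixFilterSpec(1, 9, 0))
        assert not helix_filter_pass(st_, HelixFilterSpec(2, 9, 0))
        assert not helix_filter_pass(st_, HelixFilterSpec(1, 10, 0))

    def test_three_hairpin_structure_with_short_third_helix(self):
        """Helices of 9, 9 and 8 pairs fail a 3x9 requirement."""
        pairs = set()
        offset = 0
        for length in (9, 9, 8):
            span = 2 * length + 4
            pairs |= {(offset + k, offset + span - k + 1) for k in range(1, length + 1)}
            offset += span
        st_ = SecondaryStructure(n=offset, pairs=pairs)
        assert helix_filter_pass(st_, HelixFilterSpec(2, 9, 3))
        assert not helix_filter_pass(st_, HelixFilterSpec(3, 9, 3))

    def test_monotone_in_every_spec_field(self):
        rng = random.Random(67)
        for _ in range(15):
            st_ = _random_structure(rng, 30)
            for count in (1, 2):
                for length in (2, 3):
                    for mm in (0, 1):
                        if helix_filter_pass(st_, HelixFilterSpec(count, length, mm)):
                            assert helix_filter_pass(
                                st_, HelixFilterSpec(count - 1 or 0, length - 1, mm + 1)
                            )

    def test_spec_parse(self):
        spec = HelixFilterSpec.parse("30:9:3")
        assert (spec.min_helix_count, spec.min_helix_length, spec.max_mismatches_per_helix) == (30, 9, 3)
        with pytest.raises(ValidationError):
            HelixFilterSpec.parse("30:9")


@st.composite
def structures(draw, n=24):
    rng = random.Random(draw(st.integers(0, 10 ** 6)))
    return _random_structure(rng, n)


class TestBasePairDistance:
    def test_identity_and_single_difference(self):
        a = SecondaryStructure(n=8, pairs={(1, 7), (2, 6)})
        b = SecondaryStructure(n=8, pairs={(2, 6)})
        assert base_pair_distance(a, a) == 0
        assert base_pair_distance(a, b) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            base_pair_distance(SecondaryStructure(n=5), SecondaryStructure(n=6))

    @given(structures(), structures(), structures())
    def test_metric_axioms(self, a, b, c):
        assert base_pair_distance(a, b) == base_pair_distance(b, a)
        assert (base_pair_distance(a, b) == 0) == (a.pairs == b.pairs)
        assert base_pair_distance(a, c) <= base_pair_distance(a, b) + base_pair_distance(b, c)

    @given(structures(), structures())
    def test_matches_independent_sorted_merge(self, a, b):
        """Second implementation: merge two sorted pair lists."""
        la, lb = sorted(a.pairs), sorted(b.pairs)
        ia = ib = common = 0
        while ia < len(la) and ib < len(lb):
            if la[ia] == lb[ib]:
                common += 1
                ia += 1
                ib += 1
            elif la[ia] < lb[ib]:
                ia += 1
            else:
                ib += 1
        expected = len(la) + len(lb) - 2 * common
        assert base_pair_distance(a, b) == expected

    def test_nucleotide_difference_bounds(self):
        a = SecondaryStructure(n=10, pairs={(1, 10), (2, 9)})
        b = SecondaryStructure(n=10, pairs={(1, 10), (3, 8)})
        assert nucleotide_difference(a, a) == 0
        assert nucleotide_difference(a, b) == 4


class TestLandscapeSummary:
    def test_singleton_ensemble(self):
        ref = SecondaryStructure(n=8, pairs={(1, 8)}, energy=-1.0)
        s = landscape_summary([ref])
        assert (s.count, s.max_distance, s.mean_distance) == (1, 0, 0.0)

    def test_hand_computed_mean(self):
        ref = SecondaryStructure(n=10, pairs={(1, 10), (2, 9)}, energy=-2.0)
        others = [
            SecondaryStructure(n=10, pairs={(1, 10)}, energy=-1.0),
            SecondaryStructure(n=10, pairs=frozenset(), energy=0.0),
        ]
        s = landscape_summary([ref] + others)
        # distances to ref: 0, 1, 2
        assert s.max_distance == 2
        assert s.mean_distance == pytest.approx(1.0)
        assert s.energy_span == pytest.approx(2.0)
        assert s.reference is ref

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValidationError):
            landscape_summary([])
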