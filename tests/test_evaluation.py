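import math
import os
import sys

import numpy as np
import pytest

from moddens import (
    Partition,
    accuracy,
    best_match,
    contingency,
    filter_small_modules,
    overlap_neg_log10_pvalue,
    precision,
    read_complex_catalogue,
    separation,
)

sys.path.insert(0, os.path.dirname(__file__))
from oracles import exact_hypergeom_tail_neg_log10


class TestPrecision:
    def test_identical_partitions(self, two_triangles):
        _, p = two_triangles
        assert precision(p, p) == 1.0

    def test_single_detected_module(self):
        planted = Partition.from_modules(
            {str(i): [f"v{i}_{j}" for j in range(5)] for i in range(4)}
        )
        detected = Partition.from_modules({"all": list(planted.nodes)})
        assert precision(detected, planted) == pytest.approx(0.25)

    def test_one_node_swapped_between_triangles(self):
        planted = Partition.from_modules({"1": "abc", "2": "def"})
        detected = Partition.from_modules({"x": "ab", "y": "cdef"})
        # matched pairs: (2,y) overlap 3 first, then (1,x) overlap 2 -> 5/6
        assert precision(detected, planted) == pytest.approx(5 / 6)

    def test_symmetric_under_relabeling(self, two_triangles):
        _, p = two_triangles
        renamed = Partition({n: "zz" + lab for n, lab in p.assignment.items()})
        assert precision(renamed, p) == 1.0

    def test_hungarian_matches_greedy_on_easy_case(self, two_triangles):
        _, p = two_triangles
        detected = Partition.from_modules({"x": "abc", "y": "def"})
        assert precision(detected, p, method="hungarian") == precision(detected, p)

    def test_disjoint_node_sets_rejected(self, two_triangles):
        _, p = two_triangles
        with pytest.raises(ValueError):
            precision(p, Partition({"q": "1"}))


class TestOverlapPValue:
    @pytest.mark.parametrize(
        "C,M,k,expected",
        [
            (12, 11, 8, 17.74),
            (4, 5, 4, 11.55),
            (8, 9, 8, 21.70),
            (14, 14, 10, 21.51),
            (9, 7, 6, 14.81),
        ],
    )
    def test_published_module_matches(self, C, M, k, expected):
        """P_ol values for the DIP yeast network (N = 2559) matches."""
        assert overlap_neg_log10_pvalue(2559, C, M, k) == pytest.approx(
            expected, abs=0.01
        )

    def test_zero_overlap_is_exactly_zero(self):
        assert overlap_neg_log10_pvalue(2559, 12, 11, 0) == 0.0

    def test_monotone_in_overlap(self):
        vals = [overlap_neg_log10_pvalue(500, 20, 30, k) for k in range(0, 21)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_agrees_with_exact_rational_tail(self):
        """Log-space tail matches exact rational arithmetic for N <= 60."""
        for N, C, M, k in [
            (60, 10, 12, 5), (60, 10, 12, 0), (40, 8, 8, 8),
            (55, 20, 30, 15), (30, 5, 25, 5), (60, 1, 1, 1),
        ]:
            got = overlap_neg_log10_pvalue(N, C, M, k)
            want = exact_hypergeom_tail_neg_log10(N, C, M, k)
            assert math.isclose(got, want, rel_tol=1e-9, abs_tol=1e-12)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            overlap_neg_log10_pvalue(100, 5, 6, 7)
        with pytest.raises(ValueError):
            overlap_neg_log10_pvalue(10, 50, 5, 2)


class TestBestMatch:
    def test_module_identical_to_complex(self):
        modules = Partition.from_modules({"m1": "abcd"})
        cat = {"c1": frozenset("abcd"), "c2": frozenset("xy")}
        (r,) = best_match(modules, cat, N=100)
        assert r.complex == "c1" and r.overlap == 4
        assert r.neg_log10_pol > 0

    def test_small_specific_overlap_beats_large_diffuse(self):
        modules = Partition.from_modules({"m1": [f"p{i}" for i in range(5)]})
        cat = {
            "A": frozenset(f"p{i}" for i in range(5)),
            "B": frozenset([f"p{i}" for i in range(5)] + [f"q{i}" for i in range(45)]),
        }
        (r,) = best_match(modules, cat, N=500)
        assert r.complex == "A"

    def test_disjoint_module_scores_zero(self):
        modules = Partition.from_modules({"m1": "xyz"})
        cat = {"c1": frozenset("ab"), "c2": frozenset("cd")}
        (r,) = best_match(modules, cat, N=50)
        assert r.neg_log10_pol == 0.0 and r.overlap == 0


class TestContingencyAccuracySeparation:
    def test_hand_counted_table(self):
        modules = Partition.from_modules({"M1": "ab", "M2": "cde"})
        cat = {"C1": frozenset("abc"), "C2": frozenset("de")}
        table = contingency(modules, cat)
        np.testing.assert_array_equal(table.values, [[2, 1], [0, 2]])
        assert table.complex_sizes == (3, 2)

    def test_protein_outside_modules_counts_in_complex_size(self):
        modules = Partition.from_modules({"M1": "ab"})
        cat = {"C1": frozenset("abz")}
        table = contingency(modules, cat)
        assert table.values[0, 0] == 2 and table.complex_sizes == (3,)

    def test_accuracy_hand_values(self):
        modules = Partition.from_modules({"M1": "ab", "M2": "cde"})
        cat = {"C1": frozenset("abc"), "C2": frozenset("de")}
        sn, ppv, acc = accuracy(contingency(modules, cat))
        assert (sn, ppv, acc) == pytest.approx((0.8, 0.8, 0.8))

    def test_perfect_bijection_all_ones(self):
        modules = Partition.from_modules({"M1": "abc", "M2": "de"})
        cat = {"C1": frozenset("abc"), "C2": frozenset("de")}
        table = contingency(modules, cat)
        assert accuracy(table) == pytest.approx((1.0, 1.0, 1.0))
        assert separation(table) == pytest.approx((1.0, 1.0, 1.0))

    def test_single_module_capturing_everything(self):
        modules = Partition.from_modules({"M1": "abcde"})
        cat = {"C1": frozenset("abc"), "C2": frozenset("de")}
        sn, ppv, acc = accuracy(contingency(modules, cat))
        assert sn == 1.0 and ppv == pytest.approx(3 / 5)
        assert acc == pytest.approx(math.sqrt(0.6))

    def test_separation_hand_values(self):
        modules = Partition.from_modules({"M1": "ab", "M2": "cde"})
        cat = {"C1": frozenset("abc"), "C2": frozenset("de")}
        sep_co, sep_cl, sep = separation(contingency(modules, cat))
        assert (sep_co, sep_cl, sep) == pytest.approx((13 / 18, 13 / 18, 13 / 18))

    def test_complex_split_evenly_across_modules(self):
        """Splitting a complex across two otherwise-pure modules is penalized
        on the module side (SEP_cl), not the complex side: each module is
        fully dedicated to the complex (col freq 1, row freq 1/2)."""
        modules = Partition.from_modules({"M1": "a", "M2": "b"})
        cat = {"C1": frozenset("ab")}
        sep_co, sep_cl, sep = separation(contingency(modules, cat))
        assert sep_co == pytest.approx(1.0)
        assert sep_cl == pytest.approx(0.5)
        assert sep == pytest.approx(math.sqrt(0.5))

    def test_measures_bounded_in_unit_interval(self):
        modules = Partition.from_modules({"M1": "abx", "M2": "cdy", "M3": "e"})
        cat = {"C1": frozenset("abc"), "C2": frozenset("de"), "C3": frozenset("ax")}
        table = contingency(modules, cat)
        for v in (*accuracy(table), *separation(table)):
            assert 0.0 <= v <= 1.0


class TestFilterSmallModules:
    def test_drops_small_modules(self):
        p = Partition.from_modules({"a": "wxyz", "b": "pqr", "c": "mn"})
        kept = filter_small_modules(p, 4)
        assert set(kept.modules) == {"a"}
        assert kept.nodes == frozenset("wxyz")

    def test_min_size_one_is_identity(self):
        p = Partition.from_modules({"a": "xy", "b": "z"})
        assert filter_small_modules(p, 1).assignment == p.assignment

    def test_all_below_threshold_empty(self):
        p = Partition.from_modules({"a": "x", "b": "y"})
        assert filter_small_modules(p, 5).assignment == {}


def test_read_complex_catalogue(tmp_path):
    f = tmp_path / "cat.tsv"
    f.write_text("# complex protein\nc1 a\nc1 b\nc2 b\nc2 c\n")
    cat = read_complex_catalogue(f)
    assert cat == {"c1": frozenset("ab"), "c2": frozenset("bc")}
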