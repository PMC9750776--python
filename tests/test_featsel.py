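"""Similarity scorers and the two-stage selection cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mongoosenet import (
    CongruenceKHSSelector,
    SynthConfig,
    cascade_select,
    congruence_score,
    generate,
    khs_score,
    select_top,
)
from mongoosenet.preprocess import impute_missing


def naive_congruence(p, r):
    num = sum(pi * ri for pi, ri in zip(p, r))
    return num / math.sqrt(sum(pi * pi for pi in p) * sum(ri * ri for ri in r))


def naive_khs(t, v):
    tv = sum(a * b for a, b in zip(t, v))
    return tv / (sum(a * a for a in t) + sum(b * b for b in v) - tv)


class TestCongruence:
    @pytest.mark.parametrize("p,r,expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),         # collinear
        ([1, 0], [0, 1], 0.0),               # orthogonal
        ([1, 2], [2, 1], 0.8),               # ΣPR=4, ΣP²=ΣR²=5
        ([1, 2], [-1, -2], -1.0),            # anti-collinear
    ])
    def test_hand_examples(self, p, r, expected):
        assert congruence_score(p, r) == pytest.approx(expected, abs=1e-15)

    def test_matches_naive_loop_oracle(self, rng):
        for _ in range(1000):
            p = rng.normal(size=5)
            r = rng.normal(size=5)
            assert congruence_score(p, r) == pytest.approx(
                naive_congruence(p, r), abs=1e-12
            )

    @given(st.lists(st.floats(-10, 10, width=32), min_size=3, max_size=8),
           st.floats(0.1, 100))
    def test_scale_invariant(self, vals, c):
        p = np.array(vals)
        r = np.arange(1.0, p.size + 1)
        if not np.any(p):
            return
        assert congruence_score(c * p, r) == pytest.approx(
            congruence_score(p, r), abs=1e-9
        )

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(200):
            s = congruence_score(rng.normal(size=6), rng.normal(size=6))
            assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12

    def test_unscaled_variant_not_scale_invariant(self):
        p, r = np.array([1.0, 2.0]), np.array([2.0, 1.0])
        a = congruence_score(p, r, form="unscaled")
        b = congruence_score(2 * p, r, form="unscaled")
        assert a != pytest.approx(b)

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError, match="undefined congruence"):
            congruence_score([0, 0], [1, 2])

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            congruence_score([1, 2, 3], [1, 2])


class TestKHS:
    @pytest.mark.parametrize("t,v,expected", [
        ([3, 1, 4], [3, 1, 4], 1.0),         # self-similarity
        ([1, 0], [0, 1], 0.0),               # disjoint support
        ([1, 2], [2, 1], 2.0 / 3.0),         # 4/(5+5-4)
    ])
    def test_hand_examples(self, t, v, expected):
        assert khs_score(t, v) == pytest.approx(expected, abs=1e-15)

    def test_matches_naive_loop_oracle(self, rng):
        for _ in range(1000):
            t = rng.normal(size=5)
            v = rng.normal(size=5)
            assert khs_score(t, v) == pytest.approx(naive_khs(t, v), abs=1e-12)

    def test_not_scale_invariant(self):
        t = np.array([1.0, 2.0, 3.0])
        assert khs_score(2 * t, t) != pytest.approx(1.0)

    def test_one_only_for_identical_vectors(self, rng):
        t = rng.normal(size=6)
        assert khs_score(t, t) == pytest.approx(1.0)
        assert khs_score(t + 0.1, t) < 1.0

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError, match="zero denominator"):
            khs_score([0, 0], [0, 0])


class TestSelectTop:
    def test_picks_largest(self):
        np.testing.assert_array_equal(select_top([0.9, 0.1, 0.5], 2), [0, 2])

    def test_tie_breaks_to_lower_index(self):
        np.testing.assert_array_equal(select_top([0.5, 0.5, 0.1], 1), [0])
        np.testing.assert_array_equal(select_top([0.3, 0.7, 0.7], 2), [1, 2])

    def test_count_equals_length_returns_all(self):
        assert set(select_top([0.2, 0.8, 0.5], 3)) == {0, 1, 2}

    def test_count_too_large_errors(self):
        with pytest.raises(ValueError):
            select_top([0.1, 0.2], 3)


class TestCascade:
    def test_label_copy_column_wins(self, rng):
        y = np.array([0, 1, 1, 0, 1, 0, 1, 0])
        X = np.column_stack([y.astype(float),
                             rng.normal(size=8), rng.normal(size=8)])
        sel = CongruenceKHSSelector(o=2, z=1).fit(X, y)
        np.testing.assert_array_equal(sel.stage2_kept_, [0])

    def test_identical_columns_kept_by_tie_rule(self):
        y = np.array([0, 1, 0, 1])
        X = np.tile(np.array([1.0, 2.0, 1.0, 2.0])[:, None], (1, 4))
        sel = CongruenceKHSSelector(o=3, z=2).fit(X, y)
        np.testing.assert_array_equal(np.sort(sel.stage1_kept_), [0, 1, 2])
        np.testing.assert_array_equal(np.sort(sel.stage2_kept_), [0, 1])

    def test_one_column_dropped_per_stage(self, rng):
        y = np.array([0, 1, 0, 1, 1])
        X = rng.normal(size=(5, 3))
        sel = CongruenceKHSSelector(o=2, z=1).fit(X, y)
        assert len(sel.stage1_kept_) == 2 and len(sel.stage2_kept_) == 1

    def test_stage2_is_subset_of_stage1(self, rng):
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        X = rng.normal(size=(30, 10))
        sel = CongruenceKHSSelector(o=6, z=3).fit(X, y)
        assert set(sel.stage2_kept_) <= set(sel.stage1_kept_)

    def test_enlarging_z_gives_superset(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        X = rng.normal(size=(40, 10))
        kept = [set(CongruenceKHSSelector(o=8, z=z).fit(X, y).stage2_kept_)
                for z in (2, 4, 6)]
        assert kept[0] <= kept[1] <= kept[2]

    def test_ordering_violation_errors(self, rng):
        y = np.array([0, 1, 0, 1])
        X = rng.normal(size=(4, 3))
        with pytest.raises(ValueError, match="n > o > z"):
            CongruenceKHSSelector(o=3, z=1).fit(X, y)  # o == n
        with pytest.raises(ValueError, match="n > o > z"):
            CongruenceKHSSelector(o=2, z=2).fit(X, y)

    def test_default_counts(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        X = rng.normal(size=(50, 13))
        sel = CongruenceKHSSelector().fit(X, y)
        assert sel.o_ == math.ceil(0.6 * 13) and sel.z_ == math.ceil(0.5 * sel.o_)

    def test_requires_imputed_dataset(self, small_dataset):
        with pytest.raises(ValueError, match="imputed"):
            cascade_select(small_dataset, o=2, z=1)

    def test_recovers_planted_signal(self):
        data, truth = generate(SynthConfig(
            n_samples=400, n_numeric=10, n_categorical=4, n_informative=4,
            effect_size=2.0, missing_rate=0.0, seed=11,
        ))
        selected, sel = cascade_select(impute_missing(data), o=8, z=4)
        overlap = set(truth["informative_columns"]) & set(sel.stage2_kept_.tolist())
        assert len(overlap) >= 3

    def test_report_table_shape(self, rng):
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        X = rng.normal(size=(30, 6))
        sel = CongruenceKHSSelector(o=4, z=2).fit(X, y)
        rep = sel.report(list("abcdef"))
        assert list(rep.columns) == [
            "column", "stage1_score", "stage1_kept", "stage2_score", "stage2_kept"
        ]
        assert rep["stage2_kept"].sum() == 2
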