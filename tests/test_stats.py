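"""Nonparametric statistics: MWU, Fisher combination, permutation test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from spikewell.features import FEATURE_COLUMNS
from spikewell.io import GroupAssignment
from spikewell.stats import (
    fisher_combine,
    mwu_test,
    per_div_series,
    permutation_test,
)


class TestMWU:
    def test_fully_separated_small_samples(self):
        res = mwu_test([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_multisets_give_p_one(self):
        res = mwu_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(0)
        for n_a, n_b in [(3, 5), (8, 8), (12, 15)]:
            a, b = rng.normal(size=n_a), rng.normal(1.0, size=n_b)
            assert mwu_test(a, b).p == pytest.approx(mwu_test(b, a).p)

    def test_exact_path_matches_scipy_enumeration_exhaustively(self):
        """Every rank arrangement for all group sizes up to 6, no ties:
        the enumeration must reproduce scipy's exact distribution."""
        for n_a, n_b in itertools.product(range(2, 7), repeat=2):
            n = n_a + n_b
            for combo in itertools.combinations(range(n), n_a):
                values = np.arange(1.0, n + 1.0)
                a = values[list(combo)]
                b = np.delete(values, list(combo))
                ours = mwu_test(a, b)
                ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
                assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-12), (
                    n_a, n_b, combo,
                )

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(1)
        a = np.round(rng.normal(size=30), 1)  # induces ties
        b = np.round(rng.normal(0.5, size=25), 1)
        ours = mwu_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.method == "asymptotic"
        assert ours.p == pytest.approx(float(ref.pvalue))

    def test_missing_values_dropped_and_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            mwu_test([1.0, math.nan], [2.0, 3.0])


class TestFisher:
    def test_two_p_of_005(self):
        res = fisher_combine([0.05, 0.05])
        assert res.chi2 == pytest.approx(-2 * 2 * math.log(0.05))
        assert res.df == 4
        assert res.p == pytest.approx(0.0175, abs=2e-4)

    def test_single_p_identity(self):
        for p in (0.001, 0.05, 0.5, 1.0):
            assert fisher_combine([p]).p == pytest.approx(p)

    def test_all_ones_boundary(self):
        res = fisher_combine([1.0, 1.0])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_combine_pvalues(self):
        rng = np.random.default_rng(2)
        ps = rng.uniform(0.001, 1.0, size=9)
        ours = fisher_combine(ps)
        ref_stat, ref_p = sps.combine_pvalues(ps, method="fisher")
        assert ours.chi2 == pytest.approx(float(ref_stat))
        assert ours.p == pytest.approx(float(ref_p))

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


def feature_frame(values_by_well: dict[str, dict[int, float]], feature="mfr_hz"):
    rows = []
    for well, per_div in values_by_well.items():
        for div, v in per_div.items():
            row = {c: math.nan for c in FEATURE_COLUMNS}
            row.update({"div": div, "well_id": well, "condition": "", feature: v})
            rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def two_group_design(n_a=6, n_b=6, shift=0.0, divs=(8, 9, 10), seed=0):
    rng = np.random.default_rng(seed)
    values, mapping = {}, {}
    for i in range(n_a):
        w = f"C{i}"
        mapping[w] = "control"
        values[w] = {d: float(rng.normal()) for d in divs}
    for i in range(n_b):
        w = f"T{i}"
        mapping[w] = "treated"
        values[w] = {d: float(rng.normal(shift)) for d in divs}
    return feature_frame(values), GroupAssignment(mapping)


class TestPermutationTest:
    def test_complete_separation_reaches_attainable_minimum(self):
        values = {f"C{i}": {8: float(i)} for i in range(17)}
        values.update({f"T{i}": {8: 100.0 + i} for i in range(16)})
        mapping = {w: ("control" if w.startswith("C") else "treated") for w in values}
        table = feature_frame(values)
        res = permutation_test(
            table, GroupAssignment(mapping), "mfr_hz", window=(8, 16),
            n_perm=10_000, seed=42,
        )
        assert res.perm_p == pytest.approx(1 / 10_001)
        assert res.perm_p < 1e-4  # reportable as p < 0.0001

    def test_lower_bound_never_violated(self):
        table, ga = two_group_design(shift=5.0)
        res = permutation_test(table, ga, "mfr_hz", n_perm=200, seed=0)
        assert res.perm_p >= 1 / 201

    def test_same_seed_reproduces_different_seed_varies(self):
        table, ga = two_group_design(shift=0.8, seed=3)
        r1 = permutation_test(table, ga, "mfr_hz", n_perm=500, seed=7)
        r2 = permutation_test(table, ga, "mfr_hz", n_perm=500, seed=7)
        r3 = permutation_test(table, ga, "mfr_hz", n_perm=500, seed=8)
        assert r1.perm_p == r2.perm_p
        assert abs(r3.perm_p - r1.perm_p) < 5 / math.sqrt(500)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        """Rank-based pipeline: exp-transforming the feature leaves the
        permutation p unchanged (single-day window, so the well reduction
        is itself rank-preserving)."""
        table, ga = two_group_design(shift=0.5, divs=(8,), seed=seed)
        transformed = table.copy()
        transformed["mfr_hz"] = np.exp(transformed["mfr_hz"])
        r1 = permutation_test(table, ga, "mfr_hz", n_perm=300, seed=99)
        r2 = permutation_test(transformed, ga, "mfr_hz", n_perm=300, seed=99)
        assert r1.perm_p == r2.perm_p
        assert r1.observed_mwu_p == pytest.approx(r2.observed_mwu_p)

    def test_concat_reducer_keeps_well_as_permutation_unit(self):
        table, ga = two_group_design(shift=1.0, divs=(8, 9, 10, 11), seed=5)
        res = permutation_test(table, ga, "mfr_hz", n_perm=500, seed=1, reducer="concat")
        assert 1 / 501 <= res.perm_p <= 1.0

    def test_group_collapse_is_an_error(self):
        table, ga = two_group_design(n_a=1, n_b=6)
        with pytest.raises(ValueError, match="2 wells"):
            permutation_test(table, ga, "mfr_hz", n_perm=100, seed=0)

    def test_empty_window_is_an_error(self):
        table, ga = two_group_design()
        with pytest.raises(ValueError, match="window"):
            permutation_test(table, ga, "mfr_hz", window=(20, 25), n_perm=100, seed=0)


class TestPerDivSeries:
    def test_single_day_window_equals_that_days_p(self):
        table, ga = two_group_design(divs=(9,), shift=1.0, seed=2)
        out = per_div_series(table, ga, "mfr_hz", window=(9, 9))
        assert out["fisher"].p == pytest.approx(out["per_div_p"][9])
        assert out["fisher"].df == 2

    def test_null_days_combine_to_large_p(self):
        """With identical group distributions every per-day p should be
        moderate and the combination far from significant (seeded check)."""
        table, ga = two_group_design(n_a=8, n_b=8, shift=0.0, divs=tuple(range(8, 17)), seed=11)
        out = per_div_series(table, ga, "mfr_hz")
        assert out["fisher"].p > 0.05
        assert out["fisher"].df == 2 * len(out["per_div_p"])

    def test_one_strong_day_among_nine_pulls_combination_down(self):
        table, ga = two_group_design(n_a=8, n_b=8, shift=0.0, divs=tuple(range(8, 17)), seed=4)
        null_out = per_div_series(table, ga, "mfr_hz")
        strong = table.copy()
        sel = (strong["div"] == 12) & strong["well_id"].str.startswith("T")
        strong.loc[sel, "mfr_hz"] += 50.0
        out = per_div_series(strong, ga, "mfr_hz")
        # the separated day drives the combination well below the null run
        assert out["per_div_p"][12] < 1e-3
        assert out["fisher"].p < null_out["fisher"].p
        assert out["fisher"].p < 0.05

    def test_days_with_too_few_wells_are_skipped_and_reported(self):
        table, ga = two_group_design(divs=(8, 9))
        table = table[~((table["div"] == 9) & table["well_id"].str.startswith("T"))]
        out = per_div_series(table, ga, "mfr_hz", window=(8, 9))
        assert out["skipped_divs"] == [9]
        assert list(out["per_div_p"]) == [8]
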