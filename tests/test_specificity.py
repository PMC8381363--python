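import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tissueatlas import (
    Category,
    CategorySummary,
    ThresholdConfig,
    TissueProfile,
    ValidationError,
    classify_all,
    classify_gene,
    detected_gene_counts,
    elevated_transcript_fraction,
)
from tissueatlas.exceptions import UndefinedStatisticError
from tissueatlas.specificity import SpecificityCall, pct, round_half_away

from conftest import brute_force_category

T4 = ["a", "b", "c", "d"]
T6 = ["a", "b", "c", "d", "e", "f"]
T8 = [f"t{i}" for i in range(8)]


class TestClassifyGene:
    """Worked examples; expected values checked by hand against the rules."""

    def test_all_zero_is_not_detected(self):
        assert classify_gene([0, 0, 0, 0], T4).category is Category.NOT_DETECTED

    def test_below_cutoff_everywhere_is_not_detected(self):
        assert classify_gene([0.9, 0.5, 0.1, 0.0], T4).category is Category.NOT_DETECTED

    def test_tissue_enriched_fold_and_high_flag(self):
        # 100 >= 5*5 -> enriched; fold 100/5 = 20 < 50 so not highly enriched
        call = classify_gene([100, 5, 5, 5], T4)
        assert call.category is Category.TISSUE_ENRICHED
        assert call.elevated_tissues == ("a",)
        assert call.fold_change == pytest.approx(20.0)
        assert not call.highly_enriched
        # 300/5 = 60 >= 50 -> highly enriched
        call = classify_gene([300, 5, 5, 5], T4)
        assert call.fold_change == pytest.approx(60.0)
        assert call.highly_enriched

    def test_enriched_over_zero_background_has_infinite_fold(self):
        call = classify_gene([10, 0, 0, 0], T4)
        assert call.category is Category.TISSUE_ENRICHED
        assert math.isinf(call.fold_change)
        assert call.highly_enriched

    def test_exact_fivefold_tie_qualifies(self):
        # inclusive reading: 25 == 5*5 counts as enriched
        assert classify_gene([25, 5, 5, 5], T4).category is Category.TISSUE_ENRICHED

    def test_group_enriched_top_two(self):
        # mean(50, 45) = 47.5 >= 5 * mean(1,1,1,1) = 5; not enriched: 50 < 5*45
        call = classify_gene([50, 45, 1, 1, 1, 1], T6)
        assert call.category is Category.GROUP_ENRICHED
        assert call.elevated_tissues == ("a", "b")
        assert call.fold_change == pytest.approx(47.5)

    def test_tissue_enhanced(self):
        # 16 >= 5 * mean(4,4,2,2,2,2,2) = 12.857; no group of 2-7 qualifies; 16 < 5*4
        call = classify_gene([16, 4, 4, 2, 2, 2, 2, 2], T8)
        assert call.category is Category.TISSUE_ENHANCED
        assert call.elevated_tissues == ("t0",)
        assert call.fold_change == pytest.approx(16 / (18 / 7))
        assert brute_force_category([16, 4, 4, 2, 2, 2, 2, 2], T8, ThresholdConfig()) == "tissue_enhanced"

    def test_expressed_in_all(self):
        assert classify_gene([2, 2, 2, 2], T4).category is Category.EXPRESSED_IN_ALL

    def test_mixed(self):
        values = [2, 2, 2, 0.5, 0.5, 0.5, 0.5, 0.5]
        assert classify_gene(values, T8).category is Category.MIXED
        assert brute_force_category(values, T8, ThresholdConfig()) == "mixed"

    def test_tie_break_is_lexicographic(self):
        call = classify_gene([10, 10, 1, 1], ["d", "c", "b", "a"])
        assert call.category is Category.GROUP_ENRICHED
        assert call.elevated_tissues == ("c", "d")

    def test_short_vector_rejected(self):
        with pytest.raises(ValidationError):
            classify_gene([5.0], ["a"])

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            classify_gene([5.0, -1.0], ["a", "b"])


class TestOracleEquivalence:
    """Gene-for-gene agreement with exhaustive subset enumeration."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_profiles_agree_with_brute_force(self, seed, config):
        rng = np.random.default_rng(seed)
        tissues = [f"t{i:02d}" for i in range(8)]
        values = 10.0 ** rng.uniform(-1.5, 3.0, size=(300, 8))
        values[rng.random((300, 8)) < 0.25] = 0.0
        for row in values:
            call = classify_gene(row, tissues, config)
            assert call.category.value == brute_force_category(row, tissues, config)

    def test_best_group_is_top_k_prefix(self, config):
        # the reported group must be the k highest-expressing tissues
        rng = np.random.default_rng(7)
        tissues = [f"t{i:02d}" for i in range(10)]
        hits = 0
        for _ in range(200):
            row = 10.0 ** rng.uniform(-1, 3, size=10)
            call = classify_gene(row, tissues, config)
            if call.category is Category.GROUP_ENRICHED:
                hits += 1
                k = len(call.elevated_tissues)
                order = np.lexsort((np.asarray(tissues, dtype=object), -row))
                assert set(call.elevated_tissues) == {tissues[i] for i in order[:k]}
        assert hits > 0


@st.composite
def expression_vectors(draw):
    n = draw(st.integers(min_value=2, max_value=10))
    values = draw(
        st.lists(
            st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    return values


class TestInvariants:
    @given(expression_vectors())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_exactly_one_category(self, values):
        tissues = [f"t{i:02d}" for i in range(len(values))]
        call = classify_gene(values, tissues)
        assert isinstance(call.category, Category)
        if call.category in (Category.TISSUE_ENRICHED, Category.TISSUE_ENHANCED):
            assert len(call.elevated_tissues) == 1
        elif call.category is Category.GROUP_ENRICHED:
            assert 2 <= len(call.elevated_tissues) <= 7
        else:
            assert call.elevated_tissues == ()
        if call.highly_enriched:
            assert call.category is Category.TISSUE_ENRICHED

    @given(expression_vectors(), st.floats(min_value=0.5, max_value=100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_invariance(self, values, c):
        # fold rules are ratios: categories depend on scale only through
        # the detection cutoff, so scaling that moves no value across it
        # must leave the category unchanged
        if any((v >= 1.0) != (v * c >= 1.0) for v in values):
            return
        tissues = [f"t{i:02d}" for i in range(len(values))]
        before = classify_gene(values, tissues)
        after = classify_gene([v * c for v in values], tissues)
        assert after.category == before.category
        assert set(after.elevated_tissues) == set(before.elevated_tissues)

    @given(expression_vectors(), st.randoms(use_true_random=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_tissue_permutation_invariance(self, values, rnd):
        tissues = [f"t{i:02d}" for i in range(len(values))]
        paired = list(zip(values, tissues))
        rnd.shuffle(paired)
        base = classify_gene(values, tissues)
        perm = classify_gene([p[0] for p in paired], [p[1] for p in paired])
        assert perm.category == base.category
        assert set(perm.elevated_tissues) == set(base.elevated_tissues)


class TestClassifyAll:
    def test_noiseless_planted_atlas_recovered_exactly(self, noiseless_atlas):
        from tissueatlas import aggregate_by_tissue

        profile = aggregate_by_tissue(noiseless_atlas.matrix, noiseless_atlas.metadata)
        calls, summary = classify_all(profile)
        truth = noiseless_atlas.truth["planted_category"].tolist()
        assert [c.category.value for c in calls] == truth
        assert summary.total == len(truth)

    def test_all_zero_profile(self):
        frame = pd.DataFrame(np.zeros((10, 3)), index=[f"g{i}" for i in range(10)],
                             columns=["a", "b", "c"])
        calls, summary = classify_all(TissueProfile(values=frame))
        assert summary.counts["not_detected"] == 10
        assert summary.total == 10
        assert all(v == 0 for k, v in summary.counts.items() if k != "not_detected")

    def test_summary_counts_partition_total(self, noiseless_atlas):
        from tissueatlas import aggregate_by_tissue

        profile = aggregate_by_tissue(noiseless_atlas.matrix, noiseless_atlas.metadata)
        calls, summary = classify_all(profile)
        assert sum(summary.counts.values()) == len(calls)


class TestElevatedFraction:
    def _profile_and_calls(self, values):
        frame = pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                             columns=["x", "y"])
        profile = TissueProfile(values=frame)
        calls, _ = classify_all(profile)
        return profile, calls

    def test_all_elevated_gives_100(self):
        profile, calls = self._profile_and_calls([[100, 2], [50, 3]])
        assert all(c.is_elevated for c in calls)
        assert elevated_transcript_fraction(profile, calls, "x") == pytest.approx(100.0)

    def test_none_elevated_gives_0(self):
        profile, calls = self._profile_and_calls([[2, 2], [3, 3]])
        assert elevated_transcript_fraction(profile, calls, "x") == pytest.approx(0.0)

    def test_matches_planted_mass_share(self, noiseless_atlas):
        profile = noiseless_atlas.profile
        calls, _ = classify_all(profile)
        tissue = profile.tissues[0]
        elevated = {
            c.gene_id for c in calls if c.is_elevated and tissue in c.elevated_tissues
        }
        col = profile.values[tissue]
        expected = 100.0 * col.loc[sorted(elevated)].sum() / col.sum()
        assert elevated_transcript_fraction(profile, calls, tissue) == pytest.approx(expected)

    def test_zero_mass_tissue_raises(self):
        frame = pd.DataFrame([[0.0, 5.0]], index=["g0"], columns=["x", "y"])
        profile = TissueProfile(values=frame)
        calls, _ = classify_all(profile)
        with pytest.raises(UndefinedStatisticError):
            elevated_transcript_fraction(profile, calls, "x")


class TestDetectedGeneCounts:
    def test_direct_counting_example(self):
        frame = pd.DataFrame({"t1": [0.5, 2.0, 20.0], "t2": [0.0, 0.0, 0.0]},
                             index=["g0", "g1", "g2"])
        counts = detected_gene_counts(TissueProfile(values=frame), bins=[1, 10, 100])
        assert counts.loc["t1"].tolist() == [2, 1, 0]
        assert counts.loc["t2"].tolist() == [0, 0, 0]

    def test_counts_weakly_decreasing_in_cut(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(10.0 ** rng.uniform(-1, 4, size=(200, 4)),
                             index=[f"g{i}" for i in range(200)],
                             columns=list("abcd"))
        counts = detected_gene_counts(TissueProfile(values=frame))
        diffs = counts.to_numpy()[:, 1:] - counts.to_numpy()[:, :-1]
        assert (diffs <= 0).all()

    def test_unsorted_bins_rejected(self):
        frame = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g0"])
        with pytest.raises(ValidationError):
            detected_gene_counts(TissueProfile(values=frame), bins=[10, 1])


class TestPrintedRounding:
    def test_round_half_away_from_zero(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(3.45, 1) == 3.5
        assert round_half_away(-2.5) == -3

    def test_global_shares_integer_per_tissue_one_decimal(self):
        assert pct(6778, 16013) == 42
        assert pct(653, 16013, 1) == 4.1

    def test_summary_pct_consistent_with_counts(self):
        summary = CategorySummary.from_counts(
            {"expressed_in_all": 50, "not_detected": 25, "mixed": 25}
        )
        shares = summary.category_pct()
        assert shares["expressed_in_all"] == 50
        assert shares["not_detected"] == 25
        assert sum(shares.values()) == 100
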