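"""Natural-breaks classification: oracle equivalence and golden tiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from troutrisk import (brute_force_breaks, classify, jenks_breaks,
                       jenks_caspall_breaks)

from conftest import GOLDEN_TIER_COUNTS, GOLDEN_TOTALS


class TestExactBreaks:
    def test_perfectly_clustered(self):
        bs = jenks_breaks([1, 1, 1, 5, 5, 5, 9, 9, 9], k=3)
        assert bs.class_values == ((1, 1, 1), (5, 5, 5), (9, 9, 9))
        assert bs.within_ssd == 0
        assert bs.gvf == 1.0

    def test_constant_vector_single_class(self):
        bs = jenks_breaks([4, 4, 4], k=1)
        assert bs.gvf == 1.0
        assert bs.breaks == ()

    def test_fewer_distinct_values_than_k(self):
        with pytest.raises(ValueError, match="distinct"):
            jenks_breaks([2, 2, 2, 2], k=3)

    def test_optimal_partition_of_packaged_totals(self):
        """Exact optimum splits the 35 totals 17/8/10 (SSD 59.2647)."""
        bs = jenks_breaks(GOLDEN_TOTALS, k=3)
        assert [len(c) for c in bs.class_values] == [17, 8, 10]
        assert bs.breaks == (18.0, 22.0)
        assert bs.within_ssd == pytest.approx(59.264705882, abs=1e-6)

    def test_breaks_ascending_and_classes_nonempty(self):
        bs = jenks_breaks([1, 2, 3, 10, 11, 30], k=3)
        assert list(bs.breaks) == sorted(bs.breaks)
        assert all(len(c) >= 1 for c in bs.class_values)


class TestBruteForceOracle:
    def test_one_value_per_class(self):
        bs = brute_force_breaks([1, 2, 3], k=3)
        assert bs.class_values == ((1,), (2,), (3,))

    def test_pairs(self):
        bs = brute_force_breaks([1, 1, 2, 2], k=2)
        assert bs.breaks == (1.0,)
        assert bs.within_ssd == 0

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="guarded"):
            brute_force_breaks(list(range(300)), k=3)

    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=40), min_size=5,
                 max_size=50).filter(lambda v: len(set(v)) >= 3)
    )
    def test_dp_matches_enumeration(self, values):
        """DP and exhaustive enumeration agree in SSD and, under the
        smallest-top-class tie rule, in the breaks themselves."""
        dp = jenks_breaks(values, k=3)
        bf = brute_force_breaks(values, k=3)
        assert dp.within_ssd == pytest.approx(bf.within_ssd, abs=1e-9)
        assert dp.breaks == bf.breaks

    def test_dp_matches_enumeration_random_floats(self, rng):
        for _ in range(100):
            values = rng.normal(size=rng.integers(5, 30)).round(2)
            if len(np.unique(values)) < 3:
                continue
            dp = jenks_breaks(values, k=3)
            bf = brute_force_breaks(values, k=3)
            assert dp.within_ssd == pytest.approx(bf.within_ssd, abs=1e-9)


class TestIterativeBreaks:
    def test_reproduces_published_partition(self):
        """The classic refinement lands on the published 15/8/12 grouping."""
        bs = jenks_caspall_breaks(GOLDEN_TOTALS, k=3)
        assert [len(c) for c in bs.class_values] == [15, 8, 12]
        assert bs.breaks == (17.0, 21.0)
        # locally optimal: strictly worse than the exact optimum here
        exact = jenks_breaks(GOLDEN_TOTALS, k=3)
        assert bs.within_ssd >= exact.within_ssd

    def test_agrees_with_exact_on_clean_clusters(self):
        bs = jenks_caspall_breaks([1, 1, 1, 5, 5, 5, 9, 9, 9], k=3)
        assert bs.class_values == ((1, 1, 1), (5, 5, 5), (9, 9, 9))
        assert bs.gvf == 1.0

    def test_never_beats_exact_optimum(self, rng):
        for _ in range(50):
            values = rng.integers(0, 30, size=rng.integers(6, 40))
            if len(np.unique(values)) < 3:
                continue
            it = jenks_caspall_breaks(values, k=3)
            ex = jenks_breaks(values, k=3)
            assert it.within_ssd >= ex.within_ssd - 1e-9


class TestClassify:
    def test_published_tier_counts(self, matrix_totals):
        cls = classify(matrix_totals, k=3)
        assert cls.tier_counts == GOLDEN_TIER_COUNTS

    def test_anchor_tiers(self, matrix_totals):
        cls = classify(matrix_totals, k=3)
        assert cls.tiers["galaxias_macronasus"] == "High"  # bignose, 26
        assert cls.tiers["geotria_australis"] == "Minor"  # pouched lamprey, 12
        # every species scoring >= 22 is High under the published grouping
        for sp, total in matrix_totals.items():
            assert (cls.tiers[sp] == "High") == (total >= 22)

    def test_fisher_method_differs_here(self, matrix_totals):
        cls = classify(matrix_totals, k=3, method="fisher")
        assert cls.tier_counts == {"High": 10, "Moderate": 8, "Minor": 17}

    def test_monotone_tiers(self, rng):
        rank = {"Minor": 0, "Moderate": 1, "High": 2}
        for method in ("caspall", "fisher"):
            for _ in range(20):
                values = rng.integers(0, 25, size=20)
                if len(np.unique(values)) < 3:
                    continue
                cls = classify(values, k=3, species=[f"s{i}" for i in range(20)],
                               method=method)
                pairs = sorted((cls.scores[sp], rank[t])
                               for sp, t in cls.tiers.items())
                tiers_sorted = [t for _, t in pairs]
                assert tiers_sorted == sorted(tiers_sorted)

    def test_constant_scores_error(self):
        with pytest.raises(ValueError, match="distinct"):
            classify({f"s{i}": 7 for i in range(10)}, k=3)

    def test_unknown_method(self, matrix_totals):
        with pytest.raises(ValueError, match="method"):
            classify(matrix_totals, method="kmeans")
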