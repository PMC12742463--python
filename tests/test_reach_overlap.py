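"""River-reach extent/overlap summaries: toy oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

from troutrisk import (ReachTable, load_reach_table, summarize_overlap,
                       threshold_presence)
from troutrisk.reach_overlap import write_reach_table


def toy_table():
    """Four reaches of 1,2,3,4 km; a High species on reaches 1-2, trout on
    2-3.  Hand enumeration: High extent = 1+2 = 3 km, overlap = 2 km."""
    return ReachTable(pd.DataFrame({
        "reach_id": ["r1", "r2", "r3", "r4"],
        "length_km": [1.0, 2.0, 3.0, 4.0],
        "trout": [0.0, 1.0, 1.0, 0.0],
        "sp_high": [1.0, 1.0, 0.0, 0.0],
    }))


class TestThresholding:
    def test_basic(self):
        out = threshold_presence([0.2, 0.5, 0.9], 0.5)
        assert list(out) == [False, True, True]

    def test_tau_zero_all_present(self):
        assert threshold_presence([0.0, 0.3, 1.0], 0.0).all()

    def test_tau_one_only_certain(self):
        assert list(threshold_presence([0.99, 1.0], 1.0)) == [False, True]

    def test_booleans_pass_through(self):
        arr = np.array([True, False])
        assert list(threshold_presence(arr, 0.7)) == [True, False]

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            threshold_presence([0.5], 1.5)


class TestSummarize:
    def test_toy_oracle(self):
        summary = summarize_overlap(toy_table(), {"sp_high": "High"}, tau=0.5)
        high = summary.tiers["High"]
        assert high.extent_km == pytest.approx(3.0)
        assert high.overlap_km == pytest.approx(2.0)
        assert high.overlap_pct == pytest.approx(100 * 2 / 3)
        assert summary.trout_extent_km == pytest.approx(5.0)
        assert summary.any_species_overlap_km == pytest.approx(2.0)

    def test_trout_nowhere(self):
        t = toy_table()
        t = ReachTable(t.data.assign(trout=0.0))
        s = summarize_overlap(t, {"sp_high": "High"})
        assert s.tiers["High"].overlap_km == 0.0

    def test_trout_everywhere(self):
        t = ReachTable(toy_table().data.assign(trout=1.0))
        s = summarize_overlap(t, {"sp_high": "High"})
        assert s.tiers["High"].overlap_km == s.tiers["High"].extent_km
        assert s.tiers["High"].overlap_pct == pytest.approx(100.0)

    def test_missing_species_raises(self):
        with pytest.raises(ValueError, match="missing"):
            summarize_overlap(toy_table(), {"sp_high": "High", "ghost": "Minor"})

    def test_unclassified_species_reported(self):
        df = toy_table().data.assign(extra_sp=0.0)
        s = summarize_overlap(ReachTable(df), {"sp_high": "High"})
        assert s.unclassified_species == ("extra_sp",)

    def test_empty_extent_pct_is_none(self):
        df = toy_table().data.assign(sp_none=0.0)
        s = summarize_overlap(ReachTable(df),
                              {"sp_high": "High", "sp_none": "Minor"})
        assert s.tiers["Minor"].extent_km == 0.0
        assert s.tiers["Minor"].overlap_pct is None

    def test_additivity_under_reach_splitting(self, rng):
        """Halving every reach into two leaves all summary values unchanged."""
        for _ in range(10):
            n = 30
            df = pd.DataFrame({
                "reach_id": [f"r{i}" for i in range(n)],
                "length_km": rng.exponential(0.7, size=n),
                "trout": rng.integers(0, 2, size=n).astype(float),
                "a": rng.integers(0, 2, size=n).astype(float),
                "b": rng.integers(0, 2, size=n).astype(float),
            })
            whole = summarize_overlap(ReachTable(df), {"a": "High", "b": "Minor"})
            halves = pd.concat([df, df]).reset_index(drop=True)
            halves["length_km"] /= 2
            halves["reach_id"] = [f"h{i}" for i in range(2 * n)]
            split = summarize_overlap(ReachTable(halves),
                                      {"a": "High", "b": "Minor"})
            for tier in ("High", "Minor"):
                assert split.tiers[tier].extent_km == pytest.approx(
                    whole.tiers[tier].extent_km)
                assert split.tiers[tier].overlap_km == pytest.approx(
                    whole.tiers[tier].overlap_km)

    def test_overlap_bounded_by_trout_extent(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 25
            df = pd.DataFrame({
                "reach_id": [f"r{i}" for i in range(n)],
                "length_km": r.exponential(1.0, size=n),
                "trout": r.integers(0, 2, size=n).astype(float),
                "a": r.integers(0, 2, size=n).astype(float),
            })
            s = summarize_overlap(ReachTable(df), {"a": "High"})
            t = s.tiers["High"]
            assert t.overlap_km <= t.extent_km + 1e-9
            assert t.overlap_km <= s.trout_extent_km + 1e-9


class TestValidationAndIO:
    def test_negative_length(self):
        df = toy_table().data.copy()
        df.loc[0, "length_km"] = -1
        with pytest.raises(ValueError, match="negative"):
            ReachTable(df)

    def test_probability_out_of_range(self):
        df = toy_table().data.copy()
        df.loc[0, "sp_high"] = 1.2
        with pytest.raises(ValueError, match="outside"):
            ReachTable(df)

    def test_duplicate_reach_ids(self):
        df = toy_table().data.copy()
        df.loc[1, "reach_id"] = "r1"
        with pytest.raises(ValueError, match="duplicate"):
            ReachTable(df)

    def test_round_trip(self, tmp_path):
        t = toy_table()
        p = tmp_path / "reaches.csv"
        write_reach_table(t, p)
        back = load_reach_table(p)
        pd.testing.assert_frame_equal(back.data, t.data)

    def test_missing_column(self):
        with pytest.raises(ValueError, match="length_km"):
            ReachTable(pd.DataFrame({"reach_id": ["a"], "trout": [0.0]}))
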