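"""Target-decoy FDR tiers, replicate merging, size profiles and overlaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollencrp.proteome import (
    FDRConfig,
    merge_replicates,
    overlap_report,
    psm_fdr,
    size_profile,
)


def _table(targets, decoys):
    return pd.DataFrame(
        {
            "score": list(targets) + list(decoys),
            "is_decoy": [False] * len(targets) + [True] * len(decoys),
        }
    )


def _sweep_oracle(targets, decoys):
    """Exhaustive threshold sweep: q(s) = min over t <= s of FDR(t)."""
    targets, decoys = np.asarray(targets, float), np.asarray(decoys, float)
    out = {}
    for s in np.concatenate([targets, decoys]):
        fdr_at = []
        for t in sorted(set(np.concatenate([targets, decoys]))):
            if t > s:
                continue
            nt = (targets >= t).sum()
            nd = (decoys >= t).sum()
            fdr_at.append(min(nd / nt, 1.0) if nt else 1.0)
        out[s] = min(fdr_at)
    return out


class TestPSMFDR:
    def test_worked_example(self):
        """targets {10,8,6,4}, decoys {9,3}: FDR at s=8 is 1/2."""
        res = psm_fdr(_table([10, 8, 6, 4], [9, 3]))
        at8 = res[(res.score == 8) & (~res.is_decoy)].iloc[0]
        assert at8.fdr == pytest.approx(0.5)
        oracle = _sweep_oracle([10, 8, 6, 4], [9, 3])
        for _, row in res.iterrows():
            assert row.q_value == pytest.approx(oracle[row.score], abs=1e-12)

    def test_no_decoys_all_high(self):
        res = psm_fdr(_table([5, 4, 3], []))
        assert (res.fdr == 0).all() and (res.tier == "high").all()

    def test_all_decoys_outrank_targets(self):
        res = psm_fdr(_table([1, 2], [5, 6, 7]))
        assert (res[~res.is_decoy].tier == "excluded").all()

    def test_ties_count_decoys_first(self):
        # decoy tied with target: the decoy inflates FDR at that threshold
        res = psm_fdr(_table([5.0], [5.0]))
        assert res[~res.is_decoy].iloc[0].fdr == pytest.approx(1.0)

    def test_tier_boundaries_inclusive(self):
        df = _table([10] * 99 + [5], [5])  # q at s=5: 1/100
        res = psm_fdr(df)
        assert res[(res.score == 5) & (~res.is_decoy)].iloc[0].tier == "high"

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError):
            psm_fdr(_table([], [1, 2]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        targets=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=30),
        decoys=st.lists(st.floats(-5, 5, allow_nan=False), max_size=30),
    )
    def test_qvalues_match_sweep_oracle_and_are_monotone(self, targets, decoys):
        res = psm_fdr(_table(targets, decoys))
        oracle = _sweep_oracle(targets, decoys)
        for _, row in res.iterrows():
            assert row.q_value == pytest.approx(oracle[row.score], abs=1e-12)
        srt = res.sort_values("score", ascending=False)
        assert (np.diff(srt.q_value.to_numpy()) >= -1e-12).all()


class TestMergeReplicates:
    def test_union_and_replicate_counts(self):
        reps = {
            "r1": pd.DataFrame({"protein_id": ["A", "B"]}),
            "r2": pd.DataFrame({"protein_id": ["B", "C"]}),
            "r3": pd.DataFrame({"protein_id": ["C", "D"]}),
        }
        merged = merge_replicates(reps)
        assert len(merged) == 4
        counts = merged.set_index("protein_id").n_replicates
        assert counts["B"] == 2 and counts["C"] == 2 and counts["A"] == 1

    def test_single_replicate_identity(self):
        rep = pd.DataFrame({"protein_id": ["A", "B"], "area": [1.0, 3.0]})
        merged = merge_replicates({"r1": rep})
        assert list(merged.protein_id) == ["A", "B"]
        assert merged.rel_abundance_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_relative_abundance_hand_arithmetic(self):
        reps = {
            "r1": pd.DataFrame({"protein_id": ["A", "B"], "area": [10.0, 30.0]}),
            "r2": pd.DataFrame({"protein_id": ["A"], "area": [60.0]}),
        }
        merged = merge_replicates(reps).set_index("protein_id")
        assert merged.loc["A", "rel_abundance_pct"] == pytest.approx(70.0)
        assert merged.loc["B", "rel_abundance_pct"] == pytest.approx(30.0)

    def test_merge_idempotent_and_order_invariant(self):
        reps = {
            "r1": pd.DataFrame({"protein_id": ["A", "B"], "area": [1.0, 2.0]}),
            "r2": pd.DataFrame({"protein_id": ["B", "C"], "area": [4.0, 8.0]}),
        }
        a = merge_replicates(reps)
        b = merge_replicates(dict(reversed(list(reps.items()))))
        pd.testing.assert_frame_equal(
            a.drop(columns="n_replicates"), b.drop(columns="n_replicates")
        )

    def test_duplicates_within_replicate_collapsed(self):
        rep = pd.DataFrame({"protein_id": ["A", "A"], "area": [1.0, 2.0]})
        merged = merge_replicates({"r1": rep})
        assert len(merged) == 1 and merged.area.iloc[0] == pytest.approx(3.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_replicates({})


class TestSizeProfile:
    def test_worked_example(self):
        prof = size_profile([10, 15, 25], edges=(20,))
        assert prof.fraction.iloc[0] == pytest.approx(2 / 3)

    def test_all_in_one_bin(self):
        prof = size_profile([5, 8, 12])
        assert prof.fraction.iloc[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one_vs_counting_oracle(self):
        rng = np.random.default_rng(8)
        w = rng.uniform(1, 120, 500)
        prof = size_profile(w)
        assert prof.fraction.sum() == pytest.approx(1.0)
        assert prof.loc[0, "count"] == (w < 20).sum()
        assert prof.loc[3, "count"] == (w >= 60).sum()

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            size_profile([])
        with pytest.raises(ValueError):
            size_profile([-1.0])


class TestOverlap:
    def test_disjoint_and_identical(self):
        rep = overlap_report({"a": {1, 2}, "b": {3, 4}}).set_index("sets")
        assert rep.loc["a&b", "n"] == 0
        rep2 = overlap_report({"a": {1, 2}, "b": {1, 2}}).set_index("sets")
        assert rep2.loc["a&b", "n"] == 2

    def test_three_way_matches_enumeration(self):
        rng = np.random.default_rng(9)
        sets = {k: set(rng.integers(0, 40, 25).tolist()) for k in "xyz"}
        rep = overlap_report(sets).set_index("sets")
        assert rep.loc["x&y&z", "n"] == len(sets["x"] & sets["y"] & sets["z"])
        assert rep.loc["x", "n"] == len(sets["x"])
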