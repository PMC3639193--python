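"""The greedy footprint caller, RPKM, strengths and interval merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import merge_intervals_unionfind, reference_call_footprints
from riscprof.footprint_calling import (
    ExpressionLookupError,
    call_footprints,
    call_footprints_vector,
    compute_rpkm,
    compute_strengths,
    index_starts,
    merge_footprints,
)
from riscprof.io_formats import TranscriptModel


class TestRpkm:
    def _counts(self, raw, lib):
        return pd.DataFrame([{"transcript_id": "tx1", "time_point": "0h",
                              "replicate": "r1", "raw_count": raw,
                              "library_size": lib}])

    def test_definition(self):
        models = [TranscriptModel("tx1", "g1", 2000)]
        out = compute_rpkm(self._counts(1000, 10_000_000), models)
        assert np.isclose(out["rpkm"].iloc[0], 50.0)  # 1000 / (2 * 10)

    def test_zero_reads(self):
        models = [TranscriptModel("tx1", "g1", 2000)]
        assert compute_rpkm(self._counts(0, 10**6), models)["rpkm"].iloc[0] == 0.0

    def test_one_kb_transcript_unit_rpkm(self):
        models = [TranscriptModel("tx1", "g1", 1000)]
        out = compute_rpkm(self._counts(10, 10_000_000), models)
        assert np.isclose(out["rpkm"].iloc[0], 1.0)

    def test_unknown_transcript_raises(self):
        with pytest.raises(ExpressionLookupError):
            compute_rpkm(self._counts(1, 10**6), [TranscriptModel("other", "g", 100)])


class TestIndexStarts:
    def test_counts_by_position(self):
        frags = pd.DataFrame({"transcript_id": "tx1", "start": [10, 12, 10],
                              "length": 30, "count": [2, 1, 2],
                              "replicate": "r1", "time_point": "0h"})
        idx = index_starts(frags, {"tx1": 100})
        v = idx[("tx1", "0h", "r1")]
        assert v[10] == 4 and v[12] == 1 and v.sum() == 5

    def test_empty_input(self):
        frags = pd.DataFrame(columns=["transcript_id", "start", "length",
                                      "count", "replicate", "time_point"])
        assert index_starts(frags, {"tx1": 100}) == {}


class TestGreedyCaller:
    def test_hand_traced_example(self):
        v = np.zeros(500, dtype=int)
        v[100], v[105], v[300] = 10, 3, 7
        fps = call_footprints_vector(v, min_reads=5, assign_window=10)
        assert [(a, r) for a, _, _, r in fps] == [(100, 13), (300, 7)]

    def test_below_min_reads_no_footprint(self):
        v = np.zeros(100, dtype=int)
        v[50] = 4
        assert call_footprints_vector(v, min_reads=5) == []

    def test_leftmost_tie_break(self):
        v = np.zeros(400, dtype=int)
        v[50], v[200] = 8, 8
        fps = call_footprints_vector(v, min_reads=5)
        assert [a for a, *_ in fps] == [50, 200]

    def test_interval_clipped_at_transcript_end(self):
        v = np.zeros(80, dtype=int)
        v[60] = 9
        (_, start, end, _), = call_footprints_vector(v, footprint_len=50)
        assert (start, end) == (60, 80)

    def test_read_conservation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            v = rng.poisson(0.5, size=300)
            v[rng.integers(0, 300, 5)] += rng.integers(5, 30, 5)
            fps = call_footprints_vector(v.copy())
            consumed = sum(r for *_, r in fps)
            # remaining reads after consumption
            w = v.copy()
            for a, *_ in fps:
                w[max(0, a - 10):a + 11] = 0
            assert consumed + w.sum() == v.sum()

    @settings(max_examples=150, deadline=None)
    @given(st.data())
    def test_matches_bruteforce_reference(self, data):
        L = data.draw(st.integers(20, 500))
        n_frag = data.draw(st.integers(0, 100))
        positions = data.draw(st.lists(st.integers(0, L - 1), min_size=n_frag,
                                       max_size=n_frag))
        v = np.zeros(L, dtype=int)
        for p in positions:
            v[p] += 1
        assert call_footprints_vector(v) == reference_call_footprints(v)

    def test_dataframe_wrapper_ids_and_columns(self):
        v = np.zeros(200, dtype=int)
        v[20] = 6
        fps = call_footprints({("tx1", "0h", "r1"): v})
        assert list(fps["footprint_id"]) == ["tx1:0h:r1:fp1"]
        assert fps.iloc[0]["anchor"] == 20


class TestStrengths:
    def _fixture(self, reads=10, lib=2_000_000, rpkm=10.0):
        fps = pd.DataFrame([{"footprint_id": "f1", "transcript_id": "tx1",
                             "anchor": 100, "start": 100, "end": 150,
                             "reads": reads, "time_point": "0h", "replicate": "r1"}])
        expr = pd.DataFrame([{"transcript_id": "tx1", "time_point": "0h",
                              "replicate": "r1", "rpkm": rpkm}])
        return fps, {("0h", "r1"): lib}, expr

    def test_strength_is_rpm_over_rpkm(self):
        fps, libs, expr = self._fixture(reads=10, lib=2_000_000, rpkm=10.0)
        out = compute_strengths(fps, libs, expr)
        assert np.isclose(out["rpm"].iloc[0], 5.0)
        assert np.isclose(out["strength"].iloc[0], 0.5)

    def test_low_rpkm_flagged_undefined(self):
        fps, libs, expr = self._fixture(rpkm=0.05)
        out = compute_strengths(fps, libs, expr, rpkm_floor=0.1)
        assert not out["strength_defined"].iloc[0]
        assert np.isnan(out["strength"].iloc[0])

    def test_scale_invariance_under_doubling(self):
        fps, libs, expr = self._fixture()
        a = compute_strengths(fps, libs, expr)
        fps2 = fps.assign(reads=fps["reads"] * 2)
        libs2 = {k: v * 2 for k, v in libs.items()}
        b = compute_strengths(fps2, libs2, expr)
        assert np.allclose(a["strength"], b["strength"])

    def test_missing_expression_record_raises(self):
        fps, libs, expr = self._fixture()
        with pytest.raises(ExpressionLookupError):
            compute_strengths(fps, libs, expr[expr["transcript_id"] != "tx1"])


class TestMerge:
    def _fps(self, intervals, strengths=None):
        rows = []
        for i, (s, e) in enumerate(intervals):
            rows.append({"footprint_id": f"f{i}", "transcript_id": "tx1",
                         "anchor": s, "start": s, "end": e, "reads": 10,
                         "time_point": "0h", "replicate": "r1",
                         "rpm": 1.0,
                         "strength": strengths[i] if strengths else 1.0,
                         "strength_defined": True})
        return pd.DataFrame(rows)

    def test_gap_within_threshold_merges(self):
        out = merge_footprints(self._fps([(100, 150), (165, 215)]), max_gap=20)
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (100, 215)
        assert out.iloc[0]["reads"] == 20 and np.isclose(out.iloc[0]["strength"], 2.0)

    def test_gap_beyond_threshold_does_not_merge(self):
        out = merge_footprints(self._fps([(100, 150), (171, 215)]), max_gap=20)
        assert len(out) == 2

    def test_transitive_chain_merges_to_one(self):
        chain = [(0, 50), (60, 110), (120, 170)]
        out = merge_footprints(self._fps(chain), max_gap=20)
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (0, 170)

    def test_anchor_of_strongest_constituent_kept(self):
        out = merge_footprints(self._fps([(100, 150), (160, 210)],
                                         strengths=[0.2, 3.0]), max_gap=20)
        assert out.iloc[0]["anchor"] == 160
        assert out.iloc[0]["member_anchors"] == [100, 160]

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 60)),
                    min_size=1, max_size=8))
    def test_matches_unionfind_oracle(self, raw):
        intervals = sorted((s, s + l) for s, l in raw)
        out = merge_footprints(self._fps(intervals), max_gap=20)
        got = sorted(zip(out["start"], out["end"]))
        assert got == merge_intervals_unionfind(intervals, 20)


def test_planted_anchor_recovery_on_study(small_study, small_results):
    """On the synthetic study, called footprints recover planted anchors."""
    truth = small_study[5]
    fps = small_results["footprints"]
    sub = fps[(fps["time_point"] == "0h") & (fps["replicate"] == "r1")]
    planted = truth.planted_footprints
    recovered = sum(
        ((sub["transcript_id"] == p.transcript_id)
         & (sub["anchor"].sub(p.anchor).abs() <= 5)).any()
        for p in planted.itertuples())
    assert recovered / len(planted) >= 0.9
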