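"""Seed scanning, miRanda import filters and footprint confirmation."""

import numpy as np
import pandas as pd
import pytest

from oracles import find_seed_matches
from riscprof.io_formats import FormatError, TranscriptModel
from riscprof.mre_prediction import (
    ConfirmationCriteria,
    confirm_mres,
    read_miranda_hits,
    seed_scan,
    summarize_refinement,
)
from riscprof.synthetic_data import reverse_complement, seed_site

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"  # nt 2-8 = GAGGUAG -> site CTACCTC


def _tx(seq, tx_id="tx1"):
    return TranscriptModel(tx_id, tx_id, len(seq), seq)


class TestSeedScan:
    def test_7mer_m8_at_five_prime_coordinate(self):
        seq = "G" * 20 + "CTACCTC" + "G" * 20  # no trailing A -> 7mer-m8
        hits = seed_scan({"let7": LET7}, [_tx(seq)])
        assert len(hits) == 1
        row = hits.iloc[0]
        assert row["site_type"] == "7mer-m8" and row["mre_start"] == 20

    def test_8mer_requires_a_opposite_nt1(self):
        seq = "G" * 20 + "CTACCTCA" + "G" * 20
        hits = seed_scan({"let7": LET7}, [_tx(seq)])
        assert hits.iloc[0]["site_type"] == "8mer" and hits.iloc[0]["mre_start"] == 20

    def test_6mer_and_7mer_a1_classes(self):
        core6 = seed_site(LET7)[1:]  # TACCTC
        plain = "G" * 10 + core6 + "G" * 10
        with_a = "G" * 10 + core6 + "A" + "G" * 10
        h6 = seed_scan({"let7": LET7}, [_tx(plain)], min_class="6mer")
        ha1 = seed_scan({"let7": LET7}, [_tx(with_a)], min_class="6mer")
        assert h6.iloc[0]["site_type"] == "6mer" and h6.iloc[0]["mre_start"] == 10
        assert ha1.iloc[0]["site_type"] == "7mer-A1" and ha1.iloc[0]["mre_start"] == 10

    def test_default_min_class_drops_weak_sites(self):
        core6 = seed_site(LET7)[1:]
        seq = "G" * 10 + core6 + "G" * 10  # only a 6mer
        assert seed_scan({"let7": LET7}, [_tx(seq)]).empty

    def test_no_complementary_site_empty(self):
        assert seed_scan({"let7": LET7}, [_tx("A" * 200)]).empty

    def test_non_nucleotide_raises(self):
        with pytest.raises(FormatError):
            seed_scan({"bad": "UGXGGUAGUA"}, [_tx("ACGT" * 10)])

    def test_agrees_with_bruteforce_substring_oracle(self):
        rng = np.random.default_rng(21)
        alphabet = np.array(list("ACGT"))
        for trial in range(50):
            seq = "".join(rng.choice(alphabet, size=500))
            mirna = "".join(rng.choice(np.array(list("ACGU")), size=22))
            hits = seed_scan({"m": mirna}, [_tx(seq)], min_class="6mer")
            core6 = seed_site(mirna)[1:]
            expected_q = find_seed_matches(core6, seq)
            # each core occurrence yields exactly one reported site whose
            # element contains the core
            assert len(hits) <= len(expected_q)
            starts = set(hits["mre_start"])
            for q in expected_q:
                assert q in starts or q - 1 in starts


class TestMirandaImport:
    def _write(self, tmp_path, rows):
        p = tmp_path / "hits.tsv"
        p.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return p

    def test_score_and_energy_thresholds(self, tmp_path):
        p = self._write(tmp_path, [
            ("m1", "tx1", 100, 139, -12.0),   # score fails
            ("m1", "tx1", 120, 150, -9.5),    # energy fails
            ("m1", "tx1", 140, 150, -12.0),   # kept
            ("m1", "tx1", 160, 140, -10.0),   # kept at both boundaries
        ])
        hits = read_miranda_hits(p)
        assert list(hits["mre_start"]) == [140, 160]
        assert (hits["site_type"] == "imported").all()

    def test_malformed_row_raises_with_line_number(self, tmp_path):
        p = self._write(tmp_path, [("m1", "tx1", "notanint", 150, -12.0)])
        with pytest.raises(FormatError, match=":1"):
            read_miranda_hits(p)


def _confirmation_fixture(offset, strength, rpm):
    pairs = pd.DataFrame([{"mirna_id": "m1", "transcript_id": "tx1",
                           "mre_start": 100 + offset, "site_type": "7mer-m8",
                           "score": 3.0, "energy": np.nan}])
    fps = pd.DataFrame([{"footprint_id": "f1", "transcript_id": "tx1",
                         "anchor": 100, "start": 100, "end": 150, "reads": 50,
                         "time_point": "0h", "replicate": "r1", "rpm": 25.0,
                         "strength": strength, "strength_defined": True}])
    loading = pd.DataFrame([{"mirna_id": "m1", "time_point": "0h",
                             "replicate": "r1", "rpm": rpm}])
    return pairs, fps, loading


class TestConfirmation:
    @pytest.mark.parametrize("offset,strength,rpm,expected", [
        (5, 0.31, 100.0, True),    # all three at inclusive boundaries
        (4, 0.31, 100.0, False),   # upstream of window
        (44, 0.31, 100.0, False),  # beyond window
        (43, 0.31, 100.0, True),   # window upper boundary
        (5, 0.30, 100.0, False),   # footprint too weak
        (5, 0.31, 99.0, False),    # miRNA under-loaded
    ])
    def test_inclusive_boundaries(self, offset, strength, rpm, expected):
        out = confirm_mres(*_confirmation_fixture(offset, strength, rpm))
        assert bool(out.iloc[0]["confirmed"]) is expected

    def test_supporting_evidence_recorded(self):
        out = confirm_mres(*_confirmation_fixture(10, 1.0, 500.0))
        assert out.iloc[0]["supporting"] == [("0h", "r1", "f1")]
        assert out.iloc[0]["n_supporting"] == 1

    def test_union_over_conditions(self):
        pairs, fps, loading = _confirmation_fixture(10, 1.0, 500.0)
        fps2 = pd.concat([fps, fps.assign(replicate="r2", footprint_id="f2")],
                         ignore_index=True)
        loading2 = pd.concat(
            [loading, loading.assign(replicate="r2", rpm=50.0)],  # fails in r2
            ignore_index=True)
        out = confirm_mres(pairs, fps2, loading2)
        assert out.iloc[0]["n_supporting"] == 1  # only r1 supports

    def test_missing_loading_condition_raises(self):
        pairs, fps, loading = _confirmation_fixture(10, 1.0, 500.0)
        with pytest.raises(ValueError, match="missing conditions"):
            confirm_mres(pairs, fps, loading.assign(replicate="other"))

    def test_monotone_in_criteria(self):
        """Loosening any threshold never removes a confirmed pair."""
        rng = np.random.default_rng(2)
        pairs = pd.DataFrame({
            "mirna_id": "m1", "transcript_id": "tx1",
            "mre_start": rng.integers(0, 200, 40),
            "site_type": "7mer-m8", "score": 3.0, "energy": np.nan})
        fps = pd.DataFrame([{"footprint_id": "f1", "transcript_id": "tx1",
                             "anchor": 100, "start": 100, "end": 150,
                             "reads": 50, "time_point": "0h", "replicate": "r1",
                             "rpm": 25.0, "strength": 0.5,
                             "strength_defined": True}])
        loading = pd.DataFrame([{"mirna_id": "m1", "time_point": "0h",
                                 "replicate": "r1", "rpm": 200.0}])
        strict = confirm_mres(pairs, fps, loading,
                              ConfirmationCriteria(100, (5, 43), 0.31))
        loose = confirm_mres(pairs, fps, loading,
                             ConfirmationCriteria(50, (2, 60), 0.1))
        strict_set = set(strict[strict["confirmed"]]["mre_start"])
        loose_set = set(loose[loose["confirmed"]]["mre_start"])
        assert strict_set <= loose_set


class TestRefinement:
    def test_ratio(self):
        raw = pd.DataFrame({"mirna_id": [f"m{i}" for i in range(400)],
                            "transcript_id": "tx1"})
        conf = raw.head(20)
        s = summarize_refinement(raw, conf)
        assert s == {"n_raw_pairs": 400, "n_confirmed_pairs": 20,
                     "refinement_fold": 20.0}

    def test_no_refinement(self):
        raw = pd.DataFrame({"mirna_id": ["m1"], "transcript_id": ["tx1"]})
        assert summarize_refinement(raw, raw)["refinement_fold"] == 1.0


def test_planted_mres_confirmed_and_decoys_rejected(small_study, small_results):
    """Planted sites inside footprint windows are confirmed (when the miRNA
    is loaded and the footprint strong); planted decoys never are."""
    truth = small_study[5]
    conf = small_results["mre_pairs"]
    confirmed = set(zip(conf.loc[conf["confirmed"], "mirna_id"],
                        conf.loc[conf["confirmed"], "transcript_id"],
                        conf.loc[conf["confirmed"], "mre_start"]))
    loading = small_results["loading"]
    rpm_max = loading.groupby("mirna_id")["rpm"].max()
    planted = truth.planted_mres[~truth.planted_mres["decoy"]]
    recoverable = [r for r in planted.itertuples() if rpm_max[r.mirna_id] >= 100]
    hits = sum((r.mirna_id, r.transcript_id, r.mre_start) in confirmed
               for r in recoverable)
    assert hits / len(recoverable) >= 0.95
    decoys = truth.planted_mres[truth.planted_mres["decoy"]]
    assert not any((r.mirna_id, r.transcript_id, r.mre_start) in confirmed
                   for r in decoys.itertuples())
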