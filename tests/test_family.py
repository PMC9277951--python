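import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kheterosis.family import (
    BLAST6_COLUMNS,
    FamilyFilterError,
    assign_families,
    filter_hits,
    query_coverage,
    read_blast6,
)


def make_hit(query="q1", subject="s1", identity=50.0, q_start=1, q_end=80,
             evalue=1e-30, bit_score=200.0):
    return dict(
        query_id=query, subject_id=subject, percent_identity=identity,
        alignment_length=q_end - q_start + 1, mismatches=5, gap_opens=1,
        q_start=q_start, q_end=q_end, s_start=1, s_end=q_end - q_start + 1,
        evalue=evalue, bit_score=bit_score,
    )


QLEN = {"q1": 100, "q2": 100, "q3": 200}


@pytest.fixture()
def toy_hits():
    rows = [
        make_hit(),                                        # passes everything
        make_hit(subject="s2", evalue=1e-20),              # fails E-value
        make_hit(subject="s3", identity=30.0),             # boundary: identity == 30 dropped
        make_hit(subject="s4", q_start=1, q_end=30),       # boundary: coverage == 30 dropped
        make_hit(subject="s5", q_start=1, q_end=31),       # coverage 31 kept
        make_hit(subject="s6", evalue=1e-25),              # boundary: evalue == max dropped
        make_hit(query="q3", subject="s7", q_end=80),      # coverage 40% of 200 kept
    ]
    return pd.DataFrame(rows)


class TestFilterHits:
    def test_clear_pass_and_fail(self, toy_hits):
        kept = filter_hits(toy_hits, QLEN)
        assert set(kept["subject_id"]) == {"s1", "s5", "s7"}

    def test_strict_boundaries(self, toy_hits):
        kept = filter_hits(toy_hits, QLEN)
        assert "s3" not in set(kept["subject_id"])  # identity exactly 30
        assert "s4" not in set(kept["subject_id"])  # coverage exactly 30
        assert "s6" not in set(kept["subject_id"])  # evalue exactly 1e-25

    def test_idempotent_and_order_preserving(self, toy_hits):
        once = filter_hits(toy_hits, QLEN)
        twice = filter_hits(once, QLEN)
        pd.testing.assert_frame_equal(once, twice)
        assert list(once.index) == sorted(once.index)

    @given(
        ev=st.floats(1e-40, 1e-10), ident=st.floats(0, 100), cov=st.floats(10, 90),
    )
    @settings(max_examples=60, deadline=None)
    def test_relaxing_thresholds_keeps_supersets(self, ev, ident, cov):
        hits = pd.DataFrame([
            make_hit(), make_hit(subject="s2", evalue=1e-20),
            make_hit(subject="s3", identity=30.0), make_hit(subject="s4", q_end=30),
            make_hit(subject="s5", q_end=31), make_hit(query="q3", subject="s7", q_end=80),
        ])
        strict = filter_hits(hits, QLEN, evalue_max=ev, identity_min=ident, coverage_min=cov)
        relaxed = filter_hits(
            hits, QLEN, evalue_max=ev * 10, identity_min=max(ident - 10, 0),
            coverage_min=max(cov - 10, 0),
        )
        assert set(strict.index) <= set(relaxed.index)

    def test_missing_query_length_named(self, toy_hits):
        with pytest.raises(FamilyFilterError, match="q3"):
            filter_hits(toy_hits, {"q1": 100, "q2": 100})

    def test_coverage_formula_is_span_over_query_length(self):
        hits = pd.DataFrame([make_hit(q_start=11, q_end=60)])
        assert query_coverage(hits, QLEN).iloc[0] == pytest.approx(50.0)


class TestAssignFamilies:
    FAMILIES = {"q1": "KAT/AKT", "q2": "NHX", "q3": "TPK"}

    def test_best_bit_score_wins(self):
        hits = pd.DataFrame([
            make_hit(query="q1", subject="s1", bit_score=200.0),
            make_hit(query="q2", subject="s1", bit_score=150.0),
        ])
        out = assign_families(hits, self.FAMILIES)
        assert len(out) == 1
        assert out["family"].iloc[0] == "KAT/AKT"

    def test_ties_resolved_by_evalue_then_query_id(self):
        hits = pd.DataFrame([
            make_hit(query="q2", subject="s1", bit_score=200.0, evalue=1e-40),
            make_hit(query="q1", subject="s1", bit_score=200.0, evalue=1e-30),
            make_hit(query="q3", subject="s2", bit_score=100.0, evalue=1e-20),
            make_hit(query="q1", subject="s2", bit_score=100.0, evalue=1e-20),
        ])
        out = assign_families(hits, self.FAMILIES)
        by_subject = out.set_index("subject_id")["family"]
        assert by_subject["s1"] == "NHX"      # lower evalue wins the tie
        assert by_subject["s2"] == "KAT/AKT"  # then lexicographic query id

    def test_six_hit_toy_table_matches_hand_resolution(self):
        hits = pd.DataFrame([
            make_hit(query="q1", subject="sA", bit_score=300.0),
            make_hit(query="q2", subject="sA", bit_score=250.0),
            make_hit(query="q2", subject="sB", bit_score=180.0),
            make_hit(query="q3", subject="sB", bit_score=179.0),
            make_hit(query="q3", subject="sC", bit_score=90.0),
            make_hit(query="q1", subject="sC", bit_score=90.0, evalue=1e-50),
        ])
        out = assign_families(hits, self.FAMILIES)
        resolved = dict(zip(out["subject_id"], out["family"]))
        # hand resolution: sA -> q1 (300), sB -> q2 (180), sC -> q1 (tie, lower evalue)
        assert resolved == {"sA": "KAT/AKT", "sB": "NHX", "sC": "KAT/AKT"}
        assert list(out["family"]) == sorted(out["family"])  # sorted by family

    def test_one_row_per_subject(self, toy_hits):
        out = assign_families(toy_hits, {"q1": "KAT/AKT", "q3": "TPK"})
        assert out["subject_id"].is_unique

    def test_empty_input_gives_empty_output(self):
        hits = pd.DataFrame(columns=list(BLAST6_COLUMNS))
        assert len(assign_families(hits, self.FAMILIES)) == 0

    def test_unmapped_query_rejected(self):
        hits = pd.DataFrame([make_hit(query="mystery")])
        with pytest.raises(FamilyFilterError, match="mystery"):
            assign_families(hits, self.FAMILIES)


def test_read_blast6_round_trip(tmp_path):
    hits = pd.DataFrame([make_hit(), make_hit(subject="s2")])
    path = tmp_path / "hits.tsv"
    hits.to_csv(path, sep="\t", header=False, index=False)
    loaded = read_blast6(path)
    assert list(loaded.columns) == list(BLAST6_COLUMNS)
    assert len(loaded) == 2
    assert loaded["subject_id"].tolist() == ["s1", "s2"]


def test_read_blast6_rejects_wrong_column_count(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("a\tb\tc\n")
    with pytest.raises(FamilyFilterError):
        read_blast6(path)
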