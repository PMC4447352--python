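import numpy as np
import pytest
from hypothesis import given, strategies as st

from paleoks.core_io import TranscriptRecord, reverse_complement
from paleoks.homology import (
    Hit,
    ParalogPairId,
    ScoringScheme,
    all_vs_all_hits,
    local_align,
    pair_best_hits,
    read_tabular_hits,
    reciprocal_paralog_pairs,
    write_tabular_hits,
)


def sw_score_oracle(a, b, match=1, mismatch=-2, gap_open=5, gap_extend=2):
    """Plain-python affine Smith-Waterman score (quadratic reference)."""
    m, n = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def mutate(rng, seq, n_subs=0, indels=()):
    out = list(seq)
    for i in rng.choice(len(out), size=n_subs, replace=False):
        out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    seq = "".join(out)
    for pos, ins in indels:
        seq = seq[:pos] + ins + seq[pos + 3 :]
    return seq


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.mark.parametrize("length,n_subs,with_indel", [
    (120, 0, False),
    (250, 12, False),
    (400, 20, False),
    (300, 15, True),
    (200, 40, True),
])
def test_alignment_score_equals_quadratic_oracle(length, n_subs, with_indel):
    rng = np.random.default_rng(length + n_subs)
    a = random_seq(rng, length)
    indels = [(length // 2, "GGTACC")] if with_indel else []
    b = mutate(rng, a, n_subs=n_subs, indels=indels)
    score, ident, q_span, s_span, alen = local_align(a, b)
    assert score == sw_score_oracle(a, b)
    assert 0 < ident <= 1.0
    assert q_span[1] - q_span[0] > 0 and s_span[1] - s_span[0] > 0


def test_unrelated_sequences_have_low_oracle_score():
    rng = np.random.default_rng(7)
    a, b = random_seq(rng, 300), random_seq(rng, 300)
    assert local_align(a, b)[0] == sw_score_oracle(a, b) < 50


def test_identical_pair_yields_reciprocal_near_zero_evalue_hits():
    rng = np.random.default_rng(11)
    s = random_seq(rng, 500)
    recs = [TranscriptRecord("x", s), TranscriptRecord("y", s)]
    hits = all_vs_all_hits(recs)
    assert {(h.query_id, h.subject_id) for h in hits} == {("x", "y"), ("y", "x")}
    for h in hits:
        assert h.evalue < 1e-100
        assert h.identity_fraction == 1.0
        assert h.strand == "+"


def test_random_pair_has_no_hits_at_threshold():
    rng = np.random.default_rng(13)
    recs = [
        TranscriptRecord("x", random_seq(rng, 300)),
        TranscriptRecord("y", random_seq(rng, 300)),
    ]
    assert all_vs_all_hits(recs, max_evalue=1e-20) == []


def test_five_percent_divergent_copy_identity():
    rng = np.random.default_rng(17)
    s = random_seq(rng, 500)
    recs = [TranscriptRecord("x", s), TranscriptRecord("y", mutate(rng, s, n_subs=25))]
    hits = all_vs_all_hits(recs)
    assert hits
    assert abs(hits[0].identity_fraction - 0.95) < 0.02


def test_reverse_complement_only_pair_is_flagged_minus_strand():
    rng = np.random.default_rng(19)
    s = random_seq(rng, 400)
    recs = [TranscriptRecord("x", s), TranscriptRecord("y", reverse_complement(s))]
    hits = all_vs_all_hits(recs)
    assert hits and all(h.strand == "-" for h in hits)
    info = pair_best_hits(hits)
    assert not info[ParalogPairId("x", "y")]["has_plus"]


def test_search_input_contracts():
    rng = np.random.default_rng(23)
    recs = [TranscriptRecord("x", random_seq(rng, 100))]
    with pytest.raises(ValueError, match="at least 2"):
        all_vs_all_hits(recs)
    recs.append(TranscriptRecord("y", random_seq(rng, 100)))
    with pytest.raises(ValueError, match="word_size"):
        all_vs_all_hits(recs, word_size=3)


# ---------------------------------------------------------------------------
# tabular interchange


def test_read_tabular_example_line(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("a\tb\t95.0\t200\t10\t0\t1\t200\t1\t200\t1e-50\t370\n")
    (h,) = read_tabular_hits(p)
    assert h.query_id == "a" and h.subject_id == "b"
    assert h.evalue == 1e-50 and h.identity_fraction == 0.95
    assert h.q_span == (0, 200) and h.s_span == (0, 200) and h.strand == "+"


def test_read_tabular_minus_strand_normalization(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("a\tb\t90.0\t100\t10\t0\t1\t100\t150\t51\t1e-30\t180\n")
    (h,) = read_tabular_hits(p)
    assert h.strand == "-" and h.s_span == (50, 150)


def test_read_tabular_empty_and_errors(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    assert read_tabular_hits(p) == []
    p.write_text("a\tb\t95.0\t200\t10\t0\t1\t200\t1\t200\t1e-50\n")
    with pytest.raises(ValueError, match="line 1"):
        read_tabular_hits(p)
    p.write_text("a\tb\tninety\t200\t10\t0\t1\t200\t1\t200\t1e-50\t370\n")
    with pytest.raises(ValueError, match="line 1"):
        read_tabular_hits(p)


def test_tabular_round_trip(tmp_path):
    rng = np.random.default_rng(29)
    s = random_seq(rng, 400)
    recs = [TranscriptRecord("x", s), TranscriptRecord("y", mutate(rng, s, 10))]
    hits = all_vs_all_hits(recs)
    p = tmp_path / "rt.tsv"
    write_tabular_hits(hits, p)
    back = read_tabular_hits(p)
    assert len(back) == len(hits)
    for h1, h2 in zip(hits, back):
        assert (h1.query_id, h1.subject_id) == (h2.query_id, h2.subject_id)
        assert h1.q_span == h2.q_span and h1.s_span == h2.s_span
        assert h2.evalue == pytest.approx(h1.evalue, rel=0.01)


# ---------------------------------------------------------------------------
# reciprocal pairing


def _hit(q, s, e):
    return Hit(q, s, e, 100.0, 0.9, (0, 100), (0, 100), 100)


def test_reciprocal_pair_definition_examples():
    assert reciprocal_paralog_pairs([_hit("A", "B", 1e-30), _hit("B", "A", 1e-25)]) == {
        ParalogPairId("A", "B")
    }
    assert reciprocal_paralog_pairs([_hit("A", "B", 1e-30)]) == set()
    assert reciprocal_paralog_pairs([_hit("A", "A", 0.0)]) == set()


hit_lists = st.lists(
    st.tuples(
        st.integers(0, 30),
        st.integers(0, 30),
        st.sampled_from([1e-40, 1e-25, 1e-10, 1e-3]),
    ),
    max_size=120,
)


@given(hit_lists)
def test_reciprocal_pairs_equal_brute_force_mutual_edge_scan(triples):
    hits = [_hit(f"t{q}", f"t{s}", e) for q, s, e in triples]
    got = reciprocal_paralog_pairs(hits, max_evalue=1e-20)
    edges = {(h.query_id, h.subject_id) for h in hits if h.evalue <= 1e-20}
    expected = set()
    for q, s in edges:
        if q != s and (s, q) in edges:
            expected.add(ParalogPairId(q, s))
    assert got == expected
    # symmetry is inherent to the canonical pair type
    assert all(p.id_a < p.id_b for p in got)


@given(hit_lists)
def test_lowering_evalue_ceiling_never_adds_pairs(triples):
    hits = [_hit(f"t{q}", f"t{s}", e) for q, s, e in triples]
    loose = reciprocal_paralog_pairs(hits, max_evalue=1e-10)
    strict = reciprocal_paralog_pairs(hits, max_evalue=1e-30)
    assert strict <= loose


def test_self_pair_is_forbidden():
    with pytest.raises(ValueError):
        ParalogPairId("a", "a")
    assert ParalogPairId("b", "a") == ParalogPairId("a", "b")
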