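import numpy as np
import pytest

from paleoks.core_io import TranscriptRecord
from paleoks.orthologs import (
    DeletionRecord,
    align_sequences,
    consensus_majority,
    three_way_rbh,
    variant_report,
)
from tests.conftest import random_cds


# ---------------------------------------------------------------------------
# consensus


def test_majority_vote_column_examples():
    assert consensus_majority(["A", "A", "G"]) == "A"
    assert consensus_majority(["A", "C", "G"]) == "A"  # 3-way tie -> fixed order
    assert consensus_majority(["-", "-", "-"]) == "-"
    assert consensus_majority(["T", "-", "-"]) == "-"


def test_consensus_of_identical_sequences_is_identity():
    s = "ACGT-TGCA"
    assert consensus_majority([s, s, s]) == s


def test_consensus_rejects_unequal_lengths():
    with pytest.raises(ValueError, match="equal gapped length"):
        consensus_majority(["ACGT", "ACG"])


def test_consensus_is_order_free():
    seqs = ["ACGTAC", "AGGTAC", "ACGTCC"]
    for perm in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
        assert consensus_majority([seqs[i] for i in perm]) == "ACGTAC"


# ---------------------------------------------------------------------------
# variant reports on constructed alignments


def test_identical_trio_has_zero_snps():
    s = "ATGGCTGCTGCT"
    rep = variant_report({"a": s, "b": s, "c": s}, frame_anchor="a")
    assert rep.snp_counts == {"a": 0, "b": 0, "c": 0}
    assert rep.deletions == []


def test_constructed_trio_snp_classification():
    # consensus = seq b = seq c; seq a differs at two columns:
    #  col 5  (codon 1 pos 2): GCT->GCG  Ala->Ala   synonymous
    #  col 6  (codon 2 pos 0): GAT->TAT  Asp->Tyr   nonsynonymous
    base = "ATGGCTGATAAA"
    varia = "ATGGCGTATAAA"
    rep = variant_report({"a": varia, "b": base, "c": base}, frame_anchor="b")
    assert rep.snp_counts == {"a": 2, "b": 0, "c": 0}
    classes = {(s.column, s.klass) for s in rep.snps}
    assert classes == {(5, "synonymous"), (6, "nonsynonymous")}
    assert {s.codon_index for s in rep.snps} == {1, 2}


def test_six_nt_gap_is_a_two_codon_inframe_deletion():
    full = "ATGGCTGCTGATAAACCC"
    gapped = "ATGGCT------AAACCC"
    rep = variant_report({"a": gapped, "b": full, "c": full}, frame_anchor="b")
    assert rep.snp_counts["a"] == 0
    (d,) = [x for x in rep.deletions if x.seq_id == "a"]
    assert d == DeletionRecord("a", 6, 6, 2, True)


def test_shared_and_unique_nonsynonymous_accounting():
    cons = "ATGGATGATGAT"
    # b and c share a nonsyn change at col 3 (GAT->CAT); c has an extra one at
    # col 9; three consensus-identical sequences keep the majority at cons
    b = "ATGCATGATGAT"
    c = "ATGCATGATCAT"
    rep = variant_report(
        {"a": cons, "d": cons, "e": cons, "b": b, "c": c},
        frame_anchor="a",
        shared_pair=("b", "c"),
    )
    assert rep.shared_nonsynonymous == 1
    assert rep.unique_nonsynonymous == {"b": 0, "c": 1}


def test_snp_counts_are_order_invariant_and_bounded():
    seqs = {"a": "ATGGCTGATAAA", "b": "ATGGCGTATAAA", "c": "ATGGCTGATAAT"}
    counts = variant_report(seqs, frame_anchor="a").snp_counts
    reordered = dict(reversed(list(seqs.items())))
    assert variant_report(reordered, frame_anchor="a").snp_counts == counts
    assert all(v <= len(seqs["a"]) for v in counts.values())


def test_missing_anchor_is_an_error():
    with pytest.raises(ValueError, match="frame anchor"):
        variant_report({"a": "ATG", "b": "ATG"}, frame_anchor="zz")


# ---------------------------------------------------------------------------
# three-way RBH


def _mutated(rng, cds, n_subs):
    out = list(cds)
    pos = rng.choice(np.arange(3, len(out)), size=n_subs, replace=False)
    for i in pos:
        out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)


def _ortholog_sets(rng, n_genes, length_codons=150, n_subs=20):
    sets = ([], [], [])
    for g in range(n_genes):
        anc = random_cds(rng, length_codons)
        for si, records in enumerate(sets):
            records.append(
                TranscriptRecord(f"s{si}_g{g}", _mutated(rng, anc, n_subs))
            )
    return sets


def test_single_similar_triple_is_found(rng):
    a, b, c = _ortholog_sets(rng, 1)
    triples = three_way_rbh(a, b, c)
    assert len(triples) == 1
    assert triples[0].ids == ("s0_g0", "s1_g0", "s2_g0")


def test_planted_orthologs_are_fully_recovered(rng):
    a, b, c = _ortholog_sets(rng, 20)
    triples = three_way_rbh(a, b, c)
    assert len(triples) == 20
    for t in triples:
        gene = t.ids[0].split("_")[1]
        assert all(i.endswith(gene) for i in t.ids)


def test_inconsistent_best_hits_break_the_triple(rng):
    a, b, c = _ortholog_sets(rng, 1)
    # c's best hit is a different, unrelated gene: no triple survives
    c = [TranscriptRecord("s2_g0", random_cds(rng, 150))]
    assert three_way_rbh(a, b, c) == []


def test_empty_set_is_an_error():
    with pytest.raises(ValueError):
        three_way_rbh([], [], [])


def test_mafft_alignment_roundtrip(rng):
    recs = [
        TranscriptRecord("x", "ATGGCTGCTGATAAACCCGGG"),
        TranscriptRecord("y", "ATGGCTGATAAACCCGGG"),
    ]
    aligned = align_sequences(recs)
    assert list(aligned) == ["x", "y"]
    assert len(aligned["x"]) == len(aligned["y"])
    assert aligned["x"].replace("-", "") == recs[0].seq
    assert aligned["y"].replace("-", "") == recs[1].seq
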