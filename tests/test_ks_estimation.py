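import math

import numpy as np
import pytest

from paleoks.core_io import CODON_TABLE, SENSE_CODONS, STOP_CODONS
from paleoks.ks_estimation import (
    CodonAlignment,
    OrfError,
    SaturationError,
    codon_pair_differences,
    estimate_ks,
    jc_correct,
    longest_orf,
    ng_site_counts,
    protein_guided_codon_align,
    syn_site_fraction,
)
from tests.conftest import random_cds

# ---------------------------------------------------------------------------
# independent oracles


def syn_fraction_oracle(codon):
    """Direct enumeration of the 9 single-base changes."""
    count = 0
    for pos, base in ((p, b) for p in range(3) for b in "ACGT" if b != codon[p]):
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt not in STOP_CODONS and CODON_TABLE[alt] == CODON_TABLE[codon]:
            count += 1
    return count / 3


def pathway_oracle(c1, c2):
    """Explicit path enumeration via intermediate codon sequences (DFS),
    independent of the implementation's permutation loop."""

    def walk(cur):
        if cur == c2:
            return [(0, 0)]
        results = []
        for pos in range(3):
            if cur[pos] == c2[pos]:
                continue
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                continue
            step = (1, 0) if CODON_TABLE[cur] == CODON_TABLE[nxt] else (0, 1)
            for sd, nd in walk(nxt):
                results.append((step[0] + sd, step[1] + nd))
        return results

    paths = walk(c1)
    if not paths:  # all routes blocked by stops: allow them

        def walk_all(cur):
            if cur == c2:
                return [(0, 0)]
            results = []
            for pos in range(3):
                if cur[pos] == c2[pos]:
                    continue
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                step = (1, 0) if CODON_TABLE[cur] == CODON_TABLE[nxt] else (0, 1)
                for sd, nd in walk_all(nxt):
                    results.append((step[0] + sd, step[1] + nd))
            return results

        paths = walk_all(c1)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def test_pathway_counts_match_oracle_on_all_sense_codon_pairs():
    for c1 in SENSE_CODONS:
        assert syn_site_fraction(c1) == pytest.approx(syn_fraction_oracle(c1), abs=1e-12)
        for c2 in SENSE_CODONS:
            got = codon_pair_differences(c1, c2)
            want = pathway_oracle(c1, c2)
            assert got == pytest.approx(want, abs=1e-12), (c1, c2)


@pytest.mark.parametrize(
    "ca,cb,sd,nd",
    [
        ("TTT", "TTT", 0.0, 0.0),
        ("TTT", "TTC", 1.0, 0.0),  # Phe->Phe third-position change
        ("TTT", "GTA", 0.5, 1.5),  # two orders: (TTT->GTT->GTA), (TTT->TTA->GTA)
    ],
)
def test_single_column_counting_examples(ca, cb, sd, nd):
    S, N, Sd, Nd = ng_site_counts(CodonAlignment(ca, cb, 1))
    assert (Sd, Nd) == pytest.approx((sd, nd))
    assert S + N == pytest.approx(3.0)
    if ca == cb == "TTT":
        assert S == pytest.approx(1 / 3)  # only TTT->TTC is synonymous


def test_columns_with_gaps_or_n_are_excluded():
    aln = CodonAlignment("TTT---GGN" + "TTC", "TTTAAAGGG" + "TTC", 2)
    S, N, Sd, Nd = ng_site_counts(aln)
    # only the TTT/TTT and TTC/TTC columns count
    assert S == pytest.approx((1 / 3 + 1 / 3) / 2 + (1 / 3 + 1 / 3) / 2)
    assert Sd == Nd == 0.0


# ---------------------------------------------------------------------------
# Jukes-Cantor


def test_jc_closed_form_and_saturation():
    assert jc_correct(0.0) == 0.0
    for p in np.linspace(0.01, 0.74, 25):
        assert jc_correct(p) == pytest.approx(-0.75 * math.log(1 - 4 * p / 3), abs=1e-12)
        assert jc_correct(p) >= p
    assert jc_correct(0.3) == pytest.approx(0.383119, abs=1e-6)
    for p in (0.75, 0.9, 1.0):
        with pytest.raises(SaturationError):
            jc_correct(p)
    # divergence as p approaches the saturation bound
    assert jc_correct(0.7499) > 2.0


# ---------------------------------------------------------------------------
# ORF gate and codon alignment


def test_identical_cds_aligns_without_gaps(rng):
    cds = random_cds(rng, 100)
    aln = protein_guided_codon_align(cds, cds)
    assert aln.aligned_a == aln.aligned_b == cds
    assert aln.n_codon_columns == 100


def test_extra_internal_codon_becomes_one_triplet_gap(rng):
    cds = random_cds(rng, 80)
    with_insert = cds[: 40 * 3] + "GAA" + cds[40 * 3 :]
    aln = protein_guided_codon_align(cds, with_insert)
    assert aln.aligned_b.replace("-", "") == with_insert
    assert aln.aligned_a.count("-") == 3
    gap_start = aln.aligned_a.index("-")
    assert aln.aligned_a[gap_start : gap_start + 3] == "---"


def test_short_input_fails_orf_gate(rng):
    short = random_cds(rng, 20)
    with pytest.raises(OrfError, match="no usable ORF"):
        protein_guided_codon_align(short, random_cds(rng, 100))


def test_longest_orf_prefers_forward_frame_on_ties(rng):
    cds = random_cds(rng, 60)
    assert longest_orf(cds) == cds


# ---------------------------------------------------------------------------
# estimate_ks


def _plant_synonymous(rng, cds, n_changes):
    from paleoks.synthetic_data import _synonymous_options

    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    eligible = [i for i, c in enumerate(codons) if _synonymous_options(c)]
    for i in rng.choice(len(eligible), size=n_changes, replace=False):
        opts = _synonymous_options(codons[eligible[i]])
        codons[eligible[i]] = opts[rng.integers(0, len(opts))]
    return "".join(codons)


def test_identical_sequences_give_ks_zero(rng):
    cds = random_cds(rng, 120)
    res = estimate_ks(cds, cds)
    assert res.accepted and res.ks == 0.0
    assert res.S + res.N_sites == pytest.approx(3 * 120, abs=1e-9)


def test_planted_synonymous_divergence_recovers_jc_target(rng):
    cds = random_cds(rng, 300)
    S_approx = sum(syn_site_fraction(cds[i : i + 3]) for i in range(0, len(cds), 3))
    target_ps = 0.2
    planted = _plant_synonymous(rng, cds, round(target_ps * S_approx))
    res = estimate_ks(cds, planted)
    assert res.accepted
    assert res.ks == pytest.approx(jc_correct(0.2), abs=0.03)
    assert res.Nd == 0.0


def test_random_codon_sequences_are_saturated(rng):
    a = random_cds(rng, 200)
    b = random_cds(rng, 200)
    res = estimate_ks(a, b)
    # unrelated sequences exceed the correctable divergence
    assert res.reject_reason in ("saturated", "too_few_sites")


def test_estimate_ks_is_symmetric(rng):
    for trial in range(5):
        cds = random_cds(rng, 150)
        other = _plant_synonymous(rng, cds, 30)
        r1 = estimate_ks(cds, other)
        r2 = estimate_ks(other, cds)
        assert r1.ks == pytest.approx(r2.ks, abs=1e-9)
        assert (r1.S, r1.Sd) == (r2.S, r2.Sd)


def test_ks_monotone_on_nested_mutation_ladder(rng):
    cds = random_cds(rng, 300)
    ks_values = []
    current = cds
    for step in range(6):
        res = estimate_ks(cds, current)
        assert res.accepted
        ks_values.append(res.ks)
        current = _plant_synonymous(rng, current, 12)
    assert all(b >= a for a, b in zip(ks_values, ks_values[1:]))


def test_site_conservation_invariant(rng):
    for trial in range(5):
        a = random_cds(rng, 100)
        b = _plant_synonymous(rng, a, 20)
        aln = protein_guided_codon_align(a, b)
        S, N, Sd, Nd = ng_site_counts(aln)
        assert S + N == pytest.approx(3 * aln.n_codon_columns, abs=1e-9)
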