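"""Per-pair synonymous divergence (Ks) by codon-aware counting.

For each potential paralog pair the synonymous substitution rate proxy Ks is
estimated in four steps:

1. each transcript is trimmed to its longest open reading frame across the
   six frames (assembled transcripts are unoriented);
2. the two translations are globally aligned (BLOSUM62-class scoring) and
   the alignment is back-mapped onto the nucleotides, so every protein gap
   becomes an in-frame 3-nt gap;
3. synonymous/nonsynonymous sites and differences are counted with the
   Nei–Gojobori pathway-averaging scheme over gap-free, N-free, stop-free
   codon columns;
4. the observed synonymous difference proportion ps = Sd/S is corrected for
   multiple hits with the Jukes–Cantor formula ``d = -(3/4) ln(1 - (4/3)p)``.

Pairs too divergent for Jukes–Cantor (ps >= 3/4) are rejected as saturated,
as are pairs with fewer than ``min_sites`` synonymous sites; the rejection
reason is carried in the result rather than raised, so a pipeline can tally
rejections.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import log
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import CODON_TABLE, STOP_CODONS, reverse_complement, translate
from .homology import ParalogPairId

__all__ = [
    "CodonAlignment",
    "KsResult",
    "OrfError",
    "SaturationError",
    "TooFewSitesError",
    "longest_orf",
    "protein_guided_codon_align",
    "ng_site_counts",
    "jc_correct",
    "estimate_ks",
    "syn_site_fraction",
    "codon_pair_differences",
]

MIN_ORF_CODONS = 30


class OrfError(ValueError):
    pass


class SaturationError(ValueError):
    pass


class TooFewSitesError(ValueError):
    pass


@dataclass(frozen=True)
class CodonAlignment:
    """Gapped, in-frame nucleotide alignment of two coding sequences."""

    aligned_a: str
    aligned_b: str
    n_codon_columns: int  # gap-free, N-free codon columns


@dataclass(frozen=True)
class KsResult:
    """Nei–Gojobori counts and the Jukes–Cantor-corrected Ks for one pair."""

    S: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    ks: Optional[float]
    reject_reason: str = "none"  # none | saturated | too_few_sites | antisense
    pair: Optional[ParalogPairId] = None

    @property
    def accepted(self) -> bool:
        return self.reject_reason == "none"


# ---------------------------------------------------------------------------
# ORF handling


@lru_cache(maxsize=4096)
def longest_orf(seq: str) -> str:
    """Trim ``seq`` to its longest stop-free codon run over all 6 frames.

    Ties are broken toward the forward strand, then the lowest frame.
    Raises :class:`OrfError` if no frame yields >= 30 codons.
    """
    best_len = 0
    best_cds = ""
    for strand_seq in (seq, reverse_complement(seq)):
        for frame in range(3):
            sub = strand_seq[frame:]
            n_codons = len(sub) // 3
            run_start = 0
            i = 0
            while i <= n_codons:
                codon = sub[3 * i : 3 * i + 3] if i < n_codons else None
                if codon is None or codon in STOP_CODONS:
                    run = i - run_start
                    if run > best_len:
                        best_len = run
                        best_cds = sub[3 * run_start : 3 * i]
                    run_start = i + 1
                i += 1
    if best_len < MIN_ORF_CODONS:
        raise OrfError("no usable ORF (need >= 30 stop-free codons)")
    return best_cds


# ---------------------------------------------------------------------------
# protein-guided codon alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def protein_guided_codon_align(cds_a: str, cds_b: str) -> CodonAlignment:
    """Align two coding sequences codon-wise via their translations.

    Inputs are first trimmed to their longest ORF; the translations are
    globally aligned and the protein gaps expanded to 3-nt gaps.
    """
    orf_a = longest_orf(cds_a)
    orf_b = longest_orf(cds_b)
    prot_a = translate(orf_a)
    prot_b = translate(orf_b)
    if "*" in prot_a or "*" in prot_b:
        raise OrfError("internal stop codon within chosen ORF")
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    gapped_a, gapped_b = str(aln[0]), str(aln[1])
    nt_a, nt_b = [], []
    ia = ib = 0
    n_clean = 0
    for ca, cb in zip(gapped_a, gapped_b):
        if ca == "-":
            nt_a.append("---")
        else:
            nt_a.append(orf_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            nt_b.append("---")
        else:
            nt_b.append(orf_b[3 * ib : 3 * ib + 3])
            ib += 1
        if ca != "-" and cb != "-" and "N" not in nt_a[-1] and "N" not in nt_b[-1]:
            n_clean += 1
    return CodonAlignment("".join(nt_a), "".join(nt_b), n_clean)


# ---------------------------------------------------------------------------
# Nei–Gojobori counting


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """Synonymous-site content of a codon: per position, the fraction of the
    3 possible single-base changes that are synonymous (changes to stop
    codons count as non-synonymous), summed over the 3 positions."""
    s = 0
    aa = CODON_TABLE[codon]
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TABLE[alt] == aa and alt not in STOP_CODONS:
                s += 1
    return s / 3.0


def _enumerate_paths(c1: str, c2: str, allow_stops: bool) -> list[tuple[int, int]]:
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    return paths


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts between
    two sense codons.  Pathways through stop codons are discarded; if every
    pathway is blocked, all pathways are used instead."""
    if c1 == c2:
        return (0.0, 0.0)
    paths = _enumerate_paths(c1, c2, allow_stops=False)
    if not paths:
        paths = _enumerate_paths(c1, c2, allow_stops=True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return (sd, nd)


def ng_site_counts(aln: CodonAlignment) -> tuple[float, float, float, float]:
    """Nei–Gojobori (S, N, Sd, Nd) over the countable codon columns.

    Countable = gap-free, N-free, stop-free in both sequences.  Site totals
    satisfy S + N = 3 x countable columns exactly.
    """
    S = N = Sd = Nd = 0.0
    n_cols = 0
    for k in range(0, len(aln.aligned_a), 3):
        ca = aln.aligned_a[k : k + 3]
        cb = aln.aligned_b[k : k + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        n_cols += 1
        s_codon = (syn_site_fraction(ca) + syn_site_fraction(cb)) / 2.0
        S += s_codon
        N += 3.0 - s_codon
        sd, nd = codon_pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    if n_cols == 0:
        raise TooFewSitesError("too_few_sites: no countable codon columns")
    return S, N, Sd, Nd


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction ``d = -(3/4) ln(1 - (4/3)p)``.

    Raises :class:`SaturationError` for p >= 3/4, where the model is
    undefined (the pair is too divergent to correct).
    """
    if not 0.0 <= p:
        raise ValueError(f"difference proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"saturated: p = {p} >= 3/4")
    return -0.75 * log(1.0 - (4.0 / 3.0) * p) + 0.0


def estimate_ks(
    cds_a: str,
    cds_b: str,
    min_sites: float = 10.0,
    pair: Optional[ParalogPairId] = None,
) -> KsResult:
    """Full per-pair Ks estimate: ORF-trim, codon-align, count, correct.

    Symmetric in its two sequence arguments (the input order is
    canonicalized internally so tie-broken gap placements cannot differ).
    Saturation and thin alignments yield a rejected result, not an error.
    """
    if cds_b < cds_a:
        cds_a, cds_b = cds_b, cds_a
    aln = protein_guided_codon_align(cds_a, cds_b)
    try:
        S, N, Sd, Nd = ng_site_counts(aln)
    except TooFewSitesError:
        return KsResult(0.0, 0.0, 0.0, 0.0, 0.0, None, "too_few_sites", pair)
    if S < min_sites:
        return KsResult(S, N, Sd, Nd, 0.0, None, "too_few_sites", pair)
    ps = Sd / S
    try:
        ks = jc_correct(ps)
    except SaturationError:
        return KsResult(S, N, Sd, Nd, ps, None, "saturated", pair)
    return KsResult(S, N, Sd, Nd, ps, ks, "none", pair)
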