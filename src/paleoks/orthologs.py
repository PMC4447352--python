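"""Cross-sample ortholog triples and consensus-based variant reports.

Given transcript sets from three related samples, ortholog candidates are
the triples (a, b, c) whose three pairwise relations are each reciprocal
*best* hits at the e-value ceiling.  Each triple is multiple-aligned, a
majority-vote consensus is built, and every sequence is compared against
that consensus: per-sequence SNP counts, synonymous/nonsynonymous
classification of each SNP (by substituting the variant base into the
consensus codon), shared vs unique nonsynonymous sites for a designated
sequence pair, and in-frame deletion records from maximal gap runs.

The multiple alignment of a triple is delegated to MAFFT (helper
:func:`align_sequences`); all reporting operations work on any pre-aligned
input of equal gapped length.
"""

from __future__ import annotations

import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .core_io import CODON_TABLE, TranscriptRecord, write_fasta
from .homology import Hit, cross_hits

__all__ = [
    "OrthologTriple",
    "SnpRecord",
    "DeletionRecord",
    "VariantReport",
    "three_way_rbh",
    "consensus_majority",
    "variant_report",
    "align_sequences",
]

# Fixed symbol order for majority-vote tie-breaking.
_SYMBOL_ORDER = {ch: i for i, ch in enumerate("ACGTN-")}


@dataclass(frozen=True)
class OrthologTriple:
    """One transcript id per sample; all three pairwise RBH relations hold."""

    ids: tuple[str, str, str]
    evalues: tuple[float, float, float]  # (a-b, b-c, a-c)


@dataclass(frozen=True)
class SnpRecord:
    seq_id: str
    column: int  # 0-based alignment column
    consensus_base: str
    observed_base: str
    codon_index: Optional[int]  # anchor-frame codon, None outside the frame
    klass: str  # synonymous | nonsynonymous | unclassified


@dataclass(frozen=True)
class DeletionRecord:
    seq_id: str
    column_start: int
    length_nt: int
    length_codons: Optional[int]  # length_nt/3 when in frame, else None
    in_frame: bool


@dataclass(frozen=True)
class VariantReport:
    snp_counts: dict[str, int]
    snps: list[SnpRecord]
    deletions: list[DeletionRecord]
    shared_nonsynonymous: Optional[int] = None
    unique_nonsynonymous: Optional[dict[str, int]] = None
    consensus: str = field(default="", repr=False)


def _best_hits(hits: Sequence[Hit]) -> dict[str, Hit]:
    """Best hit per query: lowest e-value, ties by bitscore then subject id."""
    best: dict[str, Hit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or (h.evalue, -h.bitscore, h.subject_id)
            < (cur.evalue, -cur.bitscore, cur.subject_id)
        ):
            best[h.query_id] = h
    return best


def _rbh_pairs(
    set_x: Sequence[TranscriptRecord],
    set_y: Sequence[TranscriptRecord],
    max_evalue: float,
) -> dict[str, tuple[str, float]]:
    """Reciprocal best hits x -> (y, evalue), keyed by x id."""
    fwd = _best_hits(cross_hits(set_x, set_y, max_evalue=max_evalue))
    rev = _best_hits(cross_hits(set_y, set_x, max_evalue=max_evalue))
    out: dict[str, tuple[str, float]] = {}
    for x_id, h in fwd.items():
        back = rev.get(h.subject_id)
        if back is not None and back.subject_id == x_id:
            out[x_id] = (h.subject_id, min(h.evalue, back.evalue))
    return out


def three_way_rbh(
    set_a: Sequence[TranscriptRecord],
    set_b: Sequence[TranscriptRecord],
    set_c: Sequence[TranscriptRecord],
    max_evalue: float = 1e-20,
) -> list[OrthologTriple]:
    """Ortholog triples: (a, b, c) where a<->b, b<->c and a<->c are each
    reciprocal best hits at <= max_evalue."""
    if not (set_a and set_b and set_c):
        raise ValueError("all three transcript sets must be non-empty")
    ab = _rbh_pairs(set_a, set_b, max_evalue)
    bc = _rbh_pairs(set_b, set_c, max_evalue)
    ac = _rbh_pairs(set_a, set_c, max_evalue)
    triples: list[OrthologTriple] = []
    for a_id, (b_id, e_ab) in sorted(ab.items()):
        if b_id not in bc or a_id not in ac:
            continue
        c_from_b, e_bc = bc[b_id]
        c_from_a, e_ac = ac[a_id]
        if c_from_b == c_from_a:
            triples.append(OrthologTriple((a_id, b_id, c_from_a), (e_ab, e_bc, e_ac)))
    return triples


def consensus_majority(aligned: Sequence[str]) -> str:
    """Per-column majority symbol (gap counts as a symbol); ties broken by
    the fixed order A < C < G < T < N < gap."""
    if len(aligned) < 2:
        raise ValueError("need >= 2 sequences for a consensus")
    length = len(aligned[0])
    if any(len(s) != length for s in aligned):
        raise ValueError("aligned sequences must have equal gapped length")
    cons = []
    for col in range(length):
        counts = Counter(s[col] for s in aligned)
        best = min(counts, key=lambda ch: (-counts[ch], _SYMBOL_ORDER.get(ch, 99)))
        cons.append(best)
    return "".join(cons)


def _anchor_codon_map(anchor_gapped: str) -> tuple[dict[int, int], dict[int, list[int]]]:
    """Column -> codon index (anchor frame), and codon index -> its columns."""
    col_to_codon: dict[int, int] = {}
    codon_cols: dict[int, list[int]] = {}
    residue = 0
    for col, ch in enumerate(anchor_gapped):
        if ch == "-":
            continue
        ci = residue // 3
        col_to_codon[col] = ci
        codon_cols.setdefault(ci, []).append(col)
        residue += 1
    return col_to_codon, codon_cols


def _classify_snp(
    consensus: str,
    codon_cols: Optional[list[int]],
    column: int,
    observed: str,
) -> str:
    if codon_cols is None or len(codon_cols) != 3:
        return "unclassified"
    ref_codon = "".join(consensus[c] for c in codon_cols)
    if "-" in ref_codon or "N" in ref_codon or observed == "N":
        return "unclassified"
    pos = codon_cols.index(column)
    alt_codon = ref_codon[:pos] + observed + ref_codon[pos + 1 :]
    aa_ref = CODON_TABLE.get(ref_codon, "X")
    aa_alt = CODON_TABLE.get(alt_codon, "X")
    if "X" in (aa_ref, aa_alt):
        return "unclassified"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def variant_report(
    aligned: Mapping[str, str],
    frame_anchor: str,
    shared_pair: Optional[tuple[str, str]] = None,
) -> VariantReport:
    """SNPs, classifications and deletions of each sequence vs the
    majority-vote consensus of the alignment.

    The reading frame starts at the first aligned base of ``frame_anchor``;
    a SNP is a non-gap mismatch column, while gap columns are reported only
    as deletion records (maximal gap runs, flagged in-frame when their
    length is divisible by 3).  ``shared_pair`` selects two sequences for
    shared/unique nonsynonymous-site accounting.
    """
    if frame_anchor not in aligned:
        raise ValueError(f"frame anchor {frame_anchor!r} not in alignment")
    seqs = dict(aligned)
    consensus = consensus_majority(list(seqs.values()))
    col_to_codon, codon_cols = _anchor_codon_map(seqs[frame_anchor])

    snps: list[SnpRecord] = []
    deletions: list[DeletionRecord] = []
    for seq_id, gapped in seqs.items():
        # SNPs: mismatch columns where neither base is a gap
        for col, (obs, ref) in enumerate(zip(gapped, consensus)):
            if obs == "-" or ref == "-" or obs == ref:
                continue
            ci = col_to_codon.get(col)
            klass = _classify_snp(consensus, codon_cols.get(ci), col, obs)
            snps.append(SnpRecord(seq_id, col, ref, obs, ci, klass))
        # deletions: maximal gap runs in this sequence spanning consensus bases
        col = 0
        length = len(gapped)
        while col < length:
            if gapped[col] != "-":
                col += 1
                continue
            start = col
            while col < length and gapped[col] == "-":
                col += 1
            nt = sum(1 for c in range(start, col) if consensus[c] != "-")
            if nt > 0:
                in_frame = nt % 3 == 0
                deletions.append(
                    DeletionRecord(seq_id, start, nt, nt // 3 if in_frame else None, in_frame)
                )

    snp_counts = {sid: 0 for sid in seqs}
    for s in snps:
        snp_counts[s.seq_id] += 1

    shared = None
    unique = None
    if shared_pair is not None:
        p, q = shared_pair
        nonsyn = {
            sid: {
                (s.column, s.observed_base)
                for s in snps
                if s.seq_id == sid and s.klass == "nonsynonymous"
            }
            for sid in (p, q)
        }
        shared = len(nonsyn[p] & nonsyn[q])
        unique = {
            p: len(nonsyn[p] - nonsyn[q]),
            q: len(nonsyn[q] - nonsyn[p]),
        }
    return VariantReport(snp_counts, snps, deletions, shared, unique, consensus)


def align_sequences(records: Sequence[TranscriptRecord]) -> dict[str, str]:
    """Multiple-align a small set of transcripts with MAFFT (--auto).

    Returns id -> gapped uppercase sequence, preserving input order in the
    dict.  Used by the ortholog-scan pipeline for each triple.
    """
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        write_fasta(records, infile)
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
    aligned = _parse_gapped_fasta(proc.stdout)
    return {r.id: aligned[r.id] for r in records}


def _parse_gapped_fasta(text: str) -> dict[str, str]:
    # gapped sequences violate TranscriptRecord's alphabet, so parse manually;
    # sequence lines (but not headers) are uppercased
    out: dict[str, list[str]] = {}
    current: Optional[str] = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith(">"):
            current = line[1:].split()[0]
            out[current] = []
        elif line and current is not None:
            out[current].append(line.upper())
    return {rid: "".join(parts) for rid, parts in out.items()}
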