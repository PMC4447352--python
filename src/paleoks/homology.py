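"""All-vs-all nucleotide similarity search and reciprocal paralog pairing.

Within-transcriptome paralog candidates are found by a self-search: every
ordered pair of transcripts sharing an exact ``word_size`` seed is extended
to a gapped local alignment, scored with simple match/mismatch + affine gap
costs, and converted to an e-value with the classical Karlin–Altschul
formula ``E = K * m * n * exp(-lambda * S)`` (database size = total residues
searched).  Pairs with reciprocal hits at or below the e-value ceiling
(default 1e-20, the conventional paralog-screen threshold) are reported as
potential paralogs; *all* reciprocal pairs are kept, not only best hits, so
one transcript may appear in several pairs.

Implementation note: candidate pairs are screened with a cheap ungapped
X-drop extension of their seeds, and survivors are aligned with a full
(exact, quadratic-time) affine Smith–Waterman, so reported scores are the
true local-alignment optimum for the pair.  Both strands are searched;
pairs whose only alignments are minus-strand are antisense artifacts and
are flagged for exclusion from downstream codon analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .core_io import TranscriptRecord, reverse_complement

__all__ = [
    "Hit",
    "ParalogPairId",
    "ScoringScheme",
    "all_vs_all_hits",
    "cross_hits",
    "local_align",
    "read_tabular_hits",
    "write_tabular_hits",
    "reciprocal_paralog_pairs",
    "pair_best_hits",
]

# Karlin-Altschul parameters for match +1 / mismatch -2 (published blastn
# table values).  Used for both ungapped and gapped scores.
LAMBDA = 1.28
KAPPA = 0.46

# problems up to this many DP cells get the full exact Smith-Waterman;
# larger ones a banded DP around the seed diagonals
_FULL_SW_MAX_CELLS = 1_000_000
_BAND_PAD = 64

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _ENCODE[ord(_ch)] = _i


@dataclass(frozen=True)
class ScoringScheme:
    """Simple nucleotide scoring: a gap of length L costs open + L*extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2


@dataclass(frozen=True)
class Hit:
    """One directed local-similarity match between two transcripts.

    Spans are 0-based half-open on the forward strand of each sequence;
    ``strand`` is '-' when the subject aligns via its reverse complement.
    """

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    identity_fraction: float
    q_span: tuple[int, int]
    s_span: tuple[int, int]
    aligned_length: int
    strand: str = "+"


class ParalogPairId(tuple):
    """Unordered transcript pair in canonical (lexicographic) order."""

    def __new__(cls, id_a: str, id_b: str):
        if id_a == id_b:
            raise ValueError(f"self-pair forbidden: {id_a}")
        if id_a > id_b:
            id_a, id_b = id_b, id_a
        return super().__new__(cls, (id_a, id_b))

    @property
    def id_a(self) -> str:
        return self[0]

    @property
    def id_b(self) -> str:
        return self[1]


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _sw_affine(a, b, match, mismatch, gap_open, gap_extend, dmin, dmax):  # pragma: no cover
    # computes cells with diagonal i-j in [dmin, dmax]; a full band
    # (dmin=-n, dmax=m) gives the exact Smith-Waterman optimum, a narrow
    # band a lower bound on it (outside-band cells stay at the local floor 0)
    m, n = len(a), len(b)
    NEG = -(10 ** 9)
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    tbH = np.zeros((m + 1, n + 1), np.uint8)
    tbE = np.zeros((m + 1, n + 1), np.uint8)
    tbF = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        jlo = i - dmax
        if jlo < 1:
            jlo = 1
        jhi = i - dmin
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                tbE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                tbF[i, j] = 1
            else:
                F[i, j] = f_open
            if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            t = 1
            if F[i, j] > h:
                h = F[i, j]
                t = 2
            if E[i, j] > h:
                h = E[i, j]
                t = 3
            if h <= 0:
                h = 0
                t = 0
            H[i, j] = h
            tbH[i, j] = t
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, tbH, tbE, tbF


@njit(cache=True)
def _sw_traceback(a, b, bi, bj, tbH, tbE, tbF):  # pragma: no cover
    i, j = bi, bj
    state = 0  # 0=H, 1=E (gap in a), 2=F (gap in b)
    matches = 0
    alen = 0
    while True:
        if state == 0:
            t = tbH[i, j]
            if t == 0:
                break
            if t == 1:
                alen += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                    matches += 1
                i -= 1
                j -= 1
            elif t == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            alen += 1
            ext = tbE[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            alen += 1
            ext = tbF[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return i, j, matches, alen


@njit(cache=True)
def _batch_ungapped(
    qcat, qoff, scat_f, soff_f, scat_r, soff_r,
    qi_g, sj_g, st_g, starts, ends, qp, sp,
    k, match, mismatch, xdrop, max_diags,
):  # pragma: no cover
    """Best ungapped X-drop seed-extension score per candidate group."""
    n_groups = len(qi_g)
    out = np.zeros(n_groups, np.int64)
    for g in range(n_groups):
        i = qi_g[g]
        j = sj_g[g]
        a = qcat[qoff[i] : qoff[i + 1]]
        if st_g[g] == 0:
            b = scat_f[soff_f[j] : soff_f[j + 1]]
        else:
            b = scat_r[soff_r[j] : soff_r[j + 1]]
        hi = ends[g]
        if hi - starts[g] > max_diags:
            hi = starts[g] + max_diags
        best = 0
        for s in range(starts[g], hi):
            sc = _ungapped_seed_score(a, b, qp[s], sp[s], k, match, mismatch, xdrop)
            if sc > best:
                best = sc
        out[g] = best
    return out


@njit(cache=True)
def _ungapped_seed_score(a, b, qpos, spos, k, match, mismatch, xdrop):  # pragma: no cover
    score = k * match
    # right extension
    cur = 0
    best = 0
    i = qpos + k
    j = spos + k
    while i < len(a) and j < len(b):
        if a[i] == b[j] and a[i] != 4:
            cur += match
        else:
            cur += mismatch
        if cur > best:
            best = cur
        if best - cur > xdrop:
            break
        i += 1
        j += 1
    score += best
    # left extension
    cur = 0
    best = 0
    i = qpos - 1
    j = spos - 1
    while i >= 0 and j >= 0:
        if a[i] == b[j] and a[i] != 4:
            cur += match
        else:
            cur += mismatch
        if cur > best:
            best = cur
        if best - cur > xdrop:
            break
        i -= 1
        j -= 1
    return score + best


# ---------------------------------------------------------------------------
# public alignment API


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _concat_encoded(arrs: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.zeros(len(arrs) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(a) for a in arrs])
    return np.concatenate(arrs), offsets


def local_align(
    seq_a: str, seq_b: str, scoring: ScoringScheme = ScoringScheme()
) -> tuple[int, float, tuple[int, int], tuple[int, int], int]:
    """Exact affine-gap Smith-Waterman local alignment of two sequences.

    Returns ``(score, identity_fraction, q_span, s_span, aligned_length)``.
    A score of 0 means no positive-scoring local alignment exists.
    """
    a = _encode(seq_a)
    b = _encode(seq_b)
    return _align_encoded(a, b, scoring, -len(b), len(a))


def _align_encoded(
    a: np.ndarray,
    b: np.ndarray,
    scoring: ScoringScheme,
    dmin: int,
    dmax: int,
) -> tuple[int, float, tuple[int, int], tuple[int, int], int]:
    score, bi, bj, tbH, tbE, tbF = _sw_affine(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
        dmin, dmax,
    )
    if score <= 0:
        return 0, 0.0, (0, 0), (0, 0), 0
    qi, qj, matches, alen = _sw_traceback(a, b, bi, bj, tbH, tbE, tbF)
    return int(score), matches / alen, (qi, bi), (qj, bj), int(alen)


def evalue_from_score(score: float, m: int, n_db: int) -> float:
    """Karlin-Altschul e-value for a raw local-alignment score."""
    return float(KAPPA * m * n_db * np.exp(-LAMBDA * score))


def bitscore_from_score(score: float) -> float:
    return float((LAMBDA * score - np.log(KAPPA)) / np.log(2.0))


# ---------------------------------------------------------------------------
# seeding


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all N-free k-mers plus their start positions."""
    n = len(arr)
    if n < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    valid = arr < 4
    ok = np.ones(n - k + 1, dtype=bool)
    for off in range(k):
        ok &= valid[off : off + n - k + 1]
    pos = np.nonzero(ok)[0]
    codes = np.zeros(len(pos), dtype=np.int64)
    for off in range(k):
        codes = codes * 4 + arr[pos + off]
    return codes, pos


def _candidate_seeds(
    q_arrs: Sequence[np.ndarray],
    s_arrs: Sequence[np.ndarray],
    s_rc_arrs: Sequence[np.ndarray],
    word_size: int,
    same_set: bool,
    max_bucket: int = 200,
):
    """Candidate (query, subject, strand) groups with their seed diagonals.

    Returns ``(qi_g, sj_g, st_g, starts, ends, diag, qp, sp)``: one entry per
    candidate group in the first five arrays (``starts``/``ends`` index into
    the per-seed arrays, one entry per distinct seed diagonal, first seed
    kept).  For a self-search only i < j pairs are produced (alignments are
    mirrored later).  Heavily repeated words (bucket > max_bucket) are
    skipped.  Matching sorts the subject word table and binary-searches
    every query word into it (vectorized).
    """
    if len(s_arrs) >= (1 << 19) or len(q_arrs) >= (1 << 19):
        raise ValueError("too many sequences for the seed index")
    # subject word table over both strands
    s_codes, s_seq, s_strand, s_pos = [], [], [], []
    for j, (fwd, rc) in enumerate(zip(s_arrs, s_rc_arrs)):
        for strand, arr in ((0, fwd), (1, rc)):
            if len(arr) >= (1 << 21):
                raise ValueError("sequence too long for the seed index")
            codes, pos = _kmer_codes(arr, word_size)
            s_codes.append(codes)
            s_pos.append(pos)
            s_seq.append(np.full(len(codes), j, np.int64))
            s_strand.append(np.full(len(codes), strand, np.int64))
    sc = np.concatenate(s_codes)
    sj_all = np.concatenate(s_seq)
    st_all = np.concatenate(s_strand)
    sp_all = np.concatenate(s_pos)
    order = np.argsort(sc, kind="stable")
    sc, sj_all, st_all, sp_all = sc[order], sj_all[order], st_all[order], sp_all[order]

    # query word table
    q_codes, q_seq, q_pos = [], [], []
    for i, arr in enumerate(q_arrs):
        codes, pos = _kmer_codes(arr, word_size)
        q_codes.append(codes)
        q_pos.append(pos)
        q_seq.append(np.full(len(codes), i, np.int64))
    qc = np.concatenate(q_codes)
    qi_all = np.concatenate(q_seq)
    qp_all = np.concatenate(q_pos)

    lo = np.searchsorted(sc, qc, side="left")
    hi = np.searchsorted(sc, qc, side="right")
    width = hi - lo
    width = np.where(width > max_bucket, 0, width)
    reps = width
    _empty = (
        np.empty(0, np.int64),
    ) * 8
    if reps.sum() == 0:
        return _empty
    qi = np.repeat(qi_all, reps)
    qp = np.repeat(qp_all, reps)
    # indices into the sorted subject table for each match
    starts = np.repeat(lo, reps)
    offsets = np.arange(len(starts)) - np.repeat(
        np.cumsum(reps) - reps, reps
    )
    sidx = starts + offsets
    sj = sj_all[sidx]
    st = st_all[sidx]
    sp = sp_all[sidx]
    if same_set:
        keep = sj > qi
        qi, qp, sj, st, sp = qi[keep], qp[keep], sj[keep], st[keep], sp[keep]
    if len(qi) == 0:
        return _empty
    diag = qp - sp
    pairkey = (qi << 20) | (sj << 1) | st
    combo = (pairkey << 22) | (diag + (1 << 21))
    order = np.argsort(combo, kind="stable")
    combo_s = combo[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = combo_s[1:] != combo_s[:-1]
    sel = order[first]
    pk_s = pairkey[sel]
    diag_s, qp_s, sp_s = diag[sel], qp[sel], sp[sel]
    new_grp = np.ones(len(pk_s), dtype=bool)
    new_grp[1:] = pk_s[1:] != pk_s[:-1]
    starts = np.flatnonzero(new_grp)
    ends = np.append(starts[1:], len(pk_s))
    pk_g = pk_s[starts]
    st_g = pk_g & 1
    sj_g = (pk_g >> 1) & ((1 << 19) - 1)
    qi_g = pk_g >> 20
    return qi_g, sj_g, st_g, starts, ends, diag_s, qp_s, sp_s


def _search(
    queries: Sequence[TranscriptRecord],
    subjects: Sequence[TranscriptRecord],
    max_evalue: float,
    word_size: int,
    scoring: ScoringScheme,
    same_set: bool,
    prefilter_min_score: int = 25,
    xdrop: int = 20,
) -> list[Hit]:
    if word_size < 4:
        raise ValueError(f"word_size must be >= 4, got {word_size}")
    q_arrs = [_encode(r.seq) for r in queries]
    s_arrs = q_arrs if same_set else [_encode(r.seq) for r in subjects]
    s_rc = [_encode(reverse_complement(r.seq)) for r in subjects]
    n_db = sum(len(r.seq) for r in subjects)
    qi_g, sj_g, st_g, starts, ends, diag, qp, sp = _candidate_seeds(
        q_arrs, s_arrs, s_rc, word_size, same_set
    )
    hits: list[Hit] = []
    if len(qi_g) == 0:
        return hits
    qcat, qoff = _concat_encoded(q_arrs)
    scat_f, soff_f = (qcat, qoff) if same_set else _concat_encoded(s_arrs)
    scat_r, soff_r = _concat_encoded(s_rc)
    # screen candidate groups with a cheap ungapped seed extension
    ungapped = _batch_ungapped(
        qcat, qoff, scat_f, soff_f, scat_r, soff_r,
        qi_g, sj_g, st_g, starts, ends, qp, sp,
        word_size, scoring.match, scoring.mismatch, xdrop, 16,
    )
    for g in np.flatnonzero(ungapped >= prefilter_min_score).tolist():
        i, j = int(qi_g[g]), int(sj_g[g])
        strand = "+" if st_g[g] == 0 else "-"
        a = q_arrs[i]
        b = s_arrs[j] if strand == "+" else s_rc[j]
        # exact SW for moderate problems; for long pairs restrict the DP to
        # a generous band around the seed diagonals (a lower bound on the
        # exact score, tight in practice)
        if len(a) * len(b) <= _FULL_SW_MAX_CELLS:
            dmin, dmax = -len(b), len(a)
        else:
            group_diags = diag[starts[g] : ends[g]]
            dmin = int(group_diags.min()) - _BAND_PAD
            dmax = int(group_diags.max()) + _BAND_PAD
        score, ident, q_span, s_span, alen = _align_encoded(a, b, scoring, dmin, dmax)
        if score <= 0:
            continue
        if strand == "-":
            L = len(subjects[j].seq)
            s_span = (L - s_span[1], L - s_span[0])
        ev = evalue_from_score(score, len(queries[i].seq), n_db)
        if ev > max_evalue:
            continue
        bs = bitscore_from_score(score)
        hits.append(
            Hit(queries[i].id, subjects[j].id, ev, bs, ident, q_span, s_span, alen, strand)
        )
        if same_set:
            ev_rev = evalue_from_score(score, len(subjects[j].seq), n_db)
            if ev_rev <= max_evalue:
                hits.append(
                    Hit(
                        subjects[j].id,
                        queries[i].id,
                        ev_rev,
                        bs,
                        ident,
                        s_span,
                        q_span,
                        alen,
                        strand,
                    )
                )
    return hits


def all_vs_all_hits(
    records: Sequence[TranscriptRecord],
    max_evalue: float = 1e-20,
    word_size: int = 11,
    scoring: ScoringScheme = ScoringScheme(),
) -> list[Hit]:
    """Self-search of a transcript set.  Self-hits are suppressed; both
    directed hits of each aligning pair are reported."""
    if len(records) < 2:
        raise ValueError("need at least 2 records for an all-vs-all search")
    return _search(records, records, max_evalue, word_size, scoring, same_set=True)


def cross_hits(
    queries: Sequence[TranscriptRecord],
    subjects: Sequence[TranscriptRecord],
    max_evalue: float = 1e-20,
    word_size: int = 11,
    scoring: ScoringScheme = ScoringScheme(),
) -> list[Hit]:
    """Directed query-vs-subject search between two transcript sets."""
    if not queries or not subjects:
        raise ValueError("empty query or subject set")
    return _search(queries, subjects, max_evalue, word_size, scoring, same_set=False)


# ---------------------------------------------------------------------------
# tabular interchange (the de facto 12-column hit format)

_TAB_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def read_tabular_hits(path: str | Path) -> list[Hit]:
    """Read 12-column tab-separated hits (1-based inclusive coordinates).

    Minus-strand subject spans (sstart > send) are normalized to forward
    coordinates with ``strand='-'``.
    """
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if sstart > send:
                strand = "-"
                s_span = (send - 1, sstart)
            else:
                strand = "+"
                s_span = (sstart - 1, send)
            hits.append(
                Hit(
                    fields[0],
                    fields[1],
                    evalue,
                    bitscore,
                    pident / 100.0,
                    (qstart - 1, qend),
                    s_span,
                    length,
                    strand,
                )
            )
    return hits


def write_tabular_hits(hits: Iterable[Hit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            mism = h.aligned_length - round(h.identity_fraction * h.aligned_length)
            if h.strand == "+":
                sstart, send = h.s_span[0] + 1, h.s_span[1]
            else:
                sstart, send = h.s_span[1], h.s_span[0] + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{100.0 * h.identity_fraction:.2f}",
                        h.aligned_length,
                        mism,
                        0,
                        h.q_span[0] + 1,
                        h.q_span[1],
                        sstart,
                        send,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# reciprocal pairing


def reciprocal_paralog_pairs(
    hits: Iterable[Hit], max_evalue: float = 1e-20
) -> set[ParalogPairId]:
    """Unordered pairs {A,B} with hits in both directions at <= max_evalue.

    All qualifying pairs are kept (not reciprocal *best* hits), so a single
    transcript may contribute to several potential-paralog pairs.  Self-hits
    never qualify.
    """
    directed: set[tuple[str, str]] = set()
    for h in hits:
        if h.evalue <= max_evalue and h.query_id != h.subject_id:
            directed.add((h.query_id, h.subject_id))
    return {
        ParalogPairId(q, s) for (q, s) in directed if (s, q) in directed and q < s
    }


def pair_best_hits(hits: Iterable[Hit]) -> dict[ParalogPairId, dict]:
    """Merge directed hits to one record per unordered pair.

    Keeps the lowest e-value hit's metadata and whether any plus-strand hit
    exists (pairs with only minus-strand hits are antisense artifacts)."""
    table: dict[ParalogPairId, dict] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        pid = ParalogPairId(h.query_id, h.subject_id)
        rec = table.setdefault(
            pid, {"best_evalue": np.inf, "has_plus": False, "best_hit": None}
        )
        if h.strand == "+":
            rec["has_plus"] = True
        if h.evalue < rec["best_evalue"]:
            rec["best_evalue"] = h.evalue
            rec["best_hit"] = h
    return table
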