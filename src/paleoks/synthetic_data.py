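"""Synthetic Ks samples and transcriptomes with planted duplication depths.

Two generators make the whole pipeline testable without real read data:

* :func:`sample_ks` draws directly from a specified mixture of Gaussian
  Ks peaks plus a uniform background — the statistical shape of a paralog
  age distribution: an excess of very recent duplicates near Ks = 0,
  a few concentrated ancient peaks, and diffuse noise.

* :func:`simulate_duplicated_transcriptome` emits a FASTA of coding
  sequences containing paralog pairs separated by a *known* synonymous
  divergence.  Each gene family is an ancestral random CDS plus one copy
  mutated until its expected pairwise synonymous difference proportion
  matches the target depth under Jukes–Cantor inversion
  ``p_s = (3/4)(1 - exp(-4d/3))``; nonsynonymous changes are added at a
  relative rate ``omega`` (dN/dS).  Synonymous changes are planted only at
  positions where a single-base change is synonymous, so codon-aware
  counting recovers them exactly; a truth table records the planted and
  realized values for parameter-recovery tests.

The default mixture profile mirrors a transcriptome-wide duplication
history with recent peaks below Ks 0.1 and ancient peaks near 0.27, 0.51
and 0.91.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp
from typing import Sequence

import numpy as np

from .core_io import CODON_TABLE, SENSE_CODONS, STOP_CODONS, TranscriptRecord
from .ks_estimation import CodonAlignment, jc_correct, ng_site_counts, syn_site_fraction

__all__ = [
    "KsMixtureSpec",
    "DuplicationTruth",
    "DEFAULT_PEAK_MEANS",
    "DEFAULT_PEAK_SDS",
    "DEFAULT_PEAK_WEIGHTS",
    "sample_ks",
    "simulate_duplicated_transcriptome",
    "write_truth_tsv",
]

# A seven-peak paralog-age profile: strong recent-duplicate excess below
# Ks 0.1 and three ancient duplication peaks.
DEFAULT_PEAK_MEANS = (0.01, 0.022, 0.05, 0.12, 0.27, 0.51, 0.91)
DEFAULT_PEAK_SDS = (0.005, 0.008, 0.015, 0.03, 0.05, 0.07, 0.10)
DEFAULT_PEAK_WEIGHTS = (0.18, 0.12, 0.12, 0.10, 0.20, 0.16, 0.12)


@dataclass(frozen=True)
class KsMixtureSpec:
    """Mixture of Gaussian Ks peaks plus a uniform background component."""

    means: tuple[float, ...] = DEFAULT_PEAK_MEANS
    sds: tuple[float, ...] = DEFAULT_PEAK_SDS
    weights: tuple[float, ...] = DEFAULT_PEAK_WEIGHTS
    background_fraction: float = 0.05
    ks_max: float = 1.5
    n: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.means) == len(self.sds) == len(self.weights)):
            raise ValueError("means, sds and weights must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")
        if any(s <= 0 for s in self.sds):
            raise ValueError("all sds must be positive")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")


@dataclass(frozen=True)
class DuplicationTruth:
    """Ground truth for one planted paralog pair."""

    family: str
    id_a: str
    id_b: str
    planted_ks: float
    realized_ps: float
    realized_ks: float
    seq_length: int


def sample_ks(spec: KsMixtureSpec) -> np.ndarray:
    """Draw ``spec.n`` Ks values; peak draws are truncated to >= 0 by
    resampling.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    out = np.empty(spec.n, dtype=float)
    comp = rng.choice(len(spec.means), size=spec.n, p=np.asarray(spec.weights))
    is_bg = rng.random(spec.n) < spec.background_fraction
    for i in range(spec.n):
        if is_bg[i]:
            out[i] = rng.uniform(0.0, spec.ks_max)
            continue
        mu, sd = spec.means[comp[i]], spec.sds[comp[i]]
        val = rng.normal(mu, sd)
        while val < 0:
            val = rng.normal(mu, sd)
        out[i] = val
    return out


def _target_ps(depth: float) -> float:
    """Invert Jukes–Cantor: the difference proportion at divergence d."""
    if not np.isfinite(depth) or depth < 0:
        raise ValueError(f"depth must be a finite value >= 0, got {depth}")
    return 0.75 * (1.0 - exp(-4.0 * depth / 3.0))


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    """ATG followed by random sense codons (no internal stops)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    return ["ATG"] + [SENSE_CODONS[i] for i in idx]


def _synonymous_options(codon: str) -> list[str]:
    aa = CODON_TABLE[codon]
    opts = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                opts.append(alt)
    return opts


def _nonsynonymous_options(codon: str) -> list[str]:
    aa = CODON_TABLE[codon]
    opts = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TABLE[alt] != aa:
                opts.append(alt)
    return opts


def _mutate_copy(
    rng: np.random.Generator, codons: list[str], depth: float, omega: float
) -> list[str]:
    """Apply planted synonymous + nonsynonymous changes for a target depth."""
    if depth == 0:
        return list(codons)
    S = sum(syn_site_fraction(c) for c in codons)
    N = 3 * len(codons) - S
    ps = _target_ps(depth)
    if ps >= 0.75:
        raise ValueError("unattainable under Jukes-Cantor: p_s >= 3/4")
    pn = _target_ps(omega * depth)
    n_syn = round(ps * S)
    n_non = round(pn * N)
    if round(n_syn) >= 0.75 * S:
        raise ValueError("unattainable under Jukes-Cantor: p_s >= 3/4")
    syn_eligible = [i for i, c in enumerate(codons) if _synonymous_options(c)]
    if n_syn > len(syn_eligible):
        raise ValueError(
            f"gene too short to plant {n_syn} synonymous changes "
            f"({len(syn_eligible)} eligible codons)"
        )
    out = list(codons)
    syn_idx = rng.choice(len(syn_eligible), size=n_syn, replace=False)
    chosen_syn = {syn_eligible[i] for i in syn_idx.tolist()}
    for i in sorted(chosen_syn):
        opts = _synonymous_options(out[i])
        out[i] = opts[int(rng.integers(0, len(opts)))]
    non_eligible = [
        i for i in range(len(codons)) if i not in chosen_syn and _nonsynonymous_options(out[i])
    ]
    if n_non > len(non_eligible):
        raise ValueError(
            f"gene too short to plant {n_non} nonsynonymous changes "
            f"({len(non_eligible)} eligible codons)"
        )
    non_idx = rng.choice(len(non_eligible), size=n_non, replace=False)
    for i in sorted(non_eligible[j] for j in non_idx.tolist()):
        opts = _nonsynonymous_options(out[i])
        out[i] = opts[int(rng.integers(0, len(opts)))]
    return out


def simulate_duplicated_transcriptome(
    n_families: int,
    depths: Sequence[float],
    codons_per_gene: int = 500,
    omega: float = 0.2,
    seed: int = 0,
) -> tuple[list[TranscriptRecord], list[DuplicationTruth]]:
    """Simulate ``n_families`` two-copy gene families *per depth*.

    Divergence is applied pairwise (one copy mutated, one kept ancestral),
    so the planted depth is directly the pairwise Ks the estimator targets.
    Returns the shuffled-free, deterministic record list and a truth table
    with realized difference proportions computed by codon-aware counting.
    """
    if codons_per_gene < 50:
        raise ValueError(f"codons_per_gene must be >= 50, got {codons_per_gene}")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []
    truth: list[DuplicationTruth] = []
    for di, depth in enumerate(depths):
        for fi in range(n_families):
            fam = f"fam_d{di}_{fi:04d}"
            anc = _random_cds(rng, codons_per_gene)
            mut = _mutate_copy(rng, anc, float(depth), omega)
            seq_a = "".join(anc)
            seq_b = "".join(mut)
            id_a, id_b = f"{fam}_a", f"{fam}_b"
            records.append(TranscriptRecord(id_a, seq_a))
            records.append(TranscriptRecord(id_b, seq_b))
            n_cols = len(anc)
            S, _, Sd, _ = ng_site_counts(CodonAlignment(seq_a, seq_b, n_cols))
            ps = Sd / S
            realized_ks = jc_correct(ps) if ps < 0.75 else float("inf")
            truth.append(
                DuplicationTruth(
                    fam, id_a, id_b, float(depth), ps, realized_ks, 3 * codons_per_gene
                )
            )
    return records, truth


def write_truth_tsv(truth: Sequence[DuplicationTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tid_a\tid_b\tplanted_ks\trealized_ps\trealized_ks\tseq_length\n")
        for t in truth:
            fh.write(
                f"{t.family}\t{t.id_a}\t{t.id_b}\t{t.planted_ks:.6g}\t"
                f"{t.realized_ps:.6g}\t{t.realized_ks:.6g}\t{t.seq_length}\n"
            )
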