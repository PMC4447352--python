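"""Assembly-quality metrics for choosing among k-mer sweep assemblies.

De novo transcriptome assemblers are typically run across a range of k-mer
lengths and the best assembly picked afterwards from summary statistics:
N50, the total scaffold count, and the number of (and bases in) scaffolds
longer than a length threshold (800 bp here).  This module scores
already-produced FASTA assemblies and applies a lexicographic selection
rule: greatest N50 first, then fewest scaffolds, then input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .core_io import TranscriptRecord

__all__ = ["AssemblyStats", "n50", "scaffold_stats", "select_best_assembly", "write_stats_tsv"]


@dataclass(frozen=True)
class AssemblyStats:
    label: str
    n_scaffolds: int
    n50: int
    n_over_threshold: int
    bp_over_threshold: int
    threshold: int = 800


def n50(lengths: Sequence[int]) -> int:
    """N50: the largest length L such that scaffolds of length >= L hold at
    least half the total assembly bases (cumulative-sum convention)."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def scaffold_stats(
    records: Iterable[TranscriptRecord], label: str, threshold: int = 800
) -> AssemblyStats:
    """Summarize one assembly.  The length threshold is strict (> threshold)."""
    lengths = [len(r) for r in records]
    if not lengths:
        raise ValueError("cannot compute stats for an empty assembly")
    over = [x for x in lengths if x > threshold]
    return AssemblyStats(
        label=label,
        n_scaffolds=len(lengths),
        n50=n50(lengths),
        n_over_threshold=len(over),
        bp_over_threshold=sum(over),
        threshold=threshold,
    )


def select_best_assembly(candidates: Sequence[AssemblyStats]) -> AssemblyStats:
    """Pick the candidate with greatest N50; ties broken by fewest scaffolds,
    then by original order."""
    if not candidates:
        raise ValueError("no candidate assemblies")
    best = min(
        range(len(candidates)),
        key=lambda i: (-candidates[i].n50, candidates[i].n_scaffolds, i),
    )
    return candidates[best]


def write_stats_tsv(stats: Sequence[AssemblyStats], path: str | Path) -> None:
    """One TSV row per assembly: label, n_scaffolds, n50, n_over, bp_over."""
    with open(path, "w") as fh:
        fh.write("label\tn_scaffolds\tn50\tn_over_threshold\tbp_over_threshold\n")
        for s in stats:
            fh.write(
                f"{s.label}\t{s.n_scaffolds}\t{s.n50}\t"
                f"{s.n_over_threshold}\t{s.bp_over_threshold}\n"
            )
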