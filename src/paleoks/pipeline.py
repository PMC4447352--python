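"""End-to-end orchestration: FASTA -> hits -> pairs -> Ks -> peaks -> ages.

`run_duplication_scan` chains the whole ancient-duplication analysis:
all-vs-all self-search, reciprocal paralog pairing, per-pair Ks estimation
(with rejection bookkeeping), mixture fitting with BIC selection, SiZer
significance mapping, and molecular-clock dating of the ancient peaks.
Every run writes machine-readable TSV/JSON artifacts plus a summary JSON
with a provenance block, and is byte-reproducible for a fixed config.

`run_ortholog_scan` runs the cross-sample analysis: three-way reciprocal
best hits, per-triple multiple alignment, majority consensus, and variant
reports.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .core_io import TranscriptRecord, read_fasta, write_fasta
from .dating import RateConstant, date_report
from .homology import all_vs_all_hits, pair_best_hits, reciprocal_paralog_pairs, write_tabular_hits
from .ks_estimation import KsResult, OrfError, estimate_ks
from .mixture_peaks import classify_peaks, select_mixture
from .orthologs import align_sequences, three_way_rbh, variant_report
from .sizer import significant_peaks, sizer_map, write_sizer_tsv

logger = logging.getLogger("paleoks")

__all__ = ["RunConfig", "run_duplication_scan", "run_ortholog_scan"]


@dataclass
class RunConfig:
    """All tunables of a duplication scan, with the conventional defaults."""

    inputs: tuple[str, ...] = ()
    output_dir: str = "paleoks_out"
    max_evalue: float = 1e-20
    min_sites: float = 10.0
    k_max: int = 10
    recent_cutoff: float = 0.1
    rate: float = 1.5e-8
    alpha: float = 0.05
    seed: int = 0
    word_size: int = 11
    per_lineage: bool = False
    figures: bool = False

    def __post_init__(self) -> None:
        for name in ("max_evalue", "min_sites", "recent_cutoff", "rate", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _load_records(paths: Sequence[str]) -> list[TranscriptRecord]:
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for p in paths:
        for rec in read_fasta(p):
            if rec.id in seen:
                raise ValueError(f"duplicate id {rec.id} across input files")
            seen.add(rec.id)
            records.append(rec)
    return records


def _write_ks_tsv(results: Sequence[KsResult], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tS\tN_sites\tSd\tNd\tps\tks\tstatus\n")
        for r in results:
            ks = f"{r.ks:.6g}" if r.ks is not None else "NA"
            fh.write(
                f"{r.pair.id_a}\t{r.pair.id_b}\t{r.S:.4f}\t{r.N_sites:.4f}\t"
                f"{r.Sd:.4f}\t{r.Nd:.4f}\t{r.ps:.6g}\t{ks}\t{r.reject_reason}\n"
            )


def run_duplication_scan(
    config: RunConfig, records: Optional[Sequence[TranscriptRecord]] = None
) -> dict:
    """Execute the full duplication scan and write all artifacts.

    ``records`` may be passed directly (e.g. from the simulator) instead of
    reading ``config.inputs``.  Returns the summary dict; with zero viable
    pairs the downstream sections are empty rather than raising.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if records is None:
        records = _load_records(config.inputs)
    if len(records) < 2:
        raise ValueError("insufficient records: need >= 2 transcripts")
    logger.info("loaded %d transcripts", len(records))

    hits = all_vs_all_hits(records, max_evalue=config.max_evalue, word_size=config.word_size)
    write_tabular_hits(hits, outdir / "hits.tsv")
    pairs = reciprocal_paralog_pairs(hits, max_evalue=config.max_evalue)
    pair_info = pair_best_hits(hits)
    logger.info("%d hits -> %d reciprocal pairs", len(hits), len(pairs))

    with open(outdir / "pairs.tsv", "w") as fh:
        fh.write("id_a\tid_b\tbest_evalue\n")
        for pid in sorted(pairs):
            fh.write(f"{pid.id_a}\t{pid.id_b}\t{pair_info[pid]['best_evalue']:.3g}\n")

    by_id = {r.id: r for r in records}
    results: list[KsResult] = []
    rejections = {"antisense": 0, "saturated": 0, "too_few_sites": 0, "no_orf": 0}
    for pid in sorted(pairs):
        info = pair_info[pid]
        if not info["has_plus"]:
            results.append(
                KsResult(0.0, 0.0, 0.0, 0.0, 0.0, None, "antisense", pid)
            )
            rejections["antisense"] += 1
            continue
        try:
            res = estimate_ks(
                by_id[pid.id_a].seq, by_id[pid.id_b].seq, config.min_sites, pid
            )
        except OrfError:
            rejections["no_orf"] += 1
            continue
        results.append(res)
        if not res.accepted:
            rejections[res.reject_reason] += 1
    _write_ks_tsv(results, outdir / "ks.tsv")

    ks_values = [r.ks for r in results if r.accepted]
    logger.info("%d viable Ks values (%s rejections)", len(ks_values), rejections)

    summary: dict = {
        "provenance": {
            "package": "paleoks",
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
        },
        "n_records": len(records),
        "n_hits": len(hits),
        "n_pairs": len(pairs),
        "n_pairs_viable": len(ks_values),
        "rejections": rejections,
        "ks_stats": {},
        "mixture": {},
        "recent_peaks": [],
        "ancient_peaks": [],
        "sizer_intervals": [],
        "ages": [],
    }

    if ks_values:
        summary["ks_stats"] = {
            "min": min(ks_values),
            "median": statistics.median(ks_values),
            "max": max(ks_values),
        }

    model = None
    if len(ks_values) >= 5:
        k_max = min(config.k_max, len(ks_values) // 5)
        model = select_mixture(ks_values, k_max=k_max, seed=config.seed)
        recent, ancient = classify_peaks(model, config.recent_cutoff)
        summary["mixture"] = {
            "k": model.k,
            "weights": list(model.weights),
            "means": list(model.means),
            "sds": list(model.sds),
            "loglik": model.loglik,
            "bic": model.bic,
        }
        summary["recent_peaks"] = recent
        summary["ancient_peaks"] = ancient
        with open(outdir / "bic.tsv", "w") as fh:
            fh.write("k\tbic\n")
            for k, bic in sorted(model.bic_table.items()):
                fh.write(f"{k}\t{bic:.6f}\n")
        with open(outdir / "mixture.json", "w") as fh:
            json.dump(summary["mixture"] | {"bic_table": model.bic_table,
                                            "recent_peaks": recent,
                                            "ancient_peaks": ancient},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")

        report = date_report(
            ancient, RateConstant(config.rate), per_lineage=config.per_lineage
        )
        report.to_csv(outdir / "dated_peaks.tsv", sep="\t", index=False)
        summary["ages"] = [
            {"ks": row.ks, "age_myr": row.age_myr, "age_myr_display": row.age_myr_display}
            for row in report.itertuples()
        ]

    if len(ks_values) >= 50:
        smap = sizer_map(ks_values, alpha=config.alpha)
        write_sizer_tsv(smap, outdir / "sizer.tsv")
        intervals = significant_peaks(smap)
        summary["sizer_intervals"] = [
            {"x_start": p.x_start, "x_end": p.x_end, "bandwidth": p.bandwidth}
            for p in intervals
        ]
        if config.figures:
            from .plotting import plot_ks_histogram, plot_sizer_map

            plot_ks_histogram(ks_values, model, outdir / "ks_histogram.png")
            plot_sizer_map(smap, outdir / "sizer_map.png")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def run_ortholog_scan(
    path_a: str,
    path_b: str,
    path_c: str,
    output_dir: str,
    max_evalue: float = 1e-20,
) -> dict:
    """Three-way RBH ortholog scan with per-triple variant reports.

    For each triple the three transcripts are multiple-aligned, a
    majority-vote consensus built, and SNPs/deletions reported vs that
    consensus (reading frame anchored on the first sample's transcript).
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sets = [read_fasta(p) for p in (path_a, path_b, path_c)]
    triples = three_way_rbh(*sets, max_evalue=max_evalue)
    if not triples:
        logger.warning("no ortholog triples found")
    by_id = {r.id: r for recs in sets for r in recs}

    summary: dict = {"n_triples": len(triples), "triples": []}
    for t in triples:
        recs = [by_id[i] for i in t.ids]
        aligned = align_sequences(recs)
        anchor = t.ids[0]
        rep = variant_report(aligned, anchor, shared_pair=(t.ids[1], t.ids[2]))
        stem = outdir / "_".join(t.ids)
        with open(f"{stem}.aln.fasta", "w") as fh:
            for sid, seq in aligned.items():
                fh.write(f">{sid}\n{seq}\n")
            fh.write(f">consensus\n{rep.consensus}\n")
        with open(f"{stem}.variants.tsv", "w") as fh:
            fh.write("seq_id\tcolumn\tconsensus_base\tobserved_base\tcodon_index\tclass\n")
            for s in rep.snps:
                ci = s.codon_index if s.codon_index is not None else "NA"
                fh.write(
                    f"{s.seq_id}\t{s.column}\t{s.consensus_base}\t{s.observed_base}\t"
                    f"{ci}\t{s.klass}\n"
                )
        with open(f"{stem}.deletions.tsv", "w") as fh:
            fh.write("seq_id\tcolumn_start\tlength_nt\tlength_codons\tin_frame\n")
            for d in rep.deletions:
                lc = d.length_codons if d.length_codons is not None else "NA"
                fh.write(f"{d.seq_id}\t{d.column_start}\t{d.length_nt}\t{lc}\t{d.in_frame}\n")
        summary["triples"].append(
            {
                "ids": list(t.ids),
                "snp_counts": rep.snp_counts,
                "shared_nonsynonymous": rep.shared_nonsynonymous,
                "unique_nonsynonymous": rep.unique_nonsynonymous,
                "n_deletions": len(rep.deletions),
            }
        )
    with open(outdir / "ortholog_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
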