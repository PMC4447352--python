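"""Transcript data model and FASTA plumbing.

The pipeline's atomic input is a :class:`TranscriptRecord` — one assembled
transcript (or CDS) with an identifier and an uppercase nucleotide sequence
over ``{A, C, G, T, N}``.  FASTA parsing is delegated to Biopython; this
module layers the validation contracts the rest of the pipeline relies on
(unique ids, IUPAC-clean sequences) on top.

All coordinates elsewhere in the package are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "TranscriptRecord",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "translate",
    "reverse_complement",
    "CODON_TABLE",
    "STOP_CODONS",
    "SENSE_CODONS",
]

_VALID_CHARS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code, as data from Biopython.  Codons containing N map to
# 'X'; stops render '*'.
_standard = CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TABLE: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TABLE[_stop] = "*"
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TABLE if CODON_TABLE[c] != "*")
)


class FastaError(ValueError):
    """Raised for malformed FASTA input (duplicate ids, bad characters, empty)."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A single transcript: id (first header token) plus nucleotide sequence.

    The remainder of the FASTA header line, if any, is retained as
    ``description`` but never interpreted.
    """

    id: str
    seq: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise FastaError(f"invalid record id {self.id!r}")
        if len(self.seq) < 1:
            raise FastaError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - _VALID_CHARS
        if bad:
            pos = next(i for i, ch in enumerate(self.seq) if ch in bad)
            raise FastaError(
                f"record {self.id!r}: non-IUPAC nucleotide {self.seq[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a (possibly line-wrapped) FASTA file into TranscriptRecords.

    Sequences are uppercased; ids must be unique.  Raises :class:`FastaError`
    on an empty file, duplicate ids, or non-``ACGTN`` characters.
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip()
        records.append(TranscriptRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Iterable[TranscriptRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as wrapped FASTA (60 columns by default).

    Round-trips with :func:`read_fasta` for any valid record list.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0) -> str:
    """Translate ``seq`` in the given frame (0/1/2) with the standard code.

    The trailing partial codon is dropped; stop codons render ``*`` and any
    codon containing ``N`` renders ``X``.  Total on valid input.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    sub = seq[frame:]
    aas = []
    for i in range(0, len(sub) - len(sub) % 3, 3):
        codon = sub[i : i + 3]
        aas.append(CODON_TABLE.get(codon, "X"))
    return "".join(aas)
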