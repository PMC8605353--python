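"""Reading/writing the standard formats the pipeline touches.

Internal alphabet is RNA {A,C,G,U}; DNA T is converted to U on input.
Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional

RNA_ALPHABET = "ACGU"
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U.

    Raises ValueError on characters outside {A,C,G,U,T,N}.
    """
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement over the RNA alphabet (A<->U, C<->G; N fixed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Convert the internal RNA representation back to DNA (U -> T)."""
    return seq.replace("U", "T")


@dataclass
class PeakInterval:
    """One cross-linking peak region and (optionally) its extracted sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.sequence is not None and len(self.sequence) != len(self):
            raise ValueError("sequence length does not match interval length")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty record id")

    def __len__(self) -> int:
        return len(self.sequence)


def read_peaks(path: str) -> list[PeakInterval]:
    """Parse a BED3/BED6 file into peak intervals.

    Lines must have >=3 tab-separated columns (chrom, start, end); column 6,
    when present, is the strand. Malformed lines raise with their line number.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "+"
            name = cols[3] if len(cols) >= 4 else "."
            try:
                peaks.append(PeakInterval(cols[0], start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def extract_sequence(genome, iv: PeakInterval) -> str:
    """Extract the strand-aware RNA sequence of an interval.

    ``genome`` is any mapping from chromosome name to a sliceable sequence
    (a dict of strings, a ``pyfaidx.Fasta``, ...). Returns the sense strand
    for '+', the reverse complement for '-'; T is normalized to U.
    """
    try:
        chrom_seq = genome[iv.chrom]
    except KeyError as exc:
        raise KeyError(f"unknown chromosome {iv.chrom!r}") from exc
    chrom_len = len(chrom_seq)
    if iv.start < 0 or iv.end > chrom_len:
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome "
            f"bounds (length {chrom_len})"
        )
    seq = normalize_rna(str(chrom_seq[iv.start : iv.end]))
    return reverse_complement(seq) if iv.strand == "-" else seq


def read_fasta(path: str) -> list[SequenceRecord]:
    """Read a FASTA file into normalized RNA records."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    rid, chunks = None, []

    def flush():
        if rid is None:
            return
        seq = normalize_rna("".join(chunks))
        if not seq:
            raise ValueError(f"record {rid!r} has empty sequence")
        records.append(SequenceRecord(rid, seq))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                rid, chunks = line[1:].split()[0], []
            else:
                if rid is None:
                    raise ValueError(f"{path}: sequence before first header")
                chunks.append(line)
        flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str, width: int = 70,
                dna_output: bool = False) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            seq = to_dna(rec.sequence) if dna_output else rec.sequence
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_id_list(path: str) -> list[str]:
    """Plain-text list of sequence/transcript IDs, one per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
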