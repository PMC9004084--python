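"""Genome and peak I/O, coordinate conventions, window extraction, one-hot encoding.

All intervals are 0-based half-open (BED convention). DNA is stored uppercase
over the alphabet {A, C, G, T, N}; any other character is mapped to N on read.
One-hot matrices are 4 x L with row order A, C, G, T and N encoded as an
all-zero column, so that column sums are 1 for called bases and 0 for Ns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class NarrowPeakRecord:
    """One row of an ENCODE narrowPeak (or BED6) file.

    ``signal`` is narrowPeak column 7 (SPP signal); ``summit_offset`` is
    column 10, -1 when absent. The absolute summit is ``start + summit_offset``.
    """

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal: float = 0.0
    p_neglog10: float = -1.0
    q_neglog10: float = -1.0
    summit_offset: int = -1

    @property
    def summit(self) -> int:
        if self.summit_offset < 0:
            # midpoint fallback for summit-less records
            return (self.interval.start + self.interval.end) // 2
        return self.interval.start + self.summit_offset


@dataclass
class GenomeSequence:
    """In-memory genome: ordered chromosome names and uppercase sequences."""

    chrom_names: list[str] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, seq: str) -> None:
        if name in self.sequences:
            raise ValueError(f"duplicate chromosome name {name!r}")
        self.chrom_names.append(name)
        self.sequences[name] = seq

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return genome[chrom][start:end); errors on out-of-bounds queries."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self.sequences[chrom]) or start >= end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome of length "
                f"{len(self.sequences[chrom])}"
            )
        return self.sequences[chrom][start:end]


def _sanitize(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        logger.warning(
            "sequence %s: %d characters outside {A,C,G,T,N} mapped to N",
            name,
            sum(seq.count(c) for c in bad),
        )
        seq = seq.translate(str.maketrans({c: "N" for c in bad}))
    return seq


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-record) FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; characters outside {A,C,G,T,N} become N with a
    logged warning. Raises on missing/empty files and duplicate record names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome = GenomeSequence()
    for rec in SeqIO.parse(str(path), "fasta"):
        genome.add(rec.id, _sanitize(str(rec.seq), rec.id))
    if not genome.chrom_names:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[c]), id=c, description="")
        for c in genome.chrom_names
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_narrowpeak(path: str | Path) -> list[NarrowPeakRecord]:
    """Read a 10-column narrowPeak or 6-column BED file.

    6-column input yields signal=0, p=q=-1 and summit_offset=-1. Records are
    returned in file order. Raises on malformed coordinates.
    """
    records: list[NarrowPeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            interval = GenomicInterval(cols[0], start, end)
            name = cols[3] if len(cols) > 3 else "."
            score = int(float(cols[4])) if len(cols) > 4 and cols[4] != "." else 0
            strand = cols[5] if len(cols) > 5 else "."
            interval.strand = strand if strand in "+-." else "."
            if len(cols) >= 10:
                rec = NarrowPeakRecord(
                    interval,
                    name=name,
                    score=score,
                    signal=float(cols[6]),
                    p_neglog10=float(cols[7]),
                    q_neglog10=float(cols[8]),
                    summit_offset=int(cols[9]),
                )
                if rec.summit_offset >= end - start:
                    raise ValueError(
                        f"{path}:{lineno}: summit offset {rec.summit_offset} "
                        f"outside peak of length {end - start}"
                    )
            else:
                rec = NarrowPeakRecord(interval, name=name, score=score)
            records.append(rec)
    return records


def write_bed(
    intervals: list[GenomicInterval], path: str | Path, names: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def extract_window(genome: GenomeSequence, chrom: str, summit: int, flank: int) -> str:
    """Sequence of the summit-centered window ``[summit - flank, summit + flank)``.

    The window has length exactly ``2 * flank``; a window extending past the
    chromosome edge raises, so callers can drop (and count) such peaks.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    return genome.fetch(chrom, summit - flank, summit + flank)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode DNA into a 4 x L float array (rows A,C,G,T; N = zeros)."""
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.zeros((4, len(seq)), dtype=np.float32)
    for i, base in enumerate(BASES):
        out[i, codes == ord(base)] = 1.0
    known = out.sum(axis=0) + (codes == ord("N"))
    if np.any(known == 0):
        bad = chr(codes[np.argmax(known == 0)])
        raise ValueError(f"invalid character {bad!r} in sequence")
    return out


def decode_one_hot(mat: np.ndarray) -> str:
    """Consensus string of a one-hot (or PFM) matrix: argmax base, N for zero columns."""
    out = []
    for col in mat.T:
        out.append("N" if col.sum() == 0 else BASES[int(np.argmax(col))])
    return "".join(out)


def revcomp_onehot(mat: np.ndarray) -> np.ndarray:
    """Reverse-complement a one-hot/score matrix: reverse columns, swap A<->T, C<->G.

    An involution; zero (N) columns stay zero. Works on any 4 x L real matrix,
    so it is also used to flip attribution and hypothetical-score tracks.
    """
    return mat[::-1, ::-1].copy()
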