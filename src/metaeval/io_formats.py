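"""Readers and writers for the sequence and alignment formats used throughout.

All coordinates are normalized on ingest to a single internal convention:
**1-based, inclusive** intervals (the BLAST tabular convention). PSL input,
which is 0-based half-open, is converted here and nowhere else.

Formats handled:

* FASTA / FASTQ (Phred+33, strict 4-line records)
* BLAST tabular ``-outfmt 6`` (12 columns)
* PSL (BLAT native output, with or without its 5-line header)
* read→contig mappings as a SAM subset (QNAME/FLAG/RNAME) or 2-column TSV
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SeqRecord",
    "TabularHit",
    "ParseError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "parse_blast_tabular",
    "parse_psl",
    "parse_read_mapping",
    "reverse_complement",
]

PHRED_OFFSET = 33  # Phred+33 fixed; no autodetection

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass
class SeqRecord:
    """A named sequence with optional per-base Phred qualities."""

    id: str
    seq: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id {self.id!r}")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"record {self.id}: {len(self.quals)} quality values for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TabularHit:
    """One pairwise alignment in internal (1-based inclusive) coordinates.

    ``matches`` is the count of identically aligned bases: taken directly
    from PSL column 1, or derived as round(pident × length / 100) for BLAST
    tabular input. ``frame`` is +1 except for BLASTX minus-frame hits
    (qstart > qend in the file), which are normalized to q_start < q_end
    with frame = −1.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    bit_score: float
    matches: int
    frame: int = 1

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}/{self.subject_id}: q_start > q_end "
                "after normalization"
            )
        if self.matches > self.aln_len:
            raise ValueError(
                f"hit {self.query_id}/{self.subject_id}: matches exceed "
                "alignment length"
            )

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a strict 4-line Phred+33 FASTQ file.

    Raises :class:`ParseError` naming the line number on a malformed
    record (bad header/separator, or seq/qual length mismatch).
    """
    with open(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"line {lineno}: expected '@' header, got {header!r}")
            seq = handle.readline().rstrip("\n")
            sep = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            if not sep.startswith("+"):
                raise ParseError(f"line {lineno + 2}: expected '+' separator")
            if len(qual) != len(seq):
                raise ParseError(
                    f"line {lineno + 3}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            lineno += 3
            yield SeqRecord(
                id=header[1:].split()[0],
                seq=seq,
                quals=[ord(c) - PHRED_OFFSET for c in qual],
            )


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            if rec.quals is None:
                raise ValueError(f"record {rec.id} has no qualities")
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quals)
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Iterator[SeqRecord]:
    """Stream FASTA records; the id is the header token before the first space."""
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise ParseError("line 1: sequence data before any '>' header")
        handle.seek(0)
        for title, seq in SimpleFastaParser(handle):
            yield SeqRecord(id=title.split()[0], seq=seq.upper())


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            if wrap:
                for i in range(0, len(rec.seq), wrap):
                    handle.write(rec.seq[i : i + wrap] + "\n")
            else:
                handle.write(rec.seq + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

def parse_blast_tabular(path: str | Path) -> Iterator[TabularHit]:
    """Parse 12-column BLAST ``-outfmt 6`` lines into :class:`TabularHit`.

    Minus-frame BLASTX hits (qstart > qend) are normalized so that
    q_start < q_end, retaining frame = −1.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                aln_len = int(fields[3])
                q_start, q_end = int(fields[6]), int(fields[7])
                s_start, s_end = int(fields[8]), int(fields[9])
                bit_score = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            frame = 1
            if q_start > q_end:
                q_start, q_end = q_end, q_start
                frame = -1
            yield TabularHit(
                query_id=fields[0],
                subject_id=fields[1],
                pct_identity=pident,
                aln_len=aln_len,
                q_start=q_start,
                q_end=q_end,
                s_start=s_start,
                s_end=s_end,
                bit_score=bit_score,
                matches=round(pident * aln_len / 100),
                frame=frame,
            )


# ---------------------------------------------------------------------------
# PSL (BLAT)
# ---------------------------------------------------------------------------

def parse_psl(path: str | Path) -> Iterator[TabularHit]:
    """Parse BLAT PSL rows (header optional) into internal coordinates.

    PSL query coordinates are 0-based half-open; they are converted to
    1-based inclusive here. ``matches`` comes from PSL column 1 and
    pct_identity = 100·matches/(matches+misMatches). BLAT reports no bit
    score, so ``bit_score`` carries the match count (the natural BLAT
    score used downstream).
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            # skip the 5-line psLayout header and any non-data line
            if not fields[0] or not fields[0].lstrip("-").isdigit():
                continue
            if len(fields) < 17:
                raise ParseError(
                    f"line {lineno}: PSL row has {len(fields)} columns, needs >= 17"
                )
            try:
                matches = int(fields[0])
                mismatches = int(fields[1])
                strand = fields[8]
                q_name = fields[9]
                q_start = int(fields[11]) + 1
                q_end = int(fields[12])
                t_name = fields[13]
                t_start = int(fields[15]) + 1
                t_end = int(fields[16])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            aligned = matches + mismatches
            pct = 100.0 * matches / aligned if aligned else 0.0
            yield TabularHit(
                query_id=q_name,
                subject_id=t_name,
                pct_identity=pct,
                aln_len=q_end - q_start + 1,
                q_start=q_start,
                q_end=q_end,
                s_start=t_start,
                s_end=t_end,
                bit_score=float(matches),
                matches=matches,
                frame=-1 if strand.startswith("-") else 1,
            )


# ---------------------------------------------------------------------------
# Read→contig mapping (SAM subset or TSV)
# ---------------------------------------------------------------------------

_SAM_FLAG_UNMAPPED = 0x4
_SAM_FLAG_SECONDARY = 0x100
_SAM_FLAG_SUPPLEMENTARY = 0x800


def parse_read_mapping(path: str | Path) -> dict[str, str]:
    """Load a read→contig map from SAM (primary alignments) or 2-column TSV.

    Unmapped reads are absent from the map; secondary and supplementary
    SAM records are ignored. A duplicate primary record for a read is an
    error.
    """
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) >= 11:  # SAM record: QNAME FLAG RNAME ...
                qname = fields[0]
                try:
                    flag = int(fields[1])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: bad SAM flag") from exc
                if flag & (_SAM_FLAG_UNMAPPED | _SAM_FLAG_SECONDARY | _SAM_FLAG_SUPPLEMENTARY):
                    continue
                rname = fields[2]
                if rname == "*":
                    continue
            elif len(fields) == 2:
                qname, rname = fields
            else:
                raise ParseError(
                    f"line {lineno}: expected SAM record or 2-column TSV, "
                    f"got {len(fields)} columns"
                )
            if qname in mapping:
                raise ParseError(
                    f"line {lineno}: duplicate primary record for read {qname!r}"
                )
            mapping[qname] = rname
    return mapping
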