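"""Gold-standard consensus assembly from simulated reads.

Reads are placed on their true source transcripts (by ground truth, so
placement is exact and dependency-free), a base-count pileup is built per
transcript, and contigs are emitted as maximal runs of covered positions
with a majority-vote consensus. The result bounds the assembly error
attributable to sequencing alone: any real assembler's contigs can be
compared against these.

An optional PSL-ingest path accepts externally computed read placements
in lieu of the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import SeqRecord, TabularHit, reverse_complement
from .simulator import TruthRecord

__all__ = ["Pileup", "pile_reads", "pile_from_psl", "consensus_contigs", "build_gold_standard"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class Pileup:
    """Per-position base counts over one transcript.

    ``counts`` is a (5, L) array over A/C/G/T/N; depth at a position is
    the column sum.
    """

    transcript_id: str
    counts: np.ndarray  # shape (5, L), integer

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, 4) for c in seq], dtype=np.int8)


def pile_reads(
    truth: Sequence[TruthRecord],
    reads: Mapping[str, SeqRecord] | Sequence[SeqRecord],
    transcripts: Mapping[str, str],
) -> dict[str, Pileup]:
    """Place each read on its source transcript and accumulate base counts.

    Each read contributes exactly ``len(read)`` observations on
    ``[start, start+len−1]``; minus-strand reads contribute their reverse
    complement on the forward frame. Unknown transcript or missing read
    id is an error.
    """
    if not isinstance(reads, Mapping):
        reads = {r.id: r for r in reads}
    pileups: dict[str, Pileup] = {}
    for rec in truth:
        if rec.transcript_id not in transcripts:
            raise KeyError(f"truth references unknown transcript {rec.transcript_id!r}")
        read = reads.get(rec.read_id)
        if read is None:
            raise KeyError(f"truth references unknown read {rec.read_id!r}")
        pile = pileups.get(rec.transcript_id)
        if pile is None:
            L = len(transcripts[rec.transcript_id])
            pile = Pileup(rec.transcript_id, np.zeros((5, L), dtype=np.int32))
            pileups[rec.transcript_id] = pile
        seq = read.seq if rec.strand == "+" else reverse_complement(read.seq)
        codes = _encode(seq)
        span = np.arange(rec.start - 1, rec.start - 1 + len(codes))
        if span[-1] >= pile.counts.shape[1]:
            raise ValueError(
                f"read {rec.read_id} overruns transcript {rec.transcript_id}"
            )
        pile.counts[codes, span] += 1
    return pileups


def pile_from_psl(
    hits: Iterable[TabularHit],
    reads: Mapping[str, SeqRecord],
    transcripts: Mapping[str, str],
) -> dict[str, Pileup]:
    """Alternative pileup path from external read→transcript alignments
    (e.g. BLAT PSL), ungapped placements only: each hit places the read's
    aligned span at its subject coordinates."""
    pileups: dict[str, Pileup] = {}
    for hit in hits:
        read = reads.get(hit.query_id)
        if read is None or hit.subject_id not in transcripts:
            continue
        pile = pileups.get(hit.subject_id)
        if pile is None:
            L = len(transcripts[hit.subject_id])
            pile = Pileup(hit.subject_id, np.zeros((5, L), dtype=np.int32))
            pileups[hit.subject_id] = pile
        seq = read.seq[hit.q_start - 1 : hit.q_end]
        if hit.frame < 0:
            seq = reverse_complement(seq)
        codes = _encode(seq)
        lo = min(hit.s_start, hit.s_end) - 1
        span = np.arange(lo, lo + len(codes))
        if span[-1] >= pile.counts.shape[1]:
            continue
        pile.counts[codes, span] += 1
    return pileups


def consensus_contigs(
    pileup: Pileup, reference_seq: str, min_depth: int = 1
) -> list[SeqRecord]:
    """Call consensus contigs as maximal runs with depth ≥ ``min_depth``.

    Consensus base is the majority vote over A/C/G/T; a tie breaks toward
    the reference transcript base (the gold standard should never do
    worse than the reference). Contig ids encode transcript and 1-based
    span, ``<transcript>:<start>-<end>``.
    """
    depth = pileup.depth
    covered = depth >= min_depth
    if not covered.any():
        return []
    counts = pileup.counts[:4]  # N never wins a vote
    best = counts.max(axis=0)
    L = len(depth)
    ref_codes = _encode(reference_seq).astype(np.int64)
    ref_count = np.where(
        ref_codes < 4, counts[np.minimum(ref_codes, 3), np.arange(L)], -1
    )
    call = np.where(
        (ref_codes < 4) & (ref_count == best), ref_codes, counts.argmax(axis=0)
    )
    base_lut = np.frombuffer(b"ACGT", dtype="S1")
    consensus = base_lut[call]

    # maximal covered runs
    padded = np.concatenate(([False], covered, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # 0-based half-open

    contigs: list[SeqRecord] = []
    for s, e in zip(starts, ends):
        contigs.append(
            SeqRecord(
                id=f"{pileup.transcript_id}:{s + 1}-{e}",
                seq=consensus[s:e].tobytes().decode(),
            )
        )
    return contigs


def build_gold_standard(
    truth: Sequence[TruthRecord],
    reads: Mapping[str, SeqRecord] | Sequence[SeqRecord],
    transcripts: Mapping[str, str],
    min_depth: int = 1,
) -> list[SeqRecord]:
    """Truth-placed pileup + consensus over every covered transcript."""
    pileups = pile_reads(truth, reads, transcripts)
    contigs: list[SeqRecord] = []
    for tid in sorted(pileups):
        contigs.extend(consensus_contigs(pileups[tid], transcripts[tid], min_depth))
    return contigs
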