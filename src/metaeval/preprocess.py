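"""Read cleaning and triage for metatranscriptomic libraries.

The protocol, in fixed order:

1. adaptor screen — truncate a read at the leftmost adaptor match; a match
   starting inside the first ``min_len`` bases discards the read as
   adaptor-contaminated;
2. quality trim — slide a 5-nt window in from each end, dropping terminal
   bases while the window's mean Phred score is below 20;
3. length filter — discard reads shorter than 50 bp; for pairs, if either
   mate is short both are discarded;
4. classification — rRNA / host / putative mRNA from alignment bit scores
   (threshold 50), with pair semantics (either mate rRNA ⇒ both rRNA,
   applied before the host rule).

Operations never alter bases; they only truncate ends. Category counts
partition the input read count exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io_formats import SeqRecord, TabularHit

__all__ = [
    "TrimParams",
    "ReadCategory",
    "AdaptorMatch",
    "screen_adaptor",
    "trim_quality",
    "filter_length",
    "classify_reads",
    "preprocess_reads",
    "DEFAULT_ADAPTORS",
]

# Illumina adaptor sequences targeted by the stringent screen
DEFAULT_ADAPTORS = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAG",
    "AGATCGGAAGAGCGTCGTGTAGGGAAAGA",
)


@dataclass(frozen=True)
class TrimParams:
    """Tunable knobs of the cleaning protocol (defaults = study protocol)."""

    window: int = 5
    min_mean_q: float = 20.0
    min_len: int = 50
    adaptors: tuple[str, ...] = DEFAULT_ADAPTORS
    adaptor_min_match: int = 10
    adaptor_min_score: int = 5
    match_score: int = 1
    mismatch_penalty: int = -2

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_len < self.window:
            raise ValueError("min_len must be >= window")


class ReadCategory(str, Enum):
    RRNA = "rRNA"
    HOST = "host"
    PUTATIVE_MRNA = "putative_mRNA"
    ADAPTOR_CONTAMINATED = "adaptor_contaminated"
    TOO_SHORT = "too_short"


@dataclass(frozen=True)
class AdaptorMatch:
    """Leftmost qualifying adaptor match: 1-based start in the read."""

    start: int
    adaptor_index: int
    score: int


# ---------------------------------------------------------------------------
# 1. adaptor screen
# ---------------------------------------------------------------------------

def _seeded_match_start(seq: str, adaptor: str, offset: int, params: TrimParams) -> tuple[int, int] | None:
    """Examine one ungapped placement of ``adaptor`` on ``seq`` at 0-based
    ``offset`` (negative = adaptor overhangs the 5' end).

    The placement qualifies only if it contains an exact shared word of
    length ≥ ``adaptor_min_match`` (the seed), in which case the seed is
    extended leftward to the best-scoring local segment containing it
    (+match/−mismatch scoring) and that segment must reach
    ``adaptor_min_score``. Returns (segment_start_in_seq, score) of the
    leftmost qualifying segment, else None.
    """
    lo = max(0, offset)
    hi = min(len(seq), offset + len(adaptor))
    if hi - lo < params.adaptor_min_match:
        return None
    # leftmost exact-match run of length >= min_match
    run_len, run_end = 0, None
    for i in range(lo, hi):
        if seq[i] == adaptor[i - offset]:
            run_len += 1
            if run_len >= params.adaptor_min_match:
                run_end = i
                break
        else:
            run_len = 0
    if run_end is None:
        return None
    seed_start = run_end - run_len + 1
    # extend seed leftward: best-scoring segment ending at the seed start
    best_score = score = run_len * params.match_score
    best_start = seed_start
    for i in range(seed_start - 1, lo - 1, -1):
        score += params.match_score if seq[i] == adaptor[i - offset] else params.mismatch_penalty
        if score > best_score:
            best_score, best_start = score, i
    if best_score < params.adaptor_min_score:
        return None
    return best_start, best_score


def find_adaptor(seq: str, params: TrimParams) -> AdaptorMatch | None:
    """Leftmost qualifying adaptor match in ``seq``, or None.

    A qualifying match is an ungapped placement of an adaptor sharing an
    exact word of length ≥ ``adaptor_min_match`` with the read (this
    covers adaptor prefixes hanging off the 3' end), locally extended
    under +1/−2 scoring to at least ``adaptor_min_score``. The exact-word
    seed requirement keeps chance 5-mer similarities in adaptor-free
    reads from triggering truncation.
    """
    best: AdaptorMatch | None = None
    for ai, adaptor in enumerate(params.adaptors):
        for offset in range(-len(adaptor) + 1, len(seq)):
            hit = _seeded_match_start(seq, adaptor, offset, params)
            if hit is not None:
                cand = AdaptorMatch(hit[0] + 1, ai, hit[1])
                if best is None or cand.start < best.start:
                    best = cand
    return best


def screen_adaptor(read: SeqRecord, params: TrimParams | None = None) -> SeqRecord | ReadCategory:
    """Truncate ``read`` at the leftmost adaptor match.

    Returns the (possibly truncated) read, or
    ``ReadCategory.ADAPTOR_CONTAMINATED`` when the match starts at
    position ≤ ``min_len`` (too little sequence would remain).
    """
    params = params or TrimParams()
    match = find_adaptor(read.seq, params)
    if match is None:
        return read
    if match.start <= params.min_len:
        return ReadCategory.ADAPTOR_CONTAMINATED
    keep = match.start - 1
    return SeqRecord(
        id=read.id,
        seq=read.seq[:keep],
        quals=read.quals[:keep] if read.quals is not None else None,
    )


# ---------------------------------------------------------------------------
# 2. quality trimming
# ---------------------------------------------------------------------------

def trim_quality(read: SeqRecord, params: TrimParams | None = None) -> SeqRecord:
    """Trim low-quality ends with a sliding mean-quality window.

    From each end independently: while the terminal ``window`` bases have
    mean quality < ``min_mean_q``, drop the terminal base and re-evaluate;
    stop when the mean reaches the threshold or fewer than ``window``
    bases remain. Never increases length; idempotent.
    """
    params = params or TrimParams()
    if read.quals is None:
        raise ValueError(f"read {read.id} has no quality scores")
    w = params.window
    quals = read.quals
    lo, hi = 0, len(quals)  # live half-open slice

    while hi - lo >= w and sum(quals[lo : lo + w]) / w < params.min_mean_q:
        lo += 1
    while hi - lo >= w and sum(quals[hi - w : hi]) / w < params.min_mean_q:
        hi -= 1

    if lo == 0 and hi == len(quals):
        return read
    return SeqRecord(id=read.id, seq=read.seq[lo:hi], quals=quals[lo:hi])


# ---------------------------------------------------------------------------
# 3. length filter
# ---------------------------------------------------------------------------

def filter_length(
    reads: Sequence[SeqRecord] | Sequence[tuple[SeqRecord, SeqRecord]],
    params: TrimParams | None = None,
) -> tuple[list, list]:
    """Keep reads (or pairs) meeting the minimum length.

    Single-end: keep iff len ≥ min_len. Paired: keep the pair iff *both*
    mates are ≥ min_len. Returns (kept, discarded) in input order.
    """
    params = params or TrimParams()
    kept, discarded = [], []
    for item in reads:
        if isinstance(item, tuple):
            ok = all(len(r) >= params.min_len for r in item)
        else:
            ok = len(item) >= params.min_len
        (kept if ok else discarded).append(item)
    return kept, discarded


# ---------------------------------------------------------------------------
# 4. classification
# ---------------------------------------------------------------------------

def _hit_ids(hits: Iterable[TabularHit], known: set[str], threshold: float) -> set[str]:
    out: set[str] = set()
    for hit in hits:
        if hit.query_id not in known:
            warnings.warn(f"hit references unknown read id {hit.query_id!r}; ignored")
            continue
        if hit.bit_score >= threshold:
            out.add(hit.query_id)
    return out


def classify_reads(
    read_ids: Sequence[str],
    rrna_hits: Iterable[TabularHit],
    host_hits: Iterable[TabularHit],
    bit_threshold: float = 50.0,
    pairs: Mapping[str, str] | None = None,
) -> dict[str, ReadCategory]:
    """Assign each read to rRNA, host, or putative mRNA.

    A hit counts iff bit_score ≥ ``bit_threshold``. Precedence is
    rRNA > host > putative_mRNA. ``pairs`` maps each mate id to the other;
    if either mate of a pair is rRNA both are rRNA, then likewise for host.
    """
    known = set(read_ids)
    rrna = _hit_ids(rrna_hits, known, bit_threshold)
    host = _hit_ids(host_hits, known, bit_threshold)
    if pairs:
        rrna |= {pairs[r] for r in list(rrna) if r in pairs and pairs[r] in known}
        host |= {pairs[r] for r in list(host) if r in pairs and pairs[r] in known}
    out: dict[str, ReadCategory] = {}
    for rid in read_ids:
        if rid in rrna:
            out[rid] = ReadCategory.RRNA
        elif rid in host:
            out[rid] = ReadCategory.HOST
        else:
            out[rid] = ReadCategory.PUTATIVE_MRNA
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def preprocess_reads(
    reads: Sequence[SeqRecord],
    rrna_hits: Iterable[TabularHit] = (),
    host_hits: Iterable[TabularHit] = (),
    params: TrimParams | None = None,
    bit_threshold: float = 50.0,
    pairs: Mapping[str, str] | None = None,
) -> tuple[dict[str, SeqRecord], dict[str, ReadCategory]]:
    """Run adaptor → quality → length → classify on single-end reads
    (pair semantics applied via ``pairs`` for the length and class steps).

    Returns (surviving reads by id, category per input read). Every input
    read receives exactly one category.
    """
    params = params or TrimParams()
    categories: dict[str, ReadCategory] = {}
    surviving: dict[str, SeqRecord] = {}

    for read in reads:
        result = screen_adaptor(read, params)
        if result is ReadCategory.ADAPTOR_CONTAMINATED:
            categories[read.id] = ReadCategory.ADAPTOR_CONTAMINATED
            continue
        trimmed = trim_quality(result, params) if result.quals is not None else result
        if len(trimmed) < params.min_len:
            categories[read.id] = ReadCategory.TOO_SHORT
        else:
            surviving[read.id] = trimmed

    if pairs:  # pair rules: a failed mate drags its partner down
        for rid in list(surviving):
            mate = pairs.get(rid)
            if mate is not None and mate not in surviving:
                categories[rid] = categories.get(mate, ReadCategory.TOO_SHORT)
                del surviving[rid]

    classes = classify_reads(
        list(surviving), rrna_hits, host_hits, bit_threshold, pairs=pairs
    )
    categories.update(classes)
    return surviving, categories
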