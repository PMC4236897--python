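"""Assembly summary statistics: N50, length histograms, annotation-rate
curves, reads-in-annotatable-contigs, and the between-assembly overlap
statistic.

An "annotatable" contig is one with a protein-database hit above a bit
score threshold (the study convention: bit score > 50). The central
observation these statistics support is that the probability of
annotating a sequence rises steeply with its length, so assemblies are
compared not only on contig counts and N50 but on how many *reads* end
up inside annotatable contigs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AssemblyEvalReport",
    "n50",
    "length_histogram",
    "annotation_curve",
    "reads_in_annotatable_contigs",
    "assembly_overlap",
    "compute_assembly_report",
]

BIT_THRESHOLD_DEFAULT = 50.0


def n50(contig_lengths: Sequence[int]) -> int:
    """Smallest length L such that contigs of length ≥ L hold at least
    half the total assembled bases."""
    if not len(contig_lengths):
        raise ValueError("n50 of an empty assembly is undefined")
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for L in lengths:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def length_histogram(
    contig_lengths: Sequence[int], bin_width: int = 20
) -> dict[tuple[int, int], int]:
    """Counts per [lo, hi) length bin; empty bins omitted."""
    hist: dict[tuple[int, int], int] = {}
    for L in contig_lengths:
        lo = (L // bin_width) * bin_width
        key = (lo, lo + bin_width)
        hist[key] = hist.get(key, 0) + 1
    return dict(sorted(hist.items()))


def annotation_curve(
    contig_lengths: Mapping[str, int],
    best_hit_scores: Mapping[str, float],
    bin_width: int = 20,
    bit_threshold: float = BIT_THRESHOLD_DEFAULT,
) -> dict[tuple[int, int], float]:
    """Fraction of contigs per length bin with best bit score > threshold.

    Contigs absent from ``best_hit_scores`` count as unannotated. Empty
    bins are omitted.
    """
    n: dict[tuple[int, int], int] = {}
    hit: dict[tuple[int, int], int] = {}
    for cid, L in contig_lengths.items():
        lo = (L // bin_width) * bin_width
        key = (lo, lo + bin_width)
        n[key] = n.get(key, 0) + 1
        if best_hit_scores.get(cid, float("-inf")) > bit_threshold:
            hit[key] = hit.get(key, 0) + 1
    return {key: hit.get(key, 0) / n[key] for key in sorted(n)}


def reads_in_annotatable_contigs(
    read_mapping: Mapping[str, str],
    contig_annotations: Mapping[str, float],
    n_total_reads: int,
    bit_threshold: float = BIT_THRESHOLD_DEFAULT,
) -> float:
    """Percent of all reads mapped to a contig whose best bit score
    exceeds the threshold.

    A mapped contig missing from the annotation table counts as
    unannotated (with a warning).
    """
    if n_total_reads <= 0:
        raise ValueError("n_total_reads must be positive")
    warned: set[str] = set()
    n_annot = 0
    for _read, contig in read_mapping.items():
        if contig not in contig_annotations:
            if contig not in warned:
                warnings.warn(f"contig {contig!r} absent from annotation table")
                warned.add(contig)
            continue
        if contig_annotations[contig] > bit_threshold:
            n_annot += 1
    return 100.0 * n_annot / n_total_reads


def assembly_overlap(mapped_reads_a: Iterable[str], mapped_reads_b: Iterable[str]) -> float:
    """Overlap between two assemblies' mapped-read sets:
    100·|A∩B| / min(|A|,|B|). Symmetric; 100 iff the smaller set is
    contained in the larger; defined as 0 (with a warning) when both
    sets are empty."""
    a, b = set(mapped_reads_a), set(mapped_reads_b)
    if not a or not b:
        if not a and not b:
            warnings.warn("overlap of two empty read sets defined as 0")
        return 0.0
    return 100.0 * len(a & b) / min(len(a), len(b))


@dataclass
class AssemblyEvalReport:
    """Per-assembly roll-up of the summary statistics."""

    n_contigs: int
    n50: int
    length_histogram: dict[tuple[int, int], int]
    annotation_curve: dict[tuple[int, int], float]
    pct_reads_mapped: float
    pct_reads_in_annotatable_contigs: float
    overlap_matrix: dict[tuple[str, str], float] = field(default_factory=dict)


def compute_assembly_report(
    contig_lengths: Mapping[str, int],
    best_hit_scores: Mapping[str, float],
    read_mapping: Mapping[str, str],
    n_total_reads: int,
    bin_width: int = 20,
    bit_threshold: float = BIT_THRESHOLD_DEFAULT,
    other_assemblies: Mapping[str, Iterable[str]] | None = None,
) -> AssemblyEvalReport:
    """Assemble the full report for one contig set.

    ``other_assemblies`` optionally maps assembly names to their mapped
    read-id sets; the overlap of this assembly against each is recorded
    in the overlap matrix.
    """
    lengths = list(contig_lengths.values())
    mapped = [r for r, c in read_mapping.items() if c in contig_lengths]
    pct_mapped = 100.0 * len(mapped) / n_total_reads if n_total_reads else 0.0
    overlap: dict[tuple[str, str], float] = {}
    if other_assemblies:
        for name, reads_b in other_assemblies.items():
            overlap[("self", name)] = assembly_overlap(mapped, reads_b)
    return AssemblyEvalReport(
        n_contigs=len(lengths),
        n50=n50(lengths),
        length_histogram=length_histogram(lengths, bin_width),
        annotation_curve=annotation_curve(
            contig_lengths, best_hit_scores, bin_width, bit_threshold
        ),
        pct_reads_mapped=pct_mapped,
        pct_reads_in_annotatable_contigs=reads_in_annotatable_contigs(
            read_mapping, best_hit_scores, n_total_reads, bit_threshold
        ),
        overlap_matrix=overlap,
    )
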