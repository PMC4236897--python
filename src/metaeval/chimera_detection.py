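"""Chimeric (multi-gene) contig detection and splitting from protein hits.

A contig assembled from reads of two unrelated genes shows two or more
non-contiguous high-scoring protein alignments. The heuristic:

1. **Positional scan** — walk the contig left to right; at the first
   position not yet covered by an accepted alignment, accept the
   highest-scoring qualifying hit (bit score ≥ 50) covering it and mark
   its whole span covered. Bases of a later-accepted hit falling on
   already-covered ground are ignored when forming components.
2. **Component merge** — accepted spans that touch or overlap merge into
   components; a gap of ≥ 1 base separates components.
3. **Fragmentation** — a contig with ≥ 2 components is flagged
   multi-gene and split into fragments, one per component, with cut
   points at gap midpoints so fragments tile the contig exactly.
4. **Partial-match flag** — a contig/fragment whose best hit covers less
   than 90% of its length is flagged as a potential residual
   misassembly (or an unannotated novel gene).

Tie-breaks in step 1 (higher score, then longer span, then smaller
q_start, then lexicographic subject id) make the accepted set
independent of input hit order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import TabularHit

__all__ = [
    "ProteinAlignment",
    "FragmentationResult",
    "select_alignments",
    "fragment_contig",
    "flag_partial",
    "process_contig",
    "summarize_chimeras",
    "BIT_THRESHOLD_DEFAULT",
    "PARTIAL_COVERAGE_FRACTION",
]

BIT_THRESHOLD_DEFAULT = 50.0
PARTIAL_COVERAGE_FRACTION = 0.90


@dataclass(frozen=True)
class ProteinAlignment:
    """One protein-database hit on a contig, in contig nucleotide coords."""

    contig_id: str
    subject_id: str
    q_start: int
    q_end: int
    bit_score: float

    @classmethod
    def from_hit(cls, hit: TabularHit) -> "ProteinAlignment":
        return cls(hit.query_id, hit.subject_id, hit.q_start, hit.q_end, hit.bit_score)

    @property
    def span(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass
class Fragment:
    """One tile of a (possibly split) contig: 1-based inclusive interval."""

    start: int
    end: int
    seq: str
    best_hit: ProteinAlignment | None
    partial: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FragmentationResult:
    contig_id: str
    contig_len: int
    accepted: list[ProteinAlignment]
    components: list[tuple[int, int]]
    fragments: list[Fragment]
    multi_gene: bool


def select_alignments(
    contig_len: int,
    hits: Iterable[ProteinAlignment | TabularHit],
    bit_threshold: float = BIT_THRESHOLD_DEFAULT,
) -> list[ProteinAlignment]:
    """Positional greedy scan for the accepted non-overlapping hit set.

    Scan positions 1..contig_len left to right; at the first uncovered
    position covered by ≥ 1 qualifying hit, accept the highest-scoring
    such hit (ties: longer span, then smaller q_start, then lexicographic
    subject id) and mark its span covered; continue from the next
    uncovered position. The result is independent of input hit order.
    """
    alns = [
        h if isinstance(h, ProteinAlignment) else ProteinAlignment.from_hit(h)
        for h in hits
    ]
    for a in alns:
        if a.q_start < 1 or a.q_end > contig_len:
            raise ValueError(
                f"hit {a.subject_id} [{a.q_start},{a.q_end}] outside contig "
                f"of length {contig_len}"
            )
    qualifying = sorted(
        (a for a in alns if a.bit_score >= bit_threshold),
        key=lambda a: a.q_start,
    )
    accepted: list[ProteinAlignment] = []
    pos = 1
    while pos <= contig_len and qualifying:
        # candidates covering pos
        cands = [a for a in qualifying if a.q_start <= pos <= a.q_end]
        if not cands:
            nxt = min(
                (a.q_start for a in qualifying if a.q_start > pos), default=None
            )
            if nxt is None:
                break
            pos = nxt
            continue
        best = min(
            cands,
            key=lambda a: (-a.bit_score, -a.span, a.q_start, a.subject_id),
        )
        accepted.append(best)
        covered = _merge_intervals([(a.q_start, a.q_end) for a in accepted])
        # next uncovered position after pos
        pos_new = pos
        for s, e in covered:
            if s <= pos_new <= e:
                pos_new = e + 1
        pos = pos_new
        qualifying = [a for a in qualifying if a is not best]
    return accepted


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals; adjacent (end+1 == start) merge too."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def flag_partial(fragment_len: int, best_hit: ProteinAlignment | None) -> bool:
    """True iff the best hit covers < 90% of the fragment.

    No qualifying hit → not flagged partial (the fragment is counted
    separately as unannotated).
    """
    if best_hit is None:
        return False
    return best_hit.span / fragment_len < PARTIAL_COVERAGE_FRACTION


def fragment_contig(
    contig_id: str,
    contig_seq: str,
    accepted: Sequence[ProteinAlignment],
) -> FragmentationResult:
    """Split a contig into single-gene fragments at component gap midpoints.

    Components are the connected components of the union of accepted
    spans. With ≥ 2 components the contig is multi-gene and fragment k
    runs from the midpoint of the gap before it (contig start for the
    first) to the midpoint of the gap after it (contig end for the
    last), so the fragments tile the contig. With ≤ 1 component the
    whole contig is one fragment.
    """
    n = len(contig_seq)
    components = _merge_intervals([(a.q_start, a.q_end) for a in accepted])
    multi = len(components) >= 2

    if not multi:
        bounds = [(1, n)]
        comp_for_frag: list[tuple[int, int] | None] = [
            components[0] if components else None
        ]
    else:
        cuts = [
            (components[k][1] + components[k + 1][0]) // 2
            for k in range(len(components) - 1)
        ]
        starts = [1] + [c + 1 for c in cuts]
        ends = cuts + [n]
        bounds = list(zip(starts, ends))
        comp_for_frag = list(components)

    fragments: list[Fragment] = []
    for (s, e), comp in zip(bounds, comp_for_frag):
        if comp is None:
            in_frag: list[ProteinAlignment] = []
        else:
            in_frag = [a for a in accepted if comp[0] <= a.q_start and a.q_end <= comp[1]]
        best = min(
            in_frag,
            key=lambda a: (-a.bit_score, -a.span, a.q_start, a.subject_id),
            default=None,
        )
        fragments.append(
            Fragment(
                start=s,
                end=e,
                seq=contig_seq[s - 1 : e],
                best_hit=best,
                partial=flag_partial(e - s + 1, best),
            )
        )
    return FragmentationResult(
        contig_id=contig_id,
        contig_len=n,
        accepted=list(accepted),
        components=components,
        fragments=fragments,
        multi_gene=multi,
    )


def process_contig(
    contig_id: str,
    contig_seq: str,
    hits: Iterable[ProteinAlignment | TabularHit],
    bit_threshold: float = BIT_THRESHOLD_DEFAULT,
) -> FragmentationResult:
    """select_alignments + fragment_contig for one contig."""
    accepted = select_alignments(len(contig_seq), hits, bit_threshold)
    return fragment_contig(contig_id, contig_seq, accepted)


def summarize_chimeras(results: Sequence[FragmentationResult]) -> dict[str, float]:
    """Assembly-level misassembly incidence.

    pct_multi_gene is over all contigs; pct_partial is over contigs and
    fragments that carry a qualifying hit (unannotated units are
    excluded from the partial denominator).
    """
    if not results:
        raise ValueError("no contigs to summarize")
    n_contigs = len(results)
    n_multi = sum(r.multi_gene for r in results)
    units = [f for r in results for f in r.fragments]
    annotated = [f for f in units if f.best_hit is not None]
    n_partial = sum(f.partial for f in annotated)
    return {
        "n_contigs": n_contigs,
        "n_fragments": len(units),
        "pct_multi_gene": 100.0 * n_multi / n_contigs,
        "pct_partial": (100.0 * n_partial / len(annotated)) if annotated else 0.0,
    }
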