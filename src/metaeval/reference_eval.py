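"""Reference-based misassembly scoring for simulated assemblies.

A contig is called misassembled when its best alignment to the reference
transcriptome leaves more than one read length (default 76 nt) of the
contig unmatched, evaluated at a sweep of percent-identity cutoffs
(97–100 by default). "Best" is the alignment maximizing matched bases
(BLAT's natural score); "unmatched" is the contig length minus the best
alignment's query span. A contig with no alignment passing the cutoff is
entirely unmatched.

Lowering the identity cutoff admits more alignments and therefore can
only shrink the misassembled set: the per-cutoff sets are nested, and
this is asserted on every evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import SeqRecord, TabularHit

__all__ = [
    "ContigCall",
    "CutoffSummary",
    "MisassemblyReport",
    "best_reference_alignment",
    "unmatched_length",
    "evaluate_assembly",
    "READ_LEN_DEFAULT",
    "IDENTITY_CUTOFFS_DEFAULT",
]

READ_LEN_DEFAULT = 76
IDENTITY_CUTOFFS_DEFAULT = (97.0, 98.0, 99.0, 100.0)


@dataclass
class ContigCall:
    contig_id: str
    contig_len: int
    best_subject: str | None
    unmatched_len: int
    flagged: bool


@dataclass
class CutoffSummary:
    identity_cutoff: float
    n_contigs: int
    n_misassembled: int
    pct_misassembled: float
    calls: dict[str, ContigCall] = field(repr=False, default_factory=dict)


@dataclass
class MisassemblyReport:
    read_len: int
    per_cutoff: dict[float, CutoffSummary]

    def misassembled_ids(self, cutoff: float) -> set[str]:
        return {
            cid
            for cid, call in self.per_cutoff[cutoff].calls.items()
            if call.flagged
        }


def best_reference_alignment(
    alignments: Iterable[TabularHit], identity_cutoff: float
) -> TabularHit | None:
    """Highest-scoring alignment at ≥ ``identity_cutoff`` percent identity.

    Score is the matched-base count; ties break toward fewer mismatches,
    then lexicographic subject id. None if nothing qualifies.
    """
    best: TabularHit | None = None
    for hit in alignments:
        if hit.pct_identity < identity_cutoff:
            continue
        if best is None:
            best = hit
            continue
        key = (-hit.matches, hit.aln_len - hit.matches, hit.subject_id)
        best_key = (-best.matches, best.aln_len - best.matches, best.subject_id)
        if key < best_key:
            best = hit
    return best


def unmatched_length(contig_len: int, best_hit: TabularHit | None) -> int:
    """Contig bases outside the best alignment's query span (all of them
    when no alignment qualifies)."""
    if contig_len <= 0:
        raise ValueError("contig_len must be positive")
    if best_hit is None:
        return contig_len
    return contig_len - best_hit.q_span


def evaluate_assembly(
    contigs: Sequence[SeqRecord] | Mapping[str, int],
    alignments: Iterable[TabularHit],
    cutoffs: Sequence[float] = IDENTITY_CUTOFFS_DEFAULT,
    read_len: int = READ_LEN_DEFAULT,
    fusion_whitelist: Iterable[str] = (),
) -> MisassemblyReport:
    """Score every contig at every identity cutoff.

    ``contigs`` is either sequence records or a contig_id → length map.
    ``fusion_whitelist`` names contigs excluded from the percentage (for
    simulators whose library-construction artifacts produce legitimate
    gene fusions; empty by default — transcript-based simulation creates
    none by construction). Alignments naming unknown contigs warn and
    are skipped.
    """
    if isinstance(contigs, Mapping):
        lengths = dict(contigs)
    else:
        lengths = {c.id: len(c.seq) for c in contigs}
    whitelist = set(fusion_whitelist)

    by_contig: dict[str, list[TabularHit]] = {}
    for hit in alignments:
        if hit.query_id not in lengths:
            warnings.warn(f"alignment references unknown contig {hit.query_id!r}")
            continue
        by_contig.setdefault(hit.query_id, []).append(hit)

    eval_ids = [cid for cid in lengths if cid not in whitelist]
    per_cutoff: dict[float, CutoffSummary] = {}
    for cutoff in cutoffs:
        calls: dict[str, ContigCall] = {}
        n_mis = 0
        for cid in eval_ids:
            best = best_reference_alignment(by_contig.get(cid, ()), cutoff)
            unmatched = unmatched_length(lengths[cid], best)
            flagged = unmatched > read_len
            n_mis += flagged
            calls[cid] = ContigCall(
                contig_id=cid,
                contig_len=lengths[cid],
                best_subject=best.subject_id if best else None,
                unmatched_len=unmatched,
                flagged=flagged,
            )
        n = len(eval_ids)
        per_cutoff[cutoff] = CutoffSummary(
            identity_cutoff=cutoff,
            n_contigs=n,
            n_misassembled=n_mis,
            pct_misassembled=100.0 * n_mis / n if n else 0.0,
            calls=calls,
        )

    report = MisassemblyReport(read_len=read_len, per_cutoff=per_cutoff)
    _assert_nested(report, sorted(cutoffs))
    return report


def _assert_nested(report: MisassemblyReport, cutoffs: Sequence[float]) -> None:
    """Lower cutoff ⇒ subset of the misassembled set at any higher cutoff."""
    for lo, hi in zip(cutoffs, cutoffs[1:]):
        if not report.misassembled_ids(lo) <= report.misassembled_ids(hi):
            raise AssertionError(
                f"misassembled set at {lo}% identity is not nested within {hi}%"
            )
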