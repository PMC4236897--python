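# Methods

## Scope and model

`metaeval` evaluates metatranscriptome assemblies without requiring real
sequencing data or assembler binaries. The pipeline treats three things
as external inputs — contig FASTA from any assembler, protein-search
hits (BLAST tabular), and contig/read alignments (PSL or tabular) — and
computes everything else itself: read triage, a simulated dataset with
ground truth, a gold-standard consensus assembly, chimera detection, and
the misassembly and annotation statistics.

## Read preprocessing

Order is fixed: adaptor screen → quality trim → length filter →
classification. No step ever edits a base; ends are only truncated, so
any surviving read is a verbatim substring of its input read.

**Adaptor screen.** Two Illumina adaptor sequences (30- and 29-mers) are
searched at every ungapped placement against the read. A placement
qualifies only when it shares an exact word of ≥ 10 bases with the read
(this covers adaptor prefixes hanging off the 3′ end); the word is then
extended leftward under +1 match / −2 mismatch scoring and the best
segment must score ≥ 5. The read is truncated at the leftmost qualifying
segment start; if that start lies within the first 50 bases, the read is
discarded as adaptor-contaminated. The exact-word seed is essential:
without it, a random 76-mer shares a chance 5-mer (local score 5) with a
30-mer adaptor with expectation ≈ 10 per read, and every clean read
would be truncated. With the seed, a clean read qualifies with
probability ≈ 76·2·21/4¹⁰ ≈ 0.3%.

**Quality trimming.** From each end independently: while the terminal
5-base window has mean Phred < 20, drop the terminal base and
re-evaluate; stop at mean ≥ 20 (the boundary mean == 20 stops) or when
fewer than 5 bases remain. One base per iteration makes the loop
order-deterministic and idempotent; a worked trace for qualities
`[30,30,30,30,30,10,10,10,10,10]` removes three 3′ bases (window means
10 → 14 → 18) and stops at `[30,30,30,10,10]` (mean 22), leaving 7
bases.

**Length filter.** Reads < 50 bp are discarded; for pairs, if either
mate is short both are discarded (50 bp exactly is kept).

**Classification.** A read with an rRNA-database hit of bit score ≥ 50
is rRNA; else a host hit ≥ 50 makes it host; else it is putative mRNA.
Pair semantics: either mate rRNA ⇒ both rRNA, then likewise for host.
The rRNA-before-host precedence is a package convention chosen for
determinism; in practice double hits are rare and the choice only
affects bookkeeping, not which reads reach assembly.

## Simulator

The simulator's job is to hand downstream modules inputs with *known
truth*, not to reproduce any particular sequencing instrument.

- **Transcriptome**: `n_species` species, `genes_per_species` random
  transcripts each, lengths uniform on [300, 3000] bp (min must be ≥ the
  read length), GC 0.5. Species abundances are rank-skewed, rank *r* ∝
  *r*⁻¹ normalized to 1, mimicking the uneven representation of gut
  communities. Optionally, the first *k* genes of every species are
  drawn from shared templates mutated to a configurable pairwise
  identity (default 95%), emulating the cross-species homologs that
  drive chimeric assembly.
- **Expression**: within each species, transcripts are randomly ranked
  and rank *r* gets weight *r*⁻ˢ/Σ*r*⁻ˢ. Default exponent *s* = 1
  (classic Zipf); *s* = 0 degenerates to uniform. The exponent is fully
  configurable because no canonical value exists for microbial
  transcriptomes.
- **Reads**: species ∝ abundance, transcript ∝ expression weight ×
  transcript length (length weighting, on by default, approximates
  fragment-count sampling; toggleable), start uniform, strand uniform.
  Paired mode samples an insert from a normal(273, 30) model (mean from
  typical library preps of this read era; sd is a package default since
  fragment-size spreads of ~10% of the mean are routine), clamps it to ≥
  read length, rejection-samples transcripts too short for the insert
  (100 tries, then the draw is skipped with a warning), and emits mate 2
  reverse-complemented. Substitution errors are independent per
  position, rate constant or positional (default 0; 0.001–0.02 are
  realistic Illumina-like settings), each error recorded in the truth
  table. Qualities are flat Q40 — quality-string realism is a non-goal.
- **Determinism**: one seeded generator; draw order is species →
  transcript → start → strand → errors, so a seed fully reproduces a
  dataset.

What the simulator does *not* model: indels, library-prep biases
(RT/fragmentation/PCR), rRNA or host reads, and read-through into
intergenic sequence. The last point means no fusion reads of neighboring
genes exist by construction, so the fusion whitelist consumed by the
misassembly metric is empty by default. Consequently, passing tests show
the *metrics* behave correctly on data with known truth; they do not
show that any particular assembler performs well on real communities.

## Gold-standard assembly

Reads are placed on their source transcripts by ground truth (exact and
dependency-free; a PSL-ingest path accepts external alignments for
parity), giving per-position counts over A/C/G/T/N. Contigs are maximal
runs of positions with depth ≥ `min_depth` (default 1 — no evidence
threshold beyond coverage); the consensus base is the majority vote,
with ties broken toward the reference transcript base so the gold
standard is never worse than the reference. At error rate 0 every
contig is therefore an exact substring of its transcript; at positive
error rates, consensus error decreases with depth (asserted empirically
in the tests at rate 0.02).

## Chimera detection

Qualifying protein hits (bit score ≥ 50) are selected by a **positional
scan**: walk contig positions left to right; at the first position not
covered by an accepted alignment, accept the highest-scoring hit
covering it and mark its whole span covered. Tie-breaks — higher score,
longer span, smaller start, lexicographic subject id — make the result
independent of input order (verified against an independently coded
literal per-position re-execution on 1,000 random instances). A
score-first greedy (accept hits in global score order) is the natural
alternative reading of "highest scoring non-overlapping alignments"; the
positional scan was chosen as the literal reading of iterating over the
contig, and differs from score-first exactly when a high-scoring hit is
nested inside a lower-scoring one that reaches further left.

Accepted spans merge into components when they touch or overlap (a gap
of ≥ 1 base separates components). A contig with ≥ 2 components is
multi-gene; it is split into fragments with cut points at gap midpoints
(`(gap_end + gap_start)//2`), so fragments always tile the contig —
required for downstream read accounting, since the source material only
says contigs are split. A contig/fragment whose best hit covers < 90% of
its length is flagged partial (exactly 90% is not partial); units with
no qualifying hit are counted unannotated, not partial.

## Reference-based misassembly

For each contig, the best reference alignment at identity cutoff *c* is
the one maximizing matched bases (BLAT's natural score; ties → fewer
mismatches, then subject id) among alignments with percent identity ≥
*c*. Unmatched length is contig length minus the best alignment's query
span — internal alignment gaps are not subtracted, which is exact for
the substitution-only simulator and documented behaviour for gapped PSL
input. A contig is misassembled iff unmatched > one read length
(76 exactly is not flagged). Because lowering *c* only admits more
alignments, the misassembled sets are nested across cutoffs; the
evaluator asserts this on every run. The identity cutoff is applied per
alignment (not per block), matching how the alignments are ingested.

## Summary metrics

N50 is the contig length at which the descending cumulative length
crosses half the assembly. The annotation curve bins contigs by length
(default 20 bp — figure-style binning; configurable) and reports the
fraction per bin with best bit score strictly > 50. The
reads-in-annotatable-contigs statistic is 100 × (reads mapped to a
contig with best score > threshold) / (all reads) and is bounded above
by % reads mapped. Assembly overlap is 100·|A∩B| / min(|A|,|B|) over
mapped read-id sets: symmetric, 100 iff the smaller set is contained in
the larger, and defined as 0 (with a warning) when both sets are empty.

## Problem sizes and numerical notes

The bundled end-to-end checks run a 10-species × 200-gene transcriptome
with 100,000 zero-error reads (the scale at which coverage is deep
enough for thousands of multi-read contigs while the whole suite stays
interactive), 1,000-instance oracle comparisons, and 1,000-contig
chimera-injection fixtures. Statistical recovery checks use 3-standard-
error binomial bounds (≈ 99.7% per-comparison coverage) and a ±0.05 band
on the recovered Zipf exponent. All randomness flows through explicit
seeds; percentages are exact ratios, no floating-point tolerance is
needed for the count-based metrics.

## Known limitations

- Adaptor screening is ungapped; an adaptor copy with an indel in its
  first 10 bases would be missed.
- The pileup is substitution-only; truth placement cannot represent
  indel errors, and the PSL path assumes ungapped placements.
- Polycistronic transcripts legitimately produce multi-gene contigs; the
  chimera metric cannot distinguish them from misassemblies (splitting
  them into per-ORF fragments is the intended behaviour).
- The misassembly metric depends on the completeness of the reference /
  protein database: novel genes surface as false-positive partial
  matches.
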