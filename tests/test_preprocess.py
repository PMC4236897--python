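import random

import pytest
from hypothesis import given, settings, strategies as st

from metaeval.io_formats import SeqRecord, TabularHit
from metaeval.preprocess import (
    DEFAULT_ADAPTORS,
    ReadCategory,
    TrimParams,
    classify_reads,
    filter_length,
    find_adaptor,
    preprocess_reads,
    screen_adaptor,
    trim_quality,
)

PARAMS = TrimParams()


def _hit(read_id, bit, subject="db1"):
    return TabularHit(read_id, subject, 99.0, 76, 1, 76, 1, 76, bit, 75)


def brute_force_adaptor_scan(seq, params):
    """Independent oracle: try every ungapped placement of every adaptor,
    find exact >=min_match words, extend left with +1/-2, return the
    leftmost qualifying 1-based segment start."""
    starts = []
    for adaptor in params.adaptors:
        for offset in range(-len(adaptor) + 1, len(seq)):
            lo, hi = max(0, offset), min(len(seq), offset + len(adaptor))
            # all exact runs
            i = lo
            while i < hi:
                j = i
                while j < hi and seq[j] == adaptor[j - offset]:
                    j += 1
                if j - i >= params.adaptor_min_match:
                    best_score = score = j - i
                    best_start = i
                    for k in range(i - 1, lo - 1, -1):
                        score += 1 if seq[k] == adaptor[k - offset] else -2
                        if score > best_score:
                            best_score, best_start = score, k
                    if best_score >= params.adaptor_min_score:
                        starts.append(best_start + 1)
                i = j + 1 if j > i else i + 1
    return min(starts) if starts else None


class TestAdaptorScreen:
    def test_prefix_at_3prime_end_truncates(self):
        # 60 bases that share no word with the adaptors, then a 16-base
        # adaptor prefix occupying positions 61-76
        read = SeqRecord("r", "T" * 60 + DEFAULT_ADAPTORS[0][:16], [40] * 76)
        assert brute_force_adaptor_scan(read.seq, PARAMS) == 61
        out = screen_adaptor(read, PARAMS)
        assert isinstance(out, SeqRecord) and len(out) == 60

    def test_clean_read_unchanged(self):
        read = SeqRecord("r", "ACGT" * 19, [40] * 76)
        assert find_adaptor(read.seq, PARAMS) is None
        assert screen_adaptor(read, PARAMS) is read

    def test_read_that_is_adaptor_flagged(self):
        read = SeqRecord("r", DEFAULT_ADAPTORS[0], [40] * 30)
        assert screen_adaptor(read, PARAMS) is ReadCategory.ADAPTOR_CONTAMINATED

    def test_matches_brute_force_oracle_on_random_reads(self):
        rnd = random.Random(7)
        for i in range(200):
            seq = "".join(rnd.choice("ACGT") for _ in range(76))
            if rnd.random() < 0.5:  # plant an adaptor chunk
                ad = rnd.choice(DEFAULT_ADAPTORS)
                k = rnd.randint(10, len(ad))
                pos = rnd.randint(0, 76 - k)
                seq = seq[:pos] + ad[:k] + seq[pos + k :]
            expected = brute_force_adaptor_scan(seq, PARAMS)
            got = find_adaptor(seq, PARAMS)
            assert (got.start if got else None) == expected, seq


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        read = SeqRecord("r", "ACGTACGTAC", [30] * 10)
        assert trim_quality(read, PARAMS) is read

    def test_stepwise_loop_endpoint(self):
        """Hand-executed loop: [30x5, 10x5] loses terminal bases while the
        3' window mean is <20 (means 10, 14, 18), stopping at [30,30,30,10,10]
        mean 22 -> final length 7."""
        read = SeqRecord("r", "ACGTACGTAC", [30] * 5 + [10] * 5)
        out = trim_quality(read, PARAMS)
        assert len(out) == 7
        assert out.seq == read.seq[:7]

    def test_five_prime_end_trimmed_symmetrically(self):
        read = SeqRecord("r", "ACGTACGTAC", [10] * 5 + [30] * 5)
        out = trim_quality(read, PARAMS)
        assert len(out) == 7 and out.seq == read.seq[3:]

    def test_boundary_mean_exactly_20_stops(self):
        read = SeqRecord("r", "ACGTA", [20] * 5)
        assert trim_quality(read, PARAMS) is read

    def test_read_without_quals_errors(self):
        with pytest.raises(ValueError):
            trim_quality(SeqRecord("r", "ACGT"), PARAMS)

    @settings(max_examples=300, derandomize=True)
    @given(
        quals=st.lists(st.integers(min_value=0, max_value=41), min_size=5, max_size=120)
    )
    def test_idempotent_and_never_longer(self, quals):
        read = SeqRecord("r", "A" * len(quals), quals)
        once = trim_quality(read, PARAMS)
        assert len(once) <= len(read)
        twice = trim_quality(once, PARAMS)
        assert twice.seq == once.seq and twice.quals == once.quals


class TestLengthFilter:
    def _read(self, n):
        return SeqRecord("r" + str(n), "A" * n, [30] * n)

    def test_single_end_boundaries(self):
        kept, discarded = filter_length([self._read(49), self._read(50)], PARAMS)
        assert [len(r) for r in kept] == [50]
        assert [len(r) for r in discarded] == [49]

    def test_pair_discarded_if_either_mate_short(self):
        pair = (self._read(76), self._read(49))
        kept, discarded = filter_length([pair], PARAMS)
        assert kept == [] and discarded == [pair]

    def test_pair_kept_at_exact_boundary(self):
        pair = (self._read(50), self._read(50))
        kept, discarded = filter_length([pair], PARAMS)
        assert kept == [pair] and discarded == []


class TestClassification:
    def test_below_threshold_is_mrna(self):
        cats = classify_reads(["r1"], [_hit("r1", 49.9)], [])
        assert cats["r1"] is ReadCategory.PUTATIVE_MRNA

    def test_rrna_mate_propagates_to_pair(self):
        cats = classify_reads(
            ["r1/1", "r1/2"],
            [_hit("r1/1", 60)],
            [],
            pairs={"r1/1": "r1/2", "r1/2": "r1/1"},
        )
        assert cats["r1/1"] is ReadCategory.RRNA
        assert cats["r1/2"] is ReadCategory.RRNA

    def test_rrna_takes_precedence_over_host(self):
        cats = classify_reads(["r1"], [_hit("r1", 55)], [_hit("r1", 55)])
        assert cats["r1"] is ReadCategory.RRNA

    def test_unknown_read_id_warns_and_ignored(self):
        with pytest.warns(UserWarning, match="unknown read id"):
            cats = classify_reads(["r1"], [_hit("ghost", 90)], [])
        assert cats["r1"] is ReadCategory.PUTATIVE_MRNA


class TestPipeline:
    def test_categories_partition_input(self):
        rnd = random.Random(5)
        reads = []
        for i in range(60):
            n = rnd.randint(20, 76)
            reads.append(
                SeqRecord(
                    f"r{i}",
                    "".join(rnd.choice("ACGT") for _ in range(n)),
                    [rnd.randint(2, 41) for _ in range(n)],
                )
            )
        _, cats = preprocess_reads(reads, [], [], PARAMS)
        assert len(cats) == len(reads)
        assert set(cats) == {r.id for r in reads}

    def test_identity_on_clean_flat_q40_reads(self, small_simulation):
        """Adaptor-free simulated reads at flat Q40 pass through untouched."""
        _, dataset, _ = small_simulation
        reads = dataset.reads[:300]
        surviving, cats = preprocess_reads(reads, [], [], PARAMS)
        assert len(surviving) == len(reads)
        for r in reads:
            assert surviving[r.id].seq == r.seq
            assert cats[r.id] is ReadCategory.PUTATIVE_MRNA
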