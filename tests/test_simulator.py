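import math

import numpy as np
import pytest

from metaeval.io_formats import reverse_complement
from metaeval.simulator import (
    ErrorModel,
    InsertModel,
    Transcript,
    apply_errors,
    assign_expression_zipf,
    make_synthetic_transcriptome,
    read_truth_table,
    simulate_reads,
    write_truth_table,
)


class TestTranscriptome:
    def test_deterministic_given_seed(self):
        a = make_synthetic_transcriptome(10, 20, seed=7)
        b = make_synthetic_transcriptome(10, 20, seed=7)
        assert [
            (t.transcript_id, t.seq) for p in a for t in p.transcripts
        ] == [(t.transcript_id, t.seq) for p in b for t in p.transcripts]

    def test_single_species_single_gene(self):
        (profile,) = make_synthetic_transcriptome(1, 1, seed=1)
        assert profile.abundance == pytest.approx(1.0)
        assert len(profile.transcripts) == 1

    def test_abundances_sum_to_one(self):
        profiles = make_synthetic_transcriptome(15, 5, seed=2)
        assert sum(p.abundance for p in profiles) == pytest.approx(1.0, abs=1e-9)

    def test_family_injection_at_full_identity_duplicates(self):
        profiles = make_synthetic_transcriptome(
            4, 6, seed=3, n_shared_families=2, family_identity=1.0
        )
        for fam in range(2):
            seqs = {p.transcripts[fam].seq for p in profiles}
            assert len(seqs) == 1

    def test_family_injection_near_identity(self):
        profiles = make_synthetic_transcriptome(
            2, 3, seed=4, n_shared_families=1, family_identity=0.95
        )
        a, b = (p.transcripts[0].seq for p in profiles)
        assert len(a) == len(b)
        ident = sum(x == y for x, y in zip(a, b)) / len(a)
        assert 0.90 < ident < 1.0

    def test_min_length_below_read_length_errors(self):
        with pytest.raises(ValueError, match="read length"):
            make_synthetic_transcriptome(1, 1, length_dist=(50, 100), seed=0)


class TestZipf:
    def _transcripts(self, n):
        return [Transcript(f"t{i}", "sp", "A" * 300) for i in range(n)]

    def test_three_transcripts_s1_harmonic_weights(self):
        txs = self._transcripts(3)
        assign_expression_zipf(txs, 1.0, seed=0)
        assert sorted((t.expression_weight for t in txs), reverse=True) == pytest.approx(
            [6 / 11, 3 / 11, 2 / 11]
        )

    def test_s0_uniform(self):
        txs = self._transcripts(5)
        assign_expression_zipf(txs, 0.0, seed=0)
        assert [t.expression_weight for t in txs] == pytest.approx([0.2] * 5)

    def test_loglog_regression_recovers_exponent(self):
        for s in (0.7, 1.0, 1.4):
            txs = self._transcripts(1000)
            assign_expression_zipf(txs, s, seed=9)
            w = np.sort([t.expression_weight for t in txs])[::-1]
            slope = np.polyfit(np.log(np.arange(1, 1001)), np.log(w), 1)[0]
            assert abs(-slope - s) < 0.05


class TestErrors:
    def test_rate_zero_identity(self, rng):
        seq = "ACGT" * 19
        out, pos = apply_errors(seq, ErrorModel(0.0), rng)
        assert out == seq and pos == []

    def test_rate_one_every_base_differs(self, rng):
        seq = "ACGT" * 19
        out, pos = apply_errors(seq, ErrorModel(1.0), rng)
        assert all(a != b for a, b in zip(seq, out))
        assert pos == list(range(1, 77))

    def test_substitution_count_within_binomial_bound(self, rng):
        n_reads, L, rate = 10_000, 76, 0.01
        total = 0
        seq = "ACGT" * 19
        model = ErrorModel(rate)
        for _ in range(n_reads):
            _, pos = apply_errors(seq, model, rng)
            total += len(pos)
        n = n_reads * L
        assert abs(total - n * rate) < 3 * math.sqrt(n * rate * (1 - rate))

    def test_positions_match_sequence_diff(self, rng):
        seq = "ACGT" * 19
        out, pos = apply_errors(seq, ErrorModel(0.05), rng)
        diffs = [i + 1 for i, (a, b) in enumerate(zip(seq, out)) if a != b]
        assert diffs == pos


class TestSimulateReads:
    def test_zero_error_reads_are_exact_substrings(self, small_simulation):
        profiles, dataset, transcripts = small_simulation
        for rec, truth in zip(dataset.reads, dataset.truth):
            tx = transcripts[truth.transcript_id]
            expected = tx[truth.start - 1 : truth.start - 1 + len(rec.seq)]
            if truth.strand == "-":
                expected = reverse_complement(expected)
            assert rec.seq == expected

    def test_species_proportions_within_binomial_bound(self):
        profiles = make_synthetic_transcriptome(2, 5, seed=21, abundance_exponent=0.0)
        profiles[0].abundance, profiles[1].abundance = 0.9, 0.1
        for p in profiles:
            assign_expression_zipf(p.transcripts, 1.0, seed=21)
        n = 100_000
        ds = simulate_reads(profiles, n, seed=21)
        counts = {p.species_id: 0 for p in profiles}
        for t in ds.truth:
            counts[t.species_id] += 1
        for p in profiles:
            se = math.sqrt(p.abundance * (1 - p.abundance) / n)
            assert abs(counts[p.species_id] / n - p.abundance) < 3 * se

    def test_paired_fixed_insert_geometry(self):
        tx = Transcript("t1", "sp1", "ACGT" * 50)
        tx.expression_weight = 1.0
        from metaeval.simulator import SpeciesProfile

        profile = SpeciesProfile("sp1", 1.0, [tx])
        ds = simulate_reads(
            [profile],
            200,
            paired=True,
            insert_model=InsertModel(mean=150.0, sd=0.0),
            seed=5,
        )
        by_id = {t.read_id: t for t in ds.truth}
        for t in ds.truth:
            if not t.read_id.endswith("/1"):
                continue
            mate = by_id[t.mate_of]
            assert abs(t.start - mate.start) == 150 - 76
            assert {t.strand, mate.strand} == {"+", "-"}

    def test_truth_table_round_trip(self, tmp_path, small_simulation):
        _, dataset, _ = small_simulation
        path = tmp_path / "truth.tsv"
        write_truth_table(dataset, path)
        back = read_truth_table(path)
        assert len(back) == len(dataset.truth)
        for a, b in zip(back, dataset.truth):
            assert (a.read_id, a.transcript_id, a.start, a.strand, a.error_positions) == (
                b.read_id, b.transcript_id, b.start, b.strand, b.error_positions
            )

    def test_truth_rows_match_reads_and_ids_unique(self, small_simulation):
        _, dataset, _ = small_simulation
        assert len(dataset.truth) == len(dataset.reads)
        ids = [r.id for r in dataset.reads]
        assert len(set(ids)) == len(ids)

    def test_deterministic_given_seed(self):
        profiles = make_synthetic_transcriptome(2, 4, seed=3)
        for p in profiles:
            assign_expression_zipf(p.transcripts, 1.0, seed=3)
        a = simulate_reads(profiles, 100, seed=9, error_model=ErrorModel(0.01))
        b = simulate_reads(profiles, 100, seed=9, error_model=ErrorModel(0.01))
        assert [r.seq for r in a.reads] == [r.seq for r in b.reads]

    def test_origin_histogram_matches_abundance_expression_product(self):
        """Chi-square GOF of read origins against abundance x (expression
        x length) sampling probabilities."""
        from scipy import stats

        profiles = make_synthetic_transcriptome(3, 10, length_dist=(300, 600), seed=31)
        for p in profiles:
            assign_expression_zipf(p.transcripts, 1.0, seed=31)
        n = 100_000
        ds = simulate_reads(profiles, n, seed=31)
        expected, observed = [], []
        counts: dict[str, int] = {}
        for t in ds.truth:
            counts[t.transcript_id] = counts.get(t.transcript_id, 0) + 1
        for p in profiles:
            w = np.array(
                [t.expression_weight * len(t.seq) for t in p.transcripts]
            )
            w = p.abundance * w / w.sum()
            for t, prob in zip(p.transcripts, w):
                expected.append(prob * n)
                observed.append(counts.get(t.transcript_id, 0))
        _, pval = stats.chisquare(observed, np.array(expected) * sum(observed) / sum(expected))
        assert pval > 0.001
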