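import numpy as np
import pytest

from metaeval import (
    ErrorModel,
    assign_expression_zipf,
    make_synthetic_transcriptome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_simulation():
    """Zero-error single-end simulation shared by downstream tests:
    3 species x 20 genes, 5,000 reads, fixed seed."""
    profiles = make_synthetic_transcriptome(
        3, 20, length_dist=(300, 1200), seed=101
    )
    for p in profiles:
        assign_expression_zipf(p.transcripts, 1.0, seed=101)
    dataset = simulate_reads(profiles, 5_000, seed=101)
    transcripts = {
        t.transcript_id: t.seq for p in profiles for t in p.transcripts
    }
    return profiles, dataset, transcripts


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
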