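import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amicoding.sequence_io import ParentSequences
from amicoding.synthetic import (
    CodonUsageTable,
    NoncodingModel,
    SyntheticGenomeSpec,
    generate_annotated_genome,
    generate_coding_parent,
    generate_noncoding_parent,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_genome():
    """A small annotated synthetic genome with genes on both strands."""
    spec = SyntheticGenomeSpec(
        species_id="toy", n_genes=15, gene_length_range=(120, 600),
        intergenic_length_range=(80, 400), seed=3,
    )
    return spec, generate_annotated_genome(spec)


@pytest.fixture(scope="session")
def bench_parents():
    """Species-A benchmark parents: biased coding vs AT-rich noncoding.

    520 kb per class supports 500 non-overlapping windows up to 1000 bp
    (plus the 3000 bp centroid analysis at reduced counts).
    """
    table = CodonUsageTable.biased()
    model = NoncodingModel.at_rich()
    return ParentSequences(
        "synthA",
        generate_coding_parent(table, 520_000, seed=101),
        generate_noncoding_parent(model, 520_000, seed=102),
    )


@pytest.fixture(scope="session")
def bench_parents_sibling():
    """Species B: same codon table and noncoding family, independent draws."""
    table = CodonUsageTable.biased()
    model = NoncodingModel.at_rich()
    return ParentSequences(
        "synthB",
        generate_coding_parent(table, 220_000, seed=201),
        generate_noncoding_parent(model, 220_000, seed=202),
    )


@pytest.fixture(scope="session")
def random_sequences():
    """100 random sequences (lengths 30-500, mixed composition, some Ns)."""
    rng = np.random.default_rng(42)
    seqs = []
    for _ in range(100):
        L = int(rng.integers(30, 501))
        base_probs = rng.dirichlet(np.ones(4) * 2)
        n_rate = rng.uniform(0.0, 0.1)
        probs = np.r_[base_probs * (1 - n_rate), n_rate]
        seqs.append("".join(rng.choice(list("ACGTN"), size=L, p=probs)))
    return seqs
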