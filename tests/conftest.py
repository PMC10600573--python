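import numpy as np
import pandas as pd
import pytest

from promoterforge import parts, rank, simulate


@pytest.fixture(scope="session")
def count_fixture():
    return simulate.gen_counts(simulate.CountSpec(), seed=101)


@pytest.fixture(scope="session")
def genome_fixture():
    pwms = simulate.gen_motifs(2, 8, seed=3)
    spec = simulate.GenomeSpec(
        planted_restriction=[(2, "terminator", "BsaI"), (4, "promoter", "BbsI")],
        planted_motifs=[(0, 120, pwms[0].consensus())],
    )
    fx = simulate.gen_genome_annotation(spec, seed=5)
    return fx, pwms


@pytest.fixture(scope="session")
def annotation(genome_fixture, tmp_path_factory):
    fx, _ = genome_fixture
    d = tmp_path_factory.mktemp("genome")
    fx.write(d / "genome.fa", d / "annotation.gff3")
    models, genome = parts.read_annotation(d / "annotation.gff3", d / "genome.fa")
    return models, genome


@pytest.fixture(scope="session")
def small_counts():
    """Tiny hand-checkable count matrix."""
    df = pd.DataFrame(
        {"S1": [10, 20, 5, 100], "S2": [20, 40, 10, 200]},
        index=["g1", "g2", "g3", "g4"],
    )
    return rank.CountMatrix(df)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
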