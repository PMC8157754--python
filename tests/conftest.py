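import numpy as np
import pytest

from imescan.annotation_io import Gene, GenomeAnnotation, Transcript
from imescan.synthetic_data import simulate_corpus


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """Desk-scale synthetic corpus shared across tests (seed-fixed)."""
    out = tmp_path_factory.mktemp("corpus")
    paths, truth = simulate_corpus(
        out, seed=7, n_genes=120, n_accessions=100, n_conditions=150
    )
    return paths, truth


@pytest.fixture(scope="session")
def null_corpus(tmp_path_factory):
    """Corpus with no planted expression structure (loading = shift = 0)."""
    out = tmp_path_factory.mktemp("null_corpus")
    paths, truth = simulate_corpus(
        out,
        seed=13,
        n_genes=120,
        n_accessions=60,
        n_conditions=150,
        latent_loading=0.0,
        level_shift=0.0,
        low_expr_frac=0.0,
    )
    return paths, truth


@pytest.fixture()
def toy_annotation():
    """One plus- and one minus-strand gene with identical exon layouts.

    Exons at 1-100, 201-300, 401-500 (1-based inclusive), i.e. 0-based
    half-open (0,100), (200,300), (400,500); gaps (100,200) and (300,400).
    """
    exons = [(0, 100), (200, 300), (400, 500)]
    plus = Gene("gplus", "chrT", "+", [Transcript("gplus.1", exons, [(0, 20)], [(20, 100)])])
    minus = Gene("gminus", "chrT", "-", [Transcript("gminus.1", exons, [(480, 500)], [(400, 480)])])
    return GenomeAnnotation([plus, minus])


@pytest.fixture()
def toy_fasta(tmp_path):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    path = tmp_path / "toy.fa"
    path.write_text(f">chrT\n{seq}\n")
    return path, seq
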