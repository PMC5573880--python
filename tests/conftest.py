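import pytest

from unitrans import orf_lncrna, sim


@pytest.fixture(scope="session")
def dataset20():
    """20 simulated genes, error-free, with truth tables."""
    return sim.simulate_dataset(20, seed=101)


@pytest.fixture(scope="session")
def hexamer_table():
    coding = [sim.random_coding_mrna(10_000 + i, n_codons=250) for i in range(30)]
    noncoding = [sim.random_noncoding_rna(20_000 + i, length=700) for i in range(30)]
    return orf_lncrna.train_hexamer_tables(coding, noncoding)
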