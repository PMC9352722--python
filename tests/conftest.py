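import pytest

from rloopscape import gc_skew, peak_hmm
from rloopscape import simulate as sim


@pytest.fixture(scope="session")
def toy_sim():
    """Full-size (2 Mb) synthetic dataset at default parameters."""
    return sim.simulate(sim.SimConfig(seed=1))


@pytest.fixture(scope="session")
def toy_called_peaks(toy_sim):
    """Peaks called on the toy dataset with the toy-scale bin width."""
    return peak_hmm.call_peaks_from_tracks(
        [toy_sim.drip], toy_sim.chrom_sizes, bin_size=100
    )


@pytest.fixture(scope="session")
def toy_skew_classes(toy_sim):
    model = gc_skew.make_model("stringent")
    return gc_skew.classify_genes(toy_sim.genome, toy_sim.genes, model)


@pytest.fixture
def small_config():
    """Scaled-down simulation for fast unit-level checks."""
    return sim.SimConfig(
        seed=7, genome_size=400_000, n_genes=40, n_rdc_genes=2,
        n_tss_junction_genes=8,
    )
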