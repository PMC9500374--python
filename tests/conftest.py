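import pytest

from doublesub.parsimony import TripletAlignment
from doublesub.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def toy_alignment():
    """Three codons; in1 carries one single (codon 2) and in2 one double (codon 3)."""
    # codon1 identity; codon2: single AAG->AAA on in1; codon3: double GGG->GCC on in2
    return TripletAlignment(
        "toy1",
        "CTT" + "AAA" + "GGG",
        "CTT" + "AAG" + "GCC",
        "CTT" + "AAG" + "GGG",
    )


@pytest.fixture
def small_dataset():
    cfg = SimulationConfig(n_genes=8, codons_per_gene=60, seed=11)
    return simulate_dataset(cfg)
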