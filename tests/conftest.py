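import pytest

from sealdiet.refdb import ReferenceDB, ReferenceEntry
from sealdiet.synthetic import SimulationConfig


@pytest.fixture
def toy_refdb():
    """Four well-separated random-ish species plus two sharing a haplotype
    (rockfishes indistinguishable at the marker)."""
    seqs = {
        "Clupea_pallasii": "ATGCATGCATGCATGCATGCATGCATGC",
        "Merluccius_productus": "TTTTGGGGCCCCAAAATTTTGGGGCCCC",
        "Sebastes_caurinus": "ACGTACGTACGTACGTACGTACGTACGT",
        "Sebastes_maliger": "ACGTACGTACGTACGTACGTACGTACGT",  # identical
        "Oncorhynchus_kisutch": "GGCCGGCCGGCCGGCCGGCCGGCCGGCC",
    }
    return ReferenceDB(
        [ReferenceEntry(sp, sp.replace("_", " "), s) for sp, s in seqs.items()]
    )


@pytest.fixture
def small_config():
    return SimulationConfig(n_samples=8, reads_per_sample=400, seed=11)
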