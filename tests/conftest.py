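import numpy as np
import pytest

from cyanocore.clogs import ClogTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_table():
    """Five genomes: 2 core CLOGs, 2 dispensable, 2 unique (one multi-seq)."""
    genomes = ["A", "B", "C", "D", "E"]
    clogs = {
        "core1": [(g, f"{g.lower()}1") for g in genomes],
        "core2": [(g, f"{g.lower()}2") for g in genomes] + [("A", "a2b")],
        "disp1": [("A", "a3"), ("B", "b3")],
        "disp2": [("B", "b4"), ("C", "c4"), ("D", "d4")],
        "uniq1": [("E", "e5")],
        "uniq2": [("A", "a6"), ("A", "a7")],
    }
    return ClogTable(clogs, genome_universe=genomes)
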