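import numpy as np
import pytest

from mena.io import AbundanceTable


@pytest.fixture
def tiny_table():
    """3 OTUs x 2 samples with taxonomy and group labels."""
    return AbundanceTable(
        otu_ids=["OTU1", "OTU2", "OTU3"],
        sample_ids=["S1", "S2"],
        counts=np.array([[2, 4], [3, 5], [5, 11]]),
        taxonomy=[
            "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria",
            "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria",
            "k__Bacteria; p__Bacteroidetes; c__Flavobacteriia",
        ],
        groups={"S1": "Control", "S2": "PM"},
    )


@pytest.fixture
def small_planted_design():
    """Planted design scaled for fast tests: 4 modules of 30, 20% noise."""
    from mena.simulate import PlantedDesign
    return PlantedDesign(n_otus=150, module_sizes=(30, 30, 30, 30),
                        n_samples=50, seed=0)
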