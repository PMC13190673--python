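import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phytocompare.io import AsvTable

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_asv():
    """Two samples, three community ASVs and one spike."""
    counts = pd.DataFrame(
        [[10, 30, 0, 60], [5, 5, 10, 40]],
        index=pd.Index(["S1", "S2"], name="sample_id"),
        columns=["A1", "A2", "A3", "SPK1"],
        dtype=np.int64,
    )
    return AsvTable(counts, ("SPK1",))


@pytest.fixture
def small_metadata():
    return pd.DataFrame(
        {
            "station": ["ST1", "ST1"],
            "basin": ["Kattegat", "Kattegat"],
            "volume_filtered": [0.2, 0.5],
            "dna_concentration": [2.0, 4.0],
            "spike_molecules": [1e4, 5e3],
        },
        index=pd.Index(["S1", "S2"], name="sample_id"),
    )


@pytest.fixture
def taxonomy_frame():
    from phytocompare.taxonomy import RANKS, UNASSIGNED

    rows = {
        "A1": ("TSAR", "Alveolata", "Dinoflagellata", "Dinophyceae",
               "Gymnodiniales", "Gymnodiniaceae", "Gyrodinium", "Gyrodinium_sp"),
        "A2": ("Cryptista", "Cryptophyta", "Cryptophytina", "Cryptophyceae",
               "Cryptomonadales", "Teleaulacaceae", "Teleaulax", "Teleaulax_amphioxeia"),
        "A3": ("TSAR", "Stramenopiles", "Gyrista", "Mediophyceae",
               "Thalassiosirales", "Thalassiosiraceae", "Thalassiosira", UNASSIGNED),
        "SPK1": (UNASSIGNED,) * 8,
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)).rename_axis("asv_id")
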