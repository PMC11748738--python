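import numpy as np
import pandas as pd
import pytest

from strepclades import SpeciesTable, CladeMap


LINEAGE_STREP = (
    "d__Bacteria|p__Bacillota|c__Bacilli|o__Lactobacillales|"
    "f__Streptococcaceae|g__Streptococcus|s__Streptococcus {sp}"
)
LINEAGE_OTHER = (
    "d__Bacteria|p__Bacteria_p|c__Bacteria_c|o__Bacteria_o|"
    "f__{genus}aceae|g__{genus}|s__{genus} {sp}"
)


def strep_lineage(species_epithet: str) -> str:
    return LINEAGE_STREP.format(sp=species_epithet)


def other_lineage(genus: str, species_epithet: str) -> str:
    return LINEAGE_OTHER.format(genus=genus, sp=species_epithet)


@pytest.fixture
def tiny_table() -> SpeciesTable:
    """3 Streptococcus species (one clade each) + 1 other-genus species."""
    counts = pd.DataFrame(
        {
            "s1": [30, 60, 10, 900],
            "s2": [100, 0, 0, 0],
        },
        index=[
            strep_lineage("sanguinis"),
            strep_lineage("mitis"),
            strep_lineage("anginosus"),
            other_lineage("Veillonella", "parvula"),
        ],
    )
    return SpeciesTable(counts)


@pytest.fixture
def tiny_clades() -> CladeMap:
    return CladeMap(
        {
            "Streptococcus sanguinis": "Sanguinis",
            "Streptococcus mitis": "Mitis",
            "Streptococcus anginosus": "Anginosus",
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
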