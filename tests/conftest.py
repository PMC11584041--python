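import numpy as np
import pytest

from trioecy import (
    CANONICAL_FEMALE,
    FITTED_MAP,
    INDEPENDENT_MAP,
    PlantGenotype,
    RecombinationMap,
)
from trioecy.genetics import HAPLOTYPES, Cytotype


@pytest.fixture
def fitted_map() -> RecombinationMap:
    """The linked map inferred from the cross data: r12=0.11, r23=0.26."""
    return FITTED_MAP


@pytest.fixture
def independent_map() -> RecombinationMap:
    return INDEPENDENT_MAP


@pytest.fixture
def canonical_female() -> PlantGenotype:
    return CANONICAL_FEMALE


def all_genotypes():
    """All 72 genotypes: unordered haplotype pairs x cytotypes."""
    out = []
    for i, a in enumerate(HAPLOTYPES):
        for b in HAPLOTYPES[i:]:
            for cyto in (Cytotype.S, Cytotype.N):
                out.append(PlantGenotype(a, b, cyto))
    return out
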