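import pytest

from gorillakin.genodata import (
    AlleleFrequencyTable,
    GenotypeTable,
    Individual,
)
from gorillakin.simdata import SimulationConfig, founder_frequency_table


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def founder_freqs(sim_config) -> AlleleFrequencyTable:
    """One fixed realization of the default founder frequency spec."""
    return founder_frequency_table(sim_config, seed=1)


@pytest.fixture()
def biallelic_half() -> AlleleFrequencyTable:
    """Single biallelic locus at p = (0.5, 0.5)."""
    return AlleleFrequencyTable({"L1": {100: 0.5, 101: 0.5}}, {"L1": 1000})


def make_table(genotypes_by_id, loci, meta=None):
    """Small helper: build a GenotypeTable from {id: {locus: pair|None}}."""
    meta = meta or {}
    inds = [Individual(id=i, **meta.get(i, {})) for i in genotypes_by_id]
    gts = {}
    for iid, by_locus in genotypes_by_id.items():
        for loc in loci:
            g = by_locus.get(loc)
            gts[(iid, loc)] = None if g is None else tuple(sorted(g))
    return GenotypeTable(inds, list(loci), gts)


@pytest.fixture()
def trio_table() -> GenotypeTable:
    """Three individuals, two loci, one missing genotype."""
    return make_table(
        {
            "a": {"L1": (100, 102), "L2": (200, 200)},
            "b": {"L1": (100, 100), "L2": (200, 202)},
            "c": {"L1": (102, 104), "L2": None},
        },
        ["L1", "L2"],
        meta={
            "a": {"sex": "female", "group_id": "G1", "country": "A"},
            "b": {"sex": "male", "role": "silverback", "group_id": "G1", "country": "A"},
            "c": {"sex": "female", "group_id": "G2", "country": "B"},
        },
    )
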