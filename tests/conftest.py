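from __future__ import annotations

import numpy as np
import pytest

from mesodiv.occurrences import Collection, Occurrence, TaxonRank, TimeBin


@pytest.fixture
def jurassic_bins():
    return [
        TimeBin("Rhaetian", 208.5, 201.4),
        TimeBin("Hettangian", 201.4, 199.3),
        TimeBin("Sinemurian", 199.3, 192.9),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_occurrence(
    occ_id="o1",
    coll_id="c1",
    name="Thomasia hahni",
    rank=TaxonRank.species,
    lineage=("Haramiyidae", "Haramiyida", "Mammalia"),
    group=None,
):
    return Occurrence(occ_id, coll_id, name, rank, tuple(lineage), group)


def make_collection(coll_id="c1", lat=45.0, lon=10.0, max_ma=205.0, min_ma=202.0):
    return Collection(coll_id, lat, lon, max_ma, min_ma)


@pytest.fixture
def occ_factory():
    return make_occurrence


@pytest.fixture
def coll_factory():
    return make_collection
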