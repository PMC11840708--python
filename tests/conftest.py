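import numpy as np
import pytest

from planctostrat import (
    AsvTable,
    CommunityConfig,
    DistanceMatrix,
    RankedTaxonomy,
    SequenceRecord,
    make_community,
    make_random_reference,
    parse_taxonomy_string,
)


@pytest.fixture(scope="session")
def reference_1200():
    return make_random_reference(1200, seed=11)


@pytest.fixture(scope="session")
def community():
    """Default depth-stratified synthetic community (pools 10/10/40/40)."""
    return make_community(CommunityConfig(seed=42))


@pytest.fixture()
def small_table():
    """Tiny hand-written 4-sample, 3-ASV table."""
    tax = {
        "asv1": parse_taxonomy_string("Bacteria;Planctomycetota;Planctomycetia"),
        "asv2": parse_taxonomy_string("Bacteria;Planctomycetota;Phycisphaerae"),
        "asv3": parse_taxonomy_string("Bacteria;Proteobacteria"),
    }
    table = AsvTable(
        sample_ids=["s1", "s2", "s3", "s4"],
        asv_ids=["asv1", "asv2", "asv3"],
        counts=np.array([
            [10, 0, 90],
            [5, 5, 90],
            [0, 20, 80],
            [30, 30, 40],
        ]),
        layer_of={"s1": "surface", "s2": "dcm", "s3": "below_dcm",
                  "s4": "mesopelagic"},
    )
    return table, tax


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    m = rng.random((n, n))
    d = (m + m.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=[f"s{i}" for i in range(n)], d=d)
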