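from fractions import Fraction

import pytest

from biopotency import io as bio_io
from biopotency.ledger import MaterialNode, PurificationTree


@pytest.fixture(scope="session")
def extracts_tree() -> PurificationTree:
    return bio_io.grey_myrtle_extracts()


@pytest.fixture(scope="session")
def fractions_tree() -> PurificationTree:
    return bio_io.grey_myrtle_fractions()


SEQUENTIAL_IDS = ["hexane_seq", "dcm_seq", "etoac_seq", "etoh_seq", "meoh_seq", "water_seq"]

FRACTION_IDS = [f"f{i:02d}" for i in range(1, 18)]


def exact_tba_l(node: MaterialNode) -> Fraction:
    """Independent high-precision TBA: exact rational EDV50 x weight.

    Deliberately bypasses the ledger code path (no PotencyEstimate.edv50,
    no compute_tba) so it can serve as a brute-force oracle.
    """
    assert node.potency is not None and node.weight_g is not None
    return Fraction(node.weight_g) / Fraction(node.potency.ic50)
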