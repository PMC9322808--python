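import numpy as np
import pytest

from ecbscreen.chem import Compound
from ecbscreen.targets import (
    ActivityTable,
    TargetProtein,
    build_homology_graph,
)

FP_LEN = 64


def _random_compound(cid: str, rng: np.random.Generator, length: int = FP_LEN) -> Compound:
    fp = (rng.random(length) < 0.3).astype(np.uint8)
    if fp.sum() == 0:
        fp[int(rng.integers(length))] = 1
    return Compound(cid, "", fp, source="synthetic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_identity():
    # T1-T2 homologous above the 0.5 threshold; T3 unrelated.
    return {
        frozenset(("T1", "T2")): 0.6,
        frozenset(("T1", "T3")): 0.2,
        frozenset(("T2", "T3")): 0.1,
    }


@pytest.fixture
def toy_graph(toy_identity):
    targets = [TargetProtein(t) for t in ("T1", "T2", "T3")]
    return build_homology_graph(
        targets,
        identity_source="identity_table",
        threshold=0.5,
        identity_table=toy_identity,
    )


@pytest.fixture
def toy_activities():
    return ActivityTable(
        [
            ("c1", "T1", True),
            ("c2", "T1", True),
            ("c3", "T2", True),
            ("c4", "T3", True),
        ]
    )


@pytest.fixture
def toy_compounds(rng):
    return [_random_compound(cid, rng) for cid in ("c1", "c2", "c3", "c4")]
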