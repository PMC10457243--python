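import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from plasmidnet import (
    IteronSpec,
    MobModuleSpec,
    PlasmidRecord,
    RepModuleSpec,
    generate_plasmid,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def random_dna():
    def make(length: int, seed: int = 0, gc: float = 0.5) -> str:
        r = np.random.default_rng(seed)
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(r.choice(list("ACGT"), size=length, p=p))

    return make


@pytest.fixture
def small_plasmid() -> tuple[PlasmidRecord, object]:
    """A 5-kb circular plasmid with a perfect 22-bp x4 iteron array, a rep
    gene and a mob gene."""
    return generate_plasmid(
        5000,
        0.40,
        rep=RepModuleSpec(iterons=IteronSpec(unit_length=22, copies=4)),
        mob=MobModuleSpec(),
        seed=42,
        plasmid_id="pSYN1",
    )
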