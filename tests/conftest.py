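import pytest

import trajstore as ts
from trajstore.fixtures import (deposit_random_walk, deposit_replica_exchange,
                                make_toy_system)


@pytest.fixture
def store():
    with ts.connect(":memory:") as s:
        yield s


@pytest.fixture
def toy_system():
    return make_toy_system(n_chains=2, chain_length=3, seed=7)


@pytest.fixture
def walk_db():
    """A store holding one deposited random-walk trajectory."""
    with ts.connect(":memory:") as s:
        ens_id, pair = deposit_random_walk(
            s, "TOY_WALK", n_chains=2, chain_length=3, n_frames=12, seed=11)
        yield s, ens_id, pair


@pytest.fixture
def remd_db():
    """A store holding a 4-replica synthetic replica-exchange ensemble."""
    with ts.connect(":memory:") as s:
        ens_id, pairs, schedule = deposit_replica_exchange(
            s, "TOY_REMD", n_replicas=4, n_frames=20, swap_every=5, seed=13)
        yield s, ens_id, pairs, schedule
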