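import random

import pytest

from cophymap import SimParams, Tanglegram, generate_instance
from cophymap.formats import read_tanglegram


def make_tanglegram(host_nwk: str, parasite_nwk: str, links: dict) -> Tanglegram:
    assoc = "\n".join(f"{p}\t{h}" for p, h in links.items())
    return read_tanglegram(host_nwk, parasite_nwk, assoc)


@pytest.fixture
def congruent3():
    return make_tanglegram(
        "((A,B),C);", "((a,b),c);", {"a": "A", "b": "B", "c": "C"}
    )


@pytest.fixture
def loss_instance():
    # optimal: codivergence at the root plus one loss on the (A,B) side
    return make_tanglegram("((A,B),C);", "(a,c);", {"a": "A", "c": "C"})


@pytest.fixture
def chain5_switch():
    # long climb on one side: a single host switch beats three losses
    return make_tanglegram(
        "((((A,B),C),D),E);", "(a,e);", {"a": "A", "e": "E"}
    )


@pytest.fixture
def small_instances():
    """A deterministic batch of small synthetic tanglegrams."""
    out = []
    for i in range(40):
        params = SimParams(n_host_leaves=4 + (i % 5), rng_seed=i)
        out.append(generate_instance(params))
    return out


@pytest.fixture
def rng():
    return random.Random(20240917)
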