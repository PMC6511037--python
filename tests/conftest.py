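import random

import pytest

from netclone import (
    CloneState,
    CostParams,
    SynapseSet,
    generate_er,
    network_to_pairs,
)


@pytest.fixture
def small_net():
    return generate_er(12, 0.3, seed=42)


@pytest.fixture
def small_ensemble(small_net):
    return network_to_pairs(small_net)


def make_random_state(n_cells=8, density=0.3, seed=0, params=None):
    """Random target + random placement on the full tabula rasa."""
    rng = random.Random(seed)
    net = generate_er(n_cells, density, seed=seed)
    ens = network_to_pairs(net)
    syn = SynapseSet.full(n_cells)
    placement = [rng.randrange(len(syn)) for _ in ens.pairs]
    orientations = [rng.randrange(2) for _ in ens.pairs]
    return CloneState(ens, syn, placement, orientations, params or CostParams())


def make_oboc_state(net, perm, params=None):
    """Place each pair (mu, nu) forward on synapse (perm^-1 applied): cell
    perm[t] hosts type t, a One-Barcode-One-Cell arrangement."""
    n = net.n_cells
    ens = network_to_pairs(net)
    syn = SynapseSet.full(n)
    sid = {ab: i for i, ab in enumerate(syn.synapses)}
    placement = [sid[(perm[mu], perm[nu])] for mu, nu in ens.pairs]
    return CloneState(ens, syn, placement, [0] * len(ens), params or CostParams())


@pytest.fixture
def random_state():
    return make_random_state()
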