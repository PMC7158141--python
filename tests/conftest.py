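import pytest

from coreprune import synthetic as syn


@pytest.fixture
def chain():
    """Consistent 3-reaction linear pathway: uptake, conversion,
    secretion."""
    return syn.linear_chain()


@pytest.fixture
def dead_end():
    """Pathway ending in an unconsumed metabolite; fully blocked."""
    return syn.dead_end_chain()


@pytest.fixture
def irr_cycle():
    return syn.irreversible_two_cycle()


@pytest.fixture
def diamond_net():
    return syn.diamond()


@pytest.fixture
def mass_bad():
    return syn.mass_inconsistent_pair()


@pytest.fixture
def rev_cycle():
    return syn.reversible_two_cycle()


@pytest.fixture
def bridge_net():
    return syn.two_cycles_with_bridge()


def small_generated(seed: int, **overrides):
    """A generated network small enough for the FVA oracle."""
    params = dict(n_pathways=3, pathway_length=4, n_cross_links=2,
                  n_planted_deadends=2, reversible_fraction=0.3,
                  rng_seed=seed)
    params.update(overrides)
    return syn.generate_network(syn.GeneratorSpec(**params))
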