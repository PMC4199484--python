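import pytest

from likfill import fixtures as fx


@pytest.fixture(scope="session")
def universe():
    return fx.make_toy_universe(1)


@pytest.fixture(scope="session")
def reaction_likelihoods(universe):
    return universe.reaction_likelihoods()


@pytest.fixture(scope="session")
def draft(universe, reaction_likelihoods):
    return fx.make_draft_model(universe.genome, universe.template,
                               universe.universal, reaction_likelihoods, 0.5)


@pytest.fixture(scope="session")
def two_pathway_draft(draft, universe):
    """Draft missing both routes to the precursor p_c."""
    return fx.remove_reactions(draft, universe.long_path_ids)
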