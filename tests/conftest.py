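import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from syntrophyflux.fba import apply_proteome_atp_constraints, pfba, community_yield
from syntrophyflux.fixture import PROTEOME_SHARES, build_community_model
from syntrophyflux.synth import CommunityDesign, MagDesign, make_toy_networks, simulate_proteomics


@pytest.fixture(scope="session")
def community_model():
    return build_community_model()


@pytest.fixture(scope="session")
def constrained_model(community_model):
    return apply_proteome_atp_constraints(community_model, PROTEOME_SHARES)


@pytest.fixture(scope="session")
def community_solution(constrained_model):
    sol = pfba(constrained_model)
    assert sol.ok
    return sol


@pytest.fixture(scope="session")
def community_yield_summary(community_solution):
    return community_yield(community_solution)


@pytest.fixture(scope="session")
def toys():
    return make_toy_networks()


@pytest.fixture(scope="session")
def small_design():
    """Small, fast synthetic proteomics design (3 MAGs, 2 time points)."""
    return CommunityDesign(
        mags=(
            MagDesign("magA", 0.5, 60, 0.01),
            MagDesign("magB", 0.3, 60, 0.012),
            MagDesign("magC", 0.2, 60, 0.008),
        ),
        time_points_h=(24.0, 408.0),
        n_replicates=2,
        noise_cv=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_tables(small_design):
    return simulate_proteomics(small_design)
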