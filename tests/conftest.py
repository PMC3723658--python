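import pytest

from nestlingqg.cli import make_fixture
from nestlingqg.gibbs import MCMCSettings, ModelSpec, PriorSpec, build_design, run_gibbs

#: short chain for fixture-scale fits in unit tests
FAST = MCMCSettings(n_iterations=1200, burn_in=300, thinning=2, seed=11)


@pytest.fixture(scope="session")
def population():
    """Miniature deterministic cross-fostered population (6 dyads)."""
    return make_fixture(seed=1)


@pytest.fixture(scope="session")
def uni_samples(population):
    spec = ModelSpec(response="hue", form="univariate")
    return run_gibbs(build_design(population, spec), PriorSpec(), FAST)


@pytest.fixture(scope="session")
def bi_samples(population):
    spec = ModelSpec(response="hue", form="bivariate", fixed=("treatment", "year"))
    return run_gibbs(build_design(population, spec), PriorSpec(), FAST)
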