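import pytest

import rxnhasse as rh
from rxnhasse import families


@pytest.fixture(scope="session")
def lyase_reactions():
    return families.ec_4_1_3_42_reactions()


@pytest.fixture(scope="session")
def lyase_diagram(lyase_reactions):
    return rh.build_diagram(lyase_reactions)


@pytest.fixture(scope="session")
def lactate_reaction():
    return families.lactate_oxidation()


@pytest.fixture(scope="session")
def transaminase_diagram():
    return rh.build_diagram(families.transaminase_toy())


def family_diagram(n=3, depth=2, seed=0, **kw):
    """Build a diagram over a synthetic dehydrogenation family."""
    spec = families.FamilySpec(n_reactions=n, depth=depth, seed=seed, **kw)
    return rh.build_diagram(families.generate_family(spec))
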