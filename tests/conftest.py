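import networkx as nx
import pytest

from fuelkit.fixtures import (
    electron_carrier_fragment,
    fig1_2_fragment,
    fig3_fragment,
    fig4_fragment,
    fig5_fragment,
    generate_random,
    receptor_fragment,
)
from fuelkit.patterns import classify_fragment

ALL_FIXTURE_BUILDERS = {
    "fig1": fig1_2_fragment,
    "fig3": fig3_fragment,
    "fig4": fig4_fragment,
    "fig5": fig5_fragment,
    "receptor": receptor_fragment,
    "electron": electron_carrier_fragment,
}


@pytest.fixture
def fig1():
    return fig1_2_fragment()


@pytest.fixture
def fig3():
    return fig3_fragment()


@pytest.fixture
def fig4():
    return fig4_fragment()


@pytest.fixture
def fig5():
    return fig5_fragment()


@pytest.fixture
def fig5_classified():
    return classify_fragment(fig5_fragment()).fragment


@pytest.fixture
def receptor():
    return receptor_fragment()


@pytest.fixture
def receptor_classified():
    return classify_fragment(receptor_fragment()).fragment


@pytest.fixture(params=sorted(ALL_FIXTURE_BUILDERS))
def any_fixture(request):
    return ALL_FIXTURE_BUILDERS[request.param]()


def planted(seed, n=12, depth=3):
    return generate_random(seed, n, depth)


def reachability(fragment):
    """Upward-reachability sets (term -> ancestors incl. itself) of the is_a graph."""
    g = fragment.isa_graph()
    return {t: {t} | nx.descendants(g, t) for t in fragment.functions}
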