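import pytest

from linkentropy import Graph, fixture_three_triangles, fixture_karate, generate_barbell


@pytest.fixture(scope="session")
def three_triangles():
    return fixture_three_triangles()


@pytest.fixture(scope="session")
def karate():
    return fixture_karate()


@pytest.fixture
def triangle():
    return Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    return Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def two_triangles():
    """Two disjoint triangles: block-diagonal adjacency with an exact
    rank-2 indicator factorization."""
    return Graph([(1, 2), (1, 3), (2, 3), (4, 5), (4, 6), (5, 6)])


@pytest.fixture
def barbell3():
    return generate_barbell(3)
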