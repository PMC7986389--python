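import pytest

from fvsnet import WeightedDigraph, WeightTable


@pytest.fixture
def triangle():
    """3-cycle a -> b -> c -> a with weights 1, 2, 3."""
    return WeightedDigraph(
        arcs=[("a", "b"), ("b", "c"), ("c", "a")],
        weights={"a": 1.0, "b": 2.0, "c": 3.0},
    )


@pytest.fixture
def two_triangles():
    """Two vertex-disjoint 3-cycles."""
    return WeightedDigraph(
        arcs=[("a", "b"), ("b", "c"), ("c", "a"),
              ("x", "y"), ("y", "z"), ("z", "x")]
    )


@pytest.fixture
def dag():
    """A small acyclic graph: a -> b -> c, a -> c."""
    return WeightedDigraph(arcs=[("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def shared_hub():
    """Two 2-cycles sharing hub b (a<->b, b<->c); Fig-6-shaped topology."""
    return WeightedDigraph(
        arcs=[("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")],
        weights={"a": -2.0, "b": -20.0, "c": -2.0},
    )


@pytest.fixture
def table():
    return WeightTable(entries={"a": 1.0, "b": 2.0})
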