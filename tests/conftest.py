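import pytest

from famtree.pedigree import PedigreeGraph, Person


def build_graph(persons, parent_edges=(), spouse_edges=()):
    g = PedigreeGraph()
    for p in persons:
        g.add_person(Person(*p) if isinstance(p, tuple) else p)
    for e in parent_edges:
        g.add_parent_edge(*e)
    for a, b in spouse_edges:
        g.add_spouse_edge(a, b)
    return g


@pytest.fixture
def nuclear_family():
    """Father, mother, an older daughter and a younger son."""
    return build_graph(
        [("dad", "M", 1960), ("mum", "W", 1962),
         ("daughter", "W", 1988), ("son", "M", 1990)],
        parent_edges=[("dad", "daughter"), ("dad", "son"),
                      ("mum", "daughter"), ("mum", "son")],
        spouse_edges=[("dad", "mum")],
    )


@pytest.fixture
def chain6():
    """Six-generation single line of descent g1 -> ... -> g6."""
    persons = [(f"g{i}", "M" if i % 2 else "W", 1900 + 25 * i)
               for i in range(1, 7)]
    edges = [(f"g{i}", f"g{i + 1}") for i in range(1, 6)]
    return build_graph(persons, parent_edges=edges)


@pytest.fixture
def cousin_pedigree():
    """Grandparents, two married sons, one child each: first cousins."""
    return build_graph(
        [("gf", "M", 1930), ("gm", "W", 1932),
         ("f1", "M", 1955), ("f2", "M", 1958),
         ("w1", "W", 1956), ("w2", "W", 1959),
         ("c1", "M", 1985), ("c2", "W", 1987)],
        parent_edges=[("gf", "f1"), ("gm", "f1"), ("gf", "f2"), ("gm", "f2"),
                      ("f1", "c1"), ("w1", "c1"), ("f2", "c2"), ("w2", "c2")],
        spouse_edges=[("gf", "gm"), ("f1", "w1"), ("f2", "w2")],
    )
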