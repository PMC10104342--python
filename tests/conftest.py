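"""Shared fixtures: small reusable models and an independent cycle oracle."""

import itertools

import pytest

from dagforge import NodeRef, NodeSpec, SimulationConfig, build_graph
from dagforge.examples.coin_toss import coin_toss_sequence
from dagforge.stdlib import randint, uniform


def const(value):
    """A literal-valued node function (module-level, so YAML-serializable)."""
    return value


def add_one(x):
    return x + 1


def coin_toss_specs():
    return [
        NodeSpec("ProbHeads", uniform, {"low": 0.0, "high": 1.0}),
        NodeSpec("NumTosses", randint, {"low": 10, "high": 20}),
        NodeSpec(
            "Sequence",
            coin_toss_sequence,
            {"p_heads": NodeRef("ProbHeads"), "n_tosses": NodeRef("NumTosses")},
        ),
    ]


@pytest.fixture
def coin_graph():
    return build_graph(coin_toss_specs(), name="coin_toss")


@pytest.fixture
def config_factory(tmp_path):
    def make(n_samples, seed=0, **kwargs):
        kwargs.setdefault("output_dir", tmp_path)
        return SimulationConfig(n_samples=n_samples, seed=seed, **kwargs)

    return make


def brute_force_has_cycle(n_vertices: int, edges: set) -> bool:
    """Independent cycle oracle: does any vertex sequence form a directed
    cycle? Exhaustive DFS with an explicit color map, no library calls."""
    adjacency = {v: [] for v in range(n_vertices)}
    for u, v in edges:
        adjacency[u].append(v)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {v: WHITE for v in range(n_vertices)}

    def visit(v):
        color[v] = GRAY
        for w in adjacency[v]:
            if color[w] == GRAY:
                return True
            if color[w] == WHITE and visit(w):
                return True
        color[v] = BLACK
        return False

    return any(visit(v) for v in range(n_vertices) if color[v] == WHITE)


def all_digraphs(n_vertices: int):
    """All labelled digraphs on n vertices without self-loops, as edge sets."""
    pairs = [
        (u, v)
        for u, v in itertools.product(range(n_vertices), repeat=2)
        if u != v
    ]
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        yield {pair for pair, bit in zip(pairs, bits) if bit}


def graph_from_edges(n_vertices: int, edges: set):
    """Build dagforge specs realizing an edge set: node i's function takes
    one kwarg per in-edge bound to the parent node."""
    names = [f"n{i}" for i in range(n_vertices)]
    specs = []
    for i in range(n_vertices):
        parents = sorted(u for u, v in edges if v == i)
        kwargs = {f"p{u}": NodeRef(names[u]) for u in parents}
        specs.append(NodeSpec(names[i], const_many, kwargs))
    return specs


def const_many(**kwargs):
    return 0
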