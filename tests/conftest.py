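from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from haplosample import (
    OrientedNode,
    PangenomeGraph,
    Path,
    build_panel_graph,
    simulate_panel,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_linear_graph(labels: list[str], with_hap: bool = True) -> PangenomeGraph:
    """Linear chain 1-2-...-n with a reference path (and a haplotype copy)."""
    g = PangenomeGraph()
    ids = [str(i + 1) for i in range(len(labels))]
    for nid, lab in zip(ids, labels):
        g.add_node(nid, lab)
    for a, b in zip(ids, ids[1:]):
        g.add_edge((a, "R"), (b, "L"))
    steps = tuple(OrientedNode(i) for i in ids)
    g.add_path(Path("ref", steps, is_reference=True))
    if with_hap:
        g.add_path(Path("hap000#0#chr1", steps, is_reference=False))
    return g


def make_bubble_graph() -> PangenomeGraph:
    """A -> (B | C) -> D bubble with two haplotypes and a reference via B."""
    g = PangenomeGraph()
    for nid, lab in [("A", "ACGTA"), ("B", "CTTGA"), ("C", "GTTCA"), ("D", "TGCAT")]:
        g.add_node(nid, lab)
    for a, b in [("A", "B"), ("A", "C")]:
        g.add_edge((a, "R"), (b, "L"))
    for a, b in [("B", "D"), ("C", "D")]:
        g.add_edge((a, "R"), (b, "L"))
    mk = lambda *ids: tuple(OrientedNode(i) for i in ids)
    g.add_path(Path("ref", mk("A", "B", "D"), is_reference=True))
    g.add_path(Path("hapB#0#c", mk("A", "B", "D"), is_reference=False))
    g.add_path(Path("hapC#0#c", mk("A", "C", "D"), is_reference=False))
    return g


@pytest.fixture(scope="session")
def small_panel():
    truth = simulate_panel(length=20_000, n_haplotypes=6, seed=42)
    return truth, build_panel_graph(truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)
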