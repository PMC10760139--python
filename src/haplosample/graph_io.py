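"""Bidirected sequence graphs with embedded haplotype paths.

The data model follows the pangenome convention: nodes carry DNA
sequences, undirected edges join *node sides*, and named oriented paths
spell haplotypes.  A forward traversal of a node enters its left side,
reads the label, and exits the right side; a reverse traversal enters the
right side and reads the reverse complement.

GFA 1.0/1.1 subset supported: S, L (overlap ``0M`` or ``*``), P and W
records.  P records are treated as reference paths, W records as
haplotype paths named ``sample#haplotype#contig``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx

__all__ = [
    "OrientedNode",
    "Path",
    "PangenomeGraph",
    "GFAError",
    "GraphError",
    "parse_gfa",
    "write_gfa",
    "clip_to_single_chain",
    "induced_subgraph",
    "reverse_complement",
]

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_RC_TABLE)[::-1]


class GraphError(ValueError):
    """Invalid graph structure or query."""


class GFAError(GraphError):
    """Malformed or referentially inconsistent GFA input."""


class OrientedNode(NamedTuple):
    """A node traversal: node identifier plus orientation."""

    node_id: str
    is_reverse: bool = False

    def flip(self) -> "OrientedNode":
        return OrientedNode(self.node_id, not self.is_reverse)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.node_id + ("-" if self.is_reverse else "+")


#: A node side: (node id, "L" | "R").
Side = tuple[str, str]


def entry_side(step: OrientedNode) -> Side:
    """Side through which a traversal enters the node."""
    return (step.node_id, "R" if step.is_reverse else "L")


def exit_side(step: OrientedNode) -> Side:
    """Side through which a traversal exits the node."""
    return (step.node_id, "L" if step.is_reverse else "R")


def edge_key(a: Side, b: Side) -> tuple[Side, Side]:
    """Canonical (sorted) representation of an undirected edge."""
    return (a, b) if a <= b else (b, a)


def step_edge(u: OrientedNode, v: OrientedNode) -> tuple[Side, Side]:
    """The edge joining two consecutive path steps."""
    return edge_key(exit_side(u), entry_side(v))


@dataclass(frozen=True)
class Path:
    """A named oriented walk through the graph."""

    name: str
    steps: tuple[OrientedNode, ...]
    is_reference: bool = False

    def reversed(self) -> "Path":
        return Path(self.name, tuple(s.flip() for s in reversed(self.steps)), self.is_reference)


class PangenomeGraph:
    """Bidirected sequence graph with embedded haplotype/reference paths."""

    def __init__(self) -> None:
        self.nodes: dict[str, str] = {}
        self.edges: set[tuple[Side, Side]] = set()
        self.paths: dict[str, Path] = {}
        self._adj: dict[Side, set[tuple[Side, Side]]] = {}

    # -- construction -------------------------------------------------

    def add_node(self, node_id: str, sequence: str) -> None:
        if node_id in self.nodes:
            raise GFAError(f"duplicate segment id {node_id!r}")
        if not sequence:
            raise GraphError(f"segment {node_id!r} has an empty sequence")
        if not re.fullmatch(r"[ACGTNacgtn]+", sequence):
            raise GraphError(f"segment {node_id!r} has a non-ACGTN sequence")
        self.nodes[node_id] = sequence.upper()

    def add_edge(self, a: Side, b: Side) -> None:
        for side in (a, b):
            if side[0] not in self.nodes:
                raise GraphError(f"edge endpoint references missing node {side[0]!r}")
            if side[1] not in ("L", "R"):
                raise GraphError(f"invalid node side {side!r}")
        e = edge_key(a, b)
        self.edges.add(e)
        self._adj.setdefault(a, set()).add(e)
        self._adj.setdefault(b, set()).add(e)

    def add_path(self, path: Path) -> None:
        if path.name in self.paths:
            raise GraphError(f"duplicate path name {path.name!r}")
        for i, step in enumerate(path.steps):
            if step.node_id not in self.nodes:
                raise GFAError(
                    f"path {path.name!r} step {i} references missing segment {step.node_id!r}"
                )
        for i in range(len(path.steps) - 1):
            e = step_edge(path.steps[i], path.steps[i + 1])
            if e not in self.edges:
                raise GraphError(
                    f"path {path.name!r} steps {i}-{i + 1} are not joined by an edge"
                )
        self.paths[path.name] = path

    def remove_edge(self, e: tuple[Side, Side]) -> None:
        self.edges.discard(e)
        for side in e:
            incident = self._adj.get(side)
            if incident is not None:
                incident.discard(e)

    def remove_node(self, node_id: str) -> None:
        for side in ((node_id, "L"), (node_id, "R")):
            for e in list(self._adj.get(side, ())):
                self.remove_edge(e)
            self._adj.pop(side, None)
        del self.nodes[node_id]

    # -- queries ------------------------------------------------------

    def degree(self, side: Side) -> int:
        return len(self._adj.get(side, ()))

    def node_length(self, node_id: str) -> int:
        return len(self.nodes[node_id])

    def components(self) -> list[frozenset[str]]:
        """Weakly connected components over node ids, ordered by smallest id."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b) in self.edges:
            g.add_edge(a[0], b[0])
        comps = [frozenset(c) for c in nx.connected_components(g)]
        return sorted(comps, key=lambda c: min(c))

    def reference_paths(self) -> list[Path]:
        return [p for p in self.paths.values() if p.is_reference]

    def haplotype_paths(self) -> list[Path]:
        return [p for p in self.paths.values() if not p.is_reference]

    def path_sequence(self, name: str) -> str:
        """Concatenated labels of a path, reverse-complemented on reverse steps."""
        if name not in self.paths:
            raise GraphError(f"unknown path {name!r}")
        return self.steps_sequence(self.paths[name].steps)

    def steps_sequence(self, steps: Sequence[OrientedNode]) -> str:
        parts = []
        for step in steps:
            label = self.nodes[step.node_id]
            parts.append(reverse_complement(label) if step.is_reverse else label)
        return "".join(parts)

    def validate(self) -> None:
        for e in self.edges:
            for side in e:
                if side[0] not in self.nodes:
                    raise GraphError(f"edge {e} references missing node {side[0]!r}")
        for path in self.paths.values():
            for i, step in enumerate(path.steps):
                if step.node_id not in self.nodes:
                    raise GraphError(
                        f"path {path.name!r} step {i} references missing node"
                    )
            for i in range(len(path.steps) - 1):
                if step_edge(path.steps[i], path.steps[i + 1]) not in self.edges:
                    raise GraphError(
                        f"path {path.name!r} uses a missing edge at steps {i}-{i + 1}"
                    )

    def copy(self) -> "PangenomeGraph":
        g = PangenomeGraph()
        g.nodes = dict(self.nodes)
        g.edges = set(self.edges)
        g.paths = dict(self.paths)
        g._adj = {side: set(es) for side, es in self._adj.items()}
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PangenomeGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.paths == other.paths
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PangenomeGraph {len(self.nodes)} nodes, {len(self.edges)} edges, "
            f"{len(self.paths)} paths>"
        )


# ---------------------------------------------------------------------------
# GFA I/O
# ---------------------------------------------------------------------------

_WALK_STEP = re.compile(r"([><])([^><\s]+)")


def _parse_walk(walk: str, path_name: str) -> tuple[OrientedNode, ...]:
    steps = []
    consumed = 0
    for m in _WALK_STEP.finditer(walk):
        consumed += len(m.group(0))
        steps.append(OrientedNode(m.group(2), m.group(1) == "<"))
    if consumed != len(walk):
        raise GFAError(f"malformed walk string in path {path_name!r}: {walk!r}")
    return tuple(steps)


def _parse_path_steps(field_: str, path_name: str) -> tuple[OrientedNode, ...]:
    steps = []
    if field_ in ("", "*"):
        return ()
    for token in field_.split(","):
        if len(token) < 2 or token[-1] not in "+-":
            raise GFAError(f"malformed path step {token!r} in path {path_name!r}")
        steps.append(OrientedNode(token[:-1], token[-1] == "-"))
    return tuple(steps)


def parse_gfa(path) -> PangenomeGraph:
    """Read a GFA file into a :class:`PangenomeGraph`.

    Segment records are buffered so record order does not matter.  Unknown
    record types are skipped with a warning; referential errors (a link or
    path step naming a missing segment, duplicate segments) are hard errors.
    """
    s_lines: list[list[str]] = []
    l_lines: list[list[str]] = []
    p_lines: list[tuple[str, list[str]]] = []  # (kind, fields)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "H":
                continue
            elif kind == "S":
                if len(fields) < 3:
                    raise GFAError(f"line {lineno}: malformed S record")
                s_lines.append(fields)
            elif kind == "L":
                if len(fields) < 6:
                    raise GFAError(f"line {lineno}: malformed L record")
                l_lines.append(fields)
            elif kind in ("P", "W"):
                p_lines.append((kind, fields))
            else:
                warnings.warn(f"skipping unknown GFA record type {kind!r} (line {lineno})")

    graph = PangenomeGraph()
    for fields in s_lines:
        graph.add_node(fields[1], fields[2])
    for fields in l_lines:
        _, from_id, from_o, to_id, to_o, overlap = fields[:6]
        if overlap not in ("0M", "*"):
            warnings.warn(f"skipping L record with unsupported overlap {overlap!r}")
            continue
        for node_id in (from_id, to_id):
            if node_id not in graph.nodes:
                raise GFAError(f"link references missing segment {node_id!r}")
        u = OrientedNode(from_id, from_o == "-")
        v = OrientedNode(to_id, to_o == "-")
        graph.add_edge(exit_side(u), entry_side(v))
    for kind, fields in p_lines:
        if kind == "P":
            if len(fields) < 3:
                raise GFAError("malformed P record")
            name = fields[1]
            steps = _parse_path_steps(fields[2], name)
            graph.add_path(Path(name, steps, is_reference=True))
        else:  # W
            if len(fields) < 7:
                raise GFAError("malformed W record")
            sample, hap, seqid = fields[1], fields[2], fields[3]
            name = f"{sample}#{hap}#{seqid}"
            steps = _parse_walk(fields[6], name)
            graph.add_path(Path(name, steps, is_reference=False))
    graph.validate()
    return graph


def _node_sort_key(node_id: str):
    return (len(node_id), node_id) if node_id.isdigit() else (0, node_id)


def write_gfa(graph: PangenomeGraph, path) -> None:
    """Write a graph as GFA 1.1 in a deterministic order.

    Segments and links are sorted; paths keep insertion order.  Reference
    paths are emitted as P records, haplotype paths as W records (the
    ``sample#haplotype#contig`` name convention is split back into walk
    columns).
    """
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.1\n")
        for node_id in sorted(graph.nodes, key=_node_sort_key):
            fh.write(f"S\t{node_id}\t{graph.nodes[node_id]}\n")
        for a, b in sorted(graph.edges):
            # Emit the link as a forward traversal out of side `a`.
            from_o = "+" if a[1] == "R" else "-"
            to_o = "+" if b[1] == "L" else "-"
            fh.write(f"L\t{a[0]}\t{from_o}\t{b[0]}\t{to_o}\t0M\n")
        for p in graph.paths.values():
            if p.is_reference:
                steps = ",".join(s.node_id + ("-" if s.is_reverse else "+") for s in p.steps)
                fh.write(f"P\t{p.name}\t{steps}\t*\n")
            else:
                parts = p.name.split("#")
                if len(parts) == 3:
                    sample, hap, seqid = parts
                else:
                    sample, hap, seqid = p.name, "0", p.name
                walk = "".join(("<" if s.is_reverse else ">") + s.node_id for s in p.steps)
                length = sum(graph.node_length(s.node_id) for s in p.steps)
                fh.write(f"W\t{sample}\t{hap}\t{seqid}\t0\t{length}\t{walk}\n")


# ---------------------------------------------------------------------------
# Clip filter and induced subgraphs
# ---------------------------------------------------------------------------


def _surviving_runs(graph: PangenomeGraph, path: Path) -> list[tuple[int, int]]:
    """Maximal step runs whose nodes and connecting edges survive."""
    kept = [s.node_id in graph.nodes for s in path.steps]
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(path.steps)
    while i < n:
        if not kept[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and kept[j + 1]
            and step_edge(path.steps[j], path.steps[j + 1]) in graph.edges
        ):
            j += 1
        runs.append((i, j + 1))
        i = j + 1
    return runs


def clip_to_single_chain(
    graph: PangenomeGraph, reference_names: Iterable[str] | None = None
) -> PangenomeGraph:
    """Clip a graph so each component has exactly two tips.

    Repeatedly removes nodes with one side of degree 0 that are not on a
    reference path, until none are left; edges hanging off the outer ends
    of each reference path are removed as well.  Haplotype paths are
    trimmed when only a prefix/suffix was removed and dropped when an
    internal step was removed.
    """
    g = graph.copy()
    if reference_names is None:
        refs = g.reference_paths()
    else:
        refs = [g.paths[name] for name in reference_names]
    if not refs:
        raise GraphError("no reference paths given for clipping")

    ref_nodes = {s.node_id for p in refs for s in p.steps}
    missing = []
    for comp in g.components():
        if not comp & ref_nodes:
            missing.append(min(comp))
    if missing:
        raise GraphError(
            "components without a reference path (smallest node ids: "
            + ", ".join(missing)
            + ")"
        )

    # Edges hanging off the outer ends of each reference path.
    for p in refs:
        if not p.steps:
            continue
        for side in (entry_side(p.steps[0]), exit_side(p.steps[-1])):
            for e in list(g._adj.get(side, ())):
                g.remove_edge(e)

    # Iterated tip removal.
    queue = [n for n in g.nodes if n not in ref_nodes]
    pending = set(queue)
    while queue:
        node = queue.pop()
        pending.discard(node)
        if node not in g.nodes:
            continue
        if g.degree((node, "L")) and g.degree((node, "R")):
            continue
        neighbours = {
            side[0]
            for s in ((node, "L"), (node, "R"))
            for e in g._adj.get(s, ())
            for side in e
            if side[0] != node
        }
        g.remove_node(node)
        for nb in neighbours:
            if nb in g.nodes and nb not in ref_nodes and nb not in pending:
                queue.append(nb)
                pending.add(nb)

    # Repair haplotype paths.
    new_paths: dict[str, Path] = {}
    for p in graph.paths.values():
        if p.is_reference:
            new_paths[p.name] = p
            continue
        runs = _surviving_runs(g, p)
        if len(runs) != 1:
            continue  # dropped: internal material removed (or nothing left)
        lo, hi = runs[0]
        new_paths[p.name] = p if (lo, hi) == (0, len(p.steps)) else Path(
            p.name, p.steps[lo:hi], p.is_reference
        )
    g.paths = new_paths
    g.validate()
    return g


def induced_subgraph(
    graph: PangenomeGraph, paths: Sequence[Path]
) -> PangenomeGraph:
    """Subgraph induced by a set of paths.

    Nodes are those visited by at least one path, edges those used by
    consecutive steps of at least one path; the input paths become the new
    graph's paths.
    """
    sub = PangenomeGraph()
    for p in paths:
        for step in p.steps:
            if step.node_id not in graph.nodes:
                raise GraphError(
                    f"path {p.name!r} step references node {step.node_id!r} "
                    "outside the graph"
                )
            if step.node_id not in sub.nodes:
                sub.add_node(step.node_id, graph.nodes[step.node_id])
    for p in paths:
        for i in range(len(p.steps) - 1):
            e = step_edge(p.steps[i], p.steps[i + 1])
            if e not in graph.edges:
                raise GraphError(f"path {p.name!r} uses edge {e} absent from the graph")
            sub.add_edge(*e)
    for p in paths:
        sub.add_path(p)
    return sub
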