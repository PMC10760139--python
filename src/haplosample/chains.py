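"""Chain decomposition, block partitioning and local haplotypes.

Each clipped component is summarised by an ordered list of *boundary
nodes*: nodes that every haplotype pass through the component visits
exactly once, in a single shared order and orientation.  On graphs whose
components form a single top-level chain this recovers the chain's
node-and-bubble skeleton.  Consecutive boundary intervals are merged
greedily into blocks of roughly ``b`` bp, and each haplotype's minimal
end-to-end visits through a block become its *local haplotypes* — the
rows of the k-mer presence matrices and the unit of sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .graph_io import (
    GraphError,
    OrientedNode,
    PangenomeGraph,
    Path,
    Side,
)

__all__ = [
    "ChainError",
    "PathPass",
    "ComponentChain",
    "Block",
    "LocalHaplotype",
    "find_tips",
    "decompose_component",
    "boundary_nodes",
    "partition_into_blocks",
    "local_haplotypes",
]

DEFAULT_BLOCK_LENGTH = 10_000


class ChainError(GraphError):
    """Component structure unsuitable for chain decomposition."""


@dataclass(frozen=True)
class PathPass:
    """One end-to-end pass of a path through a component, left-tip first."""

    path_name: str
    ordinal: int
    is_reference: bool
    steps: tuple[OrientedNode, ...]


@dataclass(frozen=True)
class LocalHaplotype:
    """One minimal boundary-to-boundary visit of a path through a block."""

    path_name: str
    ordinal: int
    is_reference: bool
    steps: tuple[OrientedNode, ...]

    @property
    def sort_key(self) -> tuple[str, int]:
        return (self.path_name, self.ordinal)


@dataclass(frozen=True)
class Block:
    """A contiguous chain interval between two boundary nodes."""

    component_id: int
    index: int
    left: OrientedNode
    right: OrientedNode
    bi_left: int  # index of `left` in the component's boundary list
    bi_right: int
    min_length: int


@dataclass
class ComponentChain:
    """Boundary-node decomposition of one graph component."""

    component_id: int
    nodes: frozenset[str]
    tips: tuple[Side, Side]
    boundaries: tuple[OrientedNode, ...]
    #: minimum traversal length (bp) between consecutive boundaries;
    #: interval i spans boundaries[i] (exclusive) to boundaries[i+1] (inclusive)
    intervals: tuple[int, ...]
    passes: tuple[PathPass, ...]


def find_tips(graph: PangenomeGraph, component: frozenset[str]) -> tuple[Side, Side]:
    """The two degree-0 node sides of a clipped component, reference start first."""
    tips = [
        (node, side)
        for node in sorted(component)
        for side in ("L", "R")
        if graph.degree((node, side)) == 0
    ]
    if len(tips) != 2:
        raise ChainError(
            f"component has {len(tips)} tips, expected 2; "
            "run clip_to_single_chain first"
        )
    ref = _component_reference(graph, component)
    from .graph_io import entry_side, exit_side

    start = entry_side(ref.steps[0])
    end = exit_side(ref.steps[-1])
    if tips[0] == start or tips[1] == end:
        return (tips[0], tips[1])
    if tips[1] == start or tips[0] == end:
        return (tips[1], tips[0])
    raise ChainError("tips do not coincide with the reference path ends")


def _component_reference(graph: PangenomeGraph, component: frozenset[str]) -> Path:
    refs = [
        p
        for p in graph.reference_paths()
        if p.steps and p.steps[0].node_id in component
    ]
    if not refs:
        raise ChainError("component has no reference path")
    if len(refs) > 1:
        raise ChainError("component has more than one reference path")
    return refs[0]


def _split_passes(
    path: Path, tip_nodes: tuple[str, str], left_tip_node: str
) -> list[tuple[OrientedNode, ...]]:
    """Split a path into tip-to-tip passes, each normalized left-tip first."""
    steps = path.steps
    hits = [i for i, s in enumerate(steps) if s.node_id in tip_nodes]
    segments: list[tuple[OrientedNode, ...]] = []
    if len(hits) < 2:
        segments.append(steps)
    else:
        if hits[0] != 0 or hits[-1] != len(steps) - 1:
            warnings.warn(
                f"path {path.name!r} does not start/end at component tips; "
                "using tip-to-tip segments only"
            )
        for a, b in zip(hits, hits[1:]):
            if steps[a].node_id == steps[b].node_id:
                warnings.warn(
                    f"path {path.name!r} has a same-tip excursion; skipping it"
                )
                continue
            segments.append(steps[a : b + 1])
    out = []
    for seg in segments:
        if seg and seg[-1].node_id == left_tip_node:
            seg = tuple(s.flip() for s in reversed(seg))
        out.append(seg)
    return out


def _longest_common_subsequence(a: list[str], b: list[str]) -> set[str]:
    """Node ids on an LCS of two orders (elements unique within each list)."""
    pos = {x: i for i, x in enumerate(b)}
    seq = [(pos[x], x) for x in a if x in pos]
    # longest increasing subsequence over positions
    import bisect

    tails: list[int] = []
    back: list[int] = []
    parents: list[int] = []
    for idx, (p, _) in enumerate(seq):
        j = bisect.bisect_left(tails, p)
        if j == len(tails):
            tails.append(p)
            back.append(idx)
        else:
            tails[j] = p
            back[j] = idx
        parents.append(back[j - 1] if j > 0 else -1)
    result: set[str] = set()
    if back:
        i = back[len(tails) - 1]
        while i != -1:
            result.add(seq[i][1])
            i = parents[i]
    return result


def decompose_component(
    graph: PangenomeGraph, component: frozenset[str], component_id: int = 0
) -> ComponentChain:
    """Boundary-node chain decomposition of one clipped component."""
    tips = find_tips(graph, component)
    tip_nodes = (tips[0][0], tips[1][0])
    ref = _component_reference(graph, component)

    passes: list[PathPass] = []
    for path in graph.paths.values():
        if not path.steps or path.steps[0].node_id not in component:
            continue
        for ordinal, seg in enumerate(_split_passes(path, tip_nodes, tips[0][0])):
            passes.append(PathPass(path.name, ordinal, path.is_reference, seg))
    if not any(not p.is_reference for p in passes):
        raise ChainError("component has no haplotype paths")
    passes.sort(key=lambda p: (p.path_name, p.ordinal))

    # Candidates: nodes visited exactly once, same orientation, by every pass.
    counts0: dict[str, int] = {}
    orient0: dict[str, bool] = {}
    first = passes[0]
    for s in first.steps:
        counts0[s.node_id] = counts0.get(s.node_id, 0) + 1
        orient0[s.node_id] = s.is_reverse
    candidates = {n for n, c in counts0.items() if c == 1}
    for pp in passes[1:]:
        counts: dict[str, int] = {}
        orient: dict[str, bool] = {}
        for s in pp.steps:
            counts[s.node_id] = counts.get(s.node_id, 0) + 1
            orient[s.node_id] = s.is_reverse
        candidates = {
            n
            for n in candidates
            if counts.get(n) == 1 and orient[n] == orient0[n]
        }

    # Enforce a single shared order, removing offenders iteratively.
    def orders() -> list[list[str]]:
        return [[s.node_id for s in pp.steps if s.node_id in candidates] for pp in passes]

    ords = orders()
    template = ords[0]
    while any(o != template for o in ords):
        keep = set(template)
        for o in ords[1:]:
            if o != template:
                keep &= _longest_common_subsequence(template, o)
        if keep == candidates:  # no progress; bail out conservatively
            raise ChainError("could not reconcile boundary-node orders")
        candidates = keep
        ords = orders()
        template = ords[0]

    ref_pass = next(p for p in passes if p.is_reference)
    boundary_steps = tuple(s for s in ref_pass.steps if s.node_id in candidates)
    if not boundary_steps or boundary_steps[0].node_id != tip_nodes[0] or (
        boundary_steps[-1].node_id != tip_nodes[1]
    ):
        raise ChainError("tip nodes are not shared boundary nodes of all passes")

    # Minimum traversal length per consecutive boundary pair.
    m = len(boundary_steps)
    intervals = [None] * (m - 1)
    for pp in passes:
        pos = {s.node_id: i for i, s in enumerate(pp.steps) if s.node_id in candidates}
        for i in range(m - 1):
            a = pos[boundary_steps[i].node_id]
            b = pos[boundary_steps[i + 1].node_id]
            length = sum(graph.node_length(s.node_id) for s in pp.steps[a + 1 : b + 1])
            if intervals[i] is None or length < intervals[i]:
                intervals[i] = length

    return ComponentChain(
        component_id=component_id,
        nodes=component,
        tips=tips,
        boundaries=boundary_steps,
        intervals=tuple(intervals),
        passes=tuple(passes),
    )


def boundary_nodes(
    graph: PangenomeGraph, component: frozenset[str]
) -> tuple[OrientedNode, ...]:
    """Ordered boundary nodes of a component (see module docstring)."""
    return decompose_component(graph, component).boundaries


def partition_into_blocks(
    chain: ComponentChain, b: int = DEFAULT_BLOCK_LENGTH
) -> list[Block]:
    """Greedy left-to-right merge of boundary intervals into ~``b`` bp blocks.

    The running block is extended boundary by boundary until its minimum
    length first reaches ``b``; a trailing remainder shorter than ``b``
    forms the final block on its own.
    """
    if b <= 0:
        raise ValueError("block length b must be positive")
    if len(chain.boundaries) < 2:
        raise ChainError("need at least two boundary nodes to form blocks")
    blocks: list[Block] = []
    start = 0
    acc = 0
    for i, length in enumerate(chain.intervals):
        acc += length
        last = i == len(chain.intervals) - 1
        if acc >= b or last:
            blocks.append(
                Block(
                    component_id=chain.component_id,
                    index=len(blocks),
                    left=chain.boundaries[start],
                    right=chain.boundaries[i + 1],
                    bi_left=start,
                    bi_right=i + 1,
                    min_length=acc,
                )
            )
            start = i + 1
            acc = 0
    return blocks


def slice_pass(
    pass_steps: tuple[OrientedNode, ...], chain: ComponentChain, block: Block
) -> tuple[OrientedNode, ...] | None:
    """Steps of one pass between a block's boundary nodes (inclusive)."""
    left = chain.boundaries[block.bi_left].node_id
    right = chain.boundaries[block.bi_right].node_id
    li = ri = None
    for i, s in enumerate(pass_steps):
        if s.node_id == left:
            li = i
        elif s.node_id == right:
            ri = i
    if li is None or ri is None or ri <= li:
        return None
    return pass_steps[li : ri + 1]


def local_haplotypes(chain: ComponentChain, block: Block) -> list[LocalHaplotype]:
    """Minimal end-to-end visits of every pass through a block.

    One entry per pass; a path crossing the component twice contributes two
    entries (distinct visit ordinals).  Output is ordered by
    (path name, visit ordinal).
    """
    out: list[LocalHaplotype] = []
    for pp in chain.passes:
        steps = slice_pass(pp.steps, chain, block)
        if steps is None:
            warnings.warn(
                f"path {pp.path_name!r} pass {pp.ordinal} does not traverse "
                f"block {block.index}; skipping that visit"
            )
            continue
        out.append(LocalHaplotype(pp.path_name, pp.ordinal, pp.is_reference, steps))
    out.sort(key=lambda lh: lh.sort_key)
    return out
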