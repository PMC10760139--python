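"""Greedy haplotype sampling, diploid pair selection, stitching.

Per block, haplotypes are scored by the classified presence-matrix
k-mers: a homozygous k-mer contributes +1 if present in the haplotype and
-1 if not; an absent-class k-mer contributes -0.8 / +0.8; heterozygous
k-mers start neutral; frequent k-mers are ignored.  The greedy selector
repeatedly takes the highest-scoring haplotype (the first pick
approximates the consensus) and reweights: homozygous k-mers present in
the pick are discounted by 0.9, heterozygous k-mers are nudged by 0.05
toward the opposite state.  Optional diploid refinement scores every
candidate pair by sum(1 - |x - y|) over expected (x) and realised (y)
k-mer copy numbers.  Selections are stitched across blocks — junctions
between different source haplotypes are recombinations — and the stitched
paths induce the personalized subgraph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .chains import LocalHaplotype
from .graph_io import PangenomeGraph, Path, induced_subgraph
from .index import HaplotypeIndex, IndexedComponent
from .kmer_index import KmerPresenceMatrix
from .read_profile import (
    ABSENT,
    FREQUENT,
    HETEROZYGOUS,
    HOMOZYGOUS,
    ClassificationThresholds,
    KmerCounts,
    ReadProfile,
)

__all__ = [
    "SamplerConfig",
    "ScoreState",
    "ParameterMismatchError",
    "initial_scores",
    "greedy_select",
    "diploid_select",
    "stitch_haplotypes",
    "sample_graph",
]


class ParameterMismatchError(ValueError):
    """Index, counts and sampler parameters disagree."""


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling parameters; scoring constants default to published values."""

    n: int = 8
    diploid: bool = False
    hom_present: float = 1.0
    hom_absent: float = -1.0
    abs_present: float = -0.8
    abs_absent: float = 0.8
    hom_discount: float = 0.9
    het_adjust: float = 0.05
    include_reference: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.diploid and self.n < 2:
            raise ValueError("diploid sampling needs n >= 2")


_EXPECTED_COPIES = {ABSENT: 0, HETEROZYGOUS: 1, HOMOZYGOUS: 2}


@dataclass
class ScoreState:
    """Per-k-mer (score-if-present, score-if-absent) pairs for one block.

    Frequent k-mers are dropped on construction; ``matrix`` is the
    presence matrix restricted to the surviving columns.
    """

    matrix: np.ndarray  # bool, rows x surviving columns
    score_present: np.ndarray
    score_absent: np.ndarray
    classes: list[str]

    def totals(self) -> np.ndarray:
        return self.matrix @ self.score_present + (~self.matrix) @ self.score_absent


def initial_scores(
    matrix: KmerPresenceMatrix, profile: ReadProfile, config: SamplerConfig
) -> ScoreState:
    """Initial per-k-mer score pairs from the k-mer classification."""
    classes = []
    for kmer in matrix.kmers:
        cls = profile.classes.get(kmer)
        if cls is None:
            raise ValueError(f"matrix k-mer {kmer!r} has no classification")
        classes.append(cls)
    keep = np.array([c != FREQUENT for c in classes], dtype=bool)
    kept_classes = [c for c in classes if c != FREQUENT]
    sp = np.empty(len(kept_classes))
    sa = np.empty(len(kept_classes))
    for i, cls in enumerate(kept_classes):
        if cls == HOMOZYGOUS:
            sp[i], sa[i] = config.hom_present, config.hom_absent
        elif cls == ABSENT:
            sp[i], sa[i] = config.abs_present, config.abs_absent
        else:  # heterozygous
            sp[i], sa[i] = 0.0, 0.0
    return ScoreState(matrix.matrix[:, keep], sp, sa, kept_classes)


def greedy_select(state: ScoreState, config: SamplerConfig) -> list[int]:
    """Greedy selection of ``n`` row indices with score reweighting.

    Rows are never reselected while unselected rows remain; if ``n``
    exceeds the number of rows, the greedy order is repeated cyclically to
    fill the request (with a warning).  Ties go to the lowest row index;
    totals are compared at 1e-9 resolution so that mathematically equal
    sums tie regardless of floating-point summation order.
    """
    r = state.matrix.shape[0]
    if r == 0:
        raise ValueError("presence matrix has no rows")
    het = np.array([c == HETEROZYGOUS for c in state.classes], dtype=bool)
    hom = np.array([c == HOMOZYGOUS for c in state.classes], dtype=bool)
    selected: list[int] = []
    remaining = list(range(r))
    for _ in range(min(config.n, r)):
        totals = np.round(state.totals(), 9)
        best = min(remaining, key=lambda i: (-totals[i], i))
        selected.append(best)
        remaining.remove(best)
        present = state.matrix[best]
        disc = hom & present
        state.score_present[disc] *= config.hom_discount
        state.score_absent[disc] *= config.hom_discount
        toward_absent = het & present
        toward_present = het & ~present
        state.score_present[toward_absent] -= config.het_adjust
        state.score_absent[toward_absent] += config.het_adjust
        state.score_present[toward_present] += config.het_adjust
        state.score_absent[toward_present] -= config.het_adjust
    if config.n > r:
        warnings.warn(
            f"requested n={config.n} haplotypes but only {r} distinct local "
            "haplotypes exist; repeating selections"
        )
        base = list(selected)
        while len(selected) < config.n:
            selected.append(base[len(selected) % r])
    return selected


def diploid_select(
    candidates: list[int], state: ScoreState
) -> tuple[tuple[int, int], float, int]:
    """Best unordered candidate pair under the copy-number score.

    Expected copies x come from the k-mer class (absent 0, heterozygous 1,
    homozygous 2); realised copies y count the pair members containing the
    k-mer; the pair score is sum(1 - |x - y|).  Same-row (homozygous)
    pairs are allowed.  Returns the pair (lexicographically first by row
    order on ties), its score, and the number of pairs attaining the
    maximum (a tie diagnostic).
    """
    if len(candidates) < 2:
        raise ValueError("diploid selection needs at least 2 candidates")
    x = np.array([_EXPECTED_COPIES[c] for c in state.classes], dtype=np.int64)
    rows = sorted(set(candidates))
    best_pair = None
    best_score = -np.inf
    n_ties = 0
    for ai, a in enumerate(rows):
        for b in rows[ai:]:
            y = state.matrix[a].astype(np.int64) + state.matrix[b].astype(np.int64)
            score = float(np.sum(1 - np.abs(x - y)))
            if score > best_score:
                best_pair, best_score, n_ties = (a, b), score, 1
            elif score == best_score:
                n_ties += 1
    assert best_pair is not None
    return best_pair, best_score, n_ties


# ---------------------------------------------------------------------------
# Stitching and end-to-end sampling
# ---------------------------------------------------------------------------


@dataclass
class ComponentSelection:
    """Per-block ordered selections for one component."""

    component: IndexedComponent
    selections: list[list[LocalHaplotype]]  # one list per block, equal lengths


def stitch_haplotypes(
    selection: ComponentSelection,
    name_prefix: str = "sampled",
    contig: str | None = None,
) -> tuple[list[Path], list[int]]:
    """Concatenate the i-th selection of each block into full-length paths.

    Shared boundary nodes are merged; each junction is a continuation when
    the adjacent selections come from the same source haplotype pass and a
    recombination otherwise.  Returns the paths and per-path recombination
    counts.
    """
    counts = {len(sel) for sel in selection.selections}
    if len(counts) > 1:
        raise ValueError("selection counts differ across blocks")
    if not selection.selections:
        return [], []
    m = counts.pop()
    cid = selection.component.component_id
    contig = contig or f"component{cid}"
    paths: list[Path] = []
    recombinations: list[int] = []
    for i in range(m):
        steps: list = []
        recomb = 0
        prev: LocalHaplotype | None = None
        for sel in selection.selections:
            lh = sel[i]
            if not steps:
                steps.extend(lh.steps)
            else:
                if steps[-1] != lh.steps[0]:
                    raise ValueError(
                        "adjacent block selections do not share the boundary node"
                    )
                steps.extend(lh.steps[1:])
                if prev is not None and (prev.path_name, prev.ordinal) != (
                    lh.path_name,
                    lh.ordinal,
                ):
                    recomb += 1
            prev = lh
        paths.append(Path(f"{name_prefix}#{i}#{contig}", tuple(steps), False))
        recombinations.append(recomb)
    return paths, recombinations


def _fallback_rows(matrix: KmerPresenceMatrix) -> list[int]:
    """Row order for blocks whose matrix cannot score: reference rows first."""
    order = sorted(
        range(len(matrix.rows)),
        key=lambda i: (not matrix.rows[i].is_reference, matrix.rows[i].sort_key),
    )
    return order


def _select_block(
    matrix: KmerPresenceMatrix, profile: ReadProfile, config: SamplerConfig
) -> tuple[list[LocalHaplotype], dict]:
    rows = matrix.rows
    if not rows:
        raise ValueError("block has no local haplotypes")
    state = initial_scores(matrix, profile, config)
    info: dict = {"n_kmers": len(state.classes), "fallback": False, "diploid_ties": 0}
    if len(state.classes) == 0 or len(rows) < 2:
        order = _fallback_rows(matrix)
        info["fallback"] = True
        picks = [order[i % len(order)] for i in range(config.n)]
        if config.diploid:
            picks = picks[:2]
        return [rows[i] for i in picks], info
    picks = greedy_select(state, config)
    if config.diploid:
        (a, b), score, ties = diploid_select(picks, state)
        info["diploid_ties"] = ties - 1
        info["pair_score"] = score
        picks = [a, b]
    return [rows[i] for i in picks], info


def sample_graph(
    graph: PangenomeGraph,
    index: HaplotypeIndex,
    counts: KmerCounts,
    config: SamplerConfig | None = None,
    coverage: float | None = None,
    thresholds: ClassificationThresholds | None = None,
) -> tuple[PangenomeGraph, dict]:
    """End-to-end sampling: profile, score, select, stitch, induce.

    Components are processed independently and deterministically, so the
    output does not depend on processing order.  Returns the sampled
    subgraph and a machine-readable report.
    """
    config = config or SamplerConfig()
    if counts.k != index.k:
        raise ParameterMismatchError(
            f"counts were made with k={counts.k} but the index uses k={index.k}"
        )
    profile = ReadProfile.build(
        counts, sorted(index.all_matrix_kmers()), coverage, thresholds
    )
    all_paths: list[Path] = []
    report: dict = {
        "coverage": profile.coverage,
        "kmer_classes": profile.class_tally(),
        "parameters": {
            "k": index.k,
            "w": index.w,
            "b": index.b,
            "n": config.n,
            "diploid": config.diploid,
        },
        "components": [],
    }
    for comp in index.components:
        selections = []
        block_infos = []
        for ib in comp.blocks:
            sel, info = _select_block(ib.matrix, profile, config)
            selections.append(sel)
            block_infos.append(info)
        paths, recombs = stitch_haplotypes(ComponentSelection(comp, selections))
        ref_names: list[str] = []
        if config.include_reference:
            boundary_ids = {s.node_id for s in comp.boundaries}
            for p in graph.reference_paths():
                if p.steps and p.steps[0].node_id in boundary_ids:
                    paths.append(p)
                    ref_names.append(p.name)
        n_blocks = len(comp.blocks)
        n_ties = sum(i["diploid_ties"] > 0 for i in block_infos)
        report["components"].append(
            {
                "component_id": comp.component_id,
                "n_blocks": n_blocks,
                "n_paths": len(paths),
                "reference_paths": ref_names,
                "recombinations": recombs,
                "blocks_with_fallback": sum(i["fallback"] for i in block_infos),
                "diploid_tied_block_fraction": (n_ties / n_blocks) if n_blocks else 0.0,
                "block_kmer_counts": [i["n_kmers"] for i in block_infos],
            }
        )
        all_paths.extend(paths)
    sampled = induced_subgraph(graph, all_paths)
    return sampled, report
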