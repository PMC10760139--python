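"""Build and serialize the haplotype-sampling index.

The index holds, per graph component, the boundary-node chain, the
~``b`` bp blocks, every block's local haplotypes and its k-mer presence
matrix.  It is written as a versioned JSON document carrying the
(k, w, b) parameters that produced it, so a later sampling run can detect
parameter mismatches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .chains import (
    Block,
    ComponentChain,
    LocalHaplotype,
    decompose_component,
    local_haplotypes,
    partition_into_blocks,
    DEFAULT_BLOCK_LENGTH,
)
from .graph_io import OrientedNode, PangenomeGraph
from .kmer_index import (
    KmerConfig,
    KmerPresenceMatrix,
    build_presence_matrix,
    graph_unique_minimizers,
)

__all__ = ["IndexedBlock", "IndexedComponent", "HaplotypeIndex", "build_index"]

INDEX_FORMAT_VERSION = 1


@dataclass
class IndexedBlock:
    block: Block
    local_haps: list[LocalHaplotype]
    matrix: KmerPresenceMatrix


@dataclass
class IndexedComponent:
    component_id: int
    boundaries: tuple[OrientedNode, ...]
    blocks: list[IndexedBlock]


@dataclass
class HaplotypeIndex:
    k: int
    w: int
    b: int
    components: list[IndexedComponent]

    def all_matrix_kmers(self) -> set[str]:
        out: set[str] = set()
        for comp in self.components:
            for ib in comp.blocks:
                out.update(ib.matrix.kmers)
        return out

    # -- serialization -------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "format_version": INDEX_FORMAT_VERSION,
            "parameters": {"k": self.k, "w": self.w, "b": self.b},
            "components": [
                {
                    "component_id": comp.component_id,
                    "boundaries": [_step_str(s) for s in comp.boundaries],
                    "blocks": [
                        {
                            "index": ib.block.index,
                            "bi_left": ib.block.bi_left,
                            "bi_right": ib.block.bi_right,
                            "min_length": ib.block.min_length,
                            "rows": [
                                {
                                    "path": lh.path_name,
                                    "ordinal": lh.ordinal,
                                    "is_reference": lh.is_reference,
                                    "steps": "".join(_step_str(s) for s in lh.steps),
                                }
                                for lh in ib.matrix.rows
                            ],
                            "kmers": ib.matrix.kmers,
                            "matrix": [
                                "".join("1" if v else "0" for v in row)
                                for row in ib.matrix.matrix
                            ],
                        }
                        for ib in comp.blocks
                    ],
                }
                for comp in self.components
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "HaplotypeIndex":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format_version") != INDEX_FORMAT_VERSION:
            raise ValueError(
                f"unsupported index format version {doc.get('format_version')!r}"
            )
        params = doc["parameters"]
        components = []
        for cdoc in doc["components"]:
            boundaries = tuple(_parse_steps(s)[0] for s in cdoc["boundaries"])
            blocks = []
            for bdoc in cdoc["blocks"]:
                rows = [
                    LocalHaplotype(
                        r["path"], r["ordinal"], r["is_reference"], _parse_steps(r["steps"])
                    )
                    for r in bdoc["rows"]
                ]
                block = Block(
                    component_id=cdoc["component_id"],
                    index=bdoc["index"],
                    left=boundaries[bdoc["bi_left"]],
                    right=boundaries[bdoc["bi_right"]],
                    bi_left=bdoc["bi_left"],
                    bi_right=bdoc["bi_right"],
                    min_length=bdoc["min_length"],
                )
                mat = np.array(
                    [[ch == "1" for ch in row] for row in bdoc["matrix"]], dtype=bool
                ).reshape(len(rows), len(bdoc["kmers"]))
                blocks.append(
                    IndexedBlock(block, rows, KmerPresenceMatrix(block, list(bdoc["kmers"]), rows, mat))
                )
            components.append(IndexedComponent(cdoc["component_id"], boundaries, blocks))
        return cls(params["k"], params["w"], params["b"], components)


def _step_str(s: OrientedNode) -> str:
    return ("<" if s.is_reverse else ">") + s.node_id


def _parse_steps(text: str) -> tuple[OrientedNode, ...]:
    steps = []
    i = 0
    while i < len(text):
        rev = text[i] == "<"
        j = i + 1
        while j < len(text) and text[j] not in "<>":
            j += 1
        steps.append(OrientedNode(text[i + 1 : j], rev))
        i = j
    return tuple(steps)


def build_index(
    graph: PangenomeGraph,
    config: KmerConfig | None = None,
    b: int = DEFAULT_BLOCK_LENGTH,
) -> HaplotypeIndex:
    """Preprocess a clipped graph into a sampling index.

    Decomposes each component into its boundary-node chain, partitions it
    into blocks, enumerates local haplotypes, selects graph-unique
    minimizers once for the whole graph, and builds each block's presence
    matrix.
    """
    config = config or KmerConfig()
    unique = graph_unique_minimizers(graph, config)
    components = []
    for cid, comp in enumerate(graph.components()):
        chain = decompose_component(graph, comp, cid)
        blocks = partition_into_blocks(chain, b)
        indexed = []
        for block in blocks:
            lhs = local_haplotypes(chain, block)
            matrix = build_presence_matrix(graph, block, lhs, unique, config)
            indexed.append(IndexedBlock(block, matrix.rows, matrix))
        components.append(IndexedComponent(cid, chain.boundaries, indexed))
    return HaplotypeIndex(config.k, config.w, b, components)
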