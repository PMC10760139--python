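"""Graph-unique minimizers and k-mer presence matrices.

Haplotypes in a block are described by *graph-unique* k-mers: canonical
k-mers with exactly one occurrence position in the whole graph.  k-mers
are subsampled with a minimizer scheme (default k = 29, w = 11): in each
window of ``w`` consecutive k-mers the one with the smallest key is kept,
where the key is an invertible 64-bit hash of the 2-bit-packed canonical
k-mer (a constant-seeded finalizer; lexicographic keys would oversample
poly-A runs).  For each block the retained k-mers become the columns of a
binary haplotype-by-k-mer presence matrix; columns present in every local
haplotype (or in none) are uninformative and dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chains import Block, LocalHaplotype
from .graph_io import OrientedNode, PangenomeGraph, reverse_complement

__all__ = [
    "KmerConfig",
    "KmerPresenceMatrix",
    "GraphPosition",
    "canonical_kmer",
    "minimizers",
    "graph_unique_minimizers",
    "build_presence_matrix",
    "kmer_codes",
    "canonical_codes",
    "minimizer_key",
    "encode_kmer",
    "decode_kmer",
]

_UINT64_MAX = np.uint64(0xFFFFFFFFFFFFFFFF)
_HASH_SEED = np.uint64(0x5851F42D4C957F2D)


@dataclass(frozen=True)
class KmerConfig:
    """Minimizer parameters: k-mer length and window size."""

    k: int = 29
    w: int = 11

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be a positive odd integer")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.k > 31:
            raise ValueError("k must fit in 62 bits (k <= 31)")


# ---------------------------------------------------------------------------
# 2-bit encoding and hashing
# ---------------------------------------------------------------------------

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = "ACGT"


def _encode_bases(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_kmer(kmer: str) -> int:
    """2-bit pack a k-mer string (A=0, C=1, G=2, T=3)."""
    code = 0
    for ch in kmer:
        v = _ENC[ord(ch)]
        if v > 3:
            raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_DEC[(code >> shift) & 3])
    return "".join(out)


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit codes and validity flags for every k-mer window of ``seq``.

    Returns ``(codes, valid)`` with one entry per 0-based window start;
    windows containing a non-ACGT base are invalid (their code is
    meaningless and must be ignored).
    """
    b = _encode_bases(seq)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = (b > 3).astype(np.int32)
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0
    b64 = np.where(b > 3, 0, b).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | b64[j : j + n]
    return codes, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of the reverse complements of 2-bit-packed k-mers."""
    rc = np.zeros_like(codes)
    c = codes.copy()
    three = np.uint64(3)
    for _ in range(k):
        rc = (rc << np.uint64(2)) | ((c & three) ^ three)
        c >>= np.uint64(2)
    return rc


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-merged) codes: minimum of a k-mer and its revcomp."""
    return np.minimum(codes, revcomp_codes(codes, k))


def minimizer_key(codes: np.ndarray | int) -> np.ndarray | int:
    """Constant-seeded invertible 64-bit mix of canonical k-mer codes."""
    scalar = np.isscalar(codes) or isinstance(codes, int)
    x = np.atleast_1d(np.asarray(codes, dtype=np.uint64)).copy()
    with np.errstate(over="ignore"):
        x ^= _HASH_SEED
        x ^= x >> np.uint64(33)
        x *= np.uint64(0xFF51AFD7ED558CCD)
        x ^= x >> np.uint64(33)
        x *= np.uint64(0xC4CEB9FE1A85EC53)
        x ^= x >> np.uint64(33)
    return int(x[0]) if scalar else x


def canonical_kmer(kmer: str, k: int | None = None) -> str | None:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Returns ``None`` (the invalid sentinel) for k-mers containing bases
    outside ACGT, e.g. N.
    """
    if k is not None and len(kmer) != k:
        raise ValueError(f"expected a {k}-mer, got length {len(kmer)}")
    kmer = kmer.upper()
    if any(ch not in "ACGT" for ch in kmer):
        return None
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


# ---------------------------------------------------------------------------
# Minimizer selection
# ---------------------------------------------------------------------------


def _minimizer_positions(keys: np.ndarray, w: int) -> np.ndarray:
    """Positions selected by sliding-window minimization (leftmost ties)."""
    n = len(keys)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    ww = min(w, n)
    windows = np.lib.stride_tricks.sliding_window_view(keys, ww)
    arg = np.argmin(windows, axis=1)  # first occurrence on ties
    pos = arg + np.arange(len(windows))
    sel = windows[np.arange(len(windows)), arg] != _UINT64_MAX
    return np.unique(pos[sel])


def minimizers(seq: str, config: KmerConfig) -> list[tuple[int, str]]:
    """Minimizers of a sequence as (position, canonical k-mer) pairs.

    Every window of ``w`` consecutive valid k-mers contributes its
    smallest-key k-mer; duplicate positions are collapsed.  Sequences
    shorter than ``k`` yield an empty list.
    """
    codes, valid = kmer_codes(seq, config.k)
    if len(codes) == 0:
        return []
    can = canonical_codes(codes, config.k)
    keys = minimizer_key(can)
    keys = np.where(valid, keys, _UINT64_MAX)
    pos = _minimizer_positions(keys, config.w)
    return [(int(p), decode_kmer(int(can[p]), config.k)) for p in pos]


# ---------------------------------------------------------------------------
# Locating occurrences on the graph
# ---------------------------------------------------------------------------

#: An exact k-mer placement: the oriented nodes it spans (in reading order
#: of the canonical strand) and the offset of its first base in the first
#: spanned node's oriented sequence.
GraphPosition = tuple[tuple[OrientedNode, ...], int]


def _path_base_map(
    graph: PangenomeGraph, steps: tuple[OrientedNode, ...]
) -> tuple[str, np.ndarray, np.ndarray]:
    """Path sequence plus per-base (step index, in-node offset) arrays."""
    seq = graph.steps_sequence(steps)
    lengths = np.array([graph.node_length(s.node_id) for s in steps], dtype=np.int64)
    step_idx = np.repeat(np.arange(len(steps), dtype=np.int64), lengths)
    starts = np.concatenate(([0], np.cumsum(lengths)))[:-1]
    offsets = np.arange(len(seq), dtype=np.int64) - starts[step_idx]
    return seq, step_idx, offsets


def _occurrence_position(
    graph: PangenomeGraph,
    steps: tuple[OrientedNode, ...],
    step_idx: np.ndarray,
    offsets: np.ndarray,
    p: int,
    k: int,
    forward_is_canonical: bool,
) -> GraphPosition:
    i0, i1 = int(step_idx[p]), int(step_idx[p + k - 1])
    span = steps[i0 : i1 + 1]
    if forward_is_canonical:
        return (span, int(offsets[p]))
    # Read on the opposite strand: reversed span, flipped orientations.
    last_len = graph.node_length(steps[i1].node_id)
    off = last_len - 1 - int(offsets[p + k - 1])
    return (tuple(s.flip() for s in reversed(span)), off)


def graph_unique_minimizers(
    graph: PangenomeGraph, config: KmerConfig
) -> dict[str, GraphPosition]:
    """Minimizers with a single occurrence position in the graph.

    Scans every embedded path's sequence for minimizers, then locates all
    occurrences of the selected canonical k-mers along the paths (k-mers
    may span node boundaries) and keeps those whose set of distinct graph
    positions has size one.  Occurrences are only visible where a path
    passes, mirroring a haplotype-based index.
    """
    k = config.k
    path_data = []
    selected: set[int] = set()
    for path in graph.paths.values():
        seq, step_idx, offsets = _path_base_map(graph, path.steps)
        codes, valid = kmer_codes(seq, k)
        if len(codes) == 0:
            path_data.append((path, step_idx, offsets, codes, valid, None))
            continue
        can = canonical_codes(codes, k)
        keys = np.where(valid, minimizer_key(can), _UINT64_MAX)
        pos = _minimizer_positions(keys, config.w)
        selected.update(int(can[p]) for p in pos)
        path_data.append((path, step_idx, offsets, codes, valid, can))

    sel_arr = np.fromiter(selected, dtype=np.uint64, count=len(selected))
    positions: dict[int, GraphPosition] = {}
    ambiguous: set[int] = set()
    for path, step_idx, offsets, codes, valid, can in path_data:
        if can is None or len(sel_arr) == 0:
            continue
        hit = valid & np.isin(can, sel_arr)
        for p in np.nonzero(hit)[0]:
            code = int(can[p])
            if code in ambiguous:
                continue
            gp = _occurrence_position(
                graph, path.steps, step_idx, offsets, int(p), k,
                forward_is_canonical=int(codes[p]) == code,
            )
            prev = positions.get(code)
            if prev is None:
                positions[code] = gp
            elif prev != gp:
                ambiguous.add(code)
                del positions[code]
    return {decode_kmer(code, k): gp for code, gp in positions.items()}


# ---------------------------------------------------------------------------
# Presence matrices
# ---------------------------------------------------------------------------


@dataclass
class KmerPresenceMatrix:
    """Binary local-haplotype x graph-unique-k-mer membership matrix."""

    block: Block
    kmers: list[str]
    rows: list[LocalHaplotype]
    matrix: np.ndarray  # bool, shape (len(rows), len(kmers))

    def __post_init__(self) -> None:
        assert self.matrix.shape == (len(self.rows), len(self.kmers))


def _position_sort_key(gp: GraphPosition, kmer: str):
    span, off = gp
    return (tuple((s.node_id, s.is_reverse) for s in span), off, kmer)


def build_presence_matrix(
    graph: PangenomeGraph,
    block: Block,
    local_haps: list[LocalHaplotype],
    unique_kmers: dict[str, GraphPosition],
    config: KmerConfig,
) -> KmerPresenceMatrix:
    """Presence matrix of a block.

    Columns are the graph-unique k-mers whose occurrence position lies
    entirely inside the block and whose presence pattern across the
    block's local haplotypes is neither all-ones nor all-zeros.  Blocks
    with fewer than two local haplotypes have zero columns — nothing
    distinguishes haplotypes there.
    """
    rows = sorted(local_haps, key=lambda lh: lh.sort_key)
    block_nodes = {s.node_id for lh in rows for s in lh.steps}
    cols = [
        (kmer, gp)
        for kmer, gp in unique_kmers.items()
        if all(s.node_id in block_nodes for s in gp[0])
    ]
    cols.sort(key=lambda item: _position_sort_key(item[1], item[0]))
    if len(rows) < 2 or not cols:
        return KmerPresenceMatrix(block, [], rows, np.zeros((len(rows), 0), dtype=bool))

    col_codes = np.array([encode_kmer(kmer) for kmer, _ in cols], dtype=np.uint64)
    mat = np.zeros((len(rows), len(cols)), dtype=bool)
    for r, lh in enumerate(rows):
        seq = graph.steps_sequence(lh.steps)
        codes, valid = kmer_codes(seq, config.k)
        if len(codes) == 0:
            continue
        present = np.unique(canonical_codes(codes, config.k)[valid])
        mat[r] = np.isin(col_codes, present)

    informative = ~(mat.all(axis=0) | (~mat).all(axis=0))
    return KmerPresenceMatrix(
        block,
        [kmer for (kmer, _), keep in zip(cols, informative) if keep],
        rows,
        mat[:, informative],
    )
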