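"""Seeded synthetic panels, bubble graphs and diploid short reads.

The generator emulates, at desk scale, the setting the sampler targets: a
haplotype panel derived from one base sequence by SNPs, small indels and
structural variants; the corresponding bubble graph with a single chain
and exactly two tips per component; and error-bearing short reads drawn
from a diploid pair of panel haplotypes (or recombinants of them) at a
stated coverage.  Every draw is driven by a caller-supplied seed, and the
truth — variants, per-haplotype alleles, the sequenced pair — is recorded
for recovery scoring.

Variants use padded (VCF-style) alleles, so every bubble branch is a
non-empty node.  A "30x" sample means 30x base coverage of the diploid
genome, i.e. ~15x per haplotype; the corresponding homozygous k-mer
coverage is about ``30 * (L - k + 1) / L`` for read length ``L``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

from .graph_io import OrientedNode, PangenomeGraph, Path

__all__ = [
    "Variant",
    "PanelTruth",
    "DiploidSample",
    "simulate_panel",
    "build_panel_graph",
    "panel_path_steps",
    "recombinant_assignment",
    "simulate_diploid_reads",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"
SV_INSERTION = "SV-insertion"
SV_DELETION = "SV-deletion"


@dataclass(frozen=True)
class Variant:
    """A biallelic site on the base sequence (0-based, padded alleles)."""

    position: int
    kind: str
    ref_allele: str
    alt_allele: str
    frequency: float

    @property
    def ref_span(self) -> int:
        return len(self.ref_allele)


@dataclass
class PanelTruth:
    """A haplotype panel: base sequence, variants, allele assignments."""

    seed: int
    base: str
    variants: list[Variant]
    #: shape (n_haplotypes, n_variants); 1 = alt allele
    assignments: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.assignments.shape[0]

    def haplotype_name(self, i: int) -> str:
        return f"hap{i:03d}#0#chr1"

    def haplotype_sequence(self, i: int) -> str:
        return self.assignment_sequence(self.assignments[i])

    def assignment_sequence(self, row: np.ndarray) -> str:
        parts = []
        prev = 0
        for v, allele in zip(self.variants, row):
            parts.append(self.base[prev : v.position])
            parts.append(v.alt_allele if allele else v.ref_allele)
            prev = v.position + v.ref_span
        parts.append(self.base[prev:])
        return "".join(parts)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def simulate_panel(
    length: int = 100_000,
    n_haplotypes: int = 10,
    snp_rate: float = 1 / 500,
    indel_rate: float = 1 / 5000,
    sv_rate: float = 1 / 20_000,
    seed: int = 0,
    indel_size: tuple[int, int] = (1, 10),
    sv_size: tuple[int, int] = (50, 2000),
) -> PanelTruth:
    """Simulate a seeded haplotype panel.

    Variant sites arise as a per-base Bernoulli process at the given
    rates; alternate-allele frequencies are drawn from Beta(0.5, 0.5) so
    both common and rare variants occur.  Sites are kept non-overlapping
    with at least one reference base between them.
    """
    rates = (snp_rate, indel_rate, sv_rate)
    if any(r < 0 or r >= 1 for r in rates):
        raise ValueError("rates must lie in [0, 1)")
    total = sum(rates)
    if total >= 1:
        raise ValueError("variant rates must sum to < 1 per position")
    if length < 1000:
        raise ValueError("panel length must be at least 1 kb")
    rng = np.random.default_rng(seed)
    base = _random_seq(rng, length)

    hits = np.nonzero(rng.random(length) < total)[0]
    kinds = rng.choice(3, size=len(hits), p=np.array(rates) / total)
    variants: list[Variant] = []
    prev_end = 1  # keep the first base as a leading reference segment
    for pos, kind_idx in zip(hits.tolist(), kinds.tolist()):
        if pos < prev_end + 1:
            continue
        if kind_idx == 0:
            ref = base[pos]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            kind = SNP
        else:
            lo, hi = indel_size if kind_idx == 1 else sv_size
            size = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5:  # insertion
                ref = base[pos]
                alt = ref + _random_seq(rng, size)
                kind = INSERTION if kind_idx == 1 else SV_INSERTION
            else:  # deletion
                if pos + 1 + size > length - 1:
                    continue
                ref = base[pos : pos + 1 + size]
                alt = base[pos]
                kind = DELETION if kind_idx == 1 else SV_DELETION
        if pos + len(ref) > length - 1:
            continue  # keep a non-empty trailing reference segment
        freq = float(rng.beta(0.5, 0.5))
        variants.append(Variant(pos, kind, ref, alt, freq))
        prev_end = pos + len(ref)

    freqs = np.array([v.frequency for v in variants])
    assignments = (rng.random((n_haplotypes, len(variants))) < freqs).astype(np.int8)
    return PanelTruth(seed, base, variants, assignments)


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def _panel_layout(truth: PanelTruth):
    """Node ids/sequences plus per-site (ref node, alt node, flanks)."""
    used_alt = truth.assignments.any(axis=0)
    nodes: list[tuple[str, str]] = []
    next_id = 1

    def new_node(seq: str) -> str:
        nonlocal next_id
        nid = str(next_id)
        next_id += 1
        nodes.append((nid, seq))
        return nid

    segments: list[str] = []
    sites: list[tuple[str, str | None]] = []  # (ref allele node, alt allele node)
    prev = 0
    for i, v in enumerate(truth.variants):
        segments.append(new_node(truth.base[prev : v.position]))
        ref_node = new_node(v.ref_allele)
        alt_node = new_node(v.alt_allele) if used_alt[i] else None
        sites.append((ref_node, alt_node))
        prev = v.position + v.ref_span
    segments.append(new_node(truth.base[prev:]))
    return nodes, segments, sites


def panel_path_steps(truth: PanelTruth, row: np.ndarray) -> tuple[OrientedNode, ...]:
    """Oriented-node walk for one allele-assignment row."""
    _, segments, sites = _panel_layout(truth)
    steps = []
    for i, (ref_node, alt_node) in enumerate(sites):
        steps.append(OrientedNode(segments[i]))
        chosen = alt_node if row[i] else ref_node
        if chosen is None:  # assignment says alt but no haplotype uses it
            raise ValueError("assignment selects an allele absent from the panel graph")
        steps.append(OrientedNode(chosen))
    steps.append(OrientedNode(segments[-1]))
    return tuple(steps)


def build_panel_graph(truth: PanelTruth) -> PangenomeGraph:
    """Bubble graph of a panel: one node per reference segment and allele.

    Haplotype walks follow the allele assignments; the reference path
    takes the reference allele at every site.  By construction each
    component is a single chain with exactly two tips.
    """
    graph = PangenomeGraph()
    nodes, segments, sites = _panel_layout(truth)
    for nid, seq in nodes:
        graph.add_node(nid, seq)
    for i, (ref_node, alt_node) in enumerate(sites):
        left, right = segments[i], segments[i + 1]
        for allele in (ref_node, alt_node):
            if allele is None:
                continue
            graph.add_edge((left, "R"), (allele, "L"))
            graph.add_edge((allele, "R"), (right, "L"))

    ref_steps = []
    for i, (ref_node, _) in enumerate(sites):
        ref_steps.append(OrientedNode(segments[i]))
        ref_steps.append(OrientedNode(ref_node))
    ref_steps.append(OrientedNode(segments[-1]))
    graph.add_path(Path("chr1", tuple(ref_steps), is_reference=True))

    for h in range(truth.n_haplotypes):
        steps = panel_path_steps(truth, truth.assignments[h])
        graph.add_path(Path(truth.haplotype_name(h), steps, is_reference=False))
    graph.validate()
    return graph


def recombinant_assignment(
    truth: PanelTruth, donors: tuple[int, int], breakpoints: list[int]
) -> np.ndarray:
    """Allele row switching between two donors at base-coordinate breakpoints."""
    a, b = donors
    row = np.empty(len(truth.variants), dtype=np.int8)
    for i, v in enumerate(truth.variants):
        switches = sum(1 for bp in breakpoints if v.position >= bp)
        donor = (a, b)[switches % 2]
        row[i] = truth.assignments[donor, i]
    return row


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class DiploidSample:
    """Read-set parameters for a diploid sample drawn from the panel.

    ``haplotypes`` holds the two sequenced haplotype sequences and
    ``truth_rows`` their allele-assignment rows (panel haplotypes or
    recombinants), recorded for recovery scoring.
    """

    haplotypes: tuple[str, str]
    truth_rows: tuple[np.ndarray, np.ndarray]
    coverage: float = 30.0
    read_length: int = 150
    error_rate: float = 0.001
    seed: int = 0


def simulate_diploid_reads(sample: DiploidSample) -> list[tuple[str, str]]:
    """Simulate (name, sequence) short reads from a diploid pair.

    Reads are drawn uniformly from both haplotypes on random strands;
    substitution errors are i.i.d. at the stated rate.  The read count is
    ``coverage * mean_haplotype_length / read_length``, giving the stated
    total base coverage of the diploid genome.
    """
    if sample.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(sample.seed)
    h1, h2 = sample.haplotypes
    L = sample.read_length
    if L > min(len(h1), len(h2)):
        raise ValueError("read length exceeds a haplotype length")
    mean_len = (len(h1) + len(h2)) / 2
    n_reads = int(round(sample.coverage * mean_len / L))
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    dec = "ACGT"
    reads: list[tuple[str, str]] = []
    haps = (h1, h2)
    which = rng.integers(0, 2, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    for i in range(n_reads):
        hap = haps[which[i]]
        start = int(rng.integers(0, len(hap) - L + 1))
        seq = hap[start : start + L]
        if strands[i]:
            from .graph_io import reverse_complement

            seq = reverse_complement(seq)
        if sample.error_rate > 0:
            errs = np.nonzero(rng.random(L) < sample.error_rate)[0]
            if len(errs):
                chars = list(seq)
                for p in errs.tolist():
                    chars[p] = dec[(enc[chars[p]] + int(rng.integers(1, 4))) % 4]
                seq = "".join(chars)
        reads.append((f"read{i}/{which[i]}", seq))
    return reads


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write (name, sequence) reads as FASTQ (gzip if the path ends in .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
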