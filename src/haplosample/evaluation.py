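"""Recovery harness: score sampled haplotypes against simulation truth.

Given a sampling index, read k-mer counts and the two *donor* haplotypes
a synthetic diploid sample was sequenced from, this module reruns the
per-block selection and measures how often the truth is recovered.  Two
notions are used: *pair recovery* (the selected diploid pair equals the
donor pair's local haplotypes, as step sequences) and *donor match*
(every selected local haplotype equals one of the two donors' locals —
the relevant notion for recombinant samples, whose genome-wide haplotypes
are absent from the panel).  Blocks are *informative* when each donor's
local haplotype carries at least ``min_distinguishing`` presence-matrix
k-mers separating it from the other donor's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_io import OrientedNode, PangenomeGraph
from .index import HaplotypeIndex
from .kmer_index import KmerPresenceMatrix
from .read_profile import ClassificationThresholds, KmerCounts, ReadProfile
from .sampler import SamplerConfig, _select_block
from .synthetic import (
    DiploidSample,
    PanelTruth,
    build_panel_graph,
    panel_path_steps,
    simulate_diploid_reads,
    simulate_panel,
)

__all__ = ["RecoveryResult", "evaluate_recovery", "synthetic_scenario", "Scenario"]


@dataclass
class RecoveryResult:
    """Per-block recovery tallies for one evaluation run."""

    blocks_total: int = 0
    blocks_scored: int = 0  # blocks with a non-empty presence matrix
    blocks_informative: int = 0
    pair_recovered: int = 0
    members_matched: int = 0

    @property
    def pair_recovery_rate(self) -> float:
        return self.pair_recovered / self.blocks_informative if self.blocks_informative else float("nan")

    @property
    def member_match_rate(self) -> float:
        return self.members_matched / self.blocks_informative if self.blocks_informative else float("nan")


def _slice_by_boundaries(
    steps: tuple[OrientedNode, ...], left: str, right: str
) -> tuple[OrientedNode, ...] | None:
    li = ri = None
    for i, s in enumerate(steps):
        if s.node_id == left:
            li = i
        elif s.node_id == right:
            ri = i
    if li is None or ri is None or ri <= li:
        return None
    return steps[li : ri + 1]


def evaluate_recovery(
    index: HaplotypeIndex,
    counts: KmerCounts,
    donor_steps: tuple[tuple[OrientedNode, ...], tuple[OrientedNode, ...]],
    config: SamplerConfig,
    coverage: float | None = None,
    thresholds: ClassificationThresholds | None = None,
    min_distinguishing: int = 5,
) -> RecoveryResult:
    """Rerun per-block selection and compare against the donor pair."""
    profile = ReadProfile.build(
        counts, sorted(index.all_matrix_kmers()), coverage, thresholds
    )
    result = RecoveryResult()
    for comp in index.components:
        for ib in comp.blocks:
            matrix = ib.matrix
            result.blocks_total += 1
            if matrix.matrix.shape[1] == 0:
                continue
            result.blocks_scored += 1
            locals_ = [
                _slice_by_boundaries(d, ib.block.left.node_id, ib.block.right.node_id)
                for d in donor_steps
            ]
            if any(l is None for l in locals_):
                continue
            by_steps = {tuple(r.steps): i for i, r in enumerate(matrix.rows)}
            rows = [by_steps.get(tuple(l)) for l in locals_]
            if any(r is None for r in rows):
                continue  # a donor's local is not a panel row here
            a, b = rows
            only_a = int((matrix.matrix[a] & ~matrix.matrix[b]).sum())
            only_b = int((matrix.matrix[b] & ~matrix.matrix[a]).sum())
            if min(only_a, only_b) < min_distinguishing:
                continue
            result.blocks_informative += 1
            selected, _ = _select_block(matrix, profile, config)
            sel_steps = [tuple(lh.steps) for lh in selected]
            truth_steps = sorted([tuple(l) for l in locals_])
            if sorted(sel_steps) == truth_steps:
                result.pair_recovered += 1
            if all(s in truth_steps for s in sel_steps):
                result.members_matched += 1
    return result


@dataclass
class Scenario:
    """A complete seeded synthetic experiment, ready for sampling."""

    truth: PanelTruth
    graph: PangenomeGraph
    index: HaplotypeIndex
    counts: KmerCounts
    sample: DiploidSample
    donor_steps: tuple[tuple[OrientedNode, ...], tuple[OrientedNode, ...]]
    donors: tuple[int, int]


def synthetic_scenario(
    seed: int,
    length: int = 100_000,
    n_haplotypes: int = 10,
    snp_rate: float = 1 / 500,
    indel_rate: float = 1 / 5000,
    sv_rate: float = 1 / 20_000,
    coverage: float = 30.0,
    read_length: int = 150,
    error_rate: float = 0.001,
    b: int = 10_000,
    recombinant_breakpoints: list[int] | None = None,
) -> Scenario:
    """Simulate a panel, build its graph and index, and sequence a sample.

    With ``recombinant_breakpoints`` the sequenced haplotypes are held-out
    recombinants of the two donors (the donors' genomes are still what
    block-local selections are scored against).
    """
    from .index import build_index
    from .kmer_index import KmerConfig
    from .read_profile import count_read_kmers
    from .synthetic import recombinant_assignment

    truth = simulate_panel(
        length=length,
        n_haplotypes=n_haplotypes,
        snp_rate=snp_rate,
        indel_rate=indel_rate,
        sv_rate=sv_rate,
        seed=seed,
    )
    graph = build_panel_graph(truth)
    index = build_index(graph, KmerConfig(), b=b)
    rng = np.random.default_rng(seed + 1)
    donors = tuple(int(x) for x in rng.choice(n_haplotypes, 2, replace=False))
    if recombinant_breakpoints:
        rows = (
            recombinant_assignment(truth, donors, recombinant_breakpoints),
            recombinant_assignment(
                truth, (donors[1], donors[0]), recombinant_breakpoints
            ),
        )
        hap_seqs = tuple(truth.assignment_sequence(r) for r in rows)
    else:
        rows = (truth.assignments[donors[0]], truth.assignments[donors[1]])
        hap_seqs = tuple(truth.haplotype_sequence(d) for d in donors)
    sample = DiploidSample(
        haplotypes=hap_seqs,
        truth_rows=rows,
        coverage=coverage,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed + 2,
    )
    reads = [s for _, s in simulate_diploid_reads(sample)]
    counts = count_read_kmers(reads, index.k)
    donor_steps = (
        panel_path_steps(truth, truth.assignments[donors[0]]),
        panel_path_steps(truth, truth.assignments[donors[1]]),
    )
    return Scenario(truth, graph, index, counts, sample, donor_steps, donors)
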