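from __future__ import annotations

import numpy as np
import pytest

from haplosample import (
    KmerConfig,
    KmerCounts,
    SamplerConfig,
    build_index,
    build_panel_graph,
    count_read_kmers,
    sample_graph,
    simulate_panel,
    write_gfa,
)
from haplosample.chains import Block, LocalHaplotype, OrientedNode
from haplosample.kmer_index import KmerPresenceMatrix
from haplosample.read_profile import (
    ABSENT,
    FREQUENT,
    HETEROZYGOUS,
    HOMOZYGOUS,
    ClassificationThresholds,
    ReadProfile,
)
from haplosample.sampler import (
    ComponentSelection,
    ScoreState,
    diploid_select,
    greedy_select,
    initial_scores,
    stitch_haplotypes,
)
from haplosample.synthetic import DiploidSample, simulate_diploid_reads
from oracles import diploid_oracle, greedy_oracle


def make_matrix(presence, classes, names=None):
    presence = np.asarray(presence, dtype=bool)
    r, c = presence.shape
    names = names or [f"hap{i:02d}#0#c" for i in range(r)]
    block = Block(0, 0, OrientedNode("L0"), OrientedNode("R0"), 0, 1, 100)
    rows = [
        LocalHaplotype(names[i], 0, False, (OrientedNode(f"n{i}"),)) for i in range(r)
    ]
    kmers = [f"K{j}" for j in range(c)]
    matrix = KmerPresenceMatrix(block, kmers, rows, presence)
    profile = ReadProfile(
        KmerCounts(29, {}),
        30.0,
        {f"K{j}": classes[j] for j in range(c)},
        ClassificationThresholds(),
    )
    return matrix, profile


class TestInitialScores:
    def test_published_constants_direct_arithmetic(self):
        # K1 homozygous, present only in A; K2 absent-class, present only in B.
        matrix, profile = make_matrix(
            [[True, False], [False, True]], [HOMOZYGOUS, ABSENT]
        )
        state = initial_scores(matrix, profile, SamplerConfig())
        totals = state.totals()
        assert totals[0] == pytest.approx(1 + 0.8)
        assert totals[1] == pytest.approx(-1 - 0.8)

    def test_heterozygous_kmers_start_neutral(self):
        matrix, profile = make_matrix(
            [[True, False], [False, True]], [HETEROZYGOUS, HETEROZYGOUS]
        )
        state = initial_scores(matrix, profile, SamplerConfig())
        assert np.allclose(state.totals(), 0.0)

    def test_frequent_columns_are_dropped(self):
        matrix, profile = make_matrix([[True], [False]], [FREQUENT])
        state = initial_scores(matrix, profile, SamplerConfig())
        assert state.matrix.shape == (2, 0)

    def test_unclassified_column_is_an_error(self):
        matrix, profile = make_matrix([[True], [False]], [HOMOZYGOUS])
        profile.classes.clear()
        with pytest.raises(ValueError, match="classification"):
            initial_scores(matrix, profile, SamplerConfig())


class TestGreedySelect:
    def test_homozygous_discount_after_first_pick(self):
        # One homozygous k-mer present in A and B, absent in C.
        matrix, profile = make_matrix(
            [[True], [True], [False]], [HOMOZYGOUS]
        )
        state = initial_scores(matrix, profile, SamplerConfig())
        picks = greedy_select(state, SamplerConfig(n=1))
        assert picks == [0]  # tie between A and B broken by row order
        assert state.score_present[0] == pytest.approx(0.9)
        assert state.score_absent[0] == pytest.approx(-0.9)

    def test_heterozygous_update_flips_the_next_pick(self):
        # One het k-mer present in A and C, absent in B; after picking A
        # the opposite (non-carrier) haplotype B is preferred over C.
        matrix, profile = make_matrix(
            [[True], [False], [True]], [HETEROZYGOUS]
        )
        state = initial_scores(matrix, profile, SamplerConfig())
        picks = greedy_select(state, SamplerConfig(n=1))
        assert picks == [0]
        totals = state.totals()
        assert totals[1] == pytest.approx(0.05)
        assert totals[2] == pytest.approx(-0.05)
        state2 = initial_scores(matrix, profile, SamplerConfig())
        assert greedy_select(state2, SamplerConfig(n=2)) == [0, 1]

    def test_cycles_when_n_exceeds_rows(self):
        matrix, profile = make_matrix([[True], [False]], [HOMOZYGOUS])
        state = initial_scores(matrix, profile, SamplerConfig())
        with pytest.warns(UserWarning, match="repeating"):
            picks = greedy_select(state, SamplerConfig(n=5))
        assert picks == [0, 1, 0, 1, 0]

    def test_score_bookkeeping_conservation(self, rng):
        presence = rng.random((6, 12)) < 0.5
        classes = list(rng.choice([HOMOZYGOUS, HETEROZYGOUS, ABSENT], 12))
        matrix, profile = make_matrix(presence, classes)
        state = initial_scores(matrix, profile, SamplerConfig())
        greedy_select(state, SamplerConfig(n=6))
        for j, cls in enumerate(state.classes):
            if cls == HETEROZYGOUS:
                assert state.score_present[j] + state.score_absent[j] == pytest.approx(0)
            elif cls == HOMOZYGOUS:
                assert state.score_present[j] > 0 > state.score_absent[j]
            else:
                assert state.score_present[j] < 0 < state.score_absent[j]

    def test_matches_stepwise_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            r = int(rng.integers(1, 7))
            c = int(rng.integers(1, 13))
            n = int(rng.integers(1, 5))
            presence = rng.random((r, c)) < rng.uniform(0.2, 0.8)
            classes = list(
                rng.choice([HOMOZYGOUS, HETEROZYGOUS, ABSENT, FREQUENT], c)
            )
            matrix, profile = make_matrix(presence, classes)
            state = initial_scores(matrix, profile, SamplerConfig())
            got = greedy_select(state, SamplerConfig(n=n))
            kept = [cl for cl in classes if cl != FREQUENT]
            kept_presence = presence[:, [j for j, cl in enumerate(classes) if cl != FREQUENT]]
            want = greedy_oracle(kept_presence.tolist(), kept, n)
            assert got == want


class TestDiploidSelect:
    def test_copy_number_score_contributions(self):
        # Single hom k-mer (x=2): pair (A,A) with the k-mer scores 1,
        # pair (B,B) without it scores -1.
        matrix, profile = make_matrix([[True], [False]], [HOMOZYGOUS])
        state = initial_scores(matrix, profile, SamplerConfig())
        (pair, score, ties) = diploid_select([0, 1], state)
        assert pair == (0, 0)
        assert score == pytest.approx(1.0)

    def test_absent_kmer_penalizes_carriers(self):
        matrix, profile = make_matrix([[True], [False]], [ABSENT])
        state = initial_scores(matrix, profile, SamplerConfig())
        (pair, score, _) = diploid_select([0, 1], state)
        assert pair == (1, 1)  # x=0 wants y=0
        assert score == pytest.approx(1.0)

    def test_selected_pair_attains_enumerated_maximum(self, rng):
        for _ in range(100):
            r = int(rng.integers(2, 9))
            c = int(rng.integers(1, 13))
            presence = rng.random((r, c)) < 0.5
            classes = list(
                rng.choice([HOMOZYGOUS, HETEROZYGOUS, ABSENT, FREQUENT], c)
            )
            matrix, profile = make_matrix(presence, classes)
            state = initial_scores(matrix, profile, SamplerConfig())
            cands = list(range(r))
            (pair, score, _) = diploid_select(cands, state)
            want_pair, want_score = diploid_oracle(
                cands, presence.tolist(), classes
            )
            assert score == pytest.approx(want_score)
            assert pair == want_pair

    def test_requires_two_candidates(self):
        matrix, profile = make_matrix([[True], [False]], [HOMOZYGOUS])
        state = initial_scores(matrix, profile, SamplerConfig())
        with pytest.raises(ValueError):
            diploid_select([0], state)


def lh(name, ordinal, *node_ids):
    return LocalHaplotype(name, ordinal, False, tuple(OrientedNode(i) for i in node_ids))


def fake_component(n_blocks=2):
    from haplosample.index import IndexedComponent

    return IndexedComponent(0, (), [])


class TestStitchHaplotypes:
    def test_same_haplotype_across_blocks_no_recombination(self):
        sel = ComponentSelection(
            fake_component(),
            [[lh("A", 0, "1", "2")], [lh("A", 0, "2", "3")]],
        )
        paths, recombs = stitch_haplotypes(sel)
        assert [s.node_id for s in paths[0].steps] == ["1", "2", "3"]
        assert recombs == [0]

    def test_switching_haplotypes_counts_a_recombination(self):
        sel = ComponentSelection(
            fake_component(),
            [[lh("A", 0, "1", "2")], [lh("B", 0, "2", "3")]],
        )
        paths, recombs = stitch_haplotypes(sel)
        assert recombs == [1]

    def test_three_blocks_two_clean_paths(self):
        sel = ComponentSelection(
            fake_component(3),
            [
                [lh("A", 0, "1", "2"), lh("B", 0, "1", "9", "2")],
                [lh("A", 0, "2", "3"), lh("B", 0, "2", "3")],
                [lh("A", 0, "3", "4"), lh("B", 0, "3", "8", "4")],
            ],
        )
        paths, recombs = stitch_haplotypes(sel)
        assert [s.node_id for s in paths[0].steps] == ["1", "2", "3", "4"]
        assert [s.node_id for s in paths[1].steps] == ["1", "9", "2", "3", "8", "4"]
        assert recombs == [0, 0]

    def test_mismatched_selection_counts_error(self):
        sel = ComponentSelection(
            fake_component(),
            [[lh("A", 0, "1", "2")], [lh("A", 0, "2", "3"), lh("B", 0, "2", "3")]],
        )
        with pytest.raises(ValueError, match="differ"):
            stitch_haplotypes(sel)


@pytest.fixture(scope="module")
def pipeline_inputs():
    truth = simulate_panel(length=20_000, n_haplotypes=6, seed=8)
    graph = build_panel_graph(truth)
    idx = build_index(graph, KmerConfig(), b=5000)
    pair = (0, 3)
    sample = DiploidSample(
        haplotypes=(truth.haplotype_sequence(0), truth.haplotype_sequence(3)),
        truth_rows=(truth.assignments[0], truth.assignments[3]),
        coverage=30.0,
        seed=9,
    )
    counts = count_read_kmers([s for _, s in simulate_diploid_reads(sample)], 29)
    return truth, graph, idx, counts


class TestSampleGraph:
    def test_subgraph_invariant_and_valid_paths(self, pipeline_inputs):
        truth, graph, idx, counts = pipeline_inputs
        sampled, report = sample_graph(
            graph, idx, counts, SamplerConfig(n=4, diploid=True)
        )
        assert set(sampled.nodes) <= set(graph.nodes)
        assert sampled.edges <= graph.edges
        from haplosample.graph_io import step_edge

        for p in sampled.paths.values():
            for a, b in zip(p.steps, p.steps[1:]):
                assert step_edge(a, b) in graph.edges

    def test_deterministic_output(self, pipeline_inputs, tmp_path):
        truth, graph, idx, counts = pipeline_inputs
        cfg = SamplerConfig(n=4, diploid=True, include_reference=True)
        g1, r1 = sample_graph(graph, idx, counts, cfg)
        g2, r2 = sample_graph(graph, idx, counts, cfg)
        assert g1 == g2 and r1 == r2
        a, b = tmp_path / "a.gfa", tmp_path / "b.gfa"
        write_gfa(g1, a)
        write_gfa(g2, b)
        assert a.read_bytes() == b.read_bytes()

    def test_saturation_recovers_haplotype_covered_graph(self, pipeline_inputs):
        truth, graph, idx, counts = pipeline_inputs
        cfg = SamplerConfig(n=truth.n_haplotypes + 1, include_reference=True)
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            sampled, _ = sample_graph(graph, idx, counts, cfg)
        covered_nodes = {
            s.node_id for p in graph.paths.values() for s in p.steps
        }
        assert set(sampled.nodes) == covered_nodes
        from haplosample.graph_io import step_edge

        covered_edges = {
            step_edge(a, b)
            for p in graph.paths.values()
            for a, b in zip(p.steps, p.steps[1:])
        }
        assert sampled.edges == covered_edges

    def test_parameter_mismatch_detected(self, pipeline_inputs):
        from haplosample import ParameterMismatchError

        truth, graph, idx, counts = pipeline_inputs
        bad = KmerCounts(31, dict(list(counts.counts.items())[:10]))
        with pytest.raises(ParameterMismatchError):
            sample_graph(graph, idx, bad, SamplerConfig(n=2))

    def test_index_json_roundtrip_same_sampling(self, pipeline_inputs, tmp_path):
        from haplosample import HaplotypeIndex

        truth, graph, idx, counts = pipeline_inputs
        path = tmp_path / "idx.json"
        idx.to_json(path)
        idx2 = HaplotypeIndex.from_json(path)
        cfg = SamplerConfig(n=4, diploid=True)
        g1, _ = sample_graph(graph, idx, counts, cfg)
        g2, _ = sample_graph(graph, idx2, counts, cfg)
        assert g1 == g2
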