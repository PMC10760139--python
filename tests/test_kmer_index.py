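from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from haplosample import (
    KmerConfig,
    OrientedNode,
    PangenomeGraph,
    Path,
    build_index,
    build_presence_matrix,
    canonical_kmer,
    graph_unique_minimizers,
    minimizers,
    reverse_complement,
)
from haplosample.chains import decompose_component, local_haplotypes, partition_into_blocks
from oracles import bruteforce_minimizers, substring_occurrences

dna = st.text(alphabet="ACGT", min_size=0, max_size=300)


class TestCanonicalKmer:
    def test_lexicographic_minimum(self):
        assert canonical_kmer("ACG") == "ACG"  # revcomp CGT is larger
        assert canonical_kmer("CGT") == "ACG"

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    def test_strand_symmetry(self, kmer):
        assert canonical_kmer(kmer) == canonical_kmer(reverse_complement(kmer))

    def test_n_gives_invalid_sentinel(self):
        assert canonical_kmer("ANG") is None

    def test_wrong_length_is_an_error(self):
        with pytest.raises(ValueError, match="length"):
            canonical_kmer("ACGT", k=3)


class TestKmerConfig:
    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            KmerConfig(k=4)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            KmerConfig(k=3, w=0)


class TestMinimizers:
    def test_sequence_of_length_k_yields_its_sole_kmer(self):
        cfg = KmerConfig(k=5, w=4)
        assert minimizers("ACGTA", cfg) == [(0, canonical_kmer("ACGTA"))]

    def test_short_sequence_yields_nothing(self):
        assert minimizers("AC", KmerConfig(k=5, w=2)) == []

    def test_matches_bruteforce_on_fixed_example(self):
        cfg = KmerConfig(k=3, w=2)
        seq = "ACGTACGTACG"
        assert minimizers(seq, cfg) == bruteforce_minimizers(seq, 3, 2)

    @given(dna)
    def test_matches_bruteforce_small_k(self, seq):
        cfg = KmerConfig(k=5, w=3)
        assert minimizers(seq, cfg) == bruteforce_minimizers(seq, 5, 3)

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=200))
    def test_matches_bruteforce_with_invalid_bases(self, seq):
        cfg = KmerConfig(k=3, w=4)
        assert minimizers(seq, cfg) == bruteforce_minimizers(seq, 3, 4)

    @given(dna.filter(lambda s: len(s) >= 40))
    def test_window_coverage_property(self, seq):
        """Every window of w consecutive k-mers contains a selected position."""
        cfg = KmerConfig(k=7, w=5)
        positions = {p for p, _ in minimizers(seq, cfg)}
        n_kmers = len(seq) - cfg.k + 1
        for start in range(n_kmers - cfg.w + 1):
            assert positions & set(range(start, start + cfg.w))


def one_path_graph(chunks: list[str], name="h#0#c") -> PangenomeGraph:
    g = PangenomeGraph()
    ids = [str(i + 1) for i in range(len(chunks))]
    for nid, seq in zip(ids, chunks):
        g.add_node(nid, seq)
    for a, b in zip(ids, ids[1:]):
        g.add_edge((a, "R"), (b, "L"))
    steps = tuple(OrientedNode(i) for i in ids)
    g.add_path(Path("ref", steps, is_reference=True))
    g.add_path(Path(name, steps, is_reference=False))
    return g


class TestGraphUniqueMinimizers:
    def test_repeated_kmer_excluded(self):
        # The 4-mer context repeats, so every k-mer inside the repeat is
        # seen at two graph positions and must be excluded.
        g = one_path_graph(["ACGTACGTT", "GGACGTACGTT"])
        cfg = KmerConfig(k=5, w=2)
        unique = graph_unique_minimizers(g, cfg)
        hap = g.path_sequence("h#0#c")
        for kmer in unique:
            assert substring_occurrences([hap], kmer) == 1

    def test_kmer_spanning_node_boundary_included(self):
        g = one_path_graph(["ACGTA", "GGCTT"])
        cfg = KmerConfig(k=5, w=1)  # w=1: every k-mer is a minimizer
        unique = graph_unique_minimizers(g, cfg)
        spanning = [
            (kmer, gp) for kmer, gp in unique.items() if len(gp[0]) == 2
        ]
        assert spanning, "expected k-mers spanning the node boundary"
        for kmer, (span, offset) in spanning:
            assert [s.node_id for s in span] in (["1", "2"], ["2", "1"])

    def test_no_repeats_keeps_every_minimizer(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 400))
        g = one_path_graph([seq[:150], seq[150:]])
        cfg = KmerConfig(k=11, w=5)
        unique = graph_unique_minimizers(g, cfg)
        mins = {kmer for _, kmer in minimizers(seq, cfg)}
        # Whatever the oracle says occurs once must be retained.
        expected = {m for m in mins if substring_occurrences([seq], m) == 1}
        assert set(unique) == expected


def snp_pair_graph():
    """Two haplotypes differing by a single SNP in the bubble middle."""
    g = PangenomeGraph()
    left, right = "ACGTAGGCTA", "TTACGGATCC"
    g.add_node("1", left)
    g.add_node("2", "C")
    g.add_node("3", "G")
    g.add_node("4", right)
    for allele in ("2", "3"):
        g.add_edge(("1", "R"), (allele, "L"))
        g.add_edge((allele, "R"), ("4", "L"))
    mk = lambda *ids: tuple(OrientedNode(i) for i in ids)
    g.add_path(Path("ref", mk("1", "2", "4"), is_reference=True))
    g.add_path(Path("a#0#c", mk("1", "2", "4"), False))
    g.add_path(Path("b#0#c", mk("1", "3", "4"), False))
    return g


class TestPresenceMatrix:
    def build(self, g, cfg, b=10_000):
        comp = g.components()[0]
        chain = decompose_component(g, comp)
        (block,) = partition_into_blocks(chain, b)
        lhs = [lh for lh in local_haplotypes(chain, block) if not lh.is_reference]
        unique = graph_unique_minimizers(g, cfg)
        return g, block, lhs, unique, cfg

    def test_snp_columns_cover_the_variant_site_only(self):
        cfg = KmerConfig(k=5, w=1)
        g, block, lhs, unique, cfg = self.build(snp_pair_graph(), cfg)
        matrix = build_presence_matrix(g, block, lhs, unique, cfg)
        seq_a = g.path_sequence("a#0#c")
        seq_b = g.path_sequence("b#0#c")
        assert matrix.kmers, "SNP should produce distinguishing k-mers"
        for j, kmer in enumerate(matrix.kmers):
            in_a = substring_occurrences([seq_a], kmer) > 0
            in_b = substring_occurrences([seq_b], kmer) > 0
            assert in_a != in_b  # each column separates the two haplotypes
            col = matrix.matrix[:, j]
            names = [matrix.rows[i].path_name for i in range(len(col)) if col[i]]
            assert names == (["a#0#c"] if in_a else ["b#0#c"])

    def test_kmer_present_in_all_haplotypes_is_uninformative(self):
        cfg = KmerConfig(k=5, w=1)
        g, block, lhs, unique, cfg = self.build(snp_pair_graph(), cfg)
        matrix = build_presence_matrix(g, block, lhs, unique, cfg)
        shared = canonical_kmer("ACGTA")  # prefix of both haplotypes
        assert shared in unique
        assert shared not in matrix.kmers

    def test_identical_haplotypes_give_zero_columns(self):
        cfg = KmerConfig(k=5, w=2)
        g = one_path_graph(["ACGTATTTGCA", "CCAGTTACGGA"])
        g.add_path(
            Path("h2#0#c", g.paths["h#0#c"].steps, False)
        )
        g2, block, lhs, unique, cfg = self.build(g, cfg)
        matrix = build_presence_matrix(g2, block, lhs, unique, cfg)
        assert matrix.kmers == []

    def test_single_row_gives_zero_columns(self):
        cfg = KmerConfig(k=5, w=2)
        g = one_path_graph(["ACGTATTTGCA", "CCAGTTACGGA"])
        g2, block, lhs, unique, cfg = self.build(g, cfg)
        only = [lh for lh in lhs if lh.path_name == "h#0#c"]
        matrix = build_presence_matrix(g2, block, only, unique, cfg)
        assert matrix.matrix.shape == (1, 0)

    def test_no_constant_columns_and_unique_occurrence(self, small_panel):
        truth, g = small_panel
        idx = build_index(g, KmerConfig(), b=5000)
        haps = [g.path_sequence(p.name) for p in g.paths.values()]
        checked = 0
        for comp in idx.components:
            for ib in comp.blocks:
                m = ib.matrix.matrix
                if m.shape[1] == 0:
                    continue
                assert not m.all(axis=0).any()
                assert m.any(axis=0).all()
                for kmer in ib.matrix.kmers[:3]:
                    assert substring_occurrences(haps, kmer) >= 1
                    checked += 1
        assert checked > 0

    def test_invariant_under_path_renaming(self):
        cfg = KmerConfig(k=5, w=1)
        g1 = snp_pair_graph()
        g2 = snp_pair_graph()
        renamed = {}
        for name, p in g2.paths.items():
            new = name.replace("a#", "x#").replace("b#", "y#")
            renamed[new] = Path(new, p.steps, p.is_reference)
        g2.paths = renamed
        m1 = build_presence_matrix(*self.build(g1, cfg)[:3], graph_unique_minimizers(g1, cfg), cfg)
        m2 = build_presence_matrix(*self.build(g2, cfg)[:3], graph_unique_minimizers(g2, cfg), cfg)
        assert m1.kmers == m2.kmers
        assert (m1.matrix == m2.matrix).all()
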