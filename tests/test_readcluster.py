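"""Clustering must agree with exhaustive all-vs-all alignment, conserve
reads across the partition, and respect the 90%/55% thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import mutated, planted_cluster_fixture, random_dna
from repeatscape.align import revcomp
from repeatscape.errors import InvalidArgumentError
from repeatscape.readcluster import (
    ClusterParams,
    Read,
    align_pair,
    build_clusters,
    candidate_pairs,
    pool_species,
)


def partition_of(result):
    return {frozenset(c.members) for c in result.clusters + result.remainder}


class TestCandidatePairs:
    def test_identical_reads_emitted(self, rng):
        seq = random_dna(rng, 100)
        reads = [Read("a", "s", seq), Read("b", "s", seq)]
        pairs = set(candidate_pairs(reads, ClusterParams(kmer_len=17)))
        assert pairs == {("a", "b")}

    def test_disjoint_kmer_reads_not_emitted(self):
        reads = [Read("a", "s", "A" * 100), Read("b", "s", "C" * 100)]
        assert list(candidate_pairs(reads, ClusterParams(kmer_len=17))) == []

    def test_reverse_complement_pair_emitted(self, rng):
        seq = random_dna(rng, 100)
        reads = [Read("a", "s", seq), Read("b", "s", revcomp(seq))]
        assert len(list(candidate_pairs(reads, ClusterParams(kmer_len=17)))) == 1

    def test_superset_of_truly_passing_pairs(self):
        """Every pair that passes align_pair is emitted by the prefilter."""
        reads = planted_cluster_fixture(seed=5, n_random=140, copies=(20, 20), divergence=0.03)
        params = ClusterParams()
        emitted = {frozenset(p) for p in candidate_pairs(reads, params)}
        by_id = {r.read_id: r for r in reads}
        ids = sorted(by_id)
        passing = {
            frozenset((a, b))
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
            if align_pair(by_id[a], by_id[b], params) is not None
        }
        assert passing <= emitted


class TestAlignPair:
    def test_self_alignment_is_perfect(self, rng):
        r = Read("a", "s", random_dna(rng, 120))
        edge = align_pair(r, Read("b", "s", r.seq))
        assert edge.identity == 1.0
        assert edge.overlap_fraction == 1.0

    def test_reverse_complement_symmetric(self, rng):
        seq = random_dna(rng, 100)
        edge = align_pair(Read("a", "s", seq), Read("b", "s", revcomp(seq)))
        assert edge is not None and edge.identity == 1.0

    @pytest.mark.parametrize("n_subs,expect_edge", [(8, True), (12, False)])
    def test_identity_threshold_arithmetic(self, n_subs, expect_edge):
        """8 interior substitutions in 100 nt -> identity 0.92 (edge);
        12 -> 0.88 (no edge)."""
        gen = np.random.default_rng(42)
        seq = random_dna(gen, 100)
        positions = np.linspace(6, 93, n_subs).astype(int)
        other = mutated(seq, positions, gen)
        edge = align_pair(Read("a", "s", seq), Read("b", "s", other))
        if expect_edge:
            assert edge is not None and edge.identity == pytest.approx(1 - n_subs / 100)
        else:
            assert edge is None

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 8))
    def test_symmetry(self, seed, n_subs):
        """align_pair(a, b) and align_pair(b, a) agree exactly."""
        gen = np.random.default_rng(seed)
        a = random_dna(gen, int(gen.integers(60, 120)))
        b = mutated(a, gen.choice(len(a), size=min(n_subs, len(a)), replace=False), gen)[: int(gen.integers(50, len(a) + 1))]
        ra, rb = Read("a", "s", a), Read("b", "s", b)
        e1, e2 = align_pair(ra, rb), align_pair(rb, ra)
        if e1 is None:
            assert e2 is None
        else:
            assert e1.identity == e2.identity
            assert e1.overlap_fraction == e2.overlap_fraction

    def test_n_bases_never_match(self):
        seq = "ACGT" * 25
        edge = align_pair(Read("a", "s", seq), Read("b", "s", seq))
        noisy = align_pair(Read("a", "s", seq), Read("b", "s", "N" * 100))
        assert edge.identity == 1.0
        assert noisy is None


class TestBuildClusters:
    def test_planted_components_and_singletons(self):
        """3 copies of A + 3 of B + 4 random reads -> components 3/3/1/1/1/1."""
        reads = planted_cluster_fixture(seed=7, n_random=4, copies=(3, 3))
        result = build_clusters(reads, ClusterParams(significant_fraction=0.0))
        sizes = sorted((c.size for c in result.clusters), reverse=True)
        assert sizes == [3, 3, 1, 1, 1, 1]
        members = {rid for c in result.clusters for rid in c.members}
        assert len(members) == len(reads)

    def test_matches_bruteforce_all_vs_all(self):
        """Prefiltered clustering equals exhaustive all-pairs clustering."""
        reads = planted_cluster_fixture(seed=13, n_random=60, copies=(15, 12, 8), divergence=0.03)
        fast = build_clusters(reads, use_prefilter=True)
        brute = build_clusters(reads, use_prefilter=False)
        assert partition_of(fast) == partition_of(brute)

    def test_all_identical_reads_one_cluster(self, rng):
        seq = random_dna(rng, 100)
        reads = [Read(f"r{i}", "s", seq) for i in range(8)]
        result = build_clusters(reads, ClusterParams(significant_fraction=0.0))
        assert len(result.clusters) == 1 and result.clusters[0].size == 8

    def test_species_counts_conserved(self):
        reads = planted_cluster_fixture(seed=21, n_random=6, copies=(5, 4))
        for i, r in enumerate(reads):
            reads[i] = Read(r.read_id, "sp1" if i % 2 else "sp2", r.seq)
        result = build_clusters(reads, ClusterParams(significant_fraction=0.0))
        totals = {}
        for cl in result.clusters + result.remainder:
            assert sum(cl.species_counts.values()) == cl.size
            for sp, n in cl.species_counts.items():
                totals[sp] = totals.get(sp, 0) + n
        expected = {"sp1": sum(1 for i in range(len(reads)) if i % 2),
                    "sp2": sum(1 for i in range(len(reads)) if not i % 2)}
        assert totals == expected

    def test_significance_cutoff_routes_to_remainder(self):
        reads = planted_cluster_fixture(seed=7, n_random=4, copies=(3, 3))
        result = build_clusters(reads, ClusterParams(significant_fraction=0.25))
        assert sorted(c.size for c in result.clusters) == [3, 3]
        assert all(c.size == 1 for c in result.remainder)
        assert result.clusters[0].cluster_id == "CL1"

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_clusters([])

    def test_high_n_reads_dropped(self, rng):
        good = random_dna(rng, 100)
        reads = [Read("ok", "s", good), Read("bad", "s", "N" * 30 + good[30:])]
        result = build_clusters(reads, ClusterParams(significant_fraction=0.0))
        assert result.n_dropped_reads == 1
        assert result.n_input_reads == 1


class TestPoolSpecies:
    @pytest.fixture()
    def readsets(self, rng):
        return {
            sp: [(f"r{i}", random_dna(rng, 100)) for i in range(100)]
            for sp in ("spA", "spB")
        }

    def test_sampling_counts_and_tagging(self, readsets):
        pooled = pool_species(readsets, per_species_sample=50, seed=1)
        assert len(pooled) == 100
        per_sp = {sp: sum(1 for r in pooled if r.species_code == sp) for sp in readsets}
        assert per_sp == {"spA": 50, "spB": 50}
        assert all(r.read_id.startswith(f"{r.species_code}|") for r in pooled)

    def test_oversampling_clamps(self, readsets):
        pooled = pool_species(readsets, per_species_sample=500, seed=1)
        assert len(pooled) == 200

    def test_deterministic(self, readsets):
        assert pool_species(readsets, 30, seed=9) == pool_species(readsets, 30, seed=9)

    def test_empty_species_named_in_error(self, readsets):
        readsets["spC"] = []
        with pytest.raises(InvalidArgumentError, match="spC"):
            pool_species(readsets, 10, seed=1)
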