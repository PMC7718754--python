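"""Upstream-window detection equals brute force; read-pair classification
honors the mapping contract and its synchronization guarantees."""

import math

import numpy as np
import pytest

from conftest import mutated, random_dna
from repeatscape.align import revcomp
from repeatscape.errors import DesynchronizedPairsError, InvalidArgumentError
from repeatscape.genedist import (
    GenomicInterval,
    MapParams,
    classify_pairs,
    prefilter_te_pairs,
    read_gff3_intervals,
    upstream_hits,
    upstream_window,
)


def gene(start, end, strand="+", gid="g1", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand, gid, "gene")


def te(start, end, tid="t1", klass="TE:gypsy", chrom="chr1"):
    return GenomicInterval(chrom, start, end, ".", tid, klass)


def brute_force_hits(genes, tes, max_kb=5):
    """Independent all-pairs scan with the distance rule applied literally."""
    out = set()
    for g in genes:
        for t in tes:
            if t.chrom != g.chrom:
                continue
            d = g.start - t.end if g.strand == "+" else t.start - g.end
            if 1 <= d <= max_kb * 1000:
                out.add((g.feature_id, t.feature_id, d, math.ceil(d / 1000)))
    return out


class TestUpstreamHits:
    def test_plus_strand_distance_and_bin(self):
        hits = upstream_hits([gene(10_000, 12_000, "+")], [te(9_400, 9_500)])
        assert len(hits) == 1
        h = hits[0]
        assert (h.distance_bp, h.bin_kb, h.te_class) == (500, 1, "TE:gypsy")

    def test_minus_strand_mirror(self):
        hits = upstream_hits([gene(10_000, 12_000, "-")], [te(12_300, 12_400)])
        assert len(hits) == 1
        assert (hits[0].distance_bp, hits[0].bin_kb) == (300, 1)

    def test_overlapping_and_abutting_te_excluded(self):
        g = gene(10_000, 12_000, "+")
        assert upstream_hits([g], [te(9_900, 10_100)]) == []   # overlaps gene start
        assert upstream_hits([g], [te(9_900, 10_000)]) == []   # abuts: distance 0

    def test_beyond_window_excluded(self):
        g = gene(10_000, 12_000, "+")
        assert upstream_hits([g], [te(4_000, 4_500)]) == []    # distance 5500
        assert upstream_hits([g], [te(4_500, 5_000)]) != []    # distance 5000

    @pytest.mark.parametrize("d,expected_bin", [(1, 1), (999, 1), (1000, 1), (1001, 2), (4999, 5), (5000, 5)])
    def test_kb_binning(self, d, expected_bin):
        g = gene(20_000, 21_000, "+")
        hits = upstream_hits([g], [te(20_000 - d - 300, 20_000 - d)])
        assert hits[0].bin_kb == expected_bin

    def test_unknown_strand_error_names_genes(self):
        with pytest.raises(InvalidArgumentError, match="gX"):
            upstream_hits([gene(100, 200, ".", "gX")], [])

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_brute_force_on_random_fixtures(self, seed):
        gen = np.random.default_rng(seed)
        genes = [
            gene(int(s), int(s) + int(gen.integers(500, 3000)),
                 "+" if gen.random() < 0.5 else "-", f"g{i}",
                 chrom=f"chr{int(gen.integers(1, 3))}")
            for i, s in enumerate(gen.integers(0, 200_000, size=100))
        ]
        tes = [
            te(int(s), int(s) + int(gen.integers(100, 2000)), f"t{i}",
               chrom=f"chr{int(gen.integers(1, 3))}")
            for i, s in enumerate(gen.integers(0, 200_000, size=200))
        ]
        got = {(h.gene_id, h.te_id, h.distance_bp, h.bin_kb) for h in upstream_hits(genes, tes)}
        assert got == brute_force_hits(genes, tes)

    def test_strand_mirror_symmetry(self):
        """Reflecting all coordinates and flipping strands preserves distances."""
        gen = np.random.default_rng(77)
        L = 100_000
        genes = [gene(int(s), int(s) + 1000, "+" if gen.random() < 0.5 else "-", f"g{i}")
                 for i, s in enumerate(gen.integers(0, L - 1000, size=40))]
        tes = [te(int(s), int(s) + 500, f"t{i}") for i, s in enumerate(gen.integers(0, L - 500, size=80))]
        flip = {"+": "-", "-": "+"}
        r_genes = [gene(L - g.end, L - g.start, flip[g.strand], g.feature_id) for g in genes]
        r_tes = [te(L - t.end, L - t.start, t.feature_id) for t in tes]
        fwd = {(h.gene_id, h.te_id, h.distance_bp) for h in upstream_hits(genes, tes)}
        rev = {(h.gene_id, h.te_id, h.distance_bp) for h in upstream_hits(r_genes, r_tes)}
        assert fwd == rev

    def test_window_clips_at_origin(self):
        assert upstream_window(gene(2_000, 3_000, "+")) == (0, 2_000)


def test_gff3_roundtrip(tmp_path, small_sim):
    """Simulated annotations survive the GFF3 write/read cycle exactly."""
    paths = small_sim.write(tmp_path)
    genes = read_gff3_intervals(paths["genes"])
    tes = read_gff3_intervals(paths["tes"])
    assert {(g.start, g.end, g.strand) for g in genes} == {
        (g.start, g.end, g.strand) for g in small_sim.genes
    }
    assert all(g.feature_class == "gene" for g in genes)
    assert {(t.start, t.end) for t in tes} == {(t.start, t.end) for t in small_sim.insertions}
    sf = {f.name: f.superfamily for f in small_sim.profile.families}
    expected_classes = {f"TE:{sf[t.family]}" for t in small_sim.insertions}
    assert {t.feature_class for t in tes} == expected_classes


class TestPrefilterPairs:
    @pytest.fixture(scope="class")
    def contig(self, rng):
        return {"te1": random_dna(rng, 1000)}

    def test_te_matching_pair_retained(self, contig, rng):
        m1 = [("p1/1", contig["te1"][100:200]), ("p2/1", random_dna(rng, 100))]
        m2 = [("p1/2", random_dna(rng, 100)), ("p2/2", random_dna(rng, 100))]
        k1, k2 = prefilter_te_pairs(m1, m2, contig)
        assert [i for i, _ in k1] == ["p1/1"]
        assert [i for i, _ in k2] == ["p1/2"]

    def test_either_mate_suffices(self, contig, rng):
        m1 = [("p1/1", random_dna(rng, 100))]
        m2 = [("p1/2", revcomp(contig["te1"][400:500]))]
        k1, k2 = prefilter_te_pairs(m1, m2, contig)
        assert len(k1) == 1

    def test_random_pairs_discarded(self, contig, rng):
        m1 = [(f"p{i}/1", random_dna(rng, 100)) for i in range(20)]
        m2 = [(f"p{i}/2", random_dna(rng, 100)) for i in range(20)]
        k1, k2 = prefilter_te_pairs(m1, m2, contig)
        assert k1 == [] and k2 == []

    def test_desync_rejected_with_name(self, contig, rng):
        m1 = [("p1/1", random_dna(rng, 100)), ("p2/1", random_dna(rng, 100))]
        m2 = [("p2/2", random_dna(rng, 100)), ("p1/2", random_dna(rng, 100))]
        with pytest.raises(DesynchronizedPairsError, match="p1"):
            prefilter_te_pairs(m1, m2, contig)


class TestClassifyPairs:
    @pytest.fixture(scope="class")
    def libs(self, rng):
        te_contigs = {"teA": random_dna(rng, 1200), "teB": random_dna(rng, 1200)}
        gene_seqs = {f"g{i}": random_dna(rng, 1500) for i in range(5)}
        return te_contigs, gene_seqs

    def test_te_gene_pair_is_a_hit(self, libs):
        te_contigs, gene_seqs = libs
        m1 = [("p1/1", te_contigs["teA"][50:150])]
        m2 = [("p1/2", revcomp(gene_seqs["g2"][300:400]))]
        hits, counts, n_amb = classify_pairs(
            m1, m2, te_contigs, gene_seqs, te_classes={"teA": "gypsy"}
        )
        assert len(hits) == 1 and n_amb == 0
        assert hits[0].gene_id == "g2" and hits[0].te_class == "TE:gypsy"
        assert counts == {("g2", "TE:gypsy"): 1}

    def test_gene_gene_pair_is_not_a_hit(self, libs):
        te_contigs, gene_seqs = libs
        m1 = [("p1/1", gene_seqs["g0"][0:100])]
        m2 = [("p1/2", gene_seqs["g1"][0:100])]
        hits, counts, _ = classify_pairs(m1, m2, te_contigs, gene_seqs)
        assert hits == [] and counts == {}

    def test_edit_distance_limit_enforced(self, libs, rng):
        te_contigs, gene_seqs = libs
        gen = np.random.default_rng(3)
        read = te_contigs["teA"][200:300]
        ok = mutated(read, gen.choice(range(20, 100), 4, replace=False), gen)
        too_many = mutated(read, gen.choice(range(20, 100), 7, replace=False), gen)
        for mate1, expect in ((ok, 1), (too_many, 0)):
            hits, _, _ = classify_pairs(
                [("p/1", mate1)], [("p/2", gene_seqs["g0"][10:110])], te_contigs, gene_seqs
            )
            assert len(hits) == expect

    def test_seed_mismatch_limit_enforced(self, libs):
        te_contigs, gene_seqs = libs
        gen = np.random.default_rng(4)
        read = te_contigs["teA"][200:300]
        bad_seed = mutated(read, [1, 5, 9], gen)  # 3 mismatches in the 12-base seed
        hits, _, _ = classify_pairs(
            [("p/1", bad_seed)], [("p/2", gene_seqs["g0"][10:110])], te_contigs, gene_seqs
        )
        assert hits == []

    def test_ambiguous_mate_discarded_and_counted(self, libs, rng):
        te_contigs, gene_seqs = libs
        shared = random_dna(rng, 100)
        te2 = {"teC": shared + random_dna(rng, 500)}
        genes2 = {"gS": shared + random_dna(rng, 700), "gT": random_dna(rng, 800)}
        hits, _, n_amb = classify_pairs(
            [("p/1", shared)], [("p/2", genes2["gT"][100:200])], te2, genes2
        )
        assert hits == [] and n_amb == 1

    def test_hits_only_name_known_genes(self, libs, rng):
        te_contigs, gene_seqs = libs
        gen = np.random.default_rng(8)
        m1, m2 = [], []
        for i in range(30):
            m1.append((f"p{i}/1", te_contigs["teA"][i * 10 : i * 10 + 100]))
            m2.append((f"p{i}/2", random_dna(gen, 100)))
        hits, counts, _ = classify_pairs(m1, m2, te_contigs, gene_seqs)
        assert hits == []  # TE + unmapped never yields a hit
        assert sum(counts.values()) == len(hits)
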