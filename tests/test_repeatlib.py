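"""Annotation, consensus assembly and LTR extraction against constructed
templates with known answers."""

import numpy as np
import pytest

from conftest import mutated, random_dna
from repeatscape import io
from repeatscape.errors import InsufficientReadsError, InvalidArgumentError
from repeatscape.readcluster import Read, RepeatCluster
from repeatscape.repeatlib import (
    ConsensusContig,
    LibraryRecord,
    annotate_cluster,
    build_consensus,
    extract_ltr,
    load_library,
    parse_superfamily,
)


def cluster_of(reads):
    counts = {}
    for r in reads:
        counts[r.species_code] = counts.get(r.species_code, 0) + 1
    return RepeatCluster("CL1", {r.read_id for r in reads}, counts)


class TestLibraryParsing:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("LTR/Copia", "copia"),
            ("LTR/Gypsy", "gypsy"),
            ("DNA/hAT", "DNA"),
            ("Satellite", "satellite"),
            ("Unknown", "other"),
        ],
    )
    def test_superfamily_normalisation(self, label, expected):
        assert parse_superfamily(label) == expected

    def test_roundtrip_and_ltr_flag(self, tmp_path, rng):
        path = tmp_path / "lib.fasta"
        io.write_fasta(
            [("opie#LTR/Copia", random_dna(rng, 300)), ("opie_LTR#LTR/Copia", random_dna(rng, 150))],
            path,
        )
        records = load_library(path)
        assert [(r.name, r.superfamily, r.is_ltr_exemplar) for r in records] == [
            ("opie", "copia", False),
            ("opie_LTR", "copia", True),
        ]

    def test_bad_header_rejected(self, tmp_path, rng):
        path = tmp_path / "lib.fasta"
        io.write_fasta([("noclass", random_dna(rng, 200))], path)
        with pytest.raises(InvalidArgumentError):
            load_library(path)


class TestAnnotateCluster:
    @pytest.fixture(scope="class")
    def library(self):
        gen = np.random.default_rng(31)
        return [
            LibraryRecord("opie", "copia", random_dna(gen, 600)),
            LibraryRecord("ji", "copia", random_dna(gen, 600)),
            LibraryRecord("huck", "gypsy", random_dna(gen, 600)),
        ]

    def _reads_from(self, record, n, gen, prefix):
        starts = gen.integers(0, len(record.seq) - 100, size=n)
        return [
            Read(f"{prefix}{i}", "sp", record.seq[s : s + 100]) for i, s in enumerate(starts)
        ]

    def test_verbatim_reads_annotated(self, library):
        gen = np.random.default_rng(5)
        reads = self._reads_from(library[0], 12, gen, "v")
        assert annotate_cluster(cluster_of(reads), reads, library) == ("opie", "copia")

    def test_random_reads_unclassified(self, library):
        gen = np.random.default_rng(6)
        reads = [Read(f"r{i}", "sp", random_dna(gen, 100)) for i in range(12)]
        assert annotate_cluster(cluster_of(reads), reads, library) == (None, None)

    def test_plurality_rule(self, library):
        gen = np.random.default_rng(7)
        reads = self._reads_from(library[0], 12, gen, "a") + self._reads_from(
            library[1], 8, gen, "b"
        )
        family, sf = annotate_cluster(cluster_of(reads), reads, library)
        assert (family, sf) == ("opie", "copia")

    def test_superfamily_fallback_without_family_majority(self, library):
        """Votes split across two copia families -> Unclass.Copia-style label."""
        gen = np.random.default_rng(8)
        reads = (
            self._reads_from(library[0], 8, gen, "a")
            + self._reads_from(library[1], 8, gen, "b")
            + [Read(f"n{i}", "sp", random_dna(gen, 100)) for i in range(2)]
        )
        family, sf = annotate_cluster(cluster_of(reads), reads, library)
        assert family is None and sf == "copia"

    def test_empty_library_rejected(self, library):
        reads = [Read("r0", "sp", "ACGT" * 30)]
        with pytest.raises(InvalidArgumentError):
            annotate_cluster(cluster_of(reads), reads, [])


class TestBuildConsensus:
    def _tiling_reads(self, template, step, read_len=100, species="sp"):
        return [
            Read(f"t{i}", species, template[s : s + read_len])
            for i, s in enumerate(range(0, len(template) - read_len + 1, step))
        ]

    def test_error_free_tiling_recovers_template(self, rng):
        template = random_dna(rng, 500)
        reads = self._tiling_reads(template, step=50)
        assert len(reads) >= 9
        contig = build_consensus(cluster_of(reads), reads, "sp")
        assert contig.seq == template
        assert contig.depth >= 1
        assert len(contig.seq) <= sum(len(r.seq) for r in reads)

    def test_noisy_reads_majority_corrected(self):
        gen = np.random.default_rng(17)
        template = random_dna(gen, 400)
        reads = []
        for i in range(40):  # depth ~10 at 1% error
            s = int(gen.integers(0, 300))
            n_err = gen.binomial(100, 0.01)
            seq = mutated(template[s : s + 100], gen.choice(100, n_err, replace=False), gen)
            reads.append(Read(f"e{i}", "sp", seq))
        contig = build_consensus(cluster_of(reads), reads, "sp")
        from repeatscape.align import local_align

        hit = local_align(contig.seq, template)
        assert len(contig.seq) >= 300
        assert hit.identity >= 0.99 and hit.query_span >= 0.95 * len(contig.seq)

    def test_reverse_complement_reads_assemble(self, rng):
        from repeatscape.align import revcomp

        template = random_dna(rng, 400)
        reads = self._tiling_reads(template, step=40)
        flipped = [
            Read(r.read_id, "sp", revcomp(r.seq)) if i % 2 else r
            for i, r in enumerate(reads)
        ]
        contig = build_consensus(cluster_of(flipped), flipped, "sp")
        # reads tile template[0:380]; the contig is that stretch, either strand
        assert contig.seq in template or revcomp(contig.seq) in template
        assert len(contig.seq) >= 350

    def test_too_few_reads_rejected(self, rng):
        reads = [Read(f"r{i}", "sp", random_dna(rng, 100)) for i in range(2)]
        with pytest.raises(InsufficientReadsError):
            build_consensus(cluster_of(reads), reads, "sp")

    def test_only_requested_species_used(self, rng):
        template = random_dna(rng, 400)
        reads = self._tiling_reads(template, step=40, species="spX")
        other = [Read(f"o{i}", "spY", random_dna(rng, 100)) for i in range(3)]
        both = reads + other
        contig = build_consensus(cluster_of(both), both, "spX")
        assert contig.species_code == "spX"
        assert contig.seq in template and len(contig.seq) >= 350


class TestExtractLtr:
    def test_exact_exemplar_coordinates(self, rng):
        ltr = random_dna(rng, 200)
        contig_seq = random_dna(rng, 150) + ltr + random_dna(rng, 250)
        contig = ConsensusContig("CL1", "sp", contig_seq, depth=5.0)
        seg = extract_ltr(contig, [LibraryRecord("fam_LTR", "gypsy", ltr, True)])
        assert (seg.start, seg.end) == (150, 350)
        assert seg.seq == contig_seq[seg.start : seg.end] == ltr
        assert seg.library_hit == "fam_LTR"

    def test_random_contig_yields_none(self, rng):
        contig = ConsensusContig("CL1", "sp", random_dna(rng, 600), depth=3.0)
        assert extract_ltr(contig, [LibraryRecord("x_LTR", "copia", random_dna(rng, 200), True)]) is None

    def test_best_hit_wins(self, rng):
        strong = random_dna(rng, 200)
        weak = random_dna(rng, 100)
        contig_seq = weak + random_dna(rng, 50) + strong
        contig = ConsensusContig("CL1", "sp", contig_seq, depth=4.0)
        seg = extract_ltr(
            contig,
            [
                LibraryRecord("weak_LTR", "copia", weak, True),
                LibraryRecord("strong_LTR", "gypsy", strong, True),
            ],
        )
        assert seg.library_hit == "strong_LTR"
        assert (seg.start, seg.end) == (150, 350)

    def test_empty_db_rejected(self, rng):
        contig = ConsensusContig("CL1", "sp", random_dna(rng, 300), depth=2.0)
        with pytest.raises(InvalidArgumentError):
            extract_ltr(contig, [])
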