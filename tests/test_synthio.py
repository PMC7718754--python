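"""The simulator must honour its own ground truth: sequence decay follows
the clock, realized megabases match the ledger, and everything is
deterministic per seed."""

import numpy as np
import pytest
from scipy import stats

from repeatscape.align import revcomp
from repeatscape.errors import InfeasibleProfileError, InvalidArgumentError
from repeatscape.synthio import (
    ClockModel,
    SpeciesProfile,
    TEFamilySpec,
    simulate_family_library,
    simulate_genome,
    simulate_reads,
)

R = 1.3e-8


def _hamming_fraction(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


def _copy_seq(sim, truth) -> str:
    seq = sim.seq[truth.start : truth.end]
    return revcomp(seq) if truth.strand == "-" else seq


class TestFamilyLibrary:
    def test_deterministic_and_unique(self):
        a = simulate_family_library(4, seed=1)
        b = simulate_family_library(4, seed=1)
        assert [f.ltr_seq for f in a] == [f.ltr_seq for f in b]
        assert len({f.name for f in a}) == 4
        sfs = {f.superfamily for f in a}
        assert {"gypsy", "copia"} <= sfs

    def test_single_family_reproducible(self):
        a = simulate_family_library(1, seed=7)
        b = simulate_family_library(1, seed=7)
        assert len(a) == 1
        assert a[0] == b[0]

    def test_rejects_zero_families(self):
        with pytest.raises(InvalidArgumentError):
            simulate_family_library(0, seed=1)


class TestGenomeDecay:
    def test_zero_age_copies_identical_to_consensus(self):
        fam = simulate_family_library(1, seed=3, target_mb_range=(0.03, 0.03))[0]
        fam = TEFamilySpec(**{**fam.__dict__, "age_my": 0.0, "age_sd_my": 0.0})
        sim = simulate_genome(SpeciesProfile("sp0", 0.2, [fam]), ClockModel(), seed=4)
        for t in sim.insertions:
            assert _copy_seq(sim, t) == fam.element_seq
            l5, l3 = sim.ltr_pair_seqs(t)
            assert l5 == l3

    def test_divergence_matches_clock_expectation(self):
        """Mean copy divergence ~ r*t and LTR-pair divergence ~ 2*r*t over >=100 copies."""
        fam = simulate_family_library(1, seed=5, target_mb_range=(0.25, 0.25))[0]
        fam = TEFamilySpec(**{**fam.__dict__, "age_my": 1.0, "age_sd_my": 0.0})
        sim = simulate_genome(SpeciesProfile("sp1", 0.7, [fam]), ClockModel(), seed=6)
        assert len(sim.insertions) >= 100
        copy_div = [
            _hamming_fraction(_copy_seq(sim, t), fam.element_seq) for t in sim.insertions
        ]
        pair_div = [_hamming_fraction(*sim.ltr_pair_seqs(t)) for t in sim.insertions]
        p = R * 1e6  # 0.013 per site at 1 My
        for observed, expected in ((copy_div, p), (pair_div, 2 * p - (4 / 3) * p**2)):
            mean = np.mean(observed)
            se = np.std(observed, ddof=1) / np.sqrt(len(observed))
            assert abs(mean - expected) < 3 * max(se, 1e-5), (mean, expected)

    def test_decay_calibration_regression(self):
        """Regressing copy divergence on planted age recovers r within 10%."""
        fam = simulate_family_library(1, seed=8, target_mb_range=(1.0, 1.0))[0]
        fam = TEFamilySpec(**{**fam.__dict__, "age_my": 3.0, "age_sd_my": 1.2})
        sim = simulate_genome(SpeciesProfile("sp2", 1.5, [fam]), ClockModel(), seed=9)
        assert len(sim.insertions) >= 500
        ages = [t.age_my * 1e6 for t in sim.insertions]
        divs = [_hamming_fraction(_copy_seq(sim, t), fam.element_seq) for t in sim.insertions]
        slope = stats.linregress(ages, divs).slope
        assert abs(slope - R) / R < 0.10

    def test_truth_ledger_conservation(self, small_sim):
        per_family = {}
        for t in small_sim.insertions:
            per_family[t.family] = per_family.get(t.family, 0) + t.length
        for fam, total in per_family.items():
            assert total / 1e6 == pytest.approx(small_sim.realized_mb[fam], abs=1e-12)

    def test_realized_within_five_percent_of_target(self, small_sim):
        for fam in small_sim.profile.families:
            assert small_sim.realized_mb[fam.name] == pytest.approx(fam.target_mb, rel=0.05)

    def test_upstream_placements_recorded_and_strand_aware(self, small_sim):
        genes = {g.gene_id: g for g in small_sim.genes}
        adjacent = [t for t in small_sim.insertions if t.nearest_gene]
        assert adjacent, "expected some gene-adjacent placements"
        for t in adjacent:
            g = genes[t.nearest_gene]
            if g.strand == "+":
                assert g.start - t.end == t.upstream_distance_bp
            else:
                assert t.start - g.end == t.upstream_distance_bp
            assert 1 <= t.upstream_distance_bp <= 2000

    def test_infeasible_profile_rejected(self):
        fam = simulate_family_library(1, seed=3, target_mb_range=(0.3, 0.3))[0]
        with pytest.raises(InfeasibleProfileError):
            SpeciesProfile("spX", 0.2, [fam])

    def test_genome_deterministic_per_seed(self, small_families):
        profile = SpeciesProfile("spD", 0.2, small_families[:1], gene_count=5)
        a = simulate_genome(profile, ClockModel(), seed=42)
        b = simulate_genome(profile, ClockModel(), seed=42)
        assert a.seq == b.seq
        assert a.insertions == b.insertions


class TestReads:
    @pytest.fixture(scope="class")
    def flat_sim(self):
        profile = SpeciesProfile("spF", 0.2, [], gene_count=0)
        return simulate_genome(profile, ClockModel(), seed=11)

    def test_read_count_arithmetic(self, flat_sim):
        reads, _ = simulate_reads(flat_sim, coverage=0.5, read_len=100, seed=1)
        assert len(reads) == round(0.5 * flat_sim.length / 100)

    def test_zero_error_reads_are_exact_substrings(self, flat_sim):
        reads, _ = simulate_reads(flat_sim, coverage=0.02, read_len=100, error_rate=0.0, seed=2)
        for rid, seq in reads:
            assert seq in flat_sim.seq or revcomp(seq) in flat_sim.seq

    def test_paired_geometry_by_remapping(self, flat_sim):
        m1, m2 = simulate_reads(
            flat_sim, coverage=0.02, read_len=100, paired=True,
            insert_size=400, error_rate=0.0, seed=3,
        )
        assert len(m1) == len(m2)
        for (id1, s1), (id2, s2) in zip(m1, m2):
            assert id1.endswith("/1") and id2.endswith("/2")
            start = int(id1.split(":")[2].split("/")[0])
            assert flat_sim.seq[start : start + 100] == s1
            assert flat_sim.seq[start + 300 : start + 400] == revcomp(s2)

    def test_error_rate_applied(self, flat_sim):
        reads, _ = simulate_reads(flat_sim, coverage=0.1, read_len=100, error_rate=0.05, seed=4)
        total = sum(
            _hamming_fraction(seq, flat_sim.seq[int(rid.split(":")[2]) :][:100])
            for rid, seq in reads
            if rid.split(":")[3] == "+"
        )
        n_fwd = sum(1 for rid, _ in reads if rid.split(":")[3] == "+")
        assert total / n_fwd == pytest.approx(0.05, rel=0.25)

    def test_invalid_args(self, flat_sim):
        with pytest.raises(InvalidArgumentError):
            simulate_reads(flat_sim, coverage=0.0)
        with pytest.raises(InvalidArgumentError):
            simulate_reads(flat_sim, coverage=1.0, read_len=40)
        with pytest.raises(InvalidArgumentError):
            simulate_reads(flat_sim, coverage=1.0, read_len=flat_sim.length + 1)

    def test_reads_deterministic_per_seed(self, flat_sim):
        a, _ = simulate_reads(flat_sim, coverage=0.05, seed=5)
        b, _ = simulate_reads(flat_sim, coverage=0.05, seed=5)
        assert a == b


def test_written_outputs_byte_identical(tmp_path, small_sim):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = small_sim.write(d1)
    p2 = small_sim.write(d2)
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()
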