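"""Synthetic genomes with planted LTR-retrotransposon landscapes.

The simulator produces, per species, a single-chromosome genome in which
full-length LTR-retrotransposon copies of known families occupy a known
number of megabases, carry known insertion ages, and a configurable
fraction of copies sit in the 1-5 kb window upstream of genes. Every
placement is recorded in a ground-truth ledger so that downstream
clustering, quantification, dating and proximity detection can be scored
against the design.

Decay model
-----------
At insertion the two LTRs of a copy are identical to the family
consensus. A copy of age ``t`` years is derived from the consensus by
substituting each site independently with probability ``min(r*t, 0.75)``
where ``r`` is the clock rate (default 1.3e-8 substitutions/site/year);
the 5' and 3' LTRs are mutated independently, so the expected LTR-LTR
divergence of a copy is ~``2*r*t`` while read-vs-consensus divergence is
~``r*t``. Each site is substituted at most once per copy, so observed
read-vs-consensus divergence equals the per-site probability exactly
(no multiple-hit correction is needed for the ages this package targets;
see docs/methods.md). Substitution-only by default: an indel knob exists
but defaults to 0 to keep identity arithmetic invertible for dating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from . import io
from .errors import InfeasibleProfileError, InvalidArgumentError, RepeatscapeError

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SUPERFAMILIES = ("gypsy", "copia", "DNA", "satellite", "other")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ClockModel:
    """Molecular clock for LTR divergence.

    rate_per_site_per_year is the TE substitution rate; the default is
    the grass-specific 1.3e-8 substitutions per site per year.
    divergence_mode states how a divergence d converts to time: 'consensus'
    (d accrued along one lineage, age = d/r) or 'pair' (d split between the
    two LTRs of one element, age = d/(2r)).
    """

    rate_per_site_per_year: float = 1.3e-8
    divergence_mode: str = "consensus"

    def __post_init__(self):
        if self.rate_per_site_per_year <= 0:
            raise InvalidArgumentError("clock rate must be > 0")
        if self.divergence_mode not in ("pair", "consensus"):
            raise InvalidArgumentError(f"unknown divergence_mode {self.divergence_mode!r}")


@dataclass
class TEFamilySpec:
    """One repeat family: its consensus parts and its planting parameters."""

    name: str
    superfamily: str
    ltr_seq: str
    internal_seq: str
    target_mb: float
    age_my: float
    age_sd_my: float = 0.0

    def __post_init__(self):
        for label, seq in (("ltr_seq", self.ltr_seq), ("internal_seq", self.internal_seq)):
            if set(seq.upper()) - set("ACGT"):
                raise InvalidArgumentError(f"{self.name}: {label} must contain only A/C/G/T")
        if not 100 <= len(self.ltr_seq) <= 2000:
            raise InvalidArgumentError(f"{self.name}: ltr_seq length must be in [100, 2000]")
        if len(self.internal_seq) < 500:
            raise InvalidArgumentError(f"{self.name}: internal_seq must be >= 500 nt")
        if self.superfamily not in SUPERFAMILIES:
            raise InvalidArgumentError(f"{self.name}: unknown superfamily {self.superfamily!r}")
        if self.target_mb < 0 or self.age_my < 0 or self.age_sd_my < 0:
            raise InvalidArgumentError(f"{self.name}: target_mb, age_my, age_sd_my must be >= 0")

    @property
    def element_seq(self) -> str:
        """Full-length element: LTR + internal + LTR."""
        return self.ltr_seq + self.internal_seq + self.ltr_seq

    @property
    def element_len(self) -> int:
        return 2 * len(self.ltr_seq) + len(self.internal_seq)


@dataclass
class SpeciesProfile:
    species_code: str
    genome_size_mb: float
    families: list[TEFamilySpec]
    gene_count: int = 0
    background_fraction: float | None = None  # informational; not enforced

    def __post_init__(self):
        if self.genome_size_mb <= 0:
            raise InvalidArgumentError(f"{self.species_code}: genome_size_mb must be > 0")
        if sum(f.target_mb for f in self.families) > self.genome_size_mb:
            raise InfeasibleProfileError(
                f"{self.species_code}: family target_mb sum exceeds genome size"
            )


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class InsertionTruth:
    family: str
    species_code: str
    chrom: str
    start: int
    end: int
    age_my: float
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    strand: str = "+"
    nearest_gene: str | None = None
    upstream_distance_bp: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimulatedGenome:
    """A simulated species genome plus its full ground truth."""

    species_code: str
    chrom: str
    seq: str
    genes: list[GeneTruth]
    insertions: list[InsertionTruth]
    realized_mb: dict[str, float]
    profile: SpeciesProfile
    clock: ClockModel

    @property
    def length(self) -> int:
        return len(self.seq)

    def gene_seq(self, gene: GeneTruth) -> str:
        return self.seq[gene.start : gene.end]

    def gene_seqs(self) -> list[tuple[str, str]]:
        return [(g.gene_id, self.gene_seq(g)) for g in self.genes]

    def ltr_pair_seqs(self, ins: InsertionTruth) -> tuple[str, str]:
        return (
            self.seq[ins.ltr5[0] : ins.ltr5[1]],
            self.seq[ins.ltr3[0] : ins.ltr3[1]],
        )

    # ------------------------------------------------------------------ output
    def write(self, outdir) -> dict[str, Path]:
        """Write genome FASTA, gene/TE GFF3 and the truth ledger TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sp = self.species_code
        paths = {
            "genome": outdir / f"{sp}.genome.fasta",
            "genes": outdir / f"{sp}.genes.gff3",
            "tes": outdir / f"{sp}.tes.gff3",
            "truth": outdir / f"{sp}.truth.tsv",
        }
        io.write_fasta([(self.chrom, self.seq)], paths["genome"])
        io.write_gff3(
            (
                (g.chrom, "repeatscape", "gene", g.start, g.end, g.strand, {"ID": g.gene_id})
                for g in self.genes
            ),
            paths["genes"],
        )
        fams = {f.name: f for f in self.profile.families}
        io.write_gff3(
            (
                (
                    t.chrom, "repeatscape", "transposable_element", t.start, t.end, t.strand,
                    {
                        "ID": f"{t.family}_{i:04d}",
                        "Family": t.family,
                        "Superfamily": fams[t.family].superfamily,
                        "AgeMy": f"{t.age_my:.4f}",
                    },
                )
                for i, t in enumerate(self.insertions)
            ),
            paths["tes"],
        )
        with open(paths["truth"], "w") as fh:
            fh.write(
                "family\tspecies\tchrom\tstart\tend\tstrand\tage_my\t"
                "ltr5_start\tltr5_end\tltr3_start\tltr3_end\tnearest_gene\tupstream_distance_bp\n"
            )
            for t in self.insertions:
                fh.write(
                    f"{t.family}\t{t.species_code}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\t"
                    f"{t.age_my:.6f}\t{t.ltr5[0]}\t{t.ltr5[1]}\t{t.ltr3[0]}\t{t.ltr3[1]}\t"
                    f"{t.nearest_gene or '.'}\t"
                    f"{t.upstream_distance_bp if t.upstream_distance_bp is not None else '.'}\n"
                )
        return paths


# ---------------------------------------------------------------------------
# low-level sequence helpers (uint8 base codes 0..3 for vectorised mutation)


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _seq_to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.empty(arr.shape, dtype=np.uint8)
    for code, base in enumerate(b"ACGT"):
        out[arr == base] = code
    return out


def mutate_codes(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability p (uniform target base)."""
    out = codes.copy()
    if p <= 0:
        return out
    mask = rng.random(codes.shape[0]) < p
    n = int(mask.sum())
    if n:
        # shift by 1..3 guarantees a different base
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


_RC = np.array([3, 2, 1, 0], dtype=np.uint8)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _RC[codes][::-1]


# ---------------------------------------------------------------------------
# operations


def simulate_family_library(
    n_families: int,
    seed: int,
    ltr_len_range: tuple[int, int] = (250, 450),
    internal_len_range: tuple[int, int] = (800, 1400),
    target_mb_range: tuple[float, float] = (0.05, 0.10),
    age_my_range: tuple[float, float] = (0.5, 2.5),
) -> list[TEFamilySpec]:
    """Draw ``n_families`` random LTR-retrotransposon family specs.

    Superfamilies alternate gypsy/copia so any library with >= 2 families
    contains at least one of each. Deterministic for a fixed seed.
    """
    if n_families < 1:
        raise InvalidArgumentError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    fams = []
    for i in range(n_families):
        ltr_len = int(rng.integers(*ltr_len_range))
        int_len = int(rng.integers(*internal_len_range))
        target = float(rng.uniform(*target_mb_range))
        age = float(rng.uniform(*age_my_range))
        fams.append(
            TEFamilySpec(
                name=f"fam{i + 1:02d}",
                superfamily="gypsy" if i % 2 == 0 else "copia",
                ltr_seq=_codes_to_seq(_random_codes(rng, ltr_len)),
                internal_seq=_codes_to_seq(_random_codes(rng, int_len)),
                target_mb=target,
                age_my=age,
                age_sd_my=0.1 * age,
            )
        )
    return fams


def write_family_library(
    families: Sequence[TEFamilySpec], path, include_ltr_exemplars: bool = True
) -> None:
    """Write a RepeatMasker-style exemplar FASTA (``name#superfamily`` headers).

    Full-length elements are written as ``name#LTR/Gypsy`` etc.; with
    ``include_ltr_exemplars`` each family's LTR is also written as
    ``name_LTR#...`` for LTR extraction.
    """
    sf_label = {"gypsy": "LTR/Gypsy", "copia": "LTR/Copia"}
    records = []
    for fam in families:
        label = sf_label.get(fam.superfamily, fam.superfamily)
        records.append((f"{fam.name}#{label}", fam.element_seq))
        if include_ltr_exemplars:
            records.append((f"{fam.name}_LTR#{label}", fam.ltr_seq))
    io.write_fasta(records, path)


class PlacementError(RepeatscapeError):
    """Could not place a TE copy without overlap after many attempts."""


def simulate_genome(
    profile: SpeciesProfile,
    clock: ClockModel,
    seed: int,
    upstream_fraction: float = 0.3,
    upstream_range: tuple[int, int] = (1, 5000),
    gene_length_range: tuple[int, int] = (1000, 2500),
    indel_rate: float = 0.0,
    chrom: str = "chr1",
    max_tries: int = 2000,
    te_margin: int = 60,
) -> SimulatedGenome:
    """Simulate one species genome with planted genes and TE copies.

    Genes are non-overlapping random background intervals with uniform
    strands. For each family, ``round(target_mb*1e6/element_len)`` copies
    are planted; each copy's age is drawn from Normal(age_my, age_sd_my)
    clipped at 0 and its sequence decayed per the module docstring. A
    fraction ``upstream_fraction`` of copies is placed with its
    gene-proximal edge 1-5 kb (configurable) upstream of a random gene,
    strand-aware ('upstream' is 5' of the gene start on the gene's own
    strand); the rest are placed uniformly. Insertions overwrite
    background so coordinates never shift. Every placement is recorded.

    TE copies keep at least ``te_margin`` bp of background between each
    other (genes may still abut TEs): two unrelated repeats closer than
    read_len * (1 - min_overlap_fraction) would let junction-spanning
    reads chain their clusters together, a configuration that graph
    clustering can only resolve with community splitting — nested and
    abutting insertions are deliberately not modelled.
    """
    if indel_rate != 0.0:
        raise NotImplementedError("indel planting is reserved; only indel_rate=0 is supported")
    L = round(profile.genome_size_mb * 1e6)
    total_target = sum(f.target_mb for f in profile.families)
    if total_target > profile.genome_size_mb:
        raise InfeasibleProfileError(
            f"{profile.species_code}: requested {total_target:.3f} Mb of repeats in a "
            f"{profile.genome_size_mb:.3f} Mb genome"
        )
    rng = np.random.default_rng(seed)
    genome = _random_codes(rng, L)
    occupied = IntervalTree()
    te_tree = IntervalTree()

    def te_spot_free(s: int, e: int) -> bool:
        return not occupied.overlaps(s, e) and not te_tree.overlaps(
            max(0, s - te_margin), e + te_margin
        )

    # --- genes
    genes: list[GeneTruth] = []
    for gi in range(profile.gene_count):
        glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        for _ in range(max_tries):
            start = int(rng.integers(0, L - glen))
            if not occupied.overlaps(start, start + glen):
                break
        else:
            raise PlacementError(f"could not place gene {gi} in {profile.species_code}")
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"{profile.species_code}_g{gi + 1:04d}"
        genes.append(GeneTruth(gid, chrom, start, start + glen, strand))
        occupied.addi(start, start + glen, ("gene", gid))

    # --- TE copies
    r = clock.rate_per_site_per_year
    insertions: list[InsertionTruth] = []
    realized: dict[str, float] = {}
    for fam in profile.families:
        elem = _seq_to_codes(fam.element_seq)
        ltr_len = len(fam.ltr_seq)
        ltr_codes = elem[:ltr_len]
        internal_codes = elem[ltr_len : ltr_len + len(fam.internal_seq)]
        n_copies = round(fam.target_mb * 1e6 / fam.element_len)
        realized[fam.name] = n_copies * fam.element_len / 1e6
        for _ in range(n_copies):
            age = max(0.0, float(rng.normal(fam.age_my, fam.age_sd_my))) if fam.age_sd_my else fam.age_my
            p = min(r * age * 1e6, 0.75)
            copy = np.concatenate(
                [
                    mutate_codes(ltr_codes, p, rng),
                    mutate_codes(internal_codes, p, rng),
                    mutate_codes(ltr_codes, p, rng),
                ]
            )
            strand = "+" if rng.random() < 0.5 else "-"
            elen = copy.shape[0]

            start = nearest_gene = upstream_d = None
            if genes and rng.random() < upstream_fraction:
                # place the copy's gene-proximal edge d bp upstream of a gene
                for _ in range(60):
                    gene = genes[int(rng.integers(len(genes)))]
                    d = int(rng.integers(upstream_range[0], upstream_range[1] + 1))
                    cand = gene.start - d - elen if gene.strand == "+" else gene.end + d
                    if cand < 0 or cand + elen > L:
                        continue
                    if te_spot_free(cand, cand + elen):
                        start, nearest_gene, upstream_d = cand, gene.gene_id, d
                        break
            if start is None:
                for _ in range(max_tries):
                    cand = int(rng.integers(0, L - elen))
                    if te_spot_free(cand, cand + elen):
                        start = cand
                        break
                else:
                    raise PlacementError(
                        f"could not place a copy of {fam.name} in {profile.species_code}"
                    )
            end = start + elen
            genome[start:end] = copy if strand == "+" else _revcomp_codes(copy)
            occupied.addi(start, end, ("te", fam.name))
            te_tree.addi(start, end)
            insertions.append(
                InsertionTruth(
                    family=fam.name,
                    species_code=profile.species_code,
                    chrom=chrom,
                    start=start,
                    end=end,
                    age_my=age,
                    ltr5=(start, start + ltr_len),
                    ltr3=(end - ltr_len, end),
                    strand=strand,
                    nearest_gene=nearest_gene,
                    upstream_distance_bp=upstream_d,
                )
            )
    return SimulatedGenome(
        species_code=profile.species_code,
        chrom=chrom,
        seq=_codes_to_seq(genome),
        genes=genes,
        insertions=insertions,
        realized_mb=realized,
        profile=profile,
        clock=clock,
    )


def simulate_reads(
    sim: SimulatedGenome,
    coverage: float,
    read_len: int = 100,
    paired: bool = False,
    insert_size: int = 500,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]] | None]:
    """Shotgun reads from a simulated genome.

    Returns (reads, None) for single-end or (mates1, mates2) for paired
    mode. Total read count is ``round(coverage * genome_len / read_len)``
    (a pair counts as two reads; an odd total is rounded down). Start
    positions are uniform; substitution errors are applied per base at
    ``error_rate``. Read names encode species, fragment origin and, for
    pairs, ``/1``-``/2`` mate suffixes.
    """
    if coverage <= 0:
        raise InvalidArgumentError("coverage must be > 0")
    if read_len < 50:
        raise InvalidArgumentError("read_len must be >= 50")
    L = sim.length
    if read_len > L:
        raise InvalidArgumentError("read_len exceeds genome length")
    if paired and insert_size > L:
        raise InvalidArgumentError("insert_size exceeds genome length")
    if paired and insert_size < 2 * read_len:
        raise InvalidArgumentError("insert_size must be >= 2 * read_len")
    rng = np.random.default_rng(seed)
    codes = _seq_to_codes(sim.seq)
    sp = sim.species_code
    total = round(coverage * L / read_len)

    def finish(sub: np.ndarray) -> str:
        return _codes_to_seq(mutate_codes(sub, error_rate, rng))

    if not paired:
        reads = []
        starts = rng.integers(0, L - read_len + 1, size=total)
        strands = rng.random(total) < 0.5
        for i in range(total):
            s = int(starts[i])
            sub = codes[s : s + read_len]
            if strands[i]:
                sub = _revcomp_codes(sub)
            strand = "-" if strands[i] else "+"
            reads.append((f"{sp}_r{i:06d}:{sim.chrom}:{s}:{strand}", finish(sub)))
        return reads, None

    n_pairs = total // 2
    starts = rng.integers(0, L - insert_size + 1, size=n_pairs)
    m1, m2 = [], []
    for i in range(n_pairs):
        s = int(starts[i])
        stem = f"{sp}_p{i:06d}:{sim.chrom}:{s}"
        m1.append((f"{stem}/1", finish(codes[s : s + read_len])))
        m2.append((f"{stem}/2", finish(_revcomp_codes(codes[s + insert_size - read_len : s + insert_size]))))
    return m1, m2


def read_true_origin(read_id: str) -> tuple[str, int, str] | None:
    """Decode (chrom, start, strand) planted in a simulated read name, if present."""
    parts = read_id.split("/")[0].split(":")
    if len(parts) == 4:
        return parts[1], int(parts[2]), parts[3]
    if len(parts) == 3:  # paired stem: fragment start, strand implicit
        return parts[1], int(parts[2]), "+"
    return None


def simulate_term_table(
    gene_ids: Sequence[str],
    favored_genes: Sequence[str],
    n_terms: int = 25,
    seed: int = 0,
    term_size_range: tuple[int, int] = (5, 30),
    favored_term: str = "T_stress_response",
    favored_capture: float = 0.6,
) -> list[tuple[str, str, frozenset]]:
    """Random flat gene->term mapping with one term concentrated on a gene set.

    Emulates a functional-annotation table: ``n_terms`` terms of random
    size drawn uniformly from all genes, plus one extra term that
    contains ~``favored_capture`` of ``favored_genes`` (e.g. the genes
    that received an upstream TE insertion) so enrichment has a planted
    positive. Returns (term_id, term_name, genes) tuples.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    terms = []
    for i in range(n_terms):
        size = int(rng.integers(term_size_range[0], min(term_size_range[1], len(gene_ids)) + 1))
        genes = frozenset(rng.choice(gene_ids, size=size, replace=False))
        terms.append((f"T{i + 1:03d}", f"random_process_{i + 1}", genes))
    favored = [g for g in favored_genes if rng.random() < favored_capture]
    others = [g for g in gene_ids if g not in set(favored_genes)]
    pad = list(rng.choice(others, size=min(3, len(others)), replace=False)) if others else []
    if favored:
        terms.append((favored_term, "planted_enriched_process", frozenset(favored + pad)))
    return terms


def write_term_table(terms, path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tterm_name\tgene_id\n")
        for term_id, term_name, genes in terms:
            for g in sorted(genes):
                fh.write(f"{term_id}\t{term_name}\t{g}\n")


def shared_family(fam: TEFamilySpec, **overrides) -> TEFamilySpec:
    """A per-species variant of a family sharing the same consensus sequences."""
    return replace(fam, **overrides)
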