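"""TE insertions upstream of genes: interval mode and read-pair mode.

Reference mode asks, for every gene, which annotated TE intervals lie in
the strand-aware 1-5 kb window 5' of the gene start; distance is the gap
between the TE's gene-proximal edge and the gene start (overlap, i.e.
distance 0, is excluded) and is binned per kb. Reference-free mode
mirrors the paired-end protocol for species without an assembly: pairs
with at least one TE-matching mate are retained, both mates are mapped
to a library of TE contigs plus gene sequences, and a pair is proximity
evidence iff one mate's best target is a TE and the other's is a gene.

The mapper is a deterministic seed-and-extend: edlib finds the best
end-to-end placement of the read inside each candidate target, and the
alignment is accepted only if it honors the mapping contract (seed
mismatches, total edit distance, gap opens/extensions — the BWA-aln
style parameter set). A shared-12-mer prescreen limits which targets are
aligned; a read placeable within 4 edits always shares a 12-mer with its
target, so the prescreen never loses a mappable read at default settings.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Mapping, Sequence

import edlib
from intervaltree import IntervalTree

from .align import revcomp
from .errors import DesynchronizedPairsError, InvalidArgumentError

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("gene", "TE:gypsy", "TE:copia", "TE:other")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open annotated interval."""

    chrom: str
    start: int
    end: int
    strand: str
    feature_id: str
    feature_class: str  # gene | TE:gypsy | TE:copia | TE:other

    def __post_init__(self):
        if self.start >= self.end:
            raise InvalidArgumentError(f"{self.feature_id}: start must be < end")


@dataclass(frozen=True)
class ProximityHit:
    gene_id: str
    te_id: str                      # TE interval id (reference) or pair id (read-pair)
    te_class: str
    distance_bp: int | None         # None in read-pair mode
    bin_kb: int | None              # ceil(distance/1000); None in read-pair mode
    evidence: str                   # "interval" | "read_pair"


@dataclass
class MapParams:
    """BWA-aln style mapping contract for read-pair classification."""

    seed_len: int = 12
    seed_max_mismatch: int = 2
    max_edit: int = 4
    max_gap_open: int = 3
    max_gap_ext: int = 3

    def __post_init__(self):
        if min(self.seed_len, self.seed_max_mismatch, self.max_edit,
               self.max_gap_open, self.max_gap_ext) < 0:
            raise InvalidArgumentError("MapParams fields must all be >= 0")


# ---------------------------------------------------------------------------
# annotation input


def _te_class(superfamily: str | None) -> str:
    sf = (superfamily or "").lower()
    if "gypsy" in sf:
        return "TE:gypsy"
    if "copia" in sf:
        return "TE:copia"
    return "TE:other"


def read_gff3_intervals(path) -> list[GenomicInterval]:
    """Load gene and transposable_element features from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based
    half-open. TE intervals are classed by their Superfamily attribute.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        id_spec="ID", merge_strategy="create_unique",
    )
    out: list[GenomicInterval] = []
    for ftype in ("gene", "transposable_element"):
        for feat in db.features_of_type(ftype):
            fclass = (
                "gene" if ftype == "gene"
                else _te_class((feat.attributes.get("Superfamily") or [None])[0])
            )
            out.append(
                GenomicInterval(
                    feat.seqid, feat.start - 1, feat.end, feat.strand, feat.id, fclass
                )
            )
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.feature_id))
    return out


def read_bed_intervals(path, feature_class: str) -> list[GenomicInterval]:
    """Load a BED file (already 0-based half-open) as one feature class."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"bed_{i + 1}"
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name, feature_class))
    return out


# ---------------------------------------------------------------------------
# reference (interval) mode


def upstream_window(gene: GenomicInterval, max_kb: int = 5) -> tuple[int, int]:
    """Strand-aware upstream window [start, end) of a gene (may clip at 0)."""
    span = max_kb * 1000
    if gene.strand == "+":
        return max(0, gene.start - span), gene.start
    if gene.strand == "-":
        return gene.end, gene.end + span
    raise InvalidArgumentError(f"gene {gene.feature_id} has unknown strand {gene.strand!r}")


def upstream_hits(
    genes: Sequence[GenomicInterval],
    tes: Sequence[GenomicInterval],
    max_kb: int = 5,
) -> list[ProximityHit]:
    """Every (gene, TE) pair with the TE in the gene's 1..max_kb upstream window.

    A TE qualifies if its interval overlaps the window and its
    gene-proximal edge is at distance >= 1 bp from the gene start
    (a TE overlapping the gene start itself is excluded). Distance is
    binned per kb: bin_kb = ceil(distance/1000).
    """
    bad = [g.feature_id for g in genes if g.strand not in ("+", "-")]
    if bad:
        raise InvalidArgumentError(f"genes with unknown strand: {', '.join(sorted(bad))}")
    by_chrom: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for te in tes:
        by_chrom[te.chrom].addi(te.start, te.end, te)
    hits: list[ProximityHit] = []
    for gene in genes:
        w_start, w_end = upstream_window(gene, max_kb)
        if w_start >= w_end:
            continue
        # query 1 bp beyond the half-open window so a TE abutting its far
        # edge (distance exactly max_kb*1000) is seen; the distance rule
        # below does the exact filtering
        for iv in sorted(by_chrom[gene.chrom].overlap(max(0, w_start - 1), w_end + 1)):
            te = iv.data
            if gene.strand == "+":
                distance = gene.start - te.end
            else:
                distance = te.start - gene.end
            if 1 <= distance <= max_kb * 1000:
                hits.append(
                    ProximityHit(
                        gene_id=gene.feature_id,
                        te_id=te.feature_id,
                        te_class=te.feature_class,
                        distance_bp=distance,
                        bin_kb=ceil(distance / 1000),
                        evidence="interval",
                    )
                )
    hits.sort(key=lambda h: (h.gene_id, h.te_id))
    return hits


# ---------------------------------------------------------------------------
# read-pair mode


def _pair_stem(read_id: str) -> str:
    return re.sub(r"/[12]$", "", read_id)


def _check_sync(pairs1, pairs2):
    if len(pairs1) != len(pairs2):
        raise DesynchronizedPairsError(
            f"mate files differ in length: {len(pairs1)} vs {len(pairs2)}"
        )
    for (id1, _), (id2, _) in zip(pairs1, pairs2):
        if _pair_stem(id1) != _pair_stem(id2):
            raise DesynchronizedPairsError(f"first desynchronized pair: {id1!r} vs {id2!r}")


class _KmerScreen:
    """Shared-k-mer prescreen mapping a read to candidate target names."""

    def __init__(self, targets: Mapping[str, str], k: int):
        self.k = k
        self.index: dict[str, set[str]] = defaultdict(set)
        comp = str.maketrans("ACGT", "TGCA")
        for name, seq in targets.items():
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                if "N" in km:
                    continue
                rc = km.translate(comp)[::-1]
                self.index[min(km, rc)].add(name)

    def candidates(self, read_seq: str) -> set[str]:
        comp = str.maketrans("ACGT", "TGCA")
        read_seq = read_seq.upper()
        out: set[str] = set()
        for i in range(len(read_seq) - self.k + 1):
            km = read_seq[i : i + self.k]
            if "N" in km:
                continue
            rc = km.translate(comp)[::-1]
            out |= self.index.get(min(km, rc), frozenset())
        return out


def prefilter_te_pairs(
    pairs1: Sequence[tuple[str, str]],
    pairs2: Sequence[tuple[str, str]],
    te_contigs: Mapping[str, str],
    min_identity: float = 0.80,
    min_len: int = 50,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Retain pairs where either mate matches a TE contig.

    A mate matches if it has a local alignment to any contig at
    >= ``min_identity`` over >= ``min_len`` columns (the BLASTn-style
    retention step). Mates stay synchronized and ordered.
    """
    from .align import local_align  # deferred: keeps module import light

    _check_sync(pairs1, pairs2)
    screen = _KmerScreen(te_contigs, k=11)
    names = sorted(te_contigs)

    def matches(seq: str) -> bool:
        for name in sorted(screen.candidates(seq)):
            hit = local_align(seq, te_contigs[name])
            if hit is not None and hit.identity >= min_identity and hit.columns >= min_len:
                return True
        return False

    kept1, kept2 = [], []
    for (id1, s1), (id2, s2) in zip(pairs1, pairs2):
        if matches(s1) or matches(s2):
            kept1.append((id1, s1))
            kept2.append((id2, s2))
    log.info("prefilter kept %d/%d pairs", len(kept1), len(pairs1))
    return kept1, kept2


def _cigar_stats(cigar: str, read_seq: str, target_seq: str, t_start: int, seed_len: int):
    """Walk an edlib CIGAR: (mismatches, gap_opens, gap_extensions, seed_mismatches)."""
    mism = opens = exts = seed_mism = 0
    qpos, tpos = 0, t_start
    for n, op in re.findall(r"(\d+)([MIDX=])", cigar):
        n = int(n)
        if op in ("M", "=", "X"):
            for i in range(n):
                if read_seq[qpos + i] != target_seq[tpos + i]:
                    mism += 1
                    if qpos + i < seed_len:
                        seed_mism += 1
            qpos += n
            tpos += n
        else:
            opens += 1
            exts += n - 1
            if op == "I":  # insertion to target == consumes read
                if qpos < seed_len:
                    seed_mism += min(n, seed_len - qpos)
                qpos += n
            else:
                tpos += n
    return mism, opens, exts, seed_mism


@dataclass(frozen=True)
class _Mapping:
    target: str
    edits: int
    strand: str


def _map_read(
    seq: str,
    targets: Mapping[str, str],
    screen: _KmerScreen,
    params: MapParams,
) -> list[_Mapping]:
    """All equal-best valid placements of a read across the target library."""
    best: list[_Mapping] = []
    best_ed = params.max_edit
    for name in sorted(screen.candidates(seq)):
        tseq = targets[name].upper()
        for strand, oriented in (("+", seq.upper()), ("-", revcomp(seq.upper()))):
            res = edlib.align(oriented, tseq, mode="HW", task="path", k=params.max_edit)
            if res["editDistance"] < 0:
                continue
            t_start = res["locations"][0][0]
            mism, opens, exts, seed_mism = _cigar_stats(
                res["cigar"], oriented, tseq, t_start, params.seed_len
            )
            if (
                opens > params.max_gap_open
                or exts > params.max_gap_ext
                or seed_mism > params.seed_max_mismatch
            ):
                continue
            ed = res["editDistance"]
            if ed < best_ed or not best:
                best = [_Mapping(name, ed, strand)]
                best_ed = ed
            elif ed == best_ed:
                best.append(_Mapping(name, ed, strand))
    # deduplicate same-target placements found on both strands
    seen, uniq = set(), []
    for m in best:
        if m.target not in seen:
            seen.add(m.target)
            uniq.append(m)
    return uniq


def classify_pairs(
    pairs1: Sequence[tuple[str, str]],
    pairs2: Sequence[tuple[str, str]],
    te_contigs: Mapping[str, str],
    gene_seqs: Mapping[str, str],
    params: MapParams | None = None,
    te_classes: Mapping[str, str] | None = None,
) -> tuple[list[ProximityHit], dict[tuple[str, str], int], int]:
    """Proximity evidence from paired reads mapped to TE contigs + genes.

    Each mate is mapped to every prescreen candidate in the combined
    library; a pair yields a hit iff one mate's best target is a TE
    contig and the other's is a gene. A mate whose equal-best targets
    span both classes is ambiguous: the pair is discarded and counted.
    Returns (hits, per-(gene, te_class) evidence counts, n_ambiguous).
    ``te_classes`` maps contig name -> superfamily for hit labelling.
    """
    if not te_contigs or not gene_seqs:
        raise InvalidArgumentError("te_contigs and gene_seqs must be non-empty")
    overlap = set(te_contigs) & set(gene_seqs)
    if overlap:
        raise InvalidArgumentError(f"names present in both libraries: {sorted(overlap)}")
    params = params or MapParams()
    _check_sync(pairs1, pairs2)
    targets = {**te_contigs, **gene_seqs}
    screen = _KmerScreen(targets, k=params.seed_len)
    te_names = set(te_contigs)

    hits: list[ProximityHit] = []
    counts: Counter[tuple[str, str]] = Counter()
    n_ambiguous = 0
    for (id1, s1), (id2, s2) in zip(pairs1, pairs2):
        mates = []
        ambiguous = False
        for seq in (s1, s2):
            maps = _map_read(seq, targets, screen, params)
            classes = {("te" if m.target in te_names else "gene") for m in maps}
            if len(classes) > 1:
                ambiguous = True
                break
            mates.append(maps[0] if maps else None)
        if ambiguous:
            n_ambiguous += 1
            continue
        if not mates or any(m is None for m in mates):
            continue
        kinds = ["te" if m.target in te_names else "gene" for m in mates]
        if sorted(kinds) != ["gene", "te"]:
            continue
        te_m = mates[kinds.index("te")]
        gene_m = mates[kinds.index("gene")]
        klass = _te_class(te_classes.get(te_m.target) if te_classes else None)
        hits.append(
            ProximityHit(
                gene_id=gene_m.target,
                te_id=_pair_stem(id1),
                te_class=klass,
                distance_bp=None,
                bin_kb=None,
                evidence="read_pair",
            )
        )
        counts[(gene_m.target, klass)] += 1
    return hits, dict(counts), n_ambiguous


def hits_to_frame(hits: Iterable[ProximityHit]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "te_id": h.te_id,
                "te_class": h.te_class,
                "distance_bp": h.distance_bp if h.distance_bp is not None else -1,
                "bin_kb": h.bin_kb if h.bin_kb is not None else -1,
                "evidence": h.evidence,
            }
            for h in hits
        ],
        columns=["gene_id", "te_id", "te_class", "distance_bp", "bin_kb", "evidence"],
    )
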