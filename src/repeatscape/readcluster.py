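"""Graph-based clustering of shotgun reads into repeat families.

Reads are nodes; an edge connects two reads whose best local alignment
(either strand) reaches >= 90% identity over at least 55% of the shorter
read. Repeat clusters are the connected components of this graph,
ordered by size and named CL1, CL2, ... A k-mer prefilter keeps the
all-vs-all alignment tractable: a pair passing the 90%/55% thresholds
over C alignment columns must contain a run of >= 9 consecutive match
columns (hence share a strand-canonical 9-mer) for every C except
C in {60, 61, 62, 70, 71, 80}, where only an 8-run is guaranteed. The
default k=9 therefore misses a qualifying pair only if its single best
alignment lands in those widths with every match run <= 8 — an
adversarial configuration that random substitution divergence
essentially never produces (and one extra missed edge rarely changes a
connected component). Setting ``kmer_len=8`` makes the prefilter a
strict superset filter for reads >= 73 nt at the cost of ~2x more
candidate alignments.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

from . import io
from .align import LocalHit, local_align
from .errors import InvalidArgumentError

log = logging.getLogger(__name__)


@dataclass
class Read:
    """A shotgun read tagged with its species of origin."""

    read_id: str
    species_code: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SimilarityEdge:
    a: str
    b: str
    identity: float
    overlap_fraction: float


@dataclass
class ClusterParams:
    """Thresholds for the read-similarity graph.

    min_identity/min_overlap_fraction are the clustering thresholds (90%
    similarity over at least 55% of the shorter read). significant_fraction
    is the minimum component size, as a fraction of input reads, for a
    component to be reported as a significant cluster (RepeatExplorer's
    0.01% convention); smaller components go to the remainder bucket.
    """

    min_identity: float = 0.90
    min_overlap_fraction: float = 0.55
    kmer_len: int = 9
    min_shared_kmers: int = 1
    significant_fraction: float = 1e-4
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0
    max_n_fraction: float = 0.10

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise InvalidArgumentError("min_identity must be in (0, 1]")
        if not 0 < self.min_overlap_fraction <= 1:
            raise InvalidArgumentError("min_overlap_fraction must be in (0, 1]")


@dataclass
class RepeatCluster:
    """A connected component of the read-similarity graph."""

    cluster_id: str
    members: set[str]
    species_counts: dict[str, int]
    annotation: str | None = None
    superfamily: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusteringResult:
    clusters: list[RepeatCluster]          # significant, size-ordered, CL1..
    remainder: list[RepeatCluster]         # below the significance cutoff
    n_input_reads: int
    n_dropped_reads: int
    edges: list[SimilarityEdge] = field(default_factory=list)

    @property
    def all_components(self) -> list[RepeatCluster]:
        return self.clusters + self.remainder


# ---------------------------------------------------------------------------


def _canonical_kmer_positions(seq: str, k: int) -> Iterator[str]:
    comp = str.maketrans("ACGT", "TGCA")
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        rc = km.translate(comp)[::-1]
        yield km if km <= rc else rc


def candidate_pairs(
    reads: Sequence[Read], params: ClusterParams | None = None
) -> Iterator[tuple[str, str]]:
    """Unordered read pairs sharing >= min_shared_kmers canonical k-mers.

    A (near-)superset of all pairs that pass :func:`align_pair` at the
    default thresholds — see the module docstring for the exact
    guarantee; each pair is emitted at most once.
    """
    params = params or ClusterParams()
    k = params.kmer_len
    index: dict[str, list[int]] = defaultdict(list)
    for idx, read in enumerate(reads):
        for km in set(_canonical_kmer_positions(read.seq.upper(), k)):
            index[km].append(idx)
    if params.min_shared_kmers <= 1:
        seen: set[tuple[int, int]] = set()
        for bucket in index.values():
            if len(bucket) < 2:
                continue
            for i, j in itertools.combinations(bucket, 2):
                if (i, j) not in seen:
                    seen.add((i, j))
                    yield reads[i].read_id, reads[j].read_id
    else:
        shared: Counter[tuple[int, int]] = Counter()
        for bucket in index.values():
            if len(bucket) < 2:
                continue
            shared.update(itertools.combinations(bucket, 2))
        for (i, j), n in shared.items():
            if n >= params.min_shared_kmers:
                yield reads[i].read_id, reads[j].read_id


def _max_strand_score(seq_a: str, seq_b: str, params: ClusterParams) -> float:
    from .align import _aligner, revcomp

    al = _aligner("local", params.match_score, params.mismatch_score, params.gap_score)
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    return max(al.score(seq_a, seq_b), al.score(revcomp(seq_a), seq_b))


def align_pair(a: Read, b: Read, params: ClusterParams | None = None) -> SimilarityEdge | None:
    """Similarity edge between two reads, or None below threshold.

    Best local alignment (both orientations) under the configured
    scoring; identity = matches / alignment columns (gap columns count);
    the aligned span is measured on the shorter read, so the edge exists
    iff identity >= min_identity and span >= min_overlap_fraction *
    min(len(a), len(b)). The computation is symmetric in (a, b): the two
    reads are put in a canonical order before aligning.
    """
    params = params or ClusterParams()
    # canonical order makes align_pair(a, b) == align_pair(b, a) exactly,
    # even when co-optimal alignments exist
    first, second = sorted((a, b), key=lambda r: (len(r.seq), r.seq))
    # sound score-only prescreen: with match/mismatch/gap = m/-m/-2m, any
    # alignment with identity >= i over >= f * min_len columns scores at
    # least (3i-2) * f * min_len * m, and score() skips the traceback
    if (
        params.match_score == -params.mismatch_score
        and params.gap_score == 2 * params.mismatch_score
        and params.min_identity > 2 / 3
    ):
        threshold = (
            (3 * params.min_identity - 2)
            * params.min_overlap_fraction
            * min(len(a.seq), len(b.seq))
            * params.match_score
        )
        if _max_strand_score(first.seq, second.seq, params) < threshold - 1e-9:
            return None
    hit = local_align(
        first.seq, second.seq,
        match=params.match_score, mismatch=params.mismatch_score, gap=params.gap_score,
    )
    if hit is None:
        return None
    min_len = min(len(a.seq), len(b.seq))
    span = min(hit.query_span, hit.target_span)
    overlap_fraction = min(1.0, span / min_len)
    if hit.identity >= params.min_identity and span >= params.min_overlap_fraction * min_len:
        return SimilarityEdge(a.read_id, b.read_id, hit.identity, overlap_fraction)
    return None


def _filter_reads(reads: Sequence[Read], params: ClusterParams) -> tuple[list[Read], int]:
    kept = []
    dropped = 0
    for r in reads:
        seq = r.seq.upper()
        if len(seq) < 50 or (seq.count("N") / len(seq)) > params.max_n_fraction:
            dropped += 1
            continue
        kept.append(Read(r.read_id, r.species_code, seq))
    if dropped:
        log.info("dropped %d reads (<50 nt or >%d%% N)", dropped, int(params.max_n_fraction * 100))
    return kept, dropped


def build_clusters(
    reads: Sequence[Read],
    params: ClusterParams | None = None,
    keep_edges: bool = False,
    use_prefilter: bool = True,
) -> ClusteringResult:
    """Partition reads into repeat clusters (connected components).

    Components with fewer than ``significant_fraction * n_reads`` members
    are reported in the remainder bucket instead of the significant list.
    Significant clusters are sorted by size (descending, ties by smallest
    member id) and named CL1, CL2, ... ``use_prefilter=False`` aligns all
    pairs exhaustively (the brute-force oracle path for small inputs).
    """
    params = params or ClusterParams()
    if not reads:
        raise InvalidArgumentError("build_clusters requires at least one read")
    kept, dropped = _filter_reads(reads, params)
    by_id = {r.read_id: r for r in kept}
    if len(by_id) != len(kept):
        raise InvalidArgumentError("duplicate read ids in input")

    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(by_id)
    edges: list[SimilarityEdge] = []
    if use_prefilter:
        pair_iter: Iterable[tuple[str, str]] = candidate_pairs(kept, params)
    else:
        ids = sorted(by_id)
        pair_iter = itertools.combinations(ids, 2)
    n_aligned = 0
    for ia, ib in pair_iter:
        n_aligned += 1
        edge = align_pair(by_id[ia], by_id[ib], params)
        if edge is not None:
            graph.add_edge(ia, ib)
            if keep_edges:
                edges.append(edge)
    log.info("aligned %d candidate pairs, %d edges", n_aligned, graph.number_of_edges())

    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    cutoff = params.significant_fraction * len(kept)
    clusters, remainder = [], []
    n_sig = 0
    for comp in comps:
        counts = dict(Counter(by_id[rid].species_code for rid in comp))
        if len(comp) >= cutoff and len(comp) > 0:
            n_sig += 1
            clusters.append(RepeatCluster(f"CL{n_sig}", comp, counts))
        else:
            remainder.append(RepeatCluster(f"rem{len(remainder) + 1}", comp, counts))
    return ClusteringResult(clusters, remainder, len(kept), dropped, edges)


def pool_species(
    readsets: Mapping[str, object],
    per_species_sample: int,
    seed: int,
) -> list[Read]:
    """Pool a uniform subsample of reads per species for comparative clustering.

    ``readsets`` maps species code to either a FASTA/FASTQ path or an
    in-memory list of (read_id, seq) tuples. Sampling is without
    replacement (all reads if fewer are available, with a logged
    warning); read ids are prefixed with the species code so pooled ids
    stay unique. Deterministic for a fixed seed, independent of mapping
    order.
    """
    if per_species_sample < 1:
        raise InvalidArgumentError("per_species_sample must be >= 1")
    pooled: list[Read] = []
    for sp in sorted(readsets):
        src = readsets[sp]
        records = io.read_seqs(src) if isinstance(src, (str, bytes)) or hasattr(src, "__fspath__") else list(src)
        if not records:
            raise InvalidArgumentError(f"empty read set for species {sp!r}")
        rng = np.random.default_rng([seed, len(sp), *map(ord, sp)])
        if len(records) <= per_species_sample:
            if len(records) < per_species_sample:
                log.warning(
                    "species %s has %d reads < requested %d; taking all",
                    sp, len(records), per_species_sample,
                )
            chosen = range(len(records))
        else:
            chosen = rng.choice(len(records), size=per_species_sample, replace=False)
            chosen = sorted(int(i) for i in chosen)
        for i in chosen:
            rid, seq = records[i]
            pooled.append(Read(f"{sp}|{rid}", sp, seq.upper()))
    return pooled


# ---------------------------------------------------------------------------
# tabular output


def write_membership_tsv(result: ClusteringResult, reads: Sequence[Read], path) -> None:
    sp = {r.read_id: r.species_code for r in reads}
    with open(path, "w") as fh:
        fh.write("read_id\tcluster_id\tspecies_code\tsignificant\n")
        for flag, clusters in (("1", result.clusters), ("0", result.remainder)):
            for cl in clusters:
                for rid in sorted(cl.members):
                    fh.write(f"{rid}\t{cl.cluster_id}\t{sp.get(rid, '.')}\t{flag}\n")


def write_cluster_summary_tsv(result: ClusteringResult, path) -> None:
    species = sorted({s for cl in result.all_components for s in cl.species_counts})
    with open(path, "w") as fh:
        fh.write("cluster_id\tsize\tannotation\tsuperfamily\t" + "\t".join(species) + "\n")
        for cl in result.clusters:
            counts = "\t".join(str(cl.species_counts.get(s, 0)) for s in species)
            fh.write(
                f"{cl.cluster_id}\t{cl.size}\t{cl.annotation or '.'}\t{cl.superfamily or '.'}\t{counts}\n"
            )
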