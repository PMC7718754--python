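"""Thin pairwise-alignment layer shared by the clustering, annotation and dating modules.

All similarity decisions in the package reduce to one of two primitives:

* a best local alignment under a simple match/mismatch/gap scheme
  (default +1/-1/-2), with identity defined as matches over alignment
  columns (internal gap columns count, unaligned flanks do not), and
* a global alignment under the same scheme, used for LTR-pair dating.

Both are computed with :class:`Bio.Align.PairwiseAligner`. ``N`` never
matches anything, including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = "ACGTN"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _matrix(match: float, mismatch: float):
    m = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            if a == b and a != "N":
                m[a, b] = match
            else:
                m[a, b] = mismatch
    return m


@lru_cache(maxsize=16)
def _aligner(mode: str, match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _matrix(match, mismatch)
    al.open_gap_score = gap
    al.extend_gap_score = gap
    return al


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of ``query`` against ``target``.

    Coordinates are 0-based half-open on the *forward* strand of each
    input sequence, regardless of the orientation in which the hit was
    found (``strand`` records that orientation).
    """

    score: float
    identity: float          # matches / alignment columns
    matches: int
    columns: int             # identities + mismatches + internal gap columns
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str              # '+' if query aligned forward, '-' if reverse-complemented

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


def _best_alignment(al: Align.PairwiseAligner, query: str, target: str):
    alns = al.align(query, target)
    try:
        return alns[0]
    except IndexError:
        return None


def _hit_from_alignment(aln, qlen: int, strand: str) -> LocalHit:
    counts = aln.counts()
    matches = int(counts.identities)
    columns = int(counts.identities + counts.mismatches + counts.gaps)
    qs, qe = int(aln.coordinates[0, 0]), int(aln.coordinates[0, -1])
    ts, te = int(aln.coordinates[1, 0]), int(aln.coordinates[1, -1])
    if strand == "-":
        qs, qe = qlen - qe, qlen - qs
    identity = matches / columns if columns else 0.0
    return LocalHit(
        score=float(aln.score), identity=identity, matches=matches, columns=columns,
        query_start=qs, query_end=qe, target_start=ts, target_end=te, strand=strand,
    )


def local_align(
    query: str,
    target: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    both_strands: bool = True,
) -> LocalHit | None:
    """Best-scoring local alignment of ``query`` vs ``target``.

    With ``both_strands`` the reverse complement of the query is also
    tried; the higher-scoring orientation wins (forward on a tie, so
    results are deterministic). Coordinates in the returned hit refer to
    the sequences as given. Returns ``None`` when no positive-scoring
    alignment exists.
    """
    query = query.upper()
    target = target.upper()
    al = _aligner("local", match, mismatch, gap)
    # PairwiseAligner is asymmetric only in which co-optimal alignment it
    # enumerates first; aligning (query, target) in a fixed role keeps the
    # caller's coordinates meaningful.
    fwd = _best_alignment(al, query, target)
    best = _hit_from_alignment(fwd, len(query), "+") if fwd is not None and fwd.score > 0 else None
    if both_strands:
        rev = _best_alignment(al, revcomp(query), target)
        if rev is not None and rev.score > 0:
            hit = _hit_from_alignment(rev, len(query), "-")
            if best is None or hit.score > best.score:
                best = hit
    return best


def global_identity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Identity (matches / columns) of the best global alignment of two sequences."""
    al = _aligner("global", match, mismatch, gap)
    aln = _best_alignment(al, a.upper(), b.upper())
    if aln is None:
        return 0.0
    counts = aln.counts()
    columns = int(counts.identities + counts.mismatches + counts.gaps)
    return int(counts.identities) / columns if columns else 0.0


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Set of strand-canonical k-mers (min of k-mer and its reverse complement).

    K-mers containing ``N`` are skipped: N never matches, so it can never
    sit inside a run of match columns.
    """
    seq = seq.upper()
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        rc = revcomp(km)
        out.add(km if km <= rc else rc)
    return out


def seq_to_array(seq: str) -> np.ndarray:
    """DNA string to a uint8 array of ASCII codes (vectorised comparisons)."""
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()
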