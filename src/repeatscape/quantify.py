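"""Genome-occupancy quantification and cross-species sharing of repeat clusters.

A cluster's genome occupancy in a species follows the read-proportion
logic: (total length of the cluster's reads, in Mb) x genome size (Mb)
/ (total length of all analyzed reads, in Mb). With the all-reads
denominator the occupancies of all components (clusters plus singleton
remainder) sum exactly to the genome size, and the repetitive fraction
comes out as the clustered fraction of read bases — consistent with
genome proportions well below 100%. A literal mode that divides by the
clustered length only (forcing proportions to 1) is kept behind a flag.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import InvalidArgumentError
from .readcluster import Read, RepeatCluster


@dataclass
class FamilyAbundance:
    species_code: str
    family: str
    superfamily: str | None
    occupancy_mb: float
    cluster_ids: list[str]


@dataclass(frozen=True)
class IntersectionRow:
    species_set: frozenset[str]
    n_clusters: int


def cluster_occupancy(
    cluster: RepeatCluster,
    reads: Mapping[str, Read],
    genome_size_mb: float,
    total_input_len_mb: float,
    species: str | None = None,
) -> float:
    """Mb of genome space attributed to one cluster in one species.

    ``total_input_len_mb`` must be the total length of all analyzed reads
    of that species (see module docstring). With ``species`` set, only
    the cluster's reads from that species are counted (pooled mode).
    """
    if genome_size_mb <= 0 or total_input_len_mb <= 0:
        raise InvalidArgumentError("genome_size_mb and total_input_len_mb must be > 0")
    cluster_len = sum(
        len(reads[rid].seq)
        for rid in cluster.members
        if species is None or reads[rid].species_code == species
    )
    return (cluster_len / 1e6) * genome_size_mb / total_input_len_mb


def total_read_length_mb(reads: Sequence[Read] | Mapping[str, Read]) -> float:
    if isinstance(reads, Mapping):
        reads = list(reads.values())
    return sum(len(r.seq) for r in reads) / 1e6


def composition_table(
    clusters: Sequence[RepeatCluster],
    reads: Mapping[str, Read],
    genome_sizes_mb: Mapping[str, float],
    total_input_len_mb: Mapping[str, float],
    literal_denominator: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Family x species occupancy table (Mb) plus per-species genome proportion.

    Cluster occupancies are summed over clusters sharing a family label;
    clusters without a family label aggregate into ``Unclass.<superfamily>``
    rows (or ``Unclassified`` when the superfamily is unknown too). The
    genome proportion of a species is the summed occupancy of all listed
    clusters divided by its genome size.
    """
    species = sorted(genome_sizes_mb)
    if literal_denominator:
        denom = {
            sp: sum(
                len(reads[rid].seq)
                for cl in clusters
                for rid in cl.members
                if reads[rid].species_code == sp
            )
            / 1e6
            for sp in species
        }
    else:
        denom = dict(total_input_len_mb)

    rows: dict[str, dict[str, float]] = defaultdict(lambda: {sp: 0.0 for sp in species})
    membership: dict[str, list[str]] = defaultdict(list)
    for cl in clusters:
        if cl.annotation:
            label = cl.annotation
        elif cl.superfamily:
            label = f"Unclass.{cl.superfamily.capitalize()}"
        else:
            label = "Unclassified"
        membership[label].append(cl.cluster_id)
        for sp in species:
            if cl.species_counts.get(sp, 0) == 0:
                continue
            rows[label][sp] += cluster_occupancy(
                cl, reads, genome_sizes_mb[sp], denom[sp], species=sp
            )
    table = pd.DataFrame.from_dict(rows, orient="index", columns=species).fillna(0.0)
    table = table.sort_index()
    table.index.name = "family"
    proportion = table.sum(axis=0) / pd.Series(genome_sizes_mb)
    proportion.name = "genome_proportion"
    return table, proportion


def sharing_matrix(
    clusters: Sequence[RepeatCluster],
    min_reads_per_species: int = 5,
) -> list[IntersectionRow]:
    """UpSet-style intersection counts over pooled (comparative) clusters.

    A species is present in a cluster iff it contributed at least
    ``min_reads_per_species`` reads; each cluster contributes to exactly
    one row (its exact presence set); clusters with an empty presence set
    are dropped. Rows are sorted by count (descending) then species set.
    """
    tally: Counter[frozenset[str]] = Counter()
    for cl in clusters:
        present = frozenset(
            sp for sp, n in cl.species_counts.items() if n >= min_reads_per_species
        )
        if present:
            tally[present] += 1
    rows = [IntersectionRow(s, n) for s, n in tally.items()]
    rows.sort(key=lambda r: (-r.n_clusters, sorted(r.species_set)))
    return rows


def sharing_table(rows: Sequence[IntersectionRow]) -> pd.DataFrame:
    """Long-format UpSet table: one row per intersection."""
    return pd.DataFrame(
        {
            "species_set": ["+".join(sorted(r.species_set)) for r in rows],
            "n_species": [len(r.species_set) for r in rows],
            "n_clusters": [r.n_clusters for r in rows],
        }
    )
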