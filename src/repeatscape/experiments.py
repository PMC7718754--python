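"""Validation experiments on synthetic ground truth.

Each function builds its own fixture from a seed, runs the relevant
slice of the package, and reports recovery metrics against the planted
design. They are used by the analysis drivers, the test suite and the
acceptance script, so the numbers those report are always recomputed
from scratch.
"""

from __future__ import annotations

import filecmp
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io, pipeline
from .enrichstats import TermMapping, bh_adjust, hypergeom_enrich, hypergeom_pvalue
from .genedist import classify_pairs, prefilter_te_pairs
from .paleoclock import (
    date_element_by_ltr_pair,
    estimate_cluster_age,
    identity_to_age,
    map_reads_to_ltr,
)
from .quantify import composition_table, sharing_matrix, total_read_length_mb
from .readcluster import ClusterParams, Read, build_clusters
from .repeatlib import LibraryRecord, build_consensus, extract_ltr
from .synthio import (
    ClockModel,
    SpeciesProfile,
    simulate_family_library,
    simulate_genome,
    simulate_reads,
)

log = logging.getLogger(__name__)


def _seed(base: int, offset: int) -> int:
    return int((base * 9973 + offset) % (2**31 - 1))


def _planted_reads(seed: int, n_total: int = 300) -> list[Read]:
    """A read set with three divergent repeat families plus random background."""
    rng = np.random.default_rng(seed)
    fams = simulate_family_library(
        3, seed=_seed(seed, 1), ltr_len_range=(150, 200), internal_len_range=(500, 600)
    )
    reads: list[Read] = []
    per_family = n_total // 5
    for f, fam in enumerate(fams):
        template = fam.element_seq
        for c in range(per_family):
            start = int(rng.integers(0, len(template) - 100))
            window = np.frombuffer(template[start : start + 100].encode(), dtype=np.uint8).copy()
            n_mut = rng.binomial(100, 0.03)
            if n_mut:
                pos = rng.choice(100, size=n_mut, replace=False)
                bases = np.frombuffer(b"ACGT", dtype=np.uint8)
                window[pos] = bases[rng.integers(0, 4, size=n_mut)]
            reads.append(Read(f"f{f}_c{c}", "sp", window.tobytes().decode()))
    while len(reads) < n_total:
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        reads.append(Read(f"bg_{len(reads)}", "sp", seq))
    return reads


def clustering_oracle_experiment(seed: int, n_reads: int = 300) -> dict:
    """Prefiltered clustering vs exhaustive all-vs-all on <= 300 reads."""
    reads = _planted_reads(_seed(seed, 11), n_reads)
    params = ClusterParams(significant_fraction=0.0)
    fast = build_clusters(reads, params, use_prefilter=True)
    brute = build_clusters(reads, params, use_prefilter=False)
    part_fast = {frozenset(c.members) for c in fast.all_components}
    part_brute = {frozenset(c.members) for c in brute.all_components}
    return {
        "n_reads": len(reads),
        "partitions_equal": part_fast == part_brute,
        "n_components": len(part_fast),
        "agreement_fraction": (
            len(part_fast & part_brute) / max(len(part_brute), 1)
        ),
    }


# ---------------------------------------------------------------------------
# demo-pipeline recovery


def _family_presence_design(cfg: pipeline.RunConfig) -> dict[str, frozenset]:
    design: dict[str, set] = {}
    for sp in cfg.species:
        for fp in sp.families:
            design.setdefault(fp.name, set()).add(sp.code)
    return {fam: frozenset(spp) for fam, spp in design.items()}


def demo_recovery_metrics(outdir) -> dict:
    """Score a finished demo-pipeline run against its planted design.

    Sharing is scored at family level: pooled clusters annotated to one
    family are merged before computing the presence set (a family can
    split into several clusters, just as real graph-clustering runs
    report more clusters than families).
    """
    outdir = Path(outdir)
    cfg = pipeline.validate_config(outdir / "resolved_config.yaml")
    design = _family_presence_design(cfg)

    # --- sharing
    mem = pd.read_csv(outdir / "cluster" / "pooled.membership.tsv", sep="\t", dtype=str)
    ann = pd.read_csv(outdir / "annotate" / "pooled.annotation.tsv", sep="\t", dtype=str).fillna("")
    fam_of = dict(zip(ann.cluster_id, ann.family))
    sig = mem[mem.significant == "1"]
    observed: dict[str, dict[str, int]] = {}
    for cid, grp in sig.groupby("cluster_id"):
        fam = fam_of.get(cid, "") or f"?{cid}"
        counts = observed.setdefault(fam, {})
        for sp, n in grp.groupby("species_code").size().items():
            counts[sp] = counts.get(sp, 0) + int(n)
    presence = {
        fam: frozenset(sp for sp, n in counts.items() if n >= cfg.min_reads_per_species)
        for fam, counts in observed.items()
    }
    sharing_exact = presence == design
    # raw cluster-level intersection rows, for reporting
    raw_rows = pd.read_csv(outdir / "quantify" / "sharing.tsv", sep="\t")

    # --- abundance
    comp = pd.read_csv(outdir / "quantify" / "composition_mb.tsv", sep="\t", index_col=0)
    rel_errors = {}
    for sp in cfg.species:
        for fp in sp.families:
            est = float(comp.loc[fp.name, sp.code]) if fp.name in comp.index else 0.0
            rel_errors[f"{sp.code}/{fp.name}"] = (est - fp.target_mb) / fp.target_mb
    max_abundance_err = max(abs(v) for v in rel_errors.values())

    # --- occupancy conservation (recomputed from cluster membership)
    conservation_residual = 0.0
    for sp in cfg.species:
        reads = {
            rid: Read(rid, sp.code, seq)
            for rid, seq in io.read_seqs(outdir / "simulate" / f"{sp.code}.reads.fastq")
        }
        m = pd.read_csv(outdir / "cluster" / f"{sp.code}.membership.tsv", sep="\t", dtype=str)
        total_mb = total_read_length_mb(reads)
        occ = 0.0
        for _, grp in m.groupby("cluster_id"):
            cl_len = sum(len(reads[rid].seq) for rid in grp.read_id)
            occ += (cl_len / 1e6) * sp.genome_size_mb / total_mb
        conservation_residual = max(
            conservation_residual, abs(occ - sp.genome_size_mb) / sp.genome_size_mb
        )

    # --- ages
    ages = pd.read_csv(outdir / "date" / "cluster_ages.tsv", sep="\t")
    planted_age = {
        (sp.code, fp.name): fp.age_my for sp in cfg.species for fp in sp.families
    }
    age_errors = {}
    for sp in cfg.species:
        a = pd.read_csv(outdir / "annotate" / f"{sp.code}.annotation.tsv", sep="\t", dtype=str).fillna("")
        fam_by_cluster = dict(zip(a.cluster_id, a.family))
        sub = ages[(ages.species_code == sp.code) & (ages.status == "dated")]
        for row in sub.itertuples():
            fam = fam_by_cluster.get(row.cluster_id, "")
            true = planted_age.get((sp.code, fam))
            if true:
                key = f"{sp.code}/{fam}"
                # largest dated cluster of the family wins
                if key not in age_errors or row.n_reads > age_errors[key][2]:
                    age_errors[key] = ((row.age_my - true) / true, row.age_my, row.n_reads)
    max_age_err = max(abs(v[0]) for v in age_errors.values())

    return {
        "sharing_exact": sharing_exact,
        "presence_observed": {k: sorted(v) for k, v in sorted(presence.items())},
        "presence_design": {k: sorted(v) for k, v in sorted(design.items())},
        "n_intersection_rows": int(len(raw_rows)),
        "abundance_rel_errors": rel_errors,
        "max_abundance_rel_error": max_abundance_err,
        "conservation_residual": conservation_residual,
        "age_rel_errors": {k: v[0] for k, v in sorted(age_errors.items())},
        "max_age_rel_error": max_age_err,
        "n_families_dated": len(age_errors),
    }


# ---------------------------------------------------------------------------
# molecular clock


CLOCK_AGES = (0.5, 1.0, 2.0, 5.0)


def clock_experiment(seed: int, error_rate: float = 0.002) -> dict:
    """Date four families planted at 0.5/1/2/5 My through the full chain.

    Reads are clustered, clusters annotated against the exemplar
    library, one consensus per family assembled, its LTR extracted and
    the cluster reads mapped back; separately every planted element is
    dated from its LTR pair and regressed on its true age.
    """
    clock = ClockModel()
    # long LTRs (as in the large grass retrotransposon families) and an
    # abundant youngest family: at 0.5 My the whole signal is < 1 mismatch
    # per read, so dating precision is bought with LTR columns
    fams = simulate_family_library(
        4, seed=_seed(seed, 21),
        ltr_len_range=(400, 450), internal_len_range=(600, 700),
    )
    targets = (0.18, 0.11, 0.09, 0.09)
    fams = [
        replace(f, age_my=age, age_sd_my=0.05 * age, target_mb=target)
        for f, age, target in zip(fams, CLOCK_AGES, targets)
    ]
    profile = SpeciesProfile("spK", 0.72, fams, gene_count=0)
    sim = simulate_genome(profile, clock, seed=_seed(seed, 22), upstream_fraction=0.0)
    raw, _ = simulate_reads(
        sim, coverage=0.5, read_len=100, error_rate=error_rate, seed=_seed(seed, 23)
    )
    reads = [Read(rid, "spK", seq) for rid, seq in raw]
    result = build_clusters(reads, ClusterParams(significant_fraction=2e-3))
    reads_by_id = {r.read_id: r for r in reads}

    sf_label = {"gypsy": "gypsy", "copia": "copia"}
    library = []
    for f in fams:
        library.append(LibraryRecord(f.name, sf_label[f.superfamily], f.element_seq))
        library.append(LibraryRecord(f"{f.name}_LTR", sf_label[f.superfamily], f.ltr_seq, True))
    ltr_db = [r for r in library if r.is_ltr_exemplar]

    from .repeatlib import annotate_cluster

    best_cluster: dict[str, object] = {}
    for cl in result.clusters:
        if cl.size < 10:
            continue
        family, _ = annotate_cluster(cl, reads_by_id, library, seed=_seed(seed, 24))
        if family and (family not in best_cluster or cl.size > best_cluster[family].size):
            best_cluster[family] = cl

    consensus_ages = {}
    for fam in fams:
        cl = best_cluster.get(fam.name)
        if cl is None:
            consensus_ages[fam.name] = (fam.age_my, float("nan"))
            continue
        contig = build_consensus(cl, reads_by_id, "spK", seed=_seed(seed, 25))
        seg = extract_ltr(contig, ltr_db)
        if seg is None:
            consensus_ages[fam.name] = (fam.age_my, float("nan"))
            continue
        dist = map_reads_to_ltr([reads_by_id[r] for r in sorted(cl.members)], seg)
        est = estimate_cluster_age(dist, clock, error_rate=error_rate)
        consensus_ages[fam.name] = (fam.age_my, est.age_my)

    # LTR pairs are read from the assembled genome, so no sequencing error term
    true_ages = [t.age_my for t in sim.insertions]
    pair_ages = [
        date_element_by_ltr_pair(*sim.ltr_pair_seqs(t), clock) for t in sim.insertions
    ]
    slope = float(stats.linregress(true_ages, pair_ages).slope)

    rel = {
        name: (est - true) / true for name, (true, est) in consensus_ages.items()
    }
    return {
        "consensus_ages": consensus_ages,
        "consensus_rel_errors": rel,
        "max_consensus_rel_error": max(abs(v) for v in rel.values()),
        "pair_regression_slope": slope,
        "n_elements_dated": len(pair_ages),
        "analytic_pair_age_at_974": identity_to_age(0.974, ClockModel(divergence_mode="pair")),
        "analytic_consensus_age_at_974": identity_to_age(
            0.974, ClockModel(divergence_mode="consensus")
        ),
    }


# ---------------------------------------------------------------------------
# proximity


def proximity_readpair_experiment(seed: int, error_rate: float = 0.002) -> dict:
    """Recovery of planted gene-adjacent insertions from read pairs alone.

    Adjacent insertions are planted 1-250 bp upstream so the TE-gene
    junction falls inside sequenced fragments: with 100 nt mates and a
    600 nt insert, read-pair evidence is geometrically blind beyond
    insert - 2*read_len = 400 bp.
    """
    insert_size, read_len = 600, 100
    clock = ClockModel()
    fams = simulate_family_library(
        2, seed=_seed(seed, 31), target_mb_range=(0.05, 0.05),
        age_my_range=(0.5, 0.6), ltr_len_range=(280, 320), internal_len_range=(600, 700),
    )
    profile = SpeciesProfile("spP", 0.4, fams, gene_count=30)
    sim = simulate_genome(
        profile, clock, seed=_seed(seed, 32),
        upstream_fraction=0.5, upstream_range=(1, 250),
    )
    m1, m2 = simulate_reads(
        sim, coverage=2.0, read_len=read_len, paired=True,
        insert_size=insert_size, error_rate=error_rate, seed=_seed(seed, 33),
    )
    te_contigs = {f.name: f.element_seq for f in fams}
    te_classes = {f.name: f.superfamily for f in fams}
    gene_seqs = dict(sim.gene_seqs())
    k1, k2 = prefilter_te_pairs(m1, m2, te_contigs)
    hits, counts, n_amb = classify_pairs(k1, k2, te_contigs, gene_seqs, te_classes=te_classes)

    klass_of = {f.name: f"TE:{f.superfamily}" for f in fams}
    planted = {
        (t.nearest_gene, klass_of[t.family])
        for t in sim.insertions
        if t.nearest_gene and t.upstream_distance_bp <= insert_size - 2 * read_len
    }
    recovered = {pair for pair in planted if counts.get(pair, 0) > 0}
    sensitivity = len(recovered) / len(planted) if planted else float("nan")

    # genes with no TE of any family within insert range, per truth
    from intervaltree import IntervalTree

    te_tree = IntervalTree()
    for t in sim.insertions:
        te_tree.addi(max(0, t.start - insert_size), t.end + insert_size)
    isolated = {
        g.gene_id for g in sim.genes if not te_tree.overlaps(g.start, g.end)
    }
    fp_hits = sum(n for (g, _), n in counts.items() if g in isolated)

    return {
        "n_planted_detectable": len(planted),
        "n_recovered": len(recovered),
        "sensitivity": sensitivity,
        "n_isolated_genes": len(isolated),
        "false_positive_hits_on_isolated_genes": fp_hits,
        "n_pairs_prefiltered": len(k1),
        "n_ambiguous": n_amb,
    }


def proximity_oracle_experiment(seed: int, n_fixtures: int = 100) -> dict:
    """upstream_hits vs an all-pairs scan on random interval fixtures."""
    from math import ceil

    from .genedist import GenomicInterval, upstream_hits

    rng = np.random.default_rng(_seed(seed, 41))
    n_equal = 0
    for _ in range(n_fixtures):
        genes = []
        tes = []
        for i, s in enumerate(rng.integers(0, 150_000, size=60)):
            genes.append(
                GenomicInterval(
                    "chr1", int(s), int(s) + int(rng.integers(300, 2500)),
                    "+" if rng.random() < 0.5 else "-", f"g{i}", "gene",
                )
            )
        for i, s in enumerate(rng.integers(0, 150_000, size=120)):
            tes.append(
                GenomicInterval(
                    "chr1", int(s), int(s) + int(rng.integers(80, 1500)), ".",
                    f"t{i}", "TE:gypsy",
                )
            )
        got = {(h.gene_id, h.te_id, h.distance_bp) for h in upstream_hits(genes, tes)}
        brute = set()
        for g in genes:
            for t in tes:
                d = g.start - t.end if g.strand == "+" else t.start - g.end
                if 1 <= d <= 5000:
                    brute.add((g.feature_id, t.feature_id, d))
        n_equal += got == brute
    return {"n_fixtures": n_fixtures, "n_equal": n_equal}


# ---------------------------------------------------------------------------
# enrichment


def enrichment_exactness_experiment(seed: int, n_cases: int = 30) -> dict:
    """Hypergeometric p vs exhaustive enumeration for N <= 12."""
    import itertools

    rng = np.random.default_rng(_seed(seed, 51))
    max_abs_diff = 0.0
    for _ in range(n_cases):
        N = int(rng.integers(5, 13))
        background = list(range(N))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        term = set(rng.choice(background, K, replace=False).tolist())
        query = set(rng.choice(background, n, replace=False).tolist())
        k = len(query & term)
        total = hits = 0
        for draw in itertools.combinations(background, n):
            total += 1
            hits += len(set(draw) & term) >= k
        max_abs_diff = max(max_abs_diff, abs(hypergeom_pvalue(k, K, n, N) - hits / total))
    return {"n_cases": n_cases, "max_abs_diff": max_abs_diff}


def enrichment_null_experiment(
    seed: int, reps: int = 1000, n_genes: int = 1000, n_terms: int = 40, query_size: int = 60
) -> dict:
    """Fraction of null terms called at q < 0.05 over random queries."""
    from scipy.stats import hypergeom

    rng = np.random.default_rng(_seed(seed, 52))
    term_sizes = rng.integers(10, 51, size=n_terms)
    member = np.zeros((n_terms, n_genes), dtype=bool)
    for t, size in enumerate(term_sizes):
        member[t, rng.choice(n_genes, size=size, replace=False)] = True
    n_called = 0
    for _ in range(reps):
        q = np.zeros(n_genes, dtype=bool)
        q[rng.choice(n_genes, size=query_size, replace=False)] = True
        k = member @ q
        p = hypergeom.sf(k - 1, n_genes, term_sizes, query_size)
        n_called += int(np.sum(np.array(bh_adjust(list(p))) < 0.05))
    return {
        "reps": reps,
        "n_terms": n_terms,
        "fdr_fraction": n_called / (reps * n_terms),
    }


# ---------------------------------------------------------------------------
# determinism


def determinism_experiment(seed: int, workdir, reuse_first: Path | None = None) -> dict:
    """Run the demo pipeline twice with one seed; compare outputs byte-wise.

    run.log carries wall-clock timings and is the one file excluded.
    """
    workdir = Path(workdir)
    cfg = pipeline.demo_config(seed)
    dirs = []
    for tag in ("run1", "run2"):
        d = workdir / tag
        if tag == "run1" and reuse_first is not None:
            d = Path(reuse_first)
        else:
            pipeline.run(cfg, d)
        dirs.append(d)
    a, b = dirs
    rel_a = {p.relative_to(a) for p in a.rglob("*") if p.is_file() and p.name != "run.log"}
    rel_b = {p.relative_to(b) for p in b.rglob("*") if p.is_file() and p.name != "run.log"}
    mismatched = sorted(
        str(rel)
        for rel in rel_a & rel_b
        if not filecmp.cmp(a / rel, b / rel, shallow=False)
    )
    return {
        "same_file_set": rel_a == rel_b,
        "n_files_compared": len(rel_a & rel_b),
        "mismatched_files": mismatched,
        "byte_identical": rel_a == rel_b and not mismatched,
    }
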