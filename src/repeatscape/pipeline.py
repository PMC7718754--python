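"""Configured, logged, resumable orchestration of the full analysis.

Stage order: simulate -> cluster -> annotate -> quantify -> date ->
proximity -> enrich. Every stage writes plain TSV/FASTA/FASTQ/JSON
outputs plus a manifest entry (parameter hash, output checksums) under
its own subdirectory; reruns with an identical config and seed are
byte-identical (run.log, which carries wall-clock timings, is the one
deliberately non-deterministic file). A stage whose manifest entry
matches the current parameter hash and whose outputs verify is reused,
so partial reruns resume instead of recomputing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .enrichstats import hypergeom_enrich, load_term_table, results_to_frame
from .errors import (
    ConfigError,
    EmptyDistributionError,
    InsufficientDataError,
    InsufficientReadsError,
    MissingStageError,
)
from .genedist import (
    MapParams,
    classify_pairs,
    hits_to_frame,
    prefilter_te_pairs,
    read_gff3_intervals,
    upstream_hits,
)
from .paleoclock import Timeline, date_element_by_ltr_pair, estimate_cluster_age, map_reads_to_ltr
from .quantify import composition_table, sharing_matrix, sharing_table, total_read_length_mb
from .readcluster import (
    ClusterParams,
    ClusteringResult,
    Read,
    RepeatCluster,
    build_clusters,
    pool_species,
    write_cluster_summary_tsv,
    write_membership_tsv,
)
from .repeatlib import build_consensus, extract_ltr, load_library, annotate_cluster
from .synthio import (
    ClockModel,
    SpeciesProfile,
    TEFamilySpec,
    simulate_genome,
    simulate_reads,
    simulate_term_table,
    write_family_library,
    write_term_table,
    _codes_to_seq,
    _random_codes,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "cluster", "annotate", "quantify", "date", "proximity", "enrich")

_STAGE_DEPS = {
    "simulate": (),
    "cluster": ("simulate",),
    "annotate": ("simulate", "cluster"),
    "quantify": ("simulate", "cluster", "annotate"),
    "date": ("simulate", "cluster", "annotate"),
    "proximity": ("simulate", "date"),
    "enrich": ("simulate", "proximity"),
}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class FamilyPlan:
    """Per-species planting parameters for one (possibly shared) family."""

    name: str
    target_mb: float
    age_my: float
    age_sd_my: float = 0.0


@dataclass
class SpeciesPlan:
    code: str
    genome_size_mb: float
    gene_count: int
    families: list[FamilyPlan]


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run."""

    seed: int
    species: list[SpeciesPlan]
    family_superfamilies: dict[str, str]          # family name -> gypsy/copia/...
    clock: ClockModel = field(default_factory=ClockModel)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    map_params: MapParams = field(default_factory=MapParams)
    coverage: float = 0.5
    read_len: int = 100
    error_rate: float = 0.002
    pooled_sample_per_species: int = 1200
    min_reads_per_species: int = 5
    upstream_fraction: float = 0.25
    upstream_range: tuple[int, int] = (1, 1000)
    gene_length_range: tuple[int, int] = (800, 1500)
    # genes count as TE-adjacent for enrichment only within this many kb
    # upstream: in a repeat-dense genome the full 5 kb window covers nearly
    # every gene and carries no signal
    enrich_max_kb: int = 1
    readpair_species: list[str] = field(default_factory=list)
    paired_coverage: float = 2.0
    insert_size: int = 600
    ltr_len_range: tuple[int, int] = (280, 320)
    internal_len_range: tuple[int, int] = (600, 700)
    n_terms: int = 25
    min_cluster_reads_for_dating: int = 10

    def family_names(self) -> list[str]:
        return sorted({fp.name for sp in self.species for fp in sp.families})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _collect_config_problems(cfg: RunConfig) -> list[str]:
    problems = []
    codes = [sp.code for sp in cfg.species]
    dupes = {c for c in codes if codes.count(c) > 1}
    if dupes:
        problems.append(f"duplicate species codes: {sorted(dupes)}")
    if not cfg.species:
        problems.append("at least one species is required")
    for sp in cfg.species:
        if sp.genome_size_mb <= 0:
            problems.append(f"species {sp.code}: genome_size_mb must be > 0")
        if sp.gene_count < 0:
            problems.append(f"species {sp.code}: gene_count must be >= 0")
        total = sum(f.target_mb for f in sp.families)
        if total > sp.genome_size_mb:
            problems.append(
                f"species {sp.code}: family target_mb sum {total:.3f} exceeds genome size"
            )
        for fp in sp.families:
            if fp.target_mb < 0:
                problems.append(f"{sp.code}/{fp.name}: target_mb must be >= 0")
            if fp.age_my < 0 or fp.age_sd_my < 0:
                problems.append(f"{sp.code}/{fp.name}: ages must be >= 0")
            if fp.name not in cfg.family_superfamilies:
                problems.append(f"{sp.code}/{fp.name}: missing superfamily assignment")
    for code in cfg.readpair_species:
        if code not in codes:
            problems.append(f"readpair_species {code!r} is not a configured species")
    if cfg.coverage <= 0:
        problems.append("coverage must be > 0")
    if cfg.insert_size < 2 * cfg.read_len:
        problems.append("insert_size must be >= 2 * read_len")
    return problems


_KNOWN_KEYS = {
    "seed", "species", "family_superfamilies", "clock", "clustering", "mapping",
    "coverage", "read_len", "error_rate", "pooled_sample_per_species",
    "min_reads_per_species", "upstream_fraction", "upstream_range",
    "readpair_species", "paired_coverage", "insert_size",
    "ltr_len_range", "internal_len_range", "n_terms", "min_cluster_reads_for_dating",
    "gene_length_range", "enrich_max_kb",
}


def config_from_dict(raw: dict) -> RunConfig:
    problems = [f"unknown config key: {k}" for k in raw if k not in _KNOWN_KEYS]
    try:
        species = [
            SpeciesPlan(
                code=s["code"],
                genome_size_mb=float(s["genome_size_mb"]),
                gene_count=int(s.get("gene_count", 0)),
                families=[FamilyPlan(**f) for f in s.get("families", [])],
            )
            for s in raw.get("species", [])
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(problems + [f"malformed species section: {exc}"]) from exc
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        species=species,
        family_superfamilies=dict(raw.get("family_superfamilies", {})),
        clock=ClockModel(**raw.get("clock", {})),
        cluster_params=ClusterParams(**raw.get("clustering", {})),
        map_params=MapParams(**raw.get("mapping", {})),
        **{
            k: (tuple(raw[k]) if k.endswith("_range") else raw[k])
            for k in (
                "coverage", "read_len", "error_rate", "pooled_sample_per_species",
                "min_reads_per_species", "upstream_fraction", "upstream_range",
                "readpair_species", "paired_coverage", "insert_size",
                "ltr_len_range", "internal_len_range", "n_terms",
                "min_cluster_reads_for_dating", "gene_length_range", "enrich_max_kb",
            )
            if k in raw
        },
    )
    problems.extend(_collect_config_problems(cfg))
    if problems:
        raise ConfigError(problems)
    return cfg


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; all problems reported together."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(["config file must contain a mapping"])
    return config_from_dict(raw)


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_yaml_dict(cfg), fh, sort_keys=True)


def _config_yaml_dict(cfg: RunConfig) -> dict:
    d = cfg.to_dict()
    out = {
        "seed": d["seed"],
        "species": [
            {
                "code": s["code"],
                "genome_size_mb": s["genome_size_mb"],
                "gene_count": s["gene_count"],
                "families": s["families"],
            }
            for s in d["species"]
        ],
        "family_superfamilies": d["family_superfamilies"],
        "clock": d["clock"],
        "clustering": d["cluster_params"],
        "mapping": d["map_params"],
    }
    for k in sorted(_KNOWN_KEYS - {"seed", "species", "family_superfamilies", "clock", "clustering", "mapping"}):
        v = d[k]
        out[k] = list(v) if isinstance(v, tuple) else v
    return out


def demo_config(seed: int = 11) -> RunConfig:
    """The bundled three-species demo design.

    Six families across three species: one shared by all three, two
    shared pairwise, and one private per species — so comparative
    clustering should recover the intersection rows {A,B,C}, {A,B},
    {B,C}, {A}, {B}, {C} exactly. Ages span 0.8-2 My and species B is
    analysed reference-free (read pairs) as well.
    """
    fams = {
        "famU": "gypsy",    # shared by all three species
        "famAB": "copia",   # shared by spA + spB
        "famBC": "copia",   # shared by spB + spC
        "famPA": "gypsy",   # private
        "famPB": "copia",
        "famPC": "gypsy",
    }

    def plan(name, target, age):
        return FamilyPlan(name=name, target_mb=target, age_my=age, age_sd_my=0.1 * age)

    species = [
        SpeciesPlan("spA", 0.5, 80, [plan("famU", 0.075, 1.0), plan("famAB", 0.075, 0.8), plan("famPA", 0.06, 1.5)]),
        SpeciesPlan("spB", 0.6, 80, [plan("famU", 0.075, 1.2), plan("famAB", 0.075, 1.0), plan("famBC", 0.075, 0.9), plan("famPB", 0.06, 2.0)]),
        SpeciesPlan("spC", 0.5, 80, [plan("famU", 0.075, 1.8), plan("famBC", 0.075, 1.1), plan("famPC", 0.06, 1.2)]),
    ]
    return RunConfig(
        seed=seed,
        species=species,
        family_superfamilies=fams,
        readpair_species=["spB"],
        cluster_params=ClusterParams(significant_fraction=2e-3),
    )


# ---------------------------------------------------------------------------
# manifest helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(cfg: RunConfig, stage: str) -> str:
    payload = json.dumps({"stage": stage, "config": cfg.to_dict()}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _derive_seed(base: int, *parts: str) -> int:
    tag = zlib.crc32(":".join(parts).encode())
    return int((base * 1_000_003 + tag) % (2**31 - 1))


class PipelineRun:
    """One pipeline execution rooted at ``outdir``."""

    def __init__(self, cfg: RunConfig, outdir):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {"stages": {}}
        )
        handler = logging.FileHandler(self.outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        self._log_handler = handler
        logging.getLogger("repeatscape").addHandler(handler)

    def close(self):
        logging.getLogger("repeatscape").removeHandler(self._log_handler)
        self._log_handler.close()

    # ------------------------------------------------------------------
    def run(self, stages=None) -> dict:
        """Execute the requested stages (default: all) in dependency order."""
        requested = list(stages) if stages else list(STAGES)
        unknown = set(requested) - set(STAGES)
        if unknown:
            raise ConfigError([f"unknown stage: {s}" for s in sorted(unknown)])
        write_config(self.cfg, self.outdir / "resolved_config.yaml")
        for stage in STAGES:
            if stage not in requested:
                continue
            for dep in _STAGE_DEPS[stage]:
                if dep not in requested and not self._stage_done(dep):
                    raise MissingStageError(
                        f"stage {stage!r} needs outputs of {dep!r}; run {dep!r} first"
                    )
            self._run_stage(stage)
        self.close()
        return self.manifest

    def _stage_done(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry or entry["params_hash"] != _params_hash(self.cfg, stage):
            return False
        return all((self.outdir / rel).exists() for rel in entry["outputs"])

    def _run_stage(self, stage: str):
        if self._stage_done(stage):
            log.info("stage %s: up to date, reusing outputs", stage)
            return
        t0 = time.perf_counter()
        outputs = getattr(self, f"_stage_{stage}")()
        self.manifest["stages"][stage] = {
            "params_hash": _params_hash(self.cfg, stage),
            "outputs": {
                str(Path(p).relative_to(self.outdir)): _sha256(Path(p)) for p in outputs
            },
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True) + "\n")
        log.info("stage %s: done in %.1f s (%d outputs)", stage, time.perf_counter() - t0, len(outputs))

    # ------------------------------------------------------------------ helpers
    def _dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(exist_ok=True)
        return d

    def _family_specs(self) -> dict[str, TEFamilySpec]:
        """Family consensus sequences, drawn once per family name from the seed."""
        import numpy as np

        specs = {}
        for name in self.cfg.family_names():
            rng = np.random.default_rng(_derive_seed(self.cfg.seed, "family", name))
            ltr_len = int(rng.integers(*self.cfg.ltr_len_range))
            int_len = int(rng.integers(*self.cfg.internal_len_range))
            specs[name] = TEFamilySpec(
                name=name,
                superfamily=self.cfg.family_superfamilies[name],
                ltr_seq=_codes_to_seq(_random_codes(rng, ltr_len)),
                internal_seq=_codes_to_seq(_random_codes(rng, int_len)),
                target_mb=0.0,
                age_my=0.0,
            )
        return specs

    def _profile(self, plan: SpeciesPlan, specs: dict[str, TEFamilySpec]) -> SpeciesProfile:
        fams = [
            dataclasses.replace(
                specs[fp.name], target_mb=fp.target_mb, age_my=fp.age_my, age_sd_my=fp.age_sd_my
            )
            for fp in plan.families
        ]
        return SpeciesProfile(
            species_code=plan.code,
            genome_size_mb=plan.genome_size_mb,
            families=fams,
            gene_count=plan.gene_count,
        )

    def _load_reads(self, sp: str) -> list[Read]:
        path = self.outdir / "simulate" / f"{sp}.reads.fastq"
        return [Read(rid, sp, seq) for rid, seq in io.read_seqs(path)]

    def _load_clusters(self, tag: str) -> ClusteringResult:
        """Rebuild a ClusteringResult from a membership TSV (+ annotations if present)."""
        path = self.outdir / "cluster" / f"{tag}.membership.tsv"
        if not path.exists():
            raise MissingStageError(f"missing {path}; run the cluster stage first")
        df = pd.read_csv(path, sep="\t", dtype=str)
        ann_path = self.outdir / "annotate" / f"{tag}.annotation.tsv"
        ann = {}
        if ann_path.exists():
            adf = pd.read_csv(ann_path, sep="\t", dtype=str).fillna("")
            ann = {
                row.cluster_id: (row.family or None, row.superfamily or None)
                for row in adf.itertuples()
            }
        clusters, remainder = [], []
        for (cid, sig), grp in df.groupby(["cluster_id", "significant"], sort=False):
            members = set(grp["read_id"])
            counts = grp.groupby("species_code").size().to_dict()
            cl = RepeatCluster(cid, members, counts, *ann.get(cid, (None, None)))
            (clusters if sig == "1" else remainder).append(cl)
        clusters.sort(key=lambda c: int(c.cluster_id[2:]))
        n = len(df)
        return ClusteringResult(clusters, remainder, n, 0)

    # ------------------------------------------------------------------ stages
    def _stage_simulate(self) -> list[Path]:
        cfg = self.cfg
        out = self._dir("simulate")
        specs = self._family_specs()
        written: list[Path] = []
        lib_path = out / "library.fasta"
        write_family_library([specs[n] for n in cfg.family_names()], lib_path)
        written.append(lib_path)
        favored: dict[str, list[str]] = {}
        for plan in cfg.species:
            profile = self._profile(plan, specs)
            sim = simulate_genome(
                profile,
                cfg.clock,
                seed=_derive_seed(cfg.seed, "genome", plan.code),
                upstream_fraction=cfg.upstream_fraction,
                upstream_range=cfg.upstream_range,
                gene_length_range=cfg.gene_length_range,
            )
            written.extend(sim.write(out).values())
            reads, _ = simulate_reads(
                sim, cfg.coverage, cfg.read_len,
                error_rate=cfg.error_rate,
                seed=_derive_seed(cfg.seed, "reads", plan.code),
            )
            rp = out / f"{plan.code}.reads.fastq"
            io.write_fastq(reads, rp)
            written.append(rp)
            if plan.code in cfg.readpair_species:
                m1, m2 = simulate_reads(
                    sim, cfg.paired_coverage, cfg.read_len, paired=True,
                    insert_size=cfg.insert_size, error_rate=cfg.error_rate,
                    seed=_derive_seed(cfg.seed, "pairs", plan.code),
                )
                for tag, recs in (("1", m1), ("2", m2)):
                    pp = out / f"{plan.code}.pairs_{tag}.fastq"
                    io.write_fastq(recs, pp)
                    written.append(pp)
            favored[plan.code] = sorted(
                {t.nearest_gene for t in sim.insertions if t.nearest_gene}
            )
            terms = simulate_term_table(
                [g.gene_id for g in sim.genes],
                favored[plan.code],
                n_terms=cfg.n_terms,
                seed=_derive_seed(cfg.seed, "terms", plan.code),
            )
            tp = out / f"{plan.code}.terms.tsv"
            write_term_table(terms, tp)
            written.append(tp)
        return written

    def _stage_cluster(self) -> list[Path]:
        cfg = self.cfg
        out = self._dir("cluster")
        written = []
        for plan in cfg.species:
            reads = self._load_reads(plan.code)
            result = build_clusters(reads, cfg.cluster_params)
            for suffix, writer in (
                ("membership", lambda r, p: write_membership_tsv(r, reads, p)),
                ("summary", write_cluster_summary_tsv),
            ):
                p = out / f"{plan.code}.{suffix}.tsv"
                writer(result, p)
                written.append(p)
        pooled = pool_species(
            {plan.code: self.outdir / "simulate" / f"{plan.code}.reads.fastq" for plan in cfg.species},
            cfg.pooled_sample_per_species,
            seed=_derive_seed(cfg.seed, "pool"),
        )
        result = build_clusters(pooled, cfg.cluster_params)
        for suffix, writer in (
            ("membership", lambda r, p: write_membership_tsv(r, pooled, p)),
            ("summary", write_cluster_summary_tsv),
        ):
            p = out / f"pooled.{suffix}.tsv"
            writer(result, p)
            written.append(p)
        return written

    def _annotate_one(self, tag: str, reads_by_id: dict[str, Read], out: Path) -> Path:
        library = load_library(self.outdir / "simulate" / "library.fasta")
        result = self._load_clusters(tag)
        rows = []
        for cl in result.clusters:
            family, sf = annotate_cluster(
                cl, reads_by_id, library,
                seed=_derive_seed(self.cfg.seed, "annotate", tag, cl.cluster_id),
            )
            cl.annotation, cl.superfamily = family, sf
            rows.append({"cluster_id": cl.cluster_id, "size": cl.size,
                         "family": family or "", "superfamily": sf or ""})
        p = out / f"{tag}.annotation.tsv"
        pd.DataFrame(rows, columns=["cluster_id", "size", "family", "superfamily"]).to_csv(
            p, sep="\t", index=False
        )
        return p

    def _stage_annotate(self) -> list[Path]:
        out = self._dir("annotate")
        written = []
        for plan in self.cfg.species:
            reads = {r.read_id: r for r in self._load_reads(plan.code)}
            written.append(self._annotate_one(plan.code, reads, out))
        pooled_reads: dict[str, Read] = {}
        for plan in self.cfg.species:
            for r in self._load_reads(plan.code):
                pooled_reads[f"{plan.code}|{r.read_id}"] = Read(
                    f"{plan.code}|{r.read_id}", plan.code, r.seq
                )
        written.append(self._annotate_one("pooled", pooled_reads, out))
        return written

    def _stage_quantify(self) -> list[Path]:
        cfg = self.cfg
        out = self._dir("quantify")
        written = []
        genome_sizes = {p.code: p.genome_size_mb for p in cfg.species}
        frames = []
        proportions = {}
        for plan in cfg.species:
            reads = {r.read_id: r for r in self._load_reads(plan.code)}
            result = self._load_clusters(plan.code)
            table, prop = composition_table(
                result.clusters, reads,
                {plan.code: genome_sizes[plan.code]},
                {plan.code: total_read_length_mb(reads)},
            )
            frames.append(table)
            proportions[plan.code] = float(prop[plan.code])
        comp = pd.concat(frames, axis=1).fillna(0.0).sort_index()
        p = out / "composition_mb.tsv"
        comp.round(4).to_csv(p, sep="\t")
        written.append(p)
        p = out / "genome_proportion.tsv"
        pd.Series(proportions, name="genome_proportion").round(4).rename_axis("species").to_csv(p, sep="\t")
        written.append(p)
        pooled = self._load_clusters("pooled")
        rows = sharing_matrix(pooled.clusters, cfg.min_reads_per_species)
        p = out / "sharing.tsv"
        sharing_table(rows).to_csv(p, sep="\t", index=False)
        written.append(p)
        return written

    def _stage_date(self) -> list[Path]:
        cfg = self.cfg
        out = self._dir("date")
        written = []
        library = load_library(self.outdir / "simulate" / "library.fasta")
        ltr_db = [rec for rec in library if rec.is_ltr_exemplar]
        timeline = Timeline()
        contigs = []
        for plan in cfg.species:
            reads = {r.read_id: r for r in self._load_reads(plan.code)}
            result = self._load_clusters(plan.code)
            for cl in result.clusters:
                if cl.size < cfg.min_cluster_reads_for_dating:
                    timeline.insufficient.append((cl.cluster_id, plan.code, "too_few_reads"))
                    continue
                try:
                    contig = build_consensus(
                        cl, reads, plan.code,
                        seed=_derive_seed(cfg.seed, "consensus", plan.code, cl.cluster_id),
                    )
                except InsufficientReadsError:
                    timeline.insufficient.append((cl.cluster_id, plan.code, "assembly_failed"))
                    continue
                contigs.append((f"{plan.code}:{cl.cluster_id}", contig.seq))
                ltr = extract_ltr(contig, ltr_db)
                if ltr is None:
                    timeline.insufficient.append((cl.cluster_id, plan.code, "no_ltr_hit"))
                    continue
                member_reads = [reads[rid] for rid in sorted(cl.members)]
                try:
                    dist = map_reads_to_ltr(member_reads, ltr)
                    timeline.estimates.append(
                        estimate_cluster_age(dist, cfg.clock, error_rate=cfg.error_rate)
                    )
                except (InsufficientDataError, EmptyDistributionError) as exc:
                    timeline.insufficient.append((cl.cluster_id, plan.code, type(exc).__name__))
        p = out / "cluster_ages.tsv"
        timeline.to_frame().round(6).to_csv(p, sep="\t", index=False)
        written.append(p)
        p = out / "consensus_contigs.fasta"
        io.write_fasta(contigs, p)
        written.append(p)

        # pair-mode dating of individual annotated insertions (truth ledger
        # stands in for a structural LTR annotation)
        rows = []
        for plan in cfg.species:
            truth = pd.read_csv(self.outdir / "simulate" / f"{plan.code}.truth.tsv", sep="\t")
            genome = dict(io.read_seqs(self.outdir / "simulate" / f"{plan.code}.genome.fasta"))
            seq = genome[truth["chrom"].iloc[0]] if len(truth) else ""
            for t in truth.itertuples():
                age = date_element_by_ltr_pair(
                    seq[t.ltr5_start : t.ltr5_end], seq[t.ltr3_start : t.ltr3_end], cfg.clock
                )
                rows.append(
                    {"species_code": plan.code, "family": t.family, "start": t.start,
                     "end": t.end, "true_age_my": t.age_my, "estimated_age_my": age}
                )
        p = out / "insertion_ages.tsv"
        pd.DataFrame(
            rows,
            columns=["species_code", "family", "start", "end", "true_age_my", "estimated_age_my"],
        ).round(6).to_csv(p, sep="\t", index=False)
        written.append(p)
        return written

    def _stage_proximity(self) -> list[Path]:
        cfg = self.cfg
        out = self._dir("proximity")
        written = []
        for plan in cfg.species:
            feats = read_gff3_intervals(self.outdir / "simulate" / f"{plan.code}.genes.gff3")
            tes = read_gff3_intervals(self.outdir / "simulate" / f"{plan.code}.tes.gff3")
            genes = [f for f in feats if f.feature_class == "gene"]
            hits = upstream_hits(genes, tes)
            p = out / f"{plan.code}.reference_hits.tsv"
            hits_to_frame(hits).to_csv(p, sep="\t", index=False)
            written.append(p)
        for sp in cfg.readpair_species:
            p1 = [(i, s) for i, s in io.read_seqs(self.outdir / "simulate" / f"{sp}.pairs_1.fastq")]
            p2 = [(i, s) for i, s in io.read_seqs(self.outdir / "simulate" / f"{sp}.pairs_2.fastq")]
            contigs = {
                name: seq
                for name, seq in io.read_seqs(self.outdir / "date" / "consensus_contigs.fasta")
                if name.startswith(f"{sp}:")
            }
            ann = pd.read_csv(self.outdir / "annotate" / f"{sp}.annotation.tsv", sep="\t", dtype=str).fillna("")
            classes = {
                f"{sp}:{row.cluster_id}": row.superfamily for row in ann.itertuples()
            }
            genome = dict(io.read_seqs(self.outdir / "simulate" / f"{sp}.genome.fasta"))
            feats = read_gff3_intervals(self.outdir / "simulate" / f"{sp}.genes.gff3")
            gene_seqs = {
                f.feature_id: genome[f.chrom][f.start : f.end]
                for f in feats
                if f.feature_class == "gene"
            }
            k1, k2 = prefilter_te_pairs(p1, p2, contigs)
            hits, counts, n_amb = classify_pairs(
                k1, k2, contigs, gene_seqs, cfg.map_params, te_classes=classes
            )
            log.info("%s read-pair proximity: %d hits, %d ambiguous pairs", sp, len(hits), n_amb)
            p = out / f"{sp}.readpair_hits.tsv"
            hits_to_frame(hits).to_csv(p, sep="\t", index=False)
            written.append(p)
            p = out / f"{sp}.readpair_gene_counts.tsv"
            pd.DataFrame(
                [
                    {"gene_id": g, "te_class": c, "n_pairs": n}
                    for (g, c), n in sorted(counts.items())
                ],
                columns=["gene_id", "te_class", "n_pairs"],
            ).to_csv(p, sep="\t", index=False)
            written.append(p)
        return written

    def _stage_enrich(self) -> list[Path]:
        cfg = self.cfg
        out = self._dir("enrich")
        written = []
        for plan in cfg.species:
            hits = pd.read_csv(
                self.outdir / "proximity" / f"{plan.code}.reference_hits.tsv", sep="\t", dtype=str
            )
            if len(hits):
                hits = hits[hits["bin_kb"].astype(int) <= cfg.enrich_max_kb]
            feats = read_gff3_intervals(self.outdir / "simulate" / f"{plan.code}.genes.gff3")
            background = [f.feature_id for f in feats if f.feature_class == "gene"]
            query = sorted(set(hits["gene_id"]) & set(background))
            terms = load_term_table(self.outdir / "simulate" / f"{plan.code}.terms.tsv")
            results = hypergeom_enrich(query, background, terms)
            p = out / f"{plan.code}.enrichment.tsv"
            results_to_frame(results).round(8).to_csv(p, sep="\t", index=False)
            written.append(p)
        return written


def run(cfg: RunConfig, outdir, stages=None) -> dict:
    """Run the pipeline; returns the manifest."""
    return PipelineRun(cfg, outdir).run(stages=stages)
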