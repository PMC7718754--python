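# repeatscape

Reference-free analysis of transposable-element evolution from low-coverage
shotgun reads — for researchers studying repeat landscapes in taxa that have
read data but no genome assembly.

Given 0.2–0.5× coverage per species, the package:

1. **clusters** reads into repeat families via a similarity graph
   (edges at ≥ 90% identity over ≥ 55% of the shorter read; clusters are
   connected components), per species and pooled across species;
2. **annotates** clusters against a repeat exemplar library
   (`name#superfamily` FASTA) and **quantifies** each family's genome
   occupancy: `Mb = cluster read length × genome size / total read length`;
3. tallies **cross-species sharing** of clusters (UpSet-style intersection
   rows);
4. **dates** family activity with the grass TE molecular clock
   (r = 1.3 × 10⁻⁸ substitutions/site/year): reads are mapped to the
   cluster's consensus LTR and the peak identity converts as
   `age = (1 − identity)/r`; individual elements date from their LTR pair as
   `age = (1 − identity)/2r`;
5. detects **TE insertions 1–5 kb upstream of genes**, from annotations
   (strand-aware interval arithmetic) or reference-free from read pairs
   (one mate on a TE contig, the other on a gene, BWA-aln-style mapping
   contract);
6. tests **functional enrichment** of TE-adjacent genes (exact upper-tail
   hypergeometric p, Benjamini–Hochberg FDR).

Because real repeat landscapes have no ground truth, the package ships a
first-class simulator (`repeatscape.synthio`) that plants LTR-retrotransposon
families with known Mb abundances, insertion ages, sharing patterns and
gene-adjacent insertions, plus a truth ledger — every stage is validated by
recovering what was planted. `docs/methods.md` has the models and numerical
choices.

## Worked example

The bundled three-species demo (six families: one shared by all three
species, two shared pairwise, one private each; 0.5–0.6 Mb genomes, 0.5×
reads) runs end-to-end through numbered drivers:

```bash
python analysis/01_simulate.py          --outdir results/run --seed 11
python analysis/02_cluster.py           --outdir results/run --seed 11
python analysis/03_annotate_quantify.py --outdir results/run --seed 11
python analysis/04_date_activity.py     --outdir results/run --seed 11
python analysis/05_proximity.py         --outdir results/run --seed 11
python analysis/06_enrichment.py        --outdir results/run --seed 11
python analysis/07_validation.py        --outdir results/run --seed 11
```

Each stage is resumable (a finished stage is reused when its parameters are
unchanged), and a rerun with the same seed is byte-identical. From
`03_annotate_quantify.py`, estimated Mb per family next to the planted
target:

```
estimated Mb (planted target in parentheses):
  famAB          0.081 (0.075)   0.081 (0.075)   0.000    -
  famBC          0.000    -      0.071 (0.075)   0.077 (0.075)
  famPA          0.058 (0.060)   0.000    -      0.000    -
  ...
cross-species sharing (pooled clusters):
species_set  n_species  n_clusters
        spA          1           1
    spA+spB          2           1
spA+spB+spC          3           1  ...
```

— the intersection rows are exactly the planted design, and the composition
table recovers each family within ±9% here (±15% is the validated bound).
`04_date_activity.py` prints the activity timeline, e.g.

```
  spA CL2   famU     peak identity 0.9846 -> 1.03 My (planted 1.0 My)
  spB CL4   famPB    peak identity 0.9749 -> 1.78 My (planted 2.0 My)
LTR-pair dating of 553 individual insertions: estimated vs planted age slope 0.919
```

(the slope shortfall below 1 is mostly the uncorrected multiple-hit bias,
see the methods note). `06_enrichment.py` surfaces the planted
stress-response term while the random terms stay flat:

```
spA: 26 terms tested
  T_stress_response  k=24 K=26 n=43 N=80 p=7.20e-07 q=1.88e-05 <-- planted
  T007               k= 9 K=12 n=43 N=80 p=9.77e-02 q=7.38e-01
```

The library is importable piecewise: `readcluster.build_clusters`,
`quantify.composition_table`, `paleoclock.date_element_by_ltr_pair`,
`genedist.upstream_hits`, `enrichstats.hypergeom_enrich`, … —
`pipeline.run(config, outdir)` orchestrates the whole study from one YAML
config (`pipeline.validate_config` collects every config problem at once).

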