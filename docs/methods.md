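# Methods

`repeatscape` reconstructs the evolutionary history of LTR-retrotransposon
families from low-coverage (0.2–0.5×) shotgun reads, without a genome
assembly, and validates every stage against synthetic genomes with planted
ground truth. This note records the models, the numerical choices, and what
the synthetic validation does and does not establish.

## Graph-based repeat clustering

Reads are nodes of a similarity graph; an edge connects two reads whose best
local alignment (either strand) reaches **≥ 90% identity over ≥ 55% of the
shorter read**. Repeat clusters are connected components, ordered by size and
named CL1, CL2, …; components smaller than `significant_fraction` of the
input (default 10⁻⁴, the usual 0.01% convention for this kind of clustering)
are reported in a remainder bucket. In comparative mode an equal-size random
sample per species is pooled first and each cluster keeps per-species read
counts.

Numerical choices:

* **Alignment scoring** is match +1 / mismatch −1 / gap −2 (configurable);
  identity is matches over alignment columns, with internal gap columns
  counting as columns. The 55% span is measured on the shorter read (the
  natural reading when read lengths differ).
* **k-mer prefilter.** Pairs are aligned only if they share a
  strand-canonical k-mer (k = 9). A pair passing the thresholds over C
  alignment columns must contain a run of ≥ 9 consecutive match columns for
  every C except C ∈ {60, 61, 62, 70, 71, 80}, where only an 8-run is
  guaranteed; a qualifying pair can therefore be missed only if its single
  best alignment falls in those widths with every match run ≤ 8 — an
  adversarial configuration that substitution divergence essentially never
  produces. `kmer_len=8` gives the strict superset guarantee at about twice
  the alignment cost. The acceptance suite checks the default path against
  brute-force all-vs-all clustering.
* **Score prescreen.** Under m/−m/−2m scoring, any qualifying alignment
  scores at least (3·i−2)·f·min_len·m (i = identity, f = span fraction), so a
  score-only pass (no traceback) filters candidate pairs exactly before the
  full alignment is computed.
* Reads with more than 10% N or shorter than 50 nt are dropped and counted;
  N never matches anything.

Connected components, not community detection: a dense cluster that would
need community splitting (e.g. two families bridged by reads from a nested
insertion) is out of scope, and the simulator correspondingly does not plant
nested or abutting copies (see below).

## Genome occupancy

A cluster's occupancy in a species is
`(cluster read length in Mb) × (genome size in Mb) / (total length of all
analyzed reads in Mb)`. With this denominator the occupancies of *all*
components — clusters plus unclustered singletons — sum exactly to the
genome size, and the repetitive genome proportion equals the clustered
fraction of read bases, which is how proportions well below 100% arise. A
literal variant that divides by the clustered length only (forcing the
proportions to 1) is available behind `literal_denominator=True`.

Cross-species sharing is tallied per pooled cluster: a species is present if
it contributed ≥ `min_reads_per_species` reads (default 5, to suppress
low-level cross-species contamination); each cluster contributes its exact
presence set to one UpSet-style intersection row. A family can legitimately
split over several clusters (sampling gaps in the overlap graph), so
family-level statements merge the clusters sharing an annotation first —
cluster counts per intersection are reported as-is.

## Molecular-clock dating

LTRs are identical at insertion and diverge at the grass TE substitution
rate r = 1.3 × 10⁻⁸ per site per year. Two dating routes:

* **Read-to-consensus** (family activity): the cluster's reads (one species)
  are assembled into a consensus; its LTR is located by best local match to
  an LTR exemplar (identity ≥ 0.85 over ≥ 80 nt); the reads are mapped back
  to the consensus LTR; the peak of the per-read identity distribution gives
  the family's main amplification era. The consensus approximates the
  ancestral state, so each read's divergence d accrues on one lineage:
  **age = d / r**.
* **LTR-pair** (single elements): the element's two LTRs are globally
  aligned; divergence is split over two lineages: **age = d / 2r**. Pairs
  under 50% identity are rejected as implausible.

A constant sequencing error rate can be subtracted from d (`error_rate`,
default 0). No multiple-hit correction is applied; for the ages this package
targets (≤ ~5 My, d ≤ 0.13) the uncorrected bias reaches ~4% at 5 My and is
visible as a pair-dating regression slope of ~0.95 rather than 1.0.

Calibration choices, each diagnosed against planted truth:

* **End-to-end identity.** A local alignment trims terminal mismatches
  (they cost score and buy nothing), deleting a roughly constant ~0.1
  mismatch per read — 20% of the entire signal for a 0.5 My family. Read
  identities are therefore computed end-to-end over the read/LTR overlap,
  with the trimmed flanks rescored ungapped (reference-mapping semantics).
* **Gap-averse mapping.** Decay is substitution-dominated, and permissive
  gaps both add spurious gap columns (~0.2% divergence) and let unrelated
  element regions scrape together ≥ 50 gapped columns. Read-to-LTR mapping
  uses gap −6; reads below 70% extended identity are excluded as unmapped.
* **Peak estimation.** Per-read identities scatter binomially
  (sd ≈ √(d/columns), one to three 1%-bins), so the raw modal bin is biased
  toward the zero-mismatch ceiling. The peak is located as the modal bin of
  a ±2-bin smoothed histogram, and reported as the pooled matches/columns
  ratio of the reads within ±0.045 of that bin's midpoint — span-weighted
  (a ratio estimator, unbiased under mixed overlap lengths) and wide enough
  that the Poisson mismatch tail is never clipped one-sidedly. Bursts closer
  than ~5 identity points blend into one peak; that is the method's
  intrinsic resolution. The unsmoothed modal bin (midpoint or mean) remains
  available via `refine=`.
* **Consensus assembly and polishing.** Greedy overlap layout (longest read
  seeds; reads join at ≥ 30 overlap columns and ≥ 85% identity; per-column
  majority). The placement threshold must tolerate *twice* the family
  divergence because the early consensus is a single copy's sequence — at
  0.90 the assembly of a 5 My family stalls before its LTRs. After layout,
  every member read (not just the ≤ 200-read layout subsample) is remapped
  for a final majority vote: residual consensus errors add a constant to
  every read's divergence, which matters most for young families.

## TE–gene proximity

*Reference mode*: for a + strand gene the upstream window is
`[start − 5000, start)`; for a − strand gene `[end, end + 5000)`. A TE
qualifies if its gene-proximal edge is 1–5000 bp from the gene start
(overlapping or abutting elements are excluded); distances are binned per
kb. Coordinates are 0-based half-open internally; GFF3 converts on read and
write.

*Reference-free mode* mirrors the paired-end protocol for species without an
assembly: pairs with at least one mate matching a TE contig (local identity
≥ 0.80 over ≥ 50 columns) are retained; both mates are then mapped end-to-end
(edlib) against TE contigs plus gene sequences under a BWA-aln-style
contract — 12-base seed with ≤ 2 mismatches, total edit distance ≤ 4, ≤ 3
gap opens, ≤ 3 gap extensions. A pair is proximity evidence iff one mate's
best target is a TE and the other's a gene; a mate whose equal-best targets
span both classes discards the pair (counted). Exact tie-breaking of the
original aligner is not replicated; best-edit-distance with
ambiguity-discard is used instead. A shared-12-mer prescreen limits the
targets aligned; a read placeable within 4 edits always shares a 12-mer with
its target, so the prescreen loses nothing at the default contract.

Read-pair evidence is geometrically blind beyond `insert − 2·read_len`
(400 bp at the defaults): only fragments whose mates fall cleanly on the two
sides of the TE–gene junction can report it. The validation fixture plants
its adjacent insertions at 1–250 bp so each junction is coverable, and
scores sensitivity over junction-detectable insertions only.

## Enrichment

One-sided hypergeometric test per term (`P(X ≥ k)` for k query hits of a
K-gene term in an n-gene query from an N-gene universe), BH step-up
q-values across tested terms, terms under 5 background genes skipped. The
background is the annotation's gene universe, not the genome. The term table
is flat — no ontology propagation.

## The simulator and what passing tests show

Each species genome is one chromosome of uniform random background with
non-overlapping random genes (uniform strands) and full-length TE copies
planted family by family. A copy of age t (drawn from a Normal clipped at 0)
substitutes each site independently with probability min(r·t, 0.75), the two
LTRs independently — so read-vs-consensus divergence is r·t and LTR–LTR
divergence ~2·r·t by construction, with each site hit at most once
(divergence arithmetic is exactly invertible, hence no Jukes–Cantor
correction on either side). A configurable fraction of copies is placed
strand-aware 1–5 kb upstream of a random gene. Reads have uniform starts,
constant Q40 qualities, per-base substitution errors, and truth-decodable
names; paired mode emits proper /1,/2 mates at a fixed insert size. Every
placement is recorded in a truth ledger whose interval lengths sum exactly
to the realized Mb.

TE copies keep ≥ 60 bp of background between each other (`te_margin`):
unrelated copies closer than read_len·(1 − 0.55) = 45 bp would let
junction-spanning reads chain their clusters — the nested-insertion
situation that needs community detection, which this package deliberately
does not model. Genes may still abut TEs (gene sequences are unique, so no
chaining), keeping 1 bp upstream insertions representable.

Not modelled: indels (knob exists, default 0), solo-LTR formation,
truncated or nested copies, GC/chromatin biases, quality decay, CpG-context
rate variation, segmental duplications. Passing the acceptance suite
therefore shows that the algorithms recover what they claim under a
substitution-only, uniformly-sampled world at 0.2–0.5× coverage; it does not
certify performance on real reads with indels, satellites, or nested TE
landscapes.

## Validation conditions and problem sizes

* **Demo design** (pipeline, sharing, abundance, determinism): three
  species, 0.5/0.6/0.5 Mb genomes, 35 genes each, six families (~1.2 kb
  elements, 0.06–0.075 Mb targets, ages 0.8–2 My): one family in all three
  species, two shared pairwise, one private each. Single-end 0.5× reads at
  error rate 0.002; pooled comparative sample 1200 reads/species; species
  spB additionally gets 2× paired reads (insert 600) for the reference-free
  route.
* **Clock fixture**: one 0.72 Mb species, four families at 0.5/1/2/5 My with
  long (400–450 nt) LTRs, the youngest the most abundant (0.18 Mb down to
  0.09 Mb) — at 0.5 My the whole signal is under one mismatch per read, so
  dating precision is bought with LTR columns and copy numbers.
* **Proximity fixture**: 0.4 Mb species, 30 genes, two young families, half
  the copies planted 1–250 bp upstream of genes; 2× paired coverage.
* **Enrichment calibration**: exhaustive enumeration for N ≤ 12; a
  1000-replicate random-query null over 40 terms × 1000 genes.

These sizes keep the full suite within desk-scale runtimes while leaving
each recovery check a comfortable noise margin (the limiting one is the
0.5 My family, whose expected dating noise is ~7% of its age against a ±20%
tolerance).

## Known limitations

* Ages below ~0.3 My are at the resolution floor once sequencing error and
  consensus residuals are subtracted; ages above ~7 My lose reads to the
  90% clustering threshold and increasingly underestimate.
* Bursts separated by less than ~5 identity points appear as one peak.
* Occupancy inherits the read-proportion estimator's assumptions: uniform
  sampling and correct genome size; biased libraries bias Mb estimates
  proportionally.
* The read-pair proximity route cannot see junctions beyond the insert
  length, reports no distances, and is orientation-blind (upstream vs
  downstream adjacency are indistinguishable without a reference).
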