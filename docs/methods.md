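# Methods

## The analysis model

Each metagenomic sample is treated as a *pool* of symbiont strains: reads
mapped to a pangenome reference (one sequence per gene cluster) provide,
at every position, counts of the four nucleotides, and those counts are
the raw material for everything downstream. The package never genotypes
individuals; every statistic is defined on read counts.

**Fixation index.** Differentiation between two populations (a population
being one sample, or several samples pooled by vent field or lifestyle) is
Hudson's F_ST with the finite-sample correction. With alt-allele
frequencies `p1, p2` from `n1, n2` allele draws at a site,
`num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)` and
`den = p1(1-p2) + p2(1-p1)`; the genome-wide value is the ratio of the
summed numerators to the summed denominators (ratio of averages), which is
robust to rare alleles and unequal sample sizes. Sites with `n < 2` in
either population or `den = 0` are excluded. Two conventions deserve
emphasis:

- `n` is the *read depth*: each read is treated as an independent allele
  draw from the pool, the standard pooled-sequencing convention when
  strain ploidy/copy number is unknown.
- Pooling sums ref/alt counts across member samples (depth-weighted).
  An equal-weight alternative would down-weight deep samples; depth
  weighting follows directly from the reads-as-draws model.
- Negative genome-wide values (expected for self-comparisons and
  undifferentiated pairs) are reported unclamped, with a clamped copy for
  display, so that averaging over pairs stays unbiased.

**Ordination.** Bray–Curtis dissimilarities are computed between sample
vectors built by concatenating, over variant sites, the per-site nucleotide
*proportions* (counts divided by site depth). Proportions rather than raw
counts remove between-sample depth artifacts; a raw-count mode is kept
behind a flag. PCoA is classical metric MDS: Gower-center the squared
distances, eigendecompose, scale eigenvectors by the square root of the
positive eigenvalues. No Cailliez/Lingoes correction is applied; negative
eigenvalues are reported, contribute no coordinates, and enter the
proportion-explained denominator by absolute value, so the reported
fractions are transparently conservative. Jaccard distances on presence
sets use the convention that two empty sets are at distance 0.

**Differentiation bands.** Genome-wide values are labelled weak (< 0.2),
moderate (0.2–0.5, inclusive) or strong (> 0.5).

**Variant filtering.** A candidate site enters the variant table iff
(a) depth ≥ `min_site_depth` (default 10, mirroring the sample-level 10×
threshold) in *every* retained sample — complete-case, so all pairwise
comparisons share one site set; (b) exactly two alleles reach
`min_allele_count` (4) pooled, and any other allele stays at or below
`noise_allele_max` (2); (c) pooled minor-allele frequency ≥ `min_maf`
(0.02). The reference allele is the pooled majority, ties broken
alphabetically. These defaults are conservative strain-variant settings
for 10–20× metagenome depth; all are configurable. Samples below the mean
depth threshold are excluded from the primary run and re-analysed on the
site set covered in them (`variants_lowcov.tsv`).

**Read mapping.** The internal mapper is deliberately simple: ungapped
seed-and-extend with exact 21-mer seeds tiled every 21 bp along the read
(plus the final k-mer), candidates scored by full-read Hamming distance
against either strand, best hit kept if within `max_mismatch_frac`
(default 5%), reads with co-best hits on different genes discarded as
ambiguous (the paralog-safe choice), ties within a gene resolved to the
forward strand and lowest coordinate. 21-mers are specific at pangenome
scale and one error can spoil at most two seed windows, so a read with
`e` errors is guaranteed a clean seed whenever `2e` is less than the
window count. Internal coordinates are 0-based half-open on the gene's
forward strand; SAM input/output converts to/from the 1-based convention,
and externally produced SAM (including paired-end data, read as single
records) can replace the internal mapper entirely.

**Marker-ratio test.** Reads are assigned to symbiont-16S / host-CO1
targets in the presence of two mandatory background decoy databases.
Assignment is a canonical-k-mer (k = 31) vote with an explicit
"unambiguous" rule: a read goes to category c iff at least half its
k-mers hit c and c has at least twice the hits of every other category.
Percentages are computed against *all* reads in the sample, and the
16S:CO1 ratio is also computable directly from printed percentages. A
sample is flagged as carrying a free-living symbiont signal when its ratio
is at least `fold_threshold` (default 10, a conservative lower bound for
"orders of magnitude") times the median host-associated ratio.

## The synthetic generator

The generator emulates the study design the analysis was built for: two to
four demes of strains over a shared pangenome, samples labelled by
(vent field × lifestyle), and marker read sets for gill and fluid samples.

- **Island model.** Ancestral frequencies are Uniform(0.05, 0.95) —
  avoiding near-fixed sites that inflate estimator variance — and deme
  frequencies are Balding–Nichols Beta draws with mean p and variance
  F·p(1−p), so the expected Hudson F_ST between demes *is* the parameter
  F. F = 0 returns the ancestral frequencies exactly.
- **Strains and samples.** Each deme carries a pool of strain haplotypes,
  alleles Bernoulli(deme frequency) per site. A sample is a mixture over
  its deme's pool; by default every sample mixes all strains uniformly,
  and the `lifestyle_drift` / `sample_drift` knobs perturb mixtures with
  Dirichlet draws of concentration K(1−d)/d (the simplex analogue of the
  island model) to create mild, controlled within-deme structure.
- **Reads.** 150 bp single-end, strain chosen per mixture weight, gene
  proportional to length among genes the strain carries, start uniform,
  orientation random, substitution errors i.i.d.; host reads come from a
  single random 50-kb host sequence at the sample's `host_read_fraction`.
  Variant sites are restricted to core genes (keeping F_ST and gene
  content orthogonal truth axes) and placed at least one read length from
  gene ends, because uniform read starts taper coverage near the
  boundaries of a finite gene model — an artifact of per-gene read
  sampling that whole-genome shotgun data does not have.
- **Markers.** Target 16S-like (~1.5 kb) and CO1-like (~0.65 kb)
  sequences, decoys diverged from them by 8% (a divergence of 0 is
  refused: decoys identical to targets make "unambiguous" meaningless),
  plus unrelated noise reads. The gill scenario plants a 16S:CO1 read
  ratio of 2.5, the fluid scenario 80 — the same order-of-magnitude
  contrast seen between gill-tissue and vent-fluid samples.

**What the generator does not emulate:** indels and structural variation,
quality-score error profiles, GC/coverage bias, paired-end inserts,
between-gene copy-number variation, chimeras, and real database taxonomy.
Passing tests therefore demonstrate that the estimators and filters do
what they claim on data matching their assumptions — not that those
assumptions hold in any particular real dataset.

## Chosen parameters and problem sizes

| parameter | default | why |
|---|---|---|
| strains per deme (K) | 40 | The sample allele frequency carries strain-pool sampling variance p(1−p)(1−F)/K that depth-based correction cannot remove, biasing F_ST recovery by ≈ (1−F)/K. K = 40 keeps that term ≤ 0.025, second order against the ±0.05 recovery band, and is the more realistic strain richness for an environmental pool; recovery is additionally property-tested at K = 20, where the bias is still inside the band at moderate/strong F. |
| core genes × length | 80 × ~1 kb | With 2000 variant sites this gives ~2.5% per-base variant density, keeping per-read mismatch load (~2.6 expected at 0.5% error) safely under the 5% mapper ceiling. Denser placement would bias mapping against alt-heavy reads. |
| mean depth | 20× | Twice the QC threshold — the regime the default filters target. |
| error rate | 0.005 | Typical short-read substitution scale; at pooled depths near 100 it keeps error pile-ups below the 4-read allele floor. |
| host read fraction | 0.05 (gill), 0.005 (fluid) | Order-of-magnitude contrast between tissue and fluid samples. |
| k_map / k_marker | 21 / 31 | Specific at pangenome / marker-database scale; 21 tolerates one error per read end. |
| θ_present / θ_absent | 0.25 / 0.05 | Presence calls on median-normalized depth; the band between them is "uncertain", treated as absent in Jaccard but disqualifying for group-unique genes, so borderline coverage cannot fabricate the module's most biology-facing output. |

Simulation-based checks use 2 demes, 3 samples per deme at 20×, 2000 core
variant sites and 10 seeds for F_ST recovery; 2 fields × 2 lifestyles ×
2 samples, 1000 sites and 10 seeds for the geography-vs-lifestyle
contrast; and 2 demes × 2 samples under panmixia (F = 0) for variant-site
recall — panmixia because under strong drift a planted site can become
genuinely monomorphic in the realized strain pools, which would measure
the simulator rather than the caller. These sizes are the package's
standard desk-scale study; the pipeline itself has no scale assumptions
beyond memory.

## Numerical and design notes

- All randomness flows from one integer seed through named SeedSequence
  substreams (per stage and per sample); identical configuration + seed
  reproduces identical FASTA/FASTQ bytes, truth sets and TSV checksums.
  The run report records SHA-256 checksums of every tabular output.
- Allele-count arithmetic is float64; the Hudson accumulation is a plain
  sum (no compensated summation) — at desk scale the relative error is
  far below the 1e-12 oracle-agreement tolerance used in tests.
- The variant caller's alphabetical reference tie-break makes tables
  reproducible across runs and platforms.
- Zero-depth sites are "missing" (NaN frequencies) rather than zero;
  Bray–Curtis input vectors drop nothing, but an all-zero sample vector is
  an error naming the sample.
- `sample_qc` raising on an empty retained set (rather than returning an
  empty partition) is deliberate: every downstream stage would fail less
  legibly.
- PCoA eigendecomposition symmetrizes B before `eigh` and treats
  eigenvalues within `1e-12·max|λ|` of zero as zero.

## Known limitations

- The mapper is ungapped: indels near a read's alignment shift mismatch
  counts and can discard the read; real data with indel variation should
  be mapped externally and supplied as SAM.
- Complete-case site filtering discards sites missing depth in any single
  retained sample; with many samples this is aggressive, and a
  per-pair mode is a plausible extension (the single shared site set was
  chosen so every pairwise F_ST is computed on identical sites).
- The marker classifier's margin rule is a deterministic stand-in for
  aligner-based read separation; it has no model of sequencing error in
  k-mer space beyond the hit-fraction threshold, so highly diverged reads
  degrade to "unassigned" rather than being rescued.
- Group-unique gene counts depend directly on the presence thresholds;
  absolute counts are therefore not comparable across threshold settings,
  only within a run.
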