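# Methods

`convergeomics` implements a cross-species convergent transcriptomics and
promoter methylomics analysis for a design with two focal species that share a
derived phenotype (the motivating case: the two bamboo-eating panda species)
contrasted against a panel of related species without it (non-herbivore
carnivores/omnivores), in one or more tissues.  This note documents the models,
the numerical choices, and what the bundled synthetic data do and do not
establish.

## Expression normalization (GeTMM)

Cross-species counts over 1:1 orthologs differ both in gene length and in
sequencing depth/composition.  Normalization combines a within-sample
gene-length correction with between-sample trimmed-mean-of-M-values (TMM)
scaling computed on the length-corrected table:

1. **RPK**: `rpk[g,s] = count[g,s] / (length_g / 1000)`.
2. **TMM on RPK**: the reference sample is the one whose upper-quartile /
   library-size ratio is closest to the mean such ratio.  For sample *s*
   against reference *r*, over genes positive in both,
   `M_g = log2((x_g/N_s)/(r_g/N_r))` and `A_g = ½·log2((x_g/N_s)·(r_g/N_r))`;
   the lowest and highest `⌊n·0.30⌋` genes by M-rank and `⌊n·0.05⌋` by A-rank
   are discarded (ordinal ranks; the published double-trim defaults), and
   `f_s = 2^(Σ w_g M_g / Σ w_g)` with delta-method precision weights
   `1/w_g = (N_s−x_g)/(N_s x_g) + (N_r−r_g)/(N_r r_g)`.  If fewer than 10
   genes survive the trim, the untrimmed weighted mean is used (logged).
   Factors are rescaled to geometric mean 1.
3. **GeTMM**: `value[g,s] = rpk[g,s]·1e6 / (Σ_g rpk[g,s] · f_s)`, i.e.
   per-million length-corrected expression on a between-sample-comparable
   scale.  Column sums satisfy `Σ_g value[g,s] = 1e6/f_s` exactly.

A subtlety worth stating: M, A, the trims and the reference choice are all
invariant to rescaling one sample's depth, but the precision weights are not,
so scaling a sample's counts reproduces its normalized column only to ~1%
rather than to machine precision.  The package asserts this invariance at
relative tolerance 1e-2.

**Filters.** The low-expression filter keeps genes with count > 0 in every
sample of every species (an `any_species` mode relaxes this to "fully
expressed in at least one species").  The exploratory log2(x+1) table is
variance-filtered by dropping the lowest-variance half of genes (the 0.5 is a
quantile, configurable); this filtered table feeds PCA (gene-centred SVD,
components signed so the largest-magnitude loading is positive) and
Spearman-correlation clustering (distance 1−ρ, complete linkage).  The
variance filter is *not* applied to the differential-expression universe.

## Differential expression

Per contrast (one focal vs one outgroup species, one tissue) the test is the
conditional negative-binomial exact test with a common dispersion — the
classic exact-test family for small replicated count designs — rather than a
re-implementation of a full DE framework (qCML, tagwise shrinkage and GLMs are
out of scope; recovery of planted truth, not bit-equality with any package, is
the target):

* **Dispersion**: variance is modelled as `μ + φμ²`.  Counts are scaled to the
  geometric-mean effective library (library size × TMM factor), residual
  variance is pooled within groups, and the common φ is the median of
  per-gene `max(0, (s²−μ̄)/μ̄²)` over genes with mean > 5 (fallback φ = 0.1
  with a warning if no gene qualifies).  The method-of-moments median is
  mildly biased low at 3-4 replicates (the median of a χ² is below its mean);
  the exact test's discreteness keeps the null calibrated regardless, which
  the null-simulation tests verify directly.
* **Exact test**: counts are scaled to the common effective library, rounded
  to pseudo-counts and summed within groups.  Under the null of equal means,
  `S_A ~ NB(n_A m, φ/n_A)` and `S_B ~ NB(n_B m, φ/n_B)` share the NB success
  probability `1/(1+φm)`, so the conditional law of `S_A` given
  `S_A+S_B = t` is free of the unknown mean — a negative hypergeometric in
  `r_A = n_A/φ`, `r_B = n_B/φ` (binomial in the φ=0 Poisson limit).  The
  p-value sums the conditional probabilities of all outcomes no more probable
  than the observed one (relative tie tolerance 1e-10); t = 0 gives p = 1.
* **Calling**: fold changes are `log2((mean_focal+1)/(mean_outgroup+1))` on
  the GeTMM scale (prior 1 stabilizes low expression; positive = higher in
  the focal species).  p-values are BH-adjusted within each contrast; a DEG
  requires padj < 0.05 and |log2FC| > 1.
* **Convergence**: per focal species a gene must be a DEG in the same
  direction against *every* outgroup; the convergent up/down sets are the
  intersections across the two focal species.  Direction conflicts drop a
  gene from the affected set rather than raising.

## Methylation quantification

Cytosines are classified CG/CHG/CHH (H = A, T or C) by reading the
trinucleotide 5'→3' along the site's strand; minus-strand contexts read the
reverse complement.  Sites within 2 bp of a chromosome end with an incomplete
context fall back to CHH (logged).  Non-ACGT bases count as H.

All region levels pool reads, never site levels: `level = Σ mC / Σ (mC+uC)`
over member sites.  This makes levels exactly decomposable: for any partition
of sites, the overall level is the coverage-weighted mean of the part levels.
Quantities provided per sample: per-context 10 kb bin levels (empty bins
omitted), coverage strata (sites at ≥1 and ≥5 reads, and the fraction of
≥5-covered sites above level 0.5), pooled CG levels per gene element
(promoter = 1 kb strand-aware upstream of the TSS, gene, exon, intron;
intervals union-merged so shared sites count once), and a 60-bin metagene
profile (20 × 100 bp upstream bins, 20 equal fractions of the gene body, 20
downstream bins, minus-strand genes mirrored).  The metagene averages
per-gene bin levels with equal gene weights so long genes do not dominate;
element levels instead pool reads across all genes (both choices are the
common conventions for their respective plots, and both are configurable).
Overlapping genes are not disambiguated: a site inside two genes contributes
to both gene-wise quantities.

## Promoter differential methylation

Promoter levels per gene × sample pool reads over promoter CG sites
(coverage ≥ 1); the matrix is variance-filtered like the expression table
(drop the lowest-variance half) before testing.

The test is the one-tailed Wilcoxon rank-sum, run in both directions per gene
for each focal species vs the outgroup.  The observation unit is the
per-(CpG site, sample) level at coverage ≥ 5.  The reason is statistical
necessity: with 3-4 biological replicates per species a per-sample rank-sum
has a minimum one-sided p of 1/35 (4 vs 3), which can never survive BH
correction across thousands of genes — promoter-scale inference requires
site-level observations.  A `unit="sample"` mode exists for designs with many
replicates.  Exact enumeration is used for tie-free pooled samples of size
≤ 12, otherwise the tie-corrected normal approximation with continuity
correction.  BH runs across genes within each direction family; hypo (focal
below outgroup) requires less-direction padj < 0.05, hyper the converse; a
gene significant in both directions (pathological ties) is left unlabeled.
Convergent promoters are those called in the same direction in both focal
species against the outgroup.

## Integration and over-representation

Promoter methylation generally represses transcription, so the signature of
interest is the inverse pair: convergent-up expression with a convergent-hypo
promoter, or down with hyper.  `integrate` joins the two convergent sets and
flags `inverse_consistent = (up ∧ hypo) ∨ (down ∧ hyper)`; the genome-wide
inverse-consistency count is an artifact-level summary that the upstream
analysis itself does not define, and is labelled as such in the output.
`ora` is a hypergeometric upper-tail over-representation test of a query list
against user-supplied GMT sets, BH-corrected across sets, with the background
defaulting to the focal species' expressed (post-filter) genes; no term
databases are bundled.

## Synthetic data generator

The generator is first-class, tested code and defines the study conditions:

* **Design**: two focal species + outgroup panel (defaults: giant_panda,
  red_panda vs ferret, dog, mouse), 4 replicates per focal and 3 per outgroup
  species, one tissue per run; multiple tissues run independently with child
  seeds.  All randomness flows from a single seed through named substreams,
  so outputs are byte-reproducible.
* **Expression**: per-gene relative abundances are log-normal (σ = 1) scaled
  by gene length; counts are NB with mean `rel_g · libsize_s` (libraries
  uniform in 0.8-1.2 M) and one common dispersion φ = 0.1 (`μ + φμ²`), which
  matches the test's assumption.  Planted convergent genes multiply the mean
  by `2^(±2)` in both focal species.
* **Genome**: each gene sits in its own slot with ≥ 2 kb flanks; background
  sequence is CpG-suppressed (mammalian CpG depletion), with CG dinucleotides
  planted at CpG-island-like density in promoters (20 per kb promoter by
  default), moderate density in gene bodies and sparse density in flanks;
  strands random, ≥ 2 exons per transcript.
* **Methylome**: each CG site's regional mean is the gene-body baseline
  (0.8) genome-wide, with a linear promoter trough tapering to 0.1 at the TSS
  (reproducing the canonical metagene dip at the transcription start).
  Planted "hypo" genes raise the *outgroup* promoter mean by δ = 0.3 (so
  focal = outgroup − δ without colliding with the low promoter baseline);
  "hyper" genes raise the focal mean.  Means are clipped to [0.01, 0.99]
  (logged).  Per (site, sample) the realized level is Beta(mean, concentration
  50), coverage is Poisson(10) truncated at ≥ 1, and mC is binomial.  Non-CG
  cytosines sit at mean 0.01; `cg_only_reports=True` emits CG-only reports
  for large runs where CHG/CHH sites (near zero methylation) would dominate
  runtime and memory without informing the promoter analysis.
* **Planted overlap**: hypo promoters are assigned to convergent-up genes
  first and hyper to convergent-down first, so inverse-consistent pairs exist
  by construction and the integration stage can be scored end to end.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: per-site methylation noise is independent across
samples (no persistent per-site or per-individual random effects, which in
real data would inflate site-level Wilcoxon false positives and argue for
more conservative units); there is no read-level error, bisulfite conversion
failure, mapping bias, or M-bias; gene-length and composition biases are
simpler than real cross-species ortholog tables; no tissue-shared individual
structure; no gene-gene correlation; compact genes and genomes.  Sensitivity
and FDR figures on synthetic data are therefore best-case calibrations of the
pipeline's logic, not field performance estimates.

## Problem sizes and defaults

The default `SimulationConfig` (2000 genes, 100 + 100 planted DEGs at
|log2FC| = 2, φ = 0.1, 100 + 100 planted promoters at δ = 0.3 with ~20 CpGs
per promoter at ~10× depth, 3-4 replicates) is the scale at which the
recovery properties are asserted: convergent DEG sensitivity ≥ 90% at
FDR ≤ 10%, convergent promoter sensitivity ≥ 80% at FDR ≤ 10%, and
end-to-end inverse-pair sensitivity ≥ 70%.  The bundled `demo.yaml` runs a
compact two-tissue study (800 genes, 80-gene planted sets) in about half a
minute.  `scripts/acceptance.py` re-runs these analyses from scratch and
writes the measured quantities as JSON.

## Degenerate inputs and tie-breaks

Zero-coverage cytosine records are dropped at parse time; zero-total exact
tests and all-identical Wilcooxon inputs return p = 1; empty bins and
uncovered elements are omitted (NaN) rather than reported as 0; variance-
filter ties at the cutoff are retained; TMM falls back to the untrimmed
weighted mean below 10 surviving genes; promoters truncate at chromosome
boundaries; genes shorter than the metagene bin count are excluded (logged).
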