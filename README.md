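# convergeomics

Cross-species **convergent transcriptomics + promoter methylomics** in Python:
a tested pipeline for asking whether two species that independently evolved
the same phenotype (the motivating case: the two bamboo-eating panda species
within Carnivora) show *convergent* gene-expression and promoter-methylation
shifts relative to a panel of species without that phenotype — and whether
those shifts are inversely related, as promoter methylation's repressive role
predicts.

It is aimed at comparative genomicists with a 1:1-ortholog read-count table
(plus gene lengths and a sample→species map) and per-cytosine bisulfite count
reports, and it ships a first-class synthetic-data generator with planted
ground truth so every stage can be exercised and scored without any download.

## What it computes

* **GeTMM normalization** — reads-per-kilobase gene-length correction
  combined with trimmed-mean-of-M-values (TMM) scaling computed from the
  published definition: `f_s = 2^(Σ w_g M_g / Σ w_g)` over doubly-trimmed
  genes (30% by M = log2 expression ratio vs a reference, 5% by A = mean
  abundance) with precision weights; normalized values are
  `RPK · 1e6 / (library · f_s)`.
* **Convergent DEGs** — per focal-vs-outgroup contrast, the conditional
  negative-binomial exact test with a common method-of-moments dispersion
  (variance `μ + φμ²`); BH correction per contrast; DEG ⇔ padj < 0.05 and
  |log2FC| > 1; a convergent DEG is one called in the same direction against
  *every* outgroup in *both* focal species.
* **Methylation quantification** — CG/CHG/CHH context classification, and
  read-pooled levels `Σ mC / Σ(mC+uC)` per site, 10 kb bin, gene element
  (promoter = 1 kb upstream of the TSS, gene, exon, intron) and 60-bin
  metagene profile (2 kb flanks + length-normalized body).
* **Convergent promoters** — promoter methylation matrix, variance filter,
  one-tailed Wilcoxon rank-sum per gene over per-(CpG site, sample) levels at
  ≥5× coverage, BH per direction; hypo = lower in the focal species;
  convergent = same direction in both focal species vs the outgroup.
* **Integration** — joins the two convergent sets and flags
  inverse-consistent genes ((up ∧ hypo) ∨ (down ∧ hyper)), plus a generic
  hypergeometric over-representation test against user GMT gene sets.

See `docs/methods.md` for the full model and the numerical choices.

## Worked example

The bundled demo simulates a compact two-tissue study (800 orthologs, 2 focal
+ 3 outgroup species, 80 convergent-up and 80 convergent-down genes planted at
|log2FC| = 2, 80 hypo- and 80 hyper-methylated promoters planted at δ = 0.3,
placed so that inverse pairs exist) and runs the whole analysis:

```sh
convergeomics run --config src/convergeomics/data/demo.yaml --out demo_out
```

prints

```
[stomach] convergent DEGs: 79 up / 80 down; promoters: 80 hypo / 80 hyper; inverse-consistent sensitivity: 0.99
[small_intestine] convergent DEGs: 80 up / 77 down; promoters: 80 hypo / 80 hyper; inverse-consistent sensitivity: 0.98
```

Reading: of the 80+80 planted convergent DEGs per tissue the intersection
logic recovered 159 and 157 with no false convergent calls; all 160 planted
convergent promoters were recovered; and ≥ 98% of the genes planted as both
convergent-up∧hypo or down∧hyper came out as inverse-consistent integration
records.  `demo_out/<tissue>/` holds every intermediate table (GeTMM values,
TMM factors, PCA scores, Spearman/Newick clustering, per-contrast DE tables,
promoter methylation matrix, per-comparison Wilcoxon tables, convergent sets,
`integration.tsv`, `metrics.json`) and `demo_out/run_manifest.json` records
versions, seeds and parameters.

The same stages are available as `convergeomics simulate / normalize / de /
meth / dmp / integrate / ora / validate`, and programmatically:

```python
from convergeomics import de, normalize
from convergeomics.simulate import SimulationConfig, simulate_expression

matrix, truth = simulate_expression(SimulationConfig(seed=1))
norm = normalize.getmm(normalize.filter_low_expression(matrix))
result = de.call_contrast(norm, matrix, "giant_panda", "ferret", tissue="stomach")
```

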