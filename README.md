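# riboresidence

Codon-resolved measurement of relative ribosome dwell times from ribosome
profiling data.

## The problem and the statistic

Ribosome profiling captures ~30-nt mRNA fragments ("footprints") protected by
translating ribosomes. If a codon is decoded slowly, ribosomes dwell on it and
footprints covering it are over-represented — in principle a direct in vivo
readout of per-codon elongation rates. In practice, footprint coverage along
any one mRNA is dominated by expression level and large codon-independent
peaks and valleys, so naive genome-wide averaging is swamped by a handful of
highly expressed genes.

The **Ribosome Residence Time (RRT)** statistic sidesteps normalization by
analyzing many small, independent windows. For a target codon (say CTC), take
every CDS position where it occurs *uniquely* within ±10 codons (a 19-codon
window). A 10-codon footprint containing that CTC belongs to exactly one of
k = 10 position classes: class *j* holds footprints whose *j*-th codon is the
CTC. Each qualifying window (≥ 20 footprints, ≥ 3 non-empty classes) yields a
relative frequency vector *f₁…f_k*, *f_j = n_j / Σn*, which is independent of
expression level. Averaging over hundreds of windows and dividing by the
uniform baseline 1/k gives

    RRT(c, j) = mean_w f_w(j) / (1/k)

RRT = 1 means average dwell; RRT = 2 means the ribosome spends twice the
average time with codon *c* at footprint position *j*. Position 6 is the
A-site (decoding), position 5 the P-site (peptide-bond formation).
Significance is assessed by permuting each window's count vector (10,000
replicates by default) and ranking the observed mean two-tailed.

Around the core statistic the package provides:

- **genome/footprint ingestion** — FASTA + GFF3 → codon-resolved coding
  regions (genes overlapping other genes, rRNAs, or tRNAs are excluded for
  mapping confidence); SAM/BAM reads filtered (≤ 2 mismatches, quality ≥ 10,
  ≥ 30 nt) and reduced to their first fully covered in-frame codon,
- **coherence testing** — do an amino acid's synonymous codons have similar
  RRT vectors (amino-acid-specific) or not (codon-specific)?
- **a dwell-model simulator** — seeded synthetic genomes and footprints with
  per-(codon, position) dwell multipliers, including the closed-form check
  RRT = k·m/(m+k−1) for a single planted multiplier m, and the random
  codon-assignment negative control,
- **ribosome-demand estimation** — relative translation time of recoded
  transcriptomes (fastest/slowest/random synonyms, abundance-weighted),
- a bundled per-codon reference table (usage per 1000 and A-site RRT for all
  61 sense codons from a published S. cerevisiae experiment).

## Worked example

```python
from riboresidence import (DwellModel, PermutationConfig, SimConfig,
                           WindowConfig, compute_rrt, simulate_footprints,
                           simulate_genome)

genome = simulate_genome(SimConfig(n_genes=60, gene_length_codons=300, seed=1))
dwell = DwellModel.uniform().with_multiplier("AAA", 6, 3.0)
footprints = simulate_footprints(genome.index, dwell, n_reads=150_000, seed=2)
profile, _ = compute_rrt(genome.index, footprints, WindowConfig(),
                         PermutationConfig(n_perm=2000, seed=3))
print(profile.rrt.loc["AAA", 6], profile.pvalues.loc["AAA", 6])
```

prints (seeds as above):

```
2.540  0.0009995
```

i.e. the planted 3× dwell multiplier on AAA in the A-site is recovered as
RRT ≈ 2.54 (closed form 2.5 — an m-fold slowdown at one position concentrates
m/(m+k−1) of the window's reads there), and no permutation replicate reached
the observed mean. The `examples/` directory has one short script per
capability (signal recovery, reference-table analyses, the shuffle negative
control, coherence contrast, demand estimation); each prints the numbers it
computes with a line on what they mean.

A thin CLI mirrors the library for shell pipelines:

```
riboresidence simulate --n-genes 60 --n-reads 150000 --seed 1 --outdir sim
riboresidence rrt --genome sim/genome.fa --annotation sim/annotation.gff3 \
    --alignments sim/footprints.sam --outdir out
riboresidence coherence --profile out/rrt.tsv --outdir coh
```

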