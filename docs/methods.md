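# Methods

## The residence-time model

A footprint of k consecutive codons is treated as a draw from the set of
placements that contain a given target codon. For a CDS position p where the
target codon occurs uniquely within ±h codons (h = 10 by default, a 19-codon
window), the k placements starting at p−k+1 … p are the k *position classes*;
class j means the target is the j-th codon of the footprint. Under no codon
preference the class counts n₁…n_k are exchangeable, so the relative
frequencies f_j = n_j/Σn have expectation 1/k. The RRT is the window-averaged
relative frequency rescaled by that baseline:

    RRT(c, j) = A_w[f_w(j)] · k,     A = mean (default) or median.

Each window is one independent trial regardless of expression level — this is
the entire normalization strategy; no gene-expression correction is applied,
deliberately. With the mean aggregator Σ_j RRT(c,j) = k identically (the
engine asserts this to machine precision in tests). Codons with no qualifying
window are reported as missing (NA), never imputed.

Interpretation caveat carried by the model: positions 1 and k of real
libraries carry end-chemistry biases unrelated to translation, so A-site
(position 6) and P-site (position 5) values are the meaningful ones.

## Qualification and filtering defaults

| parameter | default | meaning |
|---|---|---|
| k | 10 codons | footprint length (7 for short-footprint data, 8 for the legacy ≥24-nt mode) |
| half_width | 10 codons | uniqueness/containment span; must be ≥ k−1 so all classes fit |
| min_reads | 20 | per-window total footprints |
| min_nonempty_classes | 3 | per-window occupied classes |
| max_mismatches | 2 | per-read NM threshold |
| min_quality | 10 | mapping quality (the ambiguous "quality" is read as MAPQ; configurable) |
| min_length_nt | 30 | aligned length, soft clips excluded |
| n_perm | 10,000 | permutation replicates |
| n_samples | 10,000 | coherence null samples |

Windows must lie entirely inside the sense codons of the CDS: the terminal
stop is never a window member, and windows near either CDS end are dropped
rather than padded. Reads are anchored at the first codon all three of whose
nucleotides are covered (a read starting mid-codon skips the partial codon);
reads whose anchor leaves fewer than k codons in the CDS are dropped.
Eligibility excludes any gene whose CDS parts overlap another gene, rRNA, or
tRNA on either strand — the motive is mapping uniqueness, so the test is
strand-insensitive by default and part-based rather than span-based (a gene
sitting wholly inside another gene's intron shares no exonic bases; a
`span` mode is available for the stricter reading). The Pro-Pro dipeptide
filter scans the window's 19-codon translation and can exclude (or retain
only) windows containing a Pro-Pro pair.

## Permutation test

For each codon the observed statistic at position j is the across-window mean
frequency. Each replicate permutes every window's count vector independently
and uniformly and re-averages. Sampled p-values use

    p = min(1, 2·min(r⁺+1, r⁻+1)/(n_perm+1)),

with r⁺/r⁻ the inclusive counts of replicates ≥/≤ the observed value; the
pseudocount avoids p = 0 and the inclusive ties are conservative. The
`exhaustive-oracle` mode computes the exact per-position null instead: at any
single position, a uniform permutation places each of a window's k entries
there with probability 1/k, independently across windows, so the exact null
is the k^W-point convolution of the windows' entry sets (feasible for a few
small windows; used to validate the sampled mode). Per-codon RNG streams are
derived from (seed, codon index), so results do not depend on execution
order and are reproducible codon by codon.

On uniform-dwell simulations the sampled p-values are uniform (KS-tested in
the acceptance suite); the +1 pseudocount and the two-tailed cap leave a
discreteness of order 1/n_perm that is negligible at the tested sizes.

## Coherence test

A codon's RRT vector across the k positions is a point in ℝᵏ. For an amino
acid with c ∈ [2,6] codons (Met and Trp are skipped), the observed statistic
is the mean pairwise Euclidean distance d among its c points (metric
configurable). The null draws c-subsets uniformly without replacement from
the profile's available sense codons — all 61, inclusive of the amino acid's
own codons — and p = (#{d_sample ≤ d_obs}+1)/(n_samples+1); small p means
the synonyms cohere. One structural property matters for interpretation: the
null universe retains the genetic code's family structure, so when *all*
families are internally coherent, a 2-codon amino acid competes against the
~5.8% of random pairs that are themselves synonymous and equally tight; its
attainable p is therefore bounded near 0.06·U rather than 1/(n+1). For c ≥ 3
the all-synonymous fraction falls below 0.3% and p reaches the floor. The
property tests assert exactly this calibrated contrast.

## Simulator

Synthetic genes are ATG + (L−1) sense codons drawn iid (uniform over the 61,
or weighted by the bundled usage table) + TAA, packed without overlap on one
chromosome with random spacers, alternating strands to exercise strand
handling. A footprint placement starting at codon s has sampling weight
Π_{j=1..k} m(codon_{s+j−1}, j) under the dwell model m (stop codons weigh 1);
reads are drawn iid from the normalized weights and can be emitted as
perfectly matching 3k-nt SAM records (MAPQ 42, NM 0) that pass ingestion by
construction. This product-of-multipliers mechanism is chosen because it
reduces to single-position biasing when only one position differs from 1 and
admits the closed form: a multiplier m on one codon at one position gives
expected within-window frequency m/(m+k−1), hence RRT = k·m/(m+k−1)
(m = 3, k = 10 → 2.5). Chi-square goodness-of-fit of sampled placements
against the stated weights is part of the test suite.

What the simulator does *not* model: sequencing errors, nuclease/ligation
end biases (the position-1/10 artifacts of real libraries), uneven gene
expression, multi-exon genes, or multi-mapping reads. Passing tests on
simulated data therefore validate the statistic's bookkeeping, calibration,
and parameter recovery — not robustness to library chemistry.

The negative-control harness (`shuffle_codon_assignment`) permutes the
target-codon labels of the collected windows uniformly, preserving the
multiset of labels and every count vector; any real codon-specific signal is
destroyed and the profile flattens to RRT ≈ 1.

## Demand estimator

Per-codon cost is RRT at position 5 plus RRT at position 6 — the P- and
A-site reactions occur sequentially, so delays add; the known negative
correlation between the two positions is not adjusted for. A transcriptome's
translation time is Σ_g abundance(g) · Σ_codons cost, stop codons excluded,
with equal initiation rates per mRNA assumed (an abundance-dependent
initiation model would widen the differences). Recoding replaces each codon
by the synonym minimizing (fastest) or maximizing (slowest) cost — ties
broken alphabetically so results are deterministic — or by a uniformly
random synonym (seeded; a usage-weighted option exists). By construction
ratio(fastest) ≤ 1 ≤ ratio(slowest) and ratio(wt) = 1; both are fuzz-tested.

## Numerical and design choices

- Coordinates: GFF3 is read 1-based inclusive, internal arithmetic is
  0-based half-open, user-facing codon positions are 1-based.
- CDS whose length is not a multiple of 3, or with internal stops, are
  dropped with a warning rather than truncated.
- The usage/RRT correlation is reported as both Pearson and Spearman, since
  scatter-plot correlations of this kind are conventionally Pearson but the
  ranking is also informative; reports carry both.
- The GC comparison groups codons with ≥2 vs ≤1 G/C bases and uses a
  two-tailed two-sample t-test; when both groups are constant and equal the
  p-value is defined as 1.
- Multi-mapped reads (NH > 1) are dropped by default; a legacy flag keeps
  them for reprocessing older datasets.
- TSV is the canonical output format everywhere; run metadata is JSON with
  no timestamps, so identical configs give byte-identical outputs.

## Problem sizes used in the shipped checks

The acceptance script and heavy tests run seeded simulations sized for a
single CPU: null calibration on 120 genes × 400 codons with 5×10⁵ reads and
2,000 permutation replicates per codon (the analysis default remains
10,000); multiplier recovery on 60 genes × 300 codons with 1.5×10⁵ reads per
panel point; coherence on profile-level draws with 10,000 (shared) and
20×2,000 (independent) null samples. At these sizes every codon accumulates
several hundred qualifying windows, comparable to the sparser end of real
datasets.

## Known limitations

- The statistic measures *relative* dwell; absolute times require an
  external baseline (the millisecond conversion is a multiplication, offered
  as such).
- Isoform structure, UTRs, and non-ATG starts are out of scope; annotation
  is taken at face value.
- Cross-dataset comparisons are supported as generic profile correlations;
  no batch-effect handling is attempted.
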