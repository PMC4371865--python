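"""Simulate dwell-biased footprints and recover the planted signal.

Plants a 3x dwell multiplier for AAA at footprint position 6 (the A-site),
samples 150k reads, and recovers the residence time.  With k=10 positions the
planted multiplier m corresponds to RRT = k*m/(m+k-1) = 2.5.
"""

from riboresidence import (
    DwellModel,
    PermutationConfig,
    SimConfig,
    WindowConfig,
    compute_rrt,
    simulate_footprints,
    simulate_genome,
)

genome = simulate_genome(SimConfig(n_genes=60, gene_length_codons=300, seed=1))
dwell = DwellModel.uniform().with_multiplier("AAA", 6, 3.0)
footprints = simulate_footprints(genome.index, dwell, n_reads=150_000, seed=2)

profile, windows = compute_rrt(
    genome.index, footprints, WindowConfig(), PermutationConfig(n_perm=2000, seed=3)
)

print(f"windows for AAA: {profile.n_windows['AAA']}")
print(f"RRT(AAA, position 6) = {profile.rrt.loc['AAA', 6]:.3f}   (closed form: 2.500)")
print(f"permutation p        = {profile.pvalues.loc['AAA', 6]:.4g}")
print(f"median RRT of all other codons at position 6: "
      f"{profile.rrt_at(6).drop('AAA').median():.3f}  (no planted signal -> ~1)")
# An RRT of ~2.5 means the ribosome dwells 2.5x the average time when AAA
# occupies the A-site; the tiny p-value says this is not sampling noise.
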