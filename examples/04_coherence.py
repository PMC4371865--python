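"""Coherence contrast: amino-acid-specific vs codon-specific dwell profiles.

Builds two synthetic RRT profiles: one where synonymous codons share a dwell
vector (amino-acid-specific behavior, as seen with short footprints) and one
where every codon has an independent vector (codon-specific behavior, as
seen with long footprints at the A-site).  The coherence p-value separates
the two regimes.
"""

import numpy as np
import pandas as pd

from riboresidence import CoherenceConfig, coherence_report
from riboresidence.genetics import AA_TO_CODONS, CODON_TO_AA, SENSE_CODONS

rng = np.random.default_rng(7)
base = {aa: rng.normal(1, 0.4, 10) for aa in AA_TO_CODONS}
shared = pd.DataFrame(
    [base[CODON_TO_AA[c]] + rng.normal(0, 0.02, 10) for c in SENSE_CODONS],
    index=list(SENSE_CODONS), columns=range(1, 11),
)
independent = pd.DataFrame(
    rng.normal(1, 0.4, (61, 10)), index=list(SENSE_CODONS), columns=range(1, 11)
)

cfg = CoherenceConfig(n_samples=5000, seed=8)
rep_shared = coherence_report(shared, cfg)
rep_indep = coherence_report(independent, cfg)

print("amino-acid-specific profile (synonyms share a vector):")
print(f"  median p = {rep_shared.p.median():.4f}, max p = {rep_shared.p.max():.4f}")
print("codon-specific profile (independent vectors):")
print(f"  median p = {rep_indep.p.median():.4f}, max p = {rep_indep.p.max():.4f}")
# Small p = the amino acid's codons sit close together in dwell space.
# Note the floor for 2-codon amino acids: ~6% of random pairs are themselves
# synonymous, so even perfect sharing cannot push their p much below ~0.03.
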