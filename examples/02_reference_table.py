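"""Analyses of the bundled per-codon reference table (S. cerevisiae).

The table carries, for each of the 61 sense codons, its usage per 1000
codons and the measured residence time at footprint position 6 (A-site).
"""

from riboresidence import dwell_time_ms, gc_group_means, table2a_rrt6, table2a_usage, usage_correlation

rrt6 = table2a_rrt6()
usage = table2a_usage()

corr = usage_correlation(rrt6, usage)
print(f"usage vs A-site RRT: Pearson r = {corr.pearson:.2f}, Spearman r = {corr.spearman:.2f}")
# Negative correlation: frequently used codons are decoded faster.

gc = gc_group_means(rrt6)
print(f"mean RRT, GC-rich codons (>=2 G/C): {gc.mean_high:.2f}")
print(f"mean RRT, GC-poor codons (<=1 G/C): {gc.mean_low:.2f}  (t-test p = {gc.p_ttest:.4f})")
# GC-rich codons are decoded more slowly than AT-rich ones.

for codon in ("CTC", "ACC"):
    print(f"{codon}: RRT {rrt6[codon]:.2f} -> {dwell_time_ms(rrt6[codon], 50):.1f} ms "
          f"at a 50 ms average A-site dwell")
# The slowest codon (CTC, ~95 ms) takes ~2.7x as long as the fastest (ACC, 35 ms).
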