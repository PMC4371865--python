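"""Bundled reference data.

``table2a.tsv`` is a per-codon reference table from a published S. cerevisiae
ribosome-profiling experiment: codon usage per 1000 codons, the ribosome
residence time at footprint position 6 (the A-site), and its permutation
p-value, for all 61 sense codons.  It drives the worked examples and the
reference analyses (usage correlation, GC grouping, dwell-time conversion).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome_model import UsageTable

__all__ = ["load_table2a", "table2a_usage", "table2a_rrt6"]


def load_table2a() -> pd.DataFrame:
    """The bundled reference table (codon, amino_acid, usage_per_1000, rrt_pos6, p_value)."""
    with resources.files("riboresidence.data").joinpath("table2a.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def table2a_usage() -> UsageTable:
    t = load_table2a().set_index("codon")
    return UsageTable(usage=t["usage_per_1000"].astype(float))


def table2a_rrt6() -> pd.Series:
    """Position-6 RRT values indexed by codon."""
    return load_table2a().set_index("codon")["rrt_pos6"].astype(float)
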