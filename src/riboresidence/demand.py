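"""Ribosome-demand estimates for alternatively recoded transcriptomes.

The per-codon elongation cost is the RRT at position 5 (P-site, peptide bond)
plus the RRT at position 6 (A-site, decoding): the two reactions happen
sequentially, so their delays add.  A transcriptome can be recoded codon by
codon — keeping the protein sequence — to use only the fastest synonymous
codon, only the slowest, or a random synonym, and the total translation time
(abundance-weighted over mRNAs, assuming equal initiation rates per mRNA) is
compared with the wild-type encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import AA_TO_CODONS, CODON_TO_AA, SENSE_CODONS
from .genome_model import CodingRegion, TranscriptomeIndex

__all__ = [
    "MrnaAbundance",
    "EncodingScheme",
    "codon_costs",
    "recode",
    "relative_time",
    "expected_random_cost",
]

SCHEMES = ("wt", "fastest", "slowest", "random")


@dataclass(frozen=True)
class MrnaAbundance:
    """mRNA copies per cell, keyed by region id."""

    abundance: dict[str, float]

    def __post_init__(self):
        if not any(v > 0 for v in self.abundance.values()):
            raise ValueError("at least one abundance must be positive")

    @classmethod
    def from_tsv(cls, path) -> "MrnaAbundance":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["region_id"].astype(str), df["copies"].astype(float))))

    @classmethod
    def uniform(cls, region_ids) -> "MrnaAbundance":
        return cls({rid: 1.0 for rid in region_ids})

    def __getitem__(self, region_id: str) -> float:
        return self.abundance.get(region_id, 0.0)


@dataclass(frozen=True)
class EncodingScheme:
    scheme: str = "wt"
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")


def codon_costs(rrt5: pd.Series, rrt6: pd.Series) -> pd.Series:
    """Per-codon cost = RRT at position 5 + RRT at position 6."""
    cost = rrt5.reindex(list(SENSE_CODONS)) + rrt6.reindex(list(SENSE_CODONS))
    missing = cost[cost.isna()].index.tolist()
    if missing:
        raise ValueError(f"missing RRT values for codons: {missing}")
    return cost.astype(float)


def _extreme_map(cost: pd.Series, slowest: bool) -> dict[str, str]:
    """codon -> synonymous codon with minimal (or maximal) cost, ties alphabetical."""
    out = {}
    for aa, codons in AA_TO_CODONS.items():
        ranked = sorted(codons, key=lambda c: (-cost[c] if slowest else cost[c], c))
        best = ranked[0]
        for c in codons:
            out[c] = best
    return out


def recode(
    region: CodingRegion | list[str],
    scheme: EncodingScheme,
    cost: pd.Series,
) -> list[str]:
    """Recode a gene's sense codons under a scheme, preserving the protein.

    ``cost`` is the rrt5+rrt6 series from :func:`codon_costs`.  The random
    scheme draws each position's codon uniformly from the amino acid's
    synonyms, seeded from the scheme.
    """
    codons = list(region.sense_codons) if isinstance(region, CodingRegion) else list(region)
    for c in codons:
        if c not in CODON_TO_AA:
            raise ValueError(f"non-sense codon {c!r} in coding sequence")
    if scheme.scheme == "wt":
        return codons
    if scheme.scheme in ("fastest", "slowest"):
        mapping = _extreme_map(cost, slowest=scheme.scheme == "slowest")
        return [mapping[c] for c in codons]
    rng = np.random.default_rng(scheme.seed)
    return [
        AA_TO_CODONS[CODON_TO_AA[c]][rng.integers(len(AA_TO_CODONS[CODON_TO_AA[c]]))]
        for c in codons
    ]


def _total_time(
    index: TranscriptomeIndex,
    abundance: MrnaAbundance,
    cost: pd.Series,
    scheme: EncodingScheme,
) -> float:
    total = 0.0
    for region in index.eligible_regions():
        codons = recode(region, scheme, cost)
        total += abundance[region.region_id] * float(sum(cost[c] for c in codons))
    return total


def relative_time(
    index: TranscriptomeIndex,
    abundance: MrnaAbundance,
    rrt5: pd.Series,
    rrt6: pd.Series,
    scheme: EncodingScheme,
) -> float:
    """Translation time of the recoded transcriptome relative to wild type.

    ``T(scheme) / T(wt)`` where ``T = sum_g abundance(g) * sum_codons cost``;
    stop codons are excluded from the cost sums, and every mRNA is assumed to
    initiate at the same rate.
    """
    cost = codon_costs(rrt5, rrt6)
    t_wt = _total_time(index, abundance, cost, EncodingScheme("wt"))
    if t_wt == 0:
        raise ValueError("wild-type translation time is zero")
    return _total_time(index, abundance, cost, scheme) / t_wt


def expected_random_cost(codons: list[str], cost: pd.Series) -> float:
    """Analytic expected cost of the uniform-random recoding of a codon list."""
    total = 0.0
    for c in codons:
        syn = AA_TO_CODONS[CODON_TO_AA[c]]
        total += float(np.mean([cost[s] for s in syn]))
    return total
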