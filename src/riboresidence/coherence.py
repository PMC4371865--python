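"""Codon-coherence testing: do synonymous codons behave alike?

Each codon's RRT values across the k footprint positions form a point in
k-dimensional space.  For an amino acid with c synonymous codons (2 <= c <= 6;
Met and Trp have one codon and are skipped), the observed statistic is the
average pairwise distance d among its c points.  The null distribution is
built by drawing random c-subsets of the sense-codon universe and computing
the same statistic; the one-sided p-value is the rank of the observed d
(small d, hence small p, means the codons cohere — amino-acid-specific
behavior rather than codon-specific behavior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .genetics import AA_TO_CODONS, AMINO_ACIDS, aa_three_letter
from .rrt_engine import RRTProfile

logger = logging.getLogger(__name__)

__all__ = ["CoherenceConfig", "avg_pairwise_distance", "coherence_pvalue", "coherence_report"]


@dataclass(frozen=True)
class CoherenceConfig:
    n_samples: int = 10_000
    seed: int = 0
    distance: str = "euclidean"

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def avg_pairwise_distance(vectors: np.ndarray, metric: str = "euclidean") -> float:
    """Mean of the c(c-1)/2 pairwise distances among c equal-length vectors."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need at least 2 vectors of equal dimension")
    return float(pdist(vectors, metric=metric).mean())


def _vector_matrix(profile) -> tuple[np.ndarray, list[str]]:
    """(n_codons, k) matrix of non-missing RRT vectors plus their codon labels."""
    frame = profile.rrt if isinstance(profile, RRTProfile) else pd.DataFrame(profile)
    frame = frame.dropna()
    return frame.to_numpy(dtype=float), list(frame.index)


def _random_subsets(rng: np.random.Generator, n: int, c: int, universe: int) -> np.ndarray:
    """(n, c) indices: uniform c-subsets without replacement within each sample."""
    # c smallest of iid uniforms = a uniformly random c-subset
    return np.argpartition(rng.random((n, universe)), c, axis=1)[:, :c]


def _euclidean_avg_pairwise(points: np.ndarray) -> np.ndarray:
    """Vectorized mean pairwise Euclidean distance for a (n, c, k) stack."""
    c = points.shape[1]
    iu, ju = np.triu_indices(c, k=1)
    diffs = points[:, iu, :] - points[:, ju, :]
    return np.linalg.norm(diffs, axis=2).mean(axis=1)


def coherence_pvalue(
    amino_acid: str, profile, config: CoherenceConfig = CoherenceConfig()
) -> tuple[float, float, int]:
    """(p, d_observed, c) for one amino acid's codon set.

    Random samples draw c codons from the profile's available sense-codon
    universe (all 61 when the profile is complete), inclusive of the amino
    acid's own codons.  p = (#{d_sample <= d_observed} + 1) / (n_samples + 1).
    """
    codons = AA_TO_CODONS.get(amino_acid, ())
    matrix, labels = _vector_matrix(profile)
    pos = {c: i for i, c in enumerate(labels)}
    own = [pos[c] for c in codons if c in pos]
    c = len(own)
    if not 2 <= c <= 6:
        raise ValueError(
            f"amino acid {amino_acid!r} has {c} codons with RRT vectors; "
            "coherence requires between 2 and 6"
        )
    d_obs = avg_pairwise_distance(matrix[own], metric=config.distance)
    rng = np.random.default_rng([config.seed, AMINO_ACIDS.index(amino_acid)])
    idx = _random_subsets(rng, config.n_samples, c, universe=len(labels))
    if config.distance == "euclidean":
        d_samples = _euclidean_avg_pairwise(matrix[idx])
    else:
        d_samples = np.array(
            [avg_pairwise_distance(matrix[row], metric=config.distance) for row in idx]
        )
    p = (np.sum(d_samples <= d_obs) + 1) / (config.n_samples + 1)
    return float(p), float(d_obs), c


def coherence_report(
    profile, config: CoherenceConfig = CoherenceConfig()
) -> pd.DataFrame:
    """Coherence p-values for every amino acid with 2..6 codons in the profile."""
    rows = []
    for aa in AMINO_ACIDS:
        codons = AA_TO_CODONS[aa]
        if not 2 <= len(codons) <= 6:
            logger.info("skipping %s: %d codon(s)", aa_three_letter(aa), len(codons))
            continue
        try:
            p, d_obs, c = coherence_pvalue(aa, profile, config)
        except ValueError as exc:
            logger.warning("skipping %s: %s", aa_three_letter(aa), exc)
            continue
        rows.append(
            {
                "amino_acid": aa_three_letter(aa),
                "c": c,
                "d_observed": d_obs,
                "p": p,
                "n_samples": config.n_samples,
                "metric": config.distance,
                "seed": config.seed,
            }
        )
    return pd.DataFrame(rows)
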