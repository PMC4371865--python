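"""Synthetic genomes and dwell-biased footprint sampling.

The simulator provides the positive and negative controls for the residence
time statistic.  Genes are random coding sequences (ATG start, drawn sense
codons, single terminal stop) packed onto one synthetic chromosome on
alternating strands.  Footprints are placements of ``k`` consecutive codons
sampled with probability proportional to the product of per-(codon, position)
dwell multipliers across the placement — with all multipliers equal the
sampling is uniform (flat RRT of 1); a single multiplier ``m`` at one position
of one codon produces the closed-form RRT ``k*m / (m + k - 1)`` at that
position, which the tests use as an analytic check.

Library-chemistry end biases at footprint positions 1 and 10 seen in real
data are deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .footprint_io import AlignedFootprint
from .genetics import CODON_INDEX, SENSE_CODONS, reverse_complement
from .genome_model import CodingRegion, TranscriptomeIndex, _AnnotatedFeature
from .window_engine import CodonWindow

__all__ = [
    "DwellModel",
    "SimConfig",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_footprints",
    "write_sam",
    "shuffle_codon_assignment",
]

_STOP = "TAA"
_CHROM = "simchr1"


@dataclass(frozen=True)
class DwellModel:
    """Positive multipliers per (codon, 1-based footprint position); default 1."""

    multipliers: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self):
        for (codon, pos), m in self.multipliers.items():
            if m <= 0:
                raise ValueError(f"multiplier for ({codon}, {pos}) must be > 0, got {m}")

    @classmethod
    def uniform(cls) -> "DwellModel":
        return cls()

    def with_multiplier(self, codon: str, position: int, m: float) -> "DwellModel":
        new = dict(self.multipliers)
        new[(codon, position)] = m
        return DwellModel(new)

    def matrix(self, k: int) -> np.ndarray:
        """(62, k) multiplier matrix; row 61 is the stop-codon row (always 1)."""
        mat = np.ones((62, k))
        for (codon, pos), m in self.multipliers.items():
            if not 1 <= pos <= k:
                continue
            mat[CODON_INDEX[codon], pos - 1] = m
        return mat


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; gene lengths count sense codons (ATG included)."""

    n_genes: int = 50
    gene_length_codons: int = 200
    codon_composition: str = "uniform"
    n_reads: int = 100_000
    k: int = 10
    seed: int = 0
    spacer_nt: int = 50

    def __post_init__(self):
        if self.codon_composition not in ("uniform", "usage"):
            raise ValueError("codon_composition must be 'uniform' or 'usage'")
        if self.n_genes < 1 or self.gene_length_codons < 3:
            raise ValueError("need at least one gene of at least 3 codons")


@dataclass
class SimulatedGenome:
    """In-memory genome fixture: sequences, annotation text, and a ready index."""

    config: SimConfig
    sequences: dict[str, str]
    gff_text: str
    index: TranscriptomeIndex

    def write(self, fasta_path, gff_path) -> None:
        with open(fasta_path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(gff_path, "w") as fh:
            fh.write(self.gff_text)


def _composition_probs(config: SimConfig) -> np.ndarray:
    if config.codon_composition == "uniform":
        return np.full(61, 1.0 / 61.0)
    from .fixtures import load_table2a  # lazy: avoids import cycle

    usage = load_table2a().set_index("codon")["usage_per_1000"]
    w = usage.reindex(list(SENSE_CODONS)).to_numpy(dtype=float)
    return w / w.sum()


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    """Generate FASTA + GFF3 fixtures with non-overlapping CDS, seeded.

    Genes alternate between the + and - strand to exercise strand handling;
    each gene is ``gene_length_codons`` sense codons plus a terminal TAA.
    """
    rng = np.random.default_rng(config.seed)
    probs = _composition_probs(config)
    chrom_parts: list[str] = []
    cursor = 0
    regions: dict[str, CodingRegion] = {}
    features = []
    gff_lines = ["##gff-version 3"]
    bases = np.array(list("ACGT"))

    for i in range(config.n_genes):
        spacer = "".join(rng.choice(bases, size=config.spacer_nt))
        chrom_parts.append(spacer)
        cursor += len(spacer)

        n_sense = config.gene_length_codons
        draws = rng.choice(61, size=n_sense - 1, p=probs)
        codons = ("ATG",) + tuple(SENSE_CODONS[c] for c in draws) + (_STOP,)
        cds = "".join(codons)
        strand = "+" if i % 2 == 0 else "-"
        genomic = cds if strand == "+" else reverse_complement(cds)
        start, end = cursor, cursor + len(genomic)
        chrom_parts.append(genomic)
        cursor = end

        gene_id = f"gene{i + 1}"
        regions[gene_id] = CodingRegion(
            region_id=gene_id,
            chromosome=_CHROM,
            strand=strand,
            cds_intervals=((start, end),),
            codons=codons,
        )
        features.append(
            _AnnotatedFeature(gene_id, _CHROM, strand, ((start, end),), "gene")
        )
        gff_lines.append(
            f"{_CHROM}\tsim\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gene_id}"
        )
        gff_lines.append(
            f"{_CHROM}\tsim\tCDS\t{start + 1}\t{end}\t.\t{strand}\t0\t"
            f"ID={gene_id}_cds;Parent={gene_id}"
        )
    chrom_parts.append("".join(rng.choice(bases, size=config.spacer_nt)))

    index = TranscriptomeIndex(
        regions=regions,
        eligible_ids=frozenset(regions),
        features=tuple(features),
    )
    return SimulatedGenome(
        config=config,
        sequences={_CHROM: "".join(chrom_parts)},
        gff_text="\n".join(gff_lines) + "\n",
        index=index,
    )


def _placement_weights(region: CodingRegion, dwell_matrix: np.ndarray, k: int) -> np.ndarray:
    codes = np.array(
        [CODON_INDEX.get(c, 61) for c in region.codons], dtype=np.int64
    )
    n_starts = len(codes) - k + 1
    if n_starts <= 0:
        return np.zeros(0)
    per_pos = dwell_matrix[codes]  # (L, k)
    w = np.ones(n_starts)
    for j in range(k):
        w *= per_pos[j : j + n_starts, j]
    return w


def simulate_footprints(
    index: TranscriptomeIndex,
    dwell: DwellModel,
    n_reads: int,
    k: int = 10,
    seed: int = 0,
) -> list[AlignedFootprint]:
    """Sample footprint placements with probability ~ product of dwell multipliers."""
    rng = np.random.default_rng(seed)
    mat = dwell.matrix(k)
    region_ids: list[str] = []
    weights: list[np.ndarray] = []
    starts_per_region: list[int] = []
    for region in index.eligible_regions():
        w = _placement_weights(region, mat, k)
        region_ids.append(region.region_id)
        weights.append(w)
        starts_per_region.append(len(w))
    all_w = np.concatenate(weights) if weights else np.zeros(0)
    if all_w.sum() <= 0:
        raise ValueError("no feasible footprint placements in the index")
    draws = rng.choice(all_w.size, size=n_reads, p=all_w / all_w.sum())
    counts = np.bincount(draws, minlength=all_w.size)

    footprints: list[AlignedFootprint] = []
    offset = 0
    for rid, n_starts in zip(region_ids, starts_per_region):
        for s in range(n_starts):
            c = counts[offset + s]
            if c:
                footprints.extend([AlignedFootprint(rid, s + 1, k)] * int(c))
        offset += n_starts
    return footprints


def write_sam(
    footprints: list[AlignedFootprint],
    genome: SimulatedGenome,
    path,
    mapq: int = 42,
) -> None:
    """Emit footprints as perfectly matching 3k-nt SAM alignments.

    Reads on minus-strand genes carry the reverse flag and the genomic
    (forward-strand) sequence, exactly as an aligner would report them.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in genome.sequences.items()],
    }
    refs = {n: i for i, n in enumerate(genome.sequences)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, fp in enumerate(footprints):
            region = genome.index.regions[fp.region_id]
            if len(region.cds_intervals) != 1:
                raise ValueError("SAM export supports single-interval simulated CDS only")
            (g0, g1) = region.cds_intervals[0]
            span = 3 * fp.k
            off = 3 * (fp.start_codon_index - 1)
            pos = g0 + off if region.strand == "+" else g1 - off - span
            a = pysam.AlignedSegment()
            a.query_name = f"simread{i + 1}"
            a.query_sequence = genome.sequences[region.chromosome][pos : pos + span]
            a.flag = 16 if region.strand == "-" else 0
            a.reference_id = refs[region.chromosome]
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = f"{span}M"
            a.set_tag("NM", 0)
            out.write(a)


def shuffle_codon_assignment(
    windows_by_codon: dict[str, list[CodonWindow]], seed: int = 0
) -> dict[str, list[CodonWindow]]:
    """Negative-control harness: permute target-codon labels across all windows.

    The multiset of labels is preserved; each window keeps its count vector
    but is reassigned a random codon identity, which destroys any real
    codon-specific signal while keeping the count structure intact.
    """
    rng = np.random.default_rng(seed)
    flat: list[CodonWindow] = []
    labels: list[str] = []
    for codon in sorted(windows_by_codon):
        for w in windows_by_codon[codon]:
            flat.append(w)
            labels.append(codon)
    perm = rng.permutation(len(labels))
    out: dict[str, list[CodonWindow]] = {c: [] for c in windows_by_codon}
    for w, li in zip(flat, perm):
        new_label = labels[li]
        out.setdefault(new_label, []).append(
            CodonWindow(
                region_id=w.region_id,
                center_codon_index=w.center_codon_index,
                target_codon=new_label,
                counts=w.counts.copy(),
            )
        )
    return out
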