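"""Ingestion of aligned ribosome footprints.

Reads are filtered (mismatches, quality, length, containment in an eligible
CDS, optional uniqueness) and then reduced to the only information the
downstream statistic needs: which coding region the read sits in and the
1-based index of the first codon of the CDS that the read covers completely.
A footprint then spans ``k`` consecutive codons from that anchor; reads whose
anchor leaves fewer than ``k`` codons inside the CDS are dropped.

Two input dialects are supported: SAM/BAM alignments (the normal route) and a
plain TSV of ``region_id<TAB>start_codon_index`` rows, convenient for fixtures
and for round-tripping simulator output without alignment files.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .genome_model import CodingRegion, TranscriptomeIndex

logger = logging.getLogger(__name__)

__all__ = [
    "FootprintFilterConfig",
    "AlignedFootprint",
    "load_footprints",
    "first_in_frame_codon",
    "load_footprints_tsv",
    "write_footprints_tsv",
]


@dataclass(frozen=True)
class FootprintFilterConfig:
    """Read filters applied before codon reduction.

    Defaults mirror the long-footprint analysis: at most 2 mismatches, mapping
    quality at least 10, aligned length at least 30 nt, footprints of k=10
    codons.  The legacy short-read mode uses ``min_length_nt=24, k=8``; note
    ``min_length_nt >= 3*k`` is deliberately not required.
    """

    max_mismatches: int = 2
    min_quality: int = 10
    min_length_nt: int = 30
    k: int = 10
    require_unique_alignment: bool = True

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("footprint length k must be >= 2")


class AlignedFootprint(NamedTuple):
    """A filtered read reduced to (region, first in-frame codon, codon span)."""

    region_id: str
    start_codon_index: int  # 1-based along the CDS
    k: int


def first_in_frame_codon(covered_cds_offsets: Iterable[int]) -> int | None:
    """Smallest 1-based codon index whose three nucleotides are all covered.

    ``covered_cds_offsets`` are 0-based nucleotide offsets along the CDS in
    translation order (strand handling happens when offsets are computed).
    Returns ``None`` when the read covers no complete codon.
    """
    offsets = set(covered_cds_offsets)
    if not offsets:
        return None
    lo, hi = min(offsets), max(offsets)
    for codon0 in range(lo // 3, hi // 3 + 1):
        base = 3 * codon0
        if base in offsets and base + 1 in offsets and base + 2 in offsets:
            return codon0 + 1
    return None


class _RegionMap:
    """Per-chromosome interval lookup from genomic position to (region, CDS offset)."""

    def __init__(self, index: TranscriptomeIndex):
        self.trees: dict[str, IntervalTree] = {}
        for region in index.eligible_regions():
            tree = self.trees.setdefault(region.chromosome, IntervalTree())
            cds_off = 0
            for s, e in region.cds_intervals:
                # store: region, CDS offset of the part's first translated base
                tree.addi(s, e, (region, cds_off))
                cds_off += e - s

    def lookup(self, chrom: str, start: int, end: int):
        """Regions whose CDS parts overlap [start, end)."""
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return list(tree.overlap(start, end))


def _cds_offsets(region: CodingRegion, part_cds_start: int, part: tuple[int, int],
                 positions: np.ndarray) -> np.ndarray:
    s, e = part
    if region.strand == "+":
        return part_cds_start + (positions - s)
    return part_cds_start + (e - 1 - positions)


def load_footprints(
    alignment_file,
    index: TranscriptomeIndex,
    config: FootprintFilterConfig = FootprintFilterConfig(),
    *,
    drop_counts: Counter | None = None,
) -> list[AlignedFootprint]:
    """Load a SAM/BAM file and reduce passing reads to codon footprints.

    A read is emitted only if it passes every filter in ``config``, all of its
    aligned bases fall inside the CDS of a single eligible region on the same
    strand, and its first fully covered codon leaves at least ``k`` codons in
    the CDS.  Per-filter drop counts are logged (and accumulated into
    ``drop_counts`` when a Counter is supplied).
    """
    counters = drop_counts if drop_counts is not None else Counter()
    region_map = _RegionMap(index)
    footprints: list[AlignedFootprint] = []
    k = config.k

    mode = "rb" if str(alignment_file).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignment_file), mode, check_sq=False) as sam:
        references = set(sam.references or ())
        for read in sam:
            if read.is_unmapped:
                counters["unmapped"] += 1
                continue
            if read.is_secondary or read.is_supplementary:
                counters["secondary_or_supplementary"] += 1
                continue
            if read.reference_name not in references:
                raise ValueError(f"unknown reference sequence {read.reference_name!r}")
            nm = read.get_tag("NM") if read.has_tag("NM") else 0
            if nm > config.max_mismatches:
                counters["too_many_mismatches"] += 1
                continue
            if (read.mapping_quality or 0) < config.min_quality:
                counters["low_quality"] += 1
                continue
            # soft-clipped bases are excluded: use the aligned portion only
            if read.query_alignment_length < config.min_length_nt:
                counters["too_short"] += 1
                continue
            if config.require_unique_alignment and read.has_tag("NH") and read.get_tag("NH") > 1:
                counters["multi_mapped"] += 1
                continue

            ref_positions = np.array(read.get_reference_positions(), dtype=np.int64)
            hits = region_map.lookup(
                read.reference_name, int(ref_positions.min()), int(ref_positions.max()) + 1
            )
            regions_hit = {iv.data[0].region_id for iv in hits}
            if len(regions_hit) != 1:
                counters["not_in_single_cds" if hits else "outside_cds"] += 1
                continue
            region = hits[0].data[0]
            if (read.is_reverse and region.strand == "+") or (
                not read.is_reverse and region.strand == "-"
            ):
                counters["strand_mismatch"] += 1
                continue

            # map every aligned base to a CDS offset; require full containment
            offsets: list[np.ndarray] = []
            covered = 0
            for iv in hits:
                _, part_cds_start = iv.data
                part = (iv.begin, iv.end)
                inside = ref_positions[
                    (ref_positions >= iv.begin) & (ref_positions < iv.end)
                ]
                covered += inside.size
                offsets.append(_cds_offsets(region, part_cds_start, part, inside))
            if covered != ref_positions.size:
                counters["not_fully_in_cds"] += 1
                continue

            start = first_in_frame_codon(np.concatenate(offsets))
            if start is None:
                counters["no_complete_codon"] += 1
                continue
            if start + k - 1 > region.length_codons:
                counters["footprint_exceeds_cds"] += 1
                continue
            footprints.append(AlignedFootprint(region.region_id, start, k))

    counters["emitted"] = len(footprints)
    logger.info(
        "footprint ingestion from %s: %s", alignment_file, dict(sorted(counters.items()))
    )
    return footprints


def load_footprints_tsv(path, k: int = 10) -> list[AlignedFootprint]:
    """Read the plain footprint dialect: region_id<TAB>start_codon_index."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    return [
        AlignedFootprint(str(r), int(s), k)
        for r, s in zip(df["region_id"], df["start_codon_index"])
    ]


def write_footprints_tsv(footprints: Iterable[AlignedFootprint], path) -> None:
    df = pd.DataFrame(
        [(fp.region_id, fp.start_codon_index) for fp in footprints],
        columns=["region_id", "start_codon_index"],
    )
    df.to_csv(path, sep="\t", index=False)
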