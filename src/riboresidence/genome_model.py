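"""Codon-resolved transcript models built from a genome FASTA and GFF3 annotation.

The unit of analysis is the :class:`CodingRegion`: one protein-coding gene's CDS
flattened into a list of codons in translation order, together with the genomic
intervals it came from.  A :class:`TranscriptomeIndex` holds all regions plus
the subset deemed *eligible* for residence-time analysis: regions whose genomic
footprint does not overlap any other gene, rRNA, or tRNA, so that reads mapping
inside them map uniquely with high confidence.

Coordinates: GFF3 input is 1-based inclusive; everything internal is 0-based
half-open; codon positions exposed to users are 1-based along the CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .genetics import (
    CODON_INDEX,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    reverse_complement,
    translate_codons,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CodingRegion",
    "TranscriptomeIndex",
    "UsageTable",
    "load_transcriptome",
    "apply_eligibility",
    "compute_usage",
]


@dataclass(frozen=True)
class CodingRegion:
    """One gene's CDS as an ordered codon list with its genomic mapping.

    ``cds_intervals`` are 0-based half-open genomic intervals in *translation*
    order (descending genomic coordinates for minus-strand genes).  ``codons``
    are read in mRNA 5'->3' order; minus-strand codons are reverse-complemented
    from the genome.  The terminal stop codon, when present, is kept but is
    never treated as one of the 61 sense codons.
    """

    region_id: str
    chromosome: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    codons: tuple[str, ...]

    @property
    def length_codons(self) -> int:
        return len(self.codons)

    @property
    def has_terminal_stop(self) -> bool:
        return bool(self.codons) and self.codons[-1] in STOP_CODONS

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Codons excluding the terminal stop (if any)."""
        return self.codons[:-1] if self.has_terminal_stop else self.codons

    @property
    def n_sense_codons(self) -> int:
        return len(self.sense_codons)

    def codon_codes(self) -> np.ndarray:
        """Integer codes (0..60) of the sense codons; -1 for non-sense codons."""
        return np.array(
            [CODON_INDEX.get(c, -1) for c in self.sense_codons], dtype=np.int64
        )

    def amino_acids(self) -> str:
        """One-letter translation of the sense codons."""
        return translate_codons(list(self.sense_codons))

    def genomic_sequence(self, genome: Fasta) -> str:
        """Reconstruct the CDS nucleotide sequence from the genome (5'->3' mRNA)."""
        parts = []
        for start, end in self.cds_intervals:
            seq = str(genome[self.chromosome][start:end]).upper()
            parts.append(reverse_complement(seq) if self.strand == "-" else seq)
        return "".join(parts)


@dataclass(frozen=True)
class _AnnotatedFeature:
    """A gene/rRNA/tRNA feature used only for the eligibility overlap test."""

    feature_id: str
    chromosome: str
    strand: str
    parts: tuple[tuple[int, int], ...]
    ftype: str

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.parts), max(e for _, e in self.parts)


@dataclass(frozen=True)
class TranscriptomeIndex:
    """All coding regions plus the eligibility verdict for each."""

    regions: dict[str, CodingRegion]
    eligible_ids: frozenset[str] = frozenset()
    features: tuple[_AnnotatedFeature, ...] = ()
    exclusion_reasons: dict[str, str] = field(default_factory=dict)
    codon_table: dict[str, str] = field(default_factory=lambda: dict(CODON_TO_AA))

    def eligible_regions(self) -> list[CodingRegion]:
        return [self.regions[r] for r in sorted(self.eligible_ids)]

    def eligibility_report(self) -> pd.DataFrame:
        """Per-region TSV-ready report: region_id, eligible, excluded_reason."""
        rows = [
            {
                "region_id": rid,
                "eligible": rid in self.eligible_ids,
                "excluded_reason": self.exclusion_reasons.get(rid, ""),
            }
            for rid in sorted(self.regions)
        ]
        return pd.DataFrame(rows, columns=["region_id", "eligible", "excluded_reason"])


@dataclass(frozen=True)
class UsageTable:
    """Codon usage expressed as frequency per 1000 codons (61 sense codons)."""

    usage: pd.Series

    def __post_init__(self):
        missing = set(SENSE_CODONS) - set(self.usage.index)
        if missing:
            raise ValueError(f"usage table missing codons: {sorted(missing)}")

    @classmethod
    def from_counts(cls, counts: pd.Series) -> "UsageTable":
        total = counts.sum()
        if total == 0:
            raise ValueError("cannot compute usage from zero codon counts")
        usage = 1000.0 * counts.reindex(list(SENSE_CODONS), fill_value=0) / total
        return cls(usage=usage)

    def __getitem__(self, codon: str) -> float:
        return float(self.usage[codon])


def _resolve_gene_id(db: gffutils.FeatureDB, parent_id: str) -> str:
    """Follow a CDS Parent up to the gene level when the parent is an mRNA."""
    try:
        parent = db[parent_id]
    except gffutils.exceptions.FeatureNotFoundError:
        return parent_id
    if parent.featuretype in ("gene", "rRNA", "tRNA"):
        return parent_id
    grand = parent.attributes.get("Parent")
    return grand[0] if grand else parent_id


def load_transcriptome(genome_file, annotation_file) -> TranscriptomeIndex:
    """Load genome + GFF3 annotation into a :class:`TranscriptomeIndex`.

    Every CDS whose total length is a multiple of 3 becomes a
    :class:`CodingRegion`; others are dropped with a warning.  Eligibility is
    *not* applied here — call :func:`apply_eligibility` afterwards.

    Raises
    ------
    ValueError
        If a feature references a chromosome absent from the genome, or the
        annotation cannot be parsed.
    """
    genome = Fasta(str(genome_file), rebuild=False)
    try:
        db = gffutils.create_db(
            str(annotation_file),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises a mix of error types
        raise ValueError(f"cannot parse annotation {annotation_file}: {exc}") from exc

    # Group CDS parts by their owning gene.
    cds_by_gene: dict[str, list[gffutils.Feature]] = {}
    for cds in db.features_of_type("CDS"):
        if cds.seqid not in genome:
            raise ValueError(
                f"feature {cds.id or cds.attributes.get('Parent')} references "
                f"unknown chromosome {cds.seqid!r}"
            )
        parents = cds.attributes.get("Parent")
        gene_id = _resolve_gene_id(db, parents[0]) if parents else (cds.id or "CDS")
        cds_by_gene.setdefault(gene_id, []).append(cds)

    regions: dict[str, CodingRegion] = {}
    for gene_id, parts in cds_by_gene.items():
        chrom = parts[0].seqid
        strand = parts[0].strand
        # 0-based half-open, genomic order first
        ivals = sorted((p.start - 1, p.end) for p in parts)
        total = sum(e - s for s, e in ivals)
        if total % 3 != 0:
            logger.warning(
                "dropping CDS %s: length %d nt is not a multiple of 3", gene_id, total
            )
            continue
        if strand == "-":
            ivals = ivals[::-1]  # translation order
        region = CodingRegion(
            region_id=gene_id,
            chromosome=chrom,
            strand=strand,
            cds_intervals=tuple(ivals),
            codons=(),
        )
        seq = region.genomic_sequence(genome)
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        internal_stops = [c for c in codons[:-1] if c in STOP_CODONS]
        if internal_stops:
            logger.warning(
                "dropping CDS %s: internal stop codon(s) %s", gene_id, internal_stops
            )
            continue
        regions[gene_id] = replace(region, codons=codons)

    features = []
    for ftype in ("gene", "rRNA", "tRNA"):
        for feat in db.features_of_type(ftype):
            if feat.seqid not in genome:
                raise ValueError(
                    f"feature {feat.id} references unknown chromosome {feat.seqid!r}"
                )
            fid = feat.id or f"{ftype}:{feat.seqid}:{feat.start}"
            if ftype == "gene" and fid in regions:
                # Use CDS parts for genes we modeled (part-based overlap test).
                parts_iv = regions[fid].cds_intervals
            else:
                parts_iv = ((feat.start - 1, feat.end),)
            features.append(
                _AnnotatedFeature(
                    feature_id=fid,
                    chromosome=feat.seqid,
                    strand=feat.strand,
                    parts=tuple(sorted(parts_iv)),
                    ftype=ftype,
                )
            )
    # Annotations that provide CDS without gene parents still need to count as
    # interfering features.
    known = {f.feature_id for f in features}
    for rid, region in regions.items():
        if rid not in known:
            features.append(
                _AnnotatedFeature(
                    feature_id=rid,
                    chromosome=region.chromosome,
                    strand=region.strand,
                    parts=tuple(sorted(region.cds_intervals)),
                    ftype="gene",
                )
            )

    logger.info("loaded %d coding regions from %s", len(regions), annotation_file)
    return TranscriptomeIndex(regions=regions, features=tuple(features))


def apply_eligibility(
    index: TranscriptomeIndex,
    *,
    overlap_mode: str = "parts",
    strand_specific: bool = False,
) -> TranscriptomeIndex:
    """Mark regions whose genomic span overlaps another gene/rRNA/tRNA as ineligible.

    The overlap test is strand-insensitive by default (the motivation is
    mapping uniqueness, which ignores strand) and uses CDS parts rather than
    the enclosing span (``overlap_mode="span"`` switches to spans, which also
    excludes genes lying inside another gene's intron).
    """
    if overlap_mode not in ("parts", "span"):
        raise ValueError(f"overlap_mode must be 'parts' or 'span', got {overlap_mode!r}")

    trees: dict[str, IntervalTree] = {}
    for feat in index.features:
        tree = trees.setdefault(feat.chromosome, IntervalTree())
        parts = feat.parts if overlap_mode == "parts" else (feat.span,)
        for s, e in parts:
            if e > s:
                tree.addi(s, e, feat)

    eligible = set()
    reasons: dict[str, str] = {}
    for rid, region in index.regions.items():
        query = (
            region.cds_intervals
            if overlap_mode == "parts"
            else (
                (
                    min(s for s, _ in region.cds_intervals),
                    max(e for _, e in region.cds_intervals),
                ),
            )
        )
        tree = trees.get(region.chromosome, IntervalTree())
        hits = set()
        for s, e in query:
            for iv in tree.overlap(s, e):
                feat = iv.data
                if feat.feature_id == rid:
                    continue
                if strand_specific and feat.strand != region.strand:
                    continue
                hits.add((feat.ftype, feat.feature_id))
        if hits:
            reasons[rid] = ";".join(
                f"overlaps_{ftype}:{fid}" for ftype, fid in sorted(hits)
            )
        else:
            eligible.add(rid)

    if not eligible:
        logger.warning("no regions are eligible after the overlap filter")
    return replace(
        index, eligible_ids=frozenset(eligible), exclusion_reasons=reasons
    )


def compute_usage(index: TranscriptomeIndex) -> UsageTable:
    """Codon frequency per 1000 codons over eligible regions (terminal stops excluded)."""
    counts = pd.Series(0, index=list(SENSE_CODONS), dtype=float)
    for region in index.eligible_regions():
        codes, n = np.unique(region.codon_codes(), return_counts=True)
        for code, cnt in zip(codes, n):
            if code >= 0:
                counts.iloc[code] += cnt
    return UsageTable.from_counts(counts)
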