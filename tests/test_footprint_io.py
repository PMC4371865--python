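"""Read filtering and reduction to codon-indexed footprints."""

from collections import Counter

import numpy as np
import pytest

from riboresidence.footprint_io import (
    AlignedFootprint,
    FootprintFilterConfig,
    first_in_frame_codon,
    load_footprints,
    load_footprints_tsv,
    write_footprints_tsv,
)

from conftest import load_toy

GENE40 = ["ATG"] + ["GCT"] * 38 + ["TAA"]  # 40 codons, 120 nt
G0 = 60  # genomic start of the toy gene


def write_sam(path, reads, length=600, chrom="chrI"):
    """reads: (pos0, flag, mapq, cigar, seq_len, nm)"""
    lines = ["@HD\tVN:1.6", f"@SQ\tSN:{chrom}\tLN:{length}"]
    for i, (pos0, flag, mapq, cigar, seq_len, nm) in enumerate(reads):
        lines.append(
            f"r{i}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t"
            f"{'A' * seq_len}\t*\tNM:i:{nm}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def plus_index(tmp_path):
    return load_toy(tmp_path, 600, [("g1", "+", G0, GENE40)])


def test_read_at_codon_boundary(tmp_path, plus_index):
    sam = write_sam(tmp_path / "a.sam", [(G0 + 30, 0, 42, "30M", 30, 0)])
    fps = load_footprints(sam, plus_index)
    assert fps == [AlignedFootprint("g1", 11, 10)]


def test_partial_first_codon_is_skipped(tmp_path, plus_index):
    # starts 1 nt before codon 5's first base -> codon 4 incomplete, anchor = 5
    sam = write_sam(tmp_path / "a.sam", [(G0 + 3 * 4 - 1, 0, 42, "30M", 30, 0)])
    fps = load_footprints(sam, plus_index)
    assert fps == [AlignedFootprint("g1", 5, 10)]


@pytest.mark.parametrize(
    "read,reason",
    [
        ((G0 + 30, 0, 42, "30M", 30, 3), "too_many_mismatches"),
        ((G0 + 30, 0, 5, "30M", 30, 0), "low_quality"),
        ((G0 + 30, 0, 42, "29M", 29, 0), "too_short"),
        ((G0 - 6, 0, 42, "30M", 30, 0), "not_fully_in_cds"),
        ((G0 + 30, 16, 42, "30M", 30, 0), "strand_mismatch"),
    ],
)
def test_filters_drop_reads_with_logged_reason(tmp_path, plus_index, read, reason):
    sam = write_sam(tmp_path / "a.sam", [read])
    drops = Counter()
    fps = load_footprints(sam, plus_index, drop_counts=drops)
    assert fps == []
    assert drops[reason] == 1


def test_anchor_too_close_to_cds_end_dropped(tmp_path, plus_index):
    # 24-nt read anchored at codon 33 of a 40-codon gene: only 8 codons remain
    sam = write_sam(tmp_path / "a.sam", [(G0 + 96, 0, 42, "24M", 24, 0)])
    drops = Counter()
    cfg = FootprintFilterConfig(min_length_nt=24)
    assert load_footprints(sam, plus_index, cfg, drop_counts=drops) == []
    assert drops["footprint_exceeds_cds"] == 1


def test_soft_clips_excluded_from_coverage(tmp_path, plus_index):
    # 4S26M: aligned portion is 26 nt < 30 -> dropped even though read is 30 nt
    sam = write_sam(tmp_path / "a.sam", [(G0 + 30, 0, 42, "4S26M", 30, 0)])
    assert load_footprints(sam, plus_index) == []


def test_minus_strand_mirror_gives_same_codon_index(tmp_path):
    """A read placed symmetrically on the minus-strand copy anchors identically."""
    plus = load_toy(tmp_path / "p", 600, [("g1", "+", G0, GENE40)])
    minus = load_toy(tmp_path / "m", 600, [("g1", "-", G0, GENE40)])
    cds_off = 30  # codon 11
    sam_p = write_sam(tmp_path / "p.sam", [(G0 + cds_off, 0, 42, "30M", 30, 0)])
    # minus gene: CDS offset o occupies genomic [end-1-o]; 30 nt from o=30
    end = G0 + 120
    sam_m = write_sam(tmp_path / "m.sam", [(end - cds_off - 30, 16, 42, "30M", 30, 0)])
    fp_p = load_footprints(sam_p, plus)
    fp_m = load_footprints(sam_m, minus)
    assert fp_p == fp_m == [AlignedFootprint("g1", 11, 10)]


def test_first_in_frame_codon_rules():
    assert first_in_frame_codon(range(0, 30)) == 1
    assert first_in_frame_codon(range(1, 31)) == 2  # codon 1 incomplete
    assert first_in_frame_codon([0, 1]) is None  # no complete codon
    assert first_in_frame_codon([]) is None


def test_relaxing_thresholds_never_loses_footprints(tmp_path, plus_index):
    rng = np.random.default_rng(7)
    reads = [
        (
            int(rng.integers(G0 - 10, G0 + 120)),
            0,
            int(rng.integers(0, 45)),
            "30M",
            30,
            int(rng.integers(0, 5)),
        )
        for _ in range(300)
    ]
    sam = write_sam(tmp_path / "fuzz.sam", reads)
    base = FootprintFilterConfig()
    n_base = len(load_footprints(sam, plus_index, base))
    for relaxed in [
        FootprintFilterConfig(max_mismatches=5),
        FootprintFilterConfig(min_quality=0),
        FootprintFilterConfig(min_length_nt=20),
    ]:
        assert len(load_footprints(sam, plus_index, relaxed)) >= n_base


def test_emitted_footprints_satisfy_containment(tmp_path, plus_index):
    rng = np.random.default_rng(11)
    reads = [
        (int(rng.integers(0, 560)), 0, 42, "30M", 30, 0) for _ in range(500)
    ]
    sam = write_sam(tmp_path / "fuzz.sam", reads)
    for fp in load_footprints(sam, plus_index):
        assert 1 <= fp.start_codon_index
        assert fp.start_codon_index + fp.k - 1 <= 40


def test_multi_mapped_reads_dropped_when_unique_required(tmp_path, plus_index):
    lines = [
        "@HD\tVN:1.6",
        "@SQ\tSN:chrI\tLN:600",
        f"rmulti\t0\tchrI\t{G0 + 31}\t42\t30M\t*\t0\t0\t{'A' * 30}\t*\tNM:i:0\tNH:i:3",
    ]
    sam = tmp_path / "m.sam"
    sam.write_text("\n".join(lines) + "\n")
    assert load_footprints(sam, plus_index) == []
    relaxed = FootprintFilterConfig(require_unique_alignment=False)
    assert len(load_footprints(sam, plus_index, relaxed)) == 1


def test_tsv_dialect_round_trip(tmp_path):
    fps = [AlignedFootprint("g1", 3, 10), AlignedFootprint("g2", 17, 10)]
    path = tmp_path / "fp.tsv"
    write_footprints_tsv(fps, path)
    assert load_footprints_tsv(path, k=10) == fps
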