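"""Simulator: determinism, sampling-weight fidelity, and the negative control."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from riboresidence.footprint_io import FootprintFilterConfig, load_footprints
from riboresidence.genetics import SENSE_CODONS
from riboresidence.genome_model import apply_eligibility, load_transcriptome
from riboresidence.pipeline import compute_rrt
from riboresidence.rrt_engine import rrt_profile
from riboresidence.simulator import (
    DwellModel,
    SimConfig,
    _placement_weights,
    shuffle_codon_assignment,
    simulate_footprints,
    simulate_genome,
    write_sam,
)
from riboresidence.window_engine import WindowConfig, collect_windows, counts_matrix


def test_same_seed_gives_byte_identical_fixtures(tmp_path):
    cfg = SimConfig(n_genes=5, gene_length_codons=80, seed=21)
    for sub in ("a", "b"):
        d = tmp_path / sub
        d.mkdir()
        g = simulate_genome(cfg)
        g.write(d / "g.fa", d / "a.gff3")
        write_sam(simulate_footprints(g.index, DwellModel.uniform(), 2000, seed=22), g, d / "r.sam")
    for name in ("g.fa", "a.gff3", "r.sam"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_gene_structure_and_length():
    g = simulate_genome(SimConfig(n_genes=1, gene_length_codons=100, seed=1))
    region = g.index.regions["gene1"]
    assert region.length_codons == 101  # 100 sense codons + terminal stop
    assert region.codons[0] == "ATG" and region.has_terminal_stop
    s, e = region.cds_intervals[0]
    assert e - s == 303


def test_genes_alternate_strands():
    g = simulate_genome(SimConfig(n_genes=4, gene_length_codons=60, seed=2))
    assert [g.index.regions[f"gene{i}"].strand for i in (1, 2, 3, 4)] == ["+", "-", "+", "-"]


def test_uniform_composition_frequencies():
    g = simulate_genome(SimConfig(n_genes=4, gene_length_codons=2000, seed=3))
    drawn = Counter()
    for region in g.index.regions.values():
        drawn.update(region.sense_codons[1:])  # skip the fixed ATG start
    counts = np.array([drawn[c] for c in SENSE_CODONS])
    assert stats.chisquare(counts).pvalue > 0.001


def test_placement_frequencies_match_dwell_weights():
    """Sampled placements follow the product-of-multipliers law (chi-square)."""
    g = simulate_genome(SimConfig(n_genes=2, gene_length_codons=60, seed=4))
    dwell = DwellModel.uniform().with_multiplier("AAA", 6, 3.0).with_multiplier("GGG", 2, 0.5)
    n_reads = 100_000
    fps = simulate_footprints(g.index, dwell, n_reads, seed=5)
    mat = dwell.matrix(10)
    expected, observed = [], []
    for region in g.index.eligible_regions():
        w = _placement_weights(region, mat, 10)
        got = Counter(f.start_codon_index for f in fps if f.region_id == region.region_id)
        expected.append(w)
        observed.append(np.array([got.get(s + 1, 0) for s in range(len(w))]))
    w = np.concatenate(expected)
    obs = np.concatenate(observed)
    exp = w / w.sum() * n_reads
    assert obs.sum() == n_reads
    assert stats.chisquare(obs, exp).pvalue > 0.01


def test_single_multiplier_recovers_closed_form_rrt():
    m, k = 3.0, 10
    g = simulate_genome(SimConfig(n_genes=30, gene_length_codons=200, seed=7))
    fps = simulate_footprints(g.index, DwellModel.uniform().with_multiplier("AAA", 6, m), 150_000, seed=8)
    profile, windows = compute_rrt(g.index, fps, WindowConfig())
    freqs = counts_matrix(windows["AAA"]).astype(float)
    freqs = freqs / freqs.sum(axis=1, keepdims=True)
    se = k * freqs[:, 5].std(ddof=1) / np.sqrt(len(freqs))
    assert profile.rrt.loc["AAA", 6] == pytest.approx(k * m / (m + k - 1), abs=3 * se)


def test_sam_round_trip_preserves_footprints(tmp_path):
    g = simulate_genome(SimConfig(n_genes=6, gene_length_codons=120, seed=9))
    fps = simulate_footprints(g.index, DwellModel.uniform(), 5000, seed=10)
    fa, gff, sam = tmp_path / "g.fa", tmp_path / "a.gff3", tmp_path / "r.sam"
    g.write(fa, gff)
    write_sam(fps, g, sam)
    index = apply_eligibility(load_transcriptome(fa, gff))
    loaded = load_footprints(sam, index, FootprintFilterConfig())
    assert Counter(loaded) == Counter(fps)


def test_shuffle_preserves_counts_and_is_seeded(uniform_sim_windows):
    shuffled = shuffle_codon_assignment(uniform_sim_windows, seed=33)
    again = shuffle_codon_assignment(uniform_sim_windows, seed=33)
    labels = lambda w: sorted((c, len(v)) for c, v in w.items())
    assert labels(shuffled) == labels(again)
    # multiset of count vectors is conserved
    def all_counts(wbc):
        return sorted(tuple(map(int, w.counts)) for ws in wbc.values() for w in ws)
    assert all_counts(shuffled) == all_counts(uniform_sim_windows)
    # total window count conserved
    assert sum(len(v) for v in shuffled.values()) == sum(
        len(v) for v in uniform_sim_windows.values()
    )


def test_shuffled_dwell_signal_flattens(uniform_sim_windows):
    """Shuffling an already-flat dataset keeps RRT near 1 everywhere."""
    shuffled = shuffle_codon_assignment(uniform_sim_windows, seed=34)
    profile = rrt_profile(shuffled)
    dev = (profile.rrt - 1).abs().to_numpy()
    assert np.nanmean(dev) < 0.1


def test_negative_control_tightens_with_depth():
    g = simulate_genome(SimConfig(n_genes=40, gene_length_codons=250, seed=11))
    devs = []
    for n_reads in (60_000, 600_000):
        fps = simulate_footprints(g.index, DwellModel.uniform(), n_reads, seed=12)
        profile, _ = compute_rrt(g.index, fps, WindowConfig())
        devs.append(float((profile.rrt_at(6) - 1).abs().max()))
    assert devs[1] < devs[0]


@pytest.mark.parametrize("k,min_len", [(8, 24), (7, 21)])
def test_alternate_footprint_lengths_end_to_end(tmp_path, k, min_len):
    """Legacy 8-codon (>=24 nt) and short 7-codon footprint modes run end to end."""
    g = simulate_genome(SimConfig(n_genes=10, gene_length_codons=150, k=k, seed=13))
    fps = simulate_footprints(g.index, DwellModel.uniform(), 30_000, k=k, seed=14)
    fa, gff, sam = tmp_path / "g.fa", tmp_path / "a.gff3", tmp_path / "r.sam"
    g.write(fa, gff)
    write_sam(fps, g, sam)
    index = apply_eligibility(load_transcriptome(fa, gff))
    loaded = load_footprints(sam, index, FootprintFilterConfig(min_length_nt=min_len, k=k))
    assert Counter(loaded) == Counter(fps)
    profile, _ = compute_rrt(g.index, fps, WindowConfig(k=k))
    assert profile.rrt.shape == (61, k)
    sums = profile.rrt.sum(axis=1).dropna()
    assert np.allclose(sums, k)


def test_invalid_multiplier_rejected():
    with pytest.raises(ValueError, match="> 0"):
        DwellModel({("AAA", 6): 0.0})
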