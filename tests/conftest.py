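"""Shared fixtures: hand-built toy genomes and a reusable simulated dataset."""

from __future__ import annotations

import pytest

from riboresidence.genetics import reverse_complement
from riboresidence.genome_model import apply_eligibility, load_transcriptome
from riboresidence.simulator import (
    DwellModel,
    SimConfig,
    simulate_footprints,
    simulate_genome,
)
from riboresidence.window_engine import WindowConfig, collect_windows


def write_toy_genome(tmp_path, length, genes, extra_features=(), name="chrI"):
    """Write a FASTA + GFF3 toy genome.

    ``genes``: iterable of (gene_id, strand, start0, codons) — codons given in
    mRNA reading order; minus-strand genes are placed reverse-complemented.
    ``extra_features``: (ftype, start0, end0, feature_id, strand).
    """
    tmp_path.mkdir(parents=True, exist_ok=True)
    seq = list(("ACGTC" * (length // 5 + 1))[:length])
    lines = ["##gff-version 3"]
    for gene_id, strand, start, codons in genes:
        cds = "".join(codons)
        genomic = cds if strand == "+" else reverse_complement(cds)
        end = start + len(genomic)
        assert end <= length, "gene does not fit on toy chromosome"
        seq[start:end] = genomic
        lines.append(f"{name}\ttoy\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gene_id}")
        lines.append(
            f"{name}\ttoy\tCDS\t{start + 1}\t{end}\t.\t{strand}\t0\t"
            f"ID={gene_id}_cds;Parent={gene_id}"
        )
    for ftype, start, end, fid, strand in extra_features:
        lines.append(f"{name}\ttoy\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\tID={fid}")
    fasta = tmp_path / "toy.fa"
    gff = tmp_path / "toy.gff3"
    fasta.write_text(f">{name}\n{''.join(seq)}\n")
    gff.write_text("\n".join(lines) + "\n")
    return fasta, gff


def load_toy(tmp_path, length, genes, extra_features=(), **kwargs):
    fasta, gff = write_toy_genome(tmp_path, length, genes, extra_features)
    return apply_eligibility(load_transcriptome(fasta, gff), **kwargs)


@pytest.fixture(scope="session")
def uniform_sim():
    """Small uniform-dwell simulation reused across tests."""
    genome = simulate_genome(SimConfig(n_genes=20, gene_length_codons=150, seed=101))
    footprints = simulate_footprints(genome.index, DwellModel.uniform(), 60_000, seed=102)
    return genome, footprints


@pytest.fixture(scope="session")
def uniform_sim_windows(uniform_sim):
    genome, footprints = uniform_sim
    return collect_windows(genome.index, footprints, WindowConfig())
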