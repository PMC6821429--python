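import pytest

from apacell.simdata import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def tiny_experiment(tmp_path_factory):
    """A small synthetic 3' tag experiment shared across tests: 8 genes,
    two clusters of 20 cells, ~10k reads."""
    cfg = SimConfig(
        n_genes=8,
        n_cells_per_cluster=20,
        reads_per_cell=250.0,
        rng_seed=7,
    )
    outdir = tmp_path_factory.mktemp("tiny_sim")
    return simulate_experiment(cfg, outdir)


def write_gtf(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def gtf_transcript(chrom, gene, tx, strand, exons, cds=(), utr3=()):
    """GTF lines (1-based inclusive) for one transcript from half-open
    intervals."""
    attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
    out = []
    for ftype, ivs in (("exon", exons), ("CDS", cds), ("three_prime_utr", utr3)):
        for s, e in ivs:
            out.append(f"{chrom}\tt\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}")
    return out
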