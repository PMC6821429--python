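"""Synthetic 3' tag scRNA-seq experiments with ground truth.

The generator emulates the library model of 3' tag protocols (10x/Drop-seq
style): oligo-dT priming anchors short cDNA fragments (~200-300 bp) at the
poly(A) tail, reads (~100 nt) are sequenced from the fragment's far end, so
aligned read 3' ends pile up a stochastic fragment-length offset upstream of
the pA site. Each simulated gene has two exons, a 3' UTR carrying 1-3 pA
sites with cluster-specific usage proportions, optionally an intronic pA
site, a planted canonical PAS (AATAAA) upstream of every true site, and a
planted A-run decoy downstream of the UTR sites at which internal-priming
reads arise. Output is already-aligned, coordinate-sorted SAM plus a cell
cluster table and per-gene / per-read truth tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam

from .peaks import reverse_complement

logger = logging.getLogger(__name__)

# gene-block layout in local sense coordinates (see docs/methods.md)
_EXON1_LEN = 300
_INTRON_LEN = 1600
_INTRONIC_PA_OFFSET = 800     # into the intron
_CDS2_LEN = 100               # CDS tail inside the last exon
_UTR_LEAD = 600               # UTR bases upstream of the proximal pA site
_DECOY_GAP = 700              # decoy A-run this far past the distal site
_UTR_TAIL = 300               # UTR bases past the last element
_DECOY_RUN = 30               # length of the planted internal-priming A-run


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    ``cluster_usage`` maps each cluster to the proximal->distal usage
    proportions of the UTR pA sites (must sum to 1); ``intronic_usage`` is
    the per-cluster fraction of a gene's transcripts cleaved at the intronic
    site (for the ``intronic_pa_fraction`` of genes that have one).
    ``internal_priming_rate`` is the per-read probability of priming at the
    planted genomic A-run instead of the poly(A) tail.
    """

    n_genes: int = 60
    pa_sites_per_utr: int = 2
    site_spacing: int = 400
    cluster_usage: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"naive": (0.3, 0.7), "activated": (0.7, 0.3)}
    )
    n_cells_per_cluster: int = 100
    reads_per_cell: float = 1000.0
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 50.0
    fragment_length_max: int = 600
    read_length: int = 100
    internal_priming_rate: float = 0.05
    planted_pas: bool = True
    intronic_pa_fraction: float = 0.25
    intronic_usage: dict[str, float] = field(
        default_factory=lambda: {"naive": 0.1, "activated": 0.3}
    )
    spacer: int = 1000
    chrom: str = "chr1"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.pa_sites_per_utr <= 3:
            raise ValueError("pa_sites_per_utr must be 1-3")
        for cl, u in self.cluster_usage.items():
            if len(u) != self.pa_sites_per_utr:
                raise ValueError(f"usage of cluster {cl} has wrong length")
            if abs(sum(u) - 1.0) > 1e-9:
                raise ValueError(f"usage of cluster {cl} must sum to 1")
        if self.fragment_length_mean <= self.read_length:
            raise ValueError("fragment mean must exceed read length")
        if not 0 <= self.internal_priming_rate <= 1:
            raise ValueError("internal_priming_rate must be in [0, 1]")

    @property
    def clusters(self) -> list[str]:
        return sorted(self.cluster_usage)


@dataclass
class GeneTruth:
    """Ground truth for one simulated gene.

    Site coordinates are the chromosome position of the 3'-most transcribed
    base (what a recovered peak's 3' edge should approach).
    ``utr_sites`` is ordered proximal -> distal in transcript orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    offset: int               # chromosome offset of the gene block
    length: int               # block length
    utr_sites: list[int]
    decoy_site: int | None
    intronic_site: int | None
    usage: dict[str, tuple[float, ...]]
    intronic_usage: dict[str, float]
    # local (sense) exclusive end coordinates, used for read placement
    utr_local_ends: list[int] = field(default_factory=list, repr=False)
    decoy_local_end: int | None = field(default=None, repr=False)
    intronic_local_end: int | None = field(default=None, repr=False)

    def local_end_to_chrom(self, local_end: int) -> int:
        """Chromosome coordinate of the 3'-most base for a local exclusive
        end coordinate."""
        if self.strand == "+":
            return self.offset + local_end - 1
        return self.offset + self.length - local_end


@dataclass
class Reference:
    genome: dict[str, str]
    genes: list[GeneTruth]
    gtf_lines: list[str]
    config: SimConfig


class SimRead(NamedTuple):
    qname: str
    chrom: str
    start: int
    end: int
    strand: str
    barcode: str
    cluster: str
    gene_id: str
    site_label: str  # "utr<k>", "intronic" or "decoy"
    is_decoy: bool


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------


def _break_runs(seq: str, base: str, sub: str, max_run: int = 5) -> str:
    """Cap homopolymer runs of ``base`` at ``max_run`` by substitution."""
    pat = re.compile(base + "{" + str(max_run + 1) + ",}")

    def fix(m: re.Match) -> str:
        run = m.group(0)
        return "".join(
            sub if (i + 1) % (max_run + 1) == 0 else base
            for i in range(len(run))
        )

    return pat.sub(fix, seq)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    """Random background with A/T homopolymer runs capped below the
    internal-priming filter thresholds."""
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
    return _break_runs(_break_runs(seq, "A", "G"), "T", "C")


def _plant(block: list[str], start: int, motif: str) -> None:
    block[start:start + len(motif)] = list(motif)


def _build_gene(
    config: SimConfig, rng: np.random.Generator, gene_id: str, strand: str,
    offset: int, has_intronic: bool,
) -> tuple[GeneTruth, str, list[tuple[str, int, int]]]:
    """One gene block: truth, sense-local sequence, local features.

    Local layout (sense): exon1 [0,300) fully coding; intron [300,1900)
    optionally carrying an intronic pA site; exon2 with a 100 nt CDS tail
    followed by the 3' UTR holding the pA sites, the decoy A-run and a
    tail. Fragments never span the splice junction by construction
    (every site is >= fragment_length_max into its exon/intron).
    """
    exon2_start = _EXON1_LEN + _INTRON_LEN
    utr_start = exon2_start + _CDS2_LEN
    pa_ends = [
        utr_start + _UTR_LEAD + k * config.site_spacing
        for k in range(config.pa_sites_per_utr)
    ]
    decoy_end = pa_ends[-1] + _DECOY_GAP
    tx_end = decoy_end + _UTR_TAIL
    intronic_end = _EXON1_LEN + _INTRONIC_PA_OFFSET if has_intronic else None

    block = list(_random_seq(rng, tx_end))
    sites = list(pa_ends) + ([intronic_end] if intronic_end else [])
    if config.planted_pas:
        # guarded PAS: AATAAA ending 20 nt upstream of the cleavage base,
        # C-flanked so no filterable A-run can form with the background
        for pe in sites:
            _plant(block, pe - 27, "CAATAAAC")
    _plant(block, decoy_end, "A" * _DECOY_RUN)

    features = [
        ("exon", 0, _EXON1_LEN),
        ("exon", exon2_start, tx_end),
        ("CDS", 0, _EXON1_LEN),
        ("CDS", exon2_start, exon2_start + _CDS2_LEN),
    ]
    seq = "".join(block)
    if strand == "-":
        seq = reverse_complement(seq)

    truth = GeneTruth(
        gene_id=gene_id,
        chrom=config.chrom,
        strand=strand,
        offset=offset,
        length=tx_end,
        utr_sites=[],
        decoy_site=None,
        intronic_site=None,
        usage={c: tuple(u) for c, u in config.cluster_usage.items()},
        intronic_usage=(
            dict(config.intronic_usage) if has_intronic
            else {c: 0.0 for c in config.clusters}
        ),
        utr_local_ends=pa_ends,
        decoy_local_end=decoy_end,
        intronic_local_end=intronic_end,
    )
    truth.utr_sites = [truth.local_end_to_chrom(pe) for pe in pa_ends]
    truth.decoy_site = truth.local_end_to_chrom(decoy_end)
    if intronic_end:
        truth.intronic_site = truth.local_end_to_chrom(intronic_end)
    return truth, seq, features


def _gtf_lines(
    gene: GeneTruth, features: list[tuple[str, int, int]]
) -> list[str]:
    """GTF (1-based inclusive) lines for one gene; local sense features are
    mapped through the block orientation."""

    def to_chrom(s: int, e: int) -> tuple[int, int]:
        if gene.strand == "+":
            return gene.offset + s, gene.offset + e
        return gene.offset + gene.length - e, gene.offset + gene.length - s

    tid = f"{gene.gene_id}.T1"
    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
    rows = [("gene", 0, gene.length), ("transcript", 0, gene.length)] + features
    out = []
    for ftype, s, e in rows:
        cs, ce = to_chrom(s, e)
        out.append(
            f"{gene.chrom}\tsim\t{ftype}\t{cs + 1}\t{ce}\t.\t{gene.strand}\t.\t{attrs}"
        )
    return out


def simulate_reference(config: SimConfig, rng: np.random.Generator | None = None) -> Reference:
    """Generate the genome FASTA content, GTF annotation and per-gene
    truth skeleton for one synthetic experiment."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    n_intronic = int(round(config.intronic_pa_fraction * config.n_genes))
    chrom_parts: list[str] = []
    genes: list[GeneTruth] = []
    gtf: list[str] = ["##description: synthetic 3' tag APA reference"]
    offset = 0
    for g in range(config.n_genes):
        spacer = _random_seq(rng, config.spacer)
        chrom_parts.append(spacer)
        offset += len(spacer)
        gene_id = f"G{g + 1:04d}"
        strand = "+" if g % 2 == 0 else "-"
        truth, seq, feats = _build_gene(
            config, rng, gene_id, strand, offset, has_intronic=g < n_intronic
        )
        genes.append(truth)
        gtf.extend(_gtf_lines(truth, feats))
        chrom_parts.append(seq)
        offset += len(seq)
    chrom_parts.append(_random_seq(rng, config.spacer))
    genome = {config.chrom: "".join(chrom_parts)}
    logger.info(
        "simulated %d genes (%d with intronic pA) on %s (%d bp)",
        config.n_genes, n_intronic, config.chrom, len(genome[config.chrom]),
    )
    return Reference(genome=genome, genes=genes, gtf_lines=gtf, config=config)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _barcode(i: int, length: int = 12) -> str:
    bases = "ACGT"
    return "".join(bases[(i >> (2 * k)) & 3] for k in reversed(range(length)))


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    out = rng.normal(mean, sd, n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _site_menu(gene: GeneTruth, cluster: str, ipr: float):
    """Site labels, local end coordinates and draw probabilities for one
    gene in one cluster (decoy = internal priming, then intronic, then the
    UTR sites by their usage proportions)."""
    labels = ["decoy"]
    ends = [gene.decoy_local_end]
    probs = [ipr]
    iu = gene.intronic_usage.get(cluster, 0.0)
    rest = 1.0 - ipr
    if gene.intronic_local_end is not None and iu > 0:
        labels.append("intronic")
        ends.append(gene.intronic_local_end)
        probs.append(rest * iu)
        rest *= 1.0 - iu
    for k, pe in enumerate(gene.utr_local_ends):
        labels.append(f"utr{k + 1}")
        ends.append(pe)
        probs.append(rest * gene.usage[cluster][k])
    return labels, np.array(ends), np.array(probs)


def simulate_reads(
    config: SimConfig, reference: Reference,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimRead], dict[str, str], pd.DataFrame]:
    """Draw aligned reads: per read a cell (hence cluster), a gene, then a
    pA site by that cluster's usage (or the decoy with probability
    ``internal_priming_rate``); fragment length ~ truncated
    Normal(fragment_length_mean, fragment_length_sd); the read footprint is
    the fragment's 5'-most ``read_length`` bases.

    Returns (reads sorted by coordinate, barcode->cluster table, per-read
    truth table).
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    genes = reference.genes
    clusters = config.clusters
    cell_table: dict[str, str] = {}
    reads: list[SimRead] = []
    truth_rows: list[tuple] = []
    read_i = 0
    for ci, cluster in enumerate(clusters):
        barcodes = [
            _barcode(ci * config.n_cells_per_cluster + j)
            for j in range(config.n_cells_per_cluster)
        ]
        for bc in barcodes:
            cell_table[bc] = cluster
        n_per_cell = rng.poisson(config.reads_per_cell, len(barcodes))
        n_reads = int(n_per_cell.sum())
        cell_of_read = np.repeat(np.arange(len(barcodes)), n_per_cell)
        gene_of_read = rng.integers(0, len(genes), n_reads)
        frag = _truncated_normal(
            rng, n_reads, config.fragment_length_mean,
            config.fragment_length_sd, config.read_length,
            config.fragment_length_max,
        ).astype(int)
        for gi, gene in enumerate(genes):
            mask = np.flatnonzero(gene_of_read == gi)
            if mask.size == 0:
                continue
            labels, ends, probs = _site_menu(
                gene, cluster, config.internal_priming_rate)
            choice = rng.choice(len(labels), size=mask.size, p=probs)
            local_end = ends[choice]
            local_start = local_end - frag[mask]
            fs, fe = local_start, local_start + config.read_length
            if gene.strand == "+":
                cs, ce = gene.offset + fs, gene.offset + fe
            else:
                cs = gene.offset + gene.length - fe
                ce = gene.offset + gene.length - fs
            for k in range(mask.size):
                qname = f"r{read_i:08d}"
                read_i += 1
                lab = labels[choice[k]]
                reads.append(SimRead(
                    qname=qname, chrom=gene.chrom, start=int(cs[k]),
                    end=int(ce[k]), strand=gene.strand,
                    barcode=barcodes[cell_of_read[mask[k]]], cluster=cluster,
                    gene_id=gene.gene_id, site_label=lab,
                    is_decoy=lab == "decoy",
                ))
                truth_rows.append(reads[-1][:1] + reads[-1][5:])
    reads.sort(key=lambda r: (r.chrom, r.start, r.qname))
    truth = pd.DataFrame(
        truth_rows,
        columns=["qname", "barcode", "cluster", "gene_id", "site_label",
                 "is_decoy"],
    )
    logger.info("simulated %d reads over %d cells", len(reads), len(cell_table))
    return reads, cell_table, truth


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------


def write_fasta(reference: Reference, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(reference: Reference, path: str | Path) -> None:
    Path(path).write_text("\n".join(reference.gtf_lines) + "\n")


def write_sam(
    reads: list[SimRead], reference: Reference, path: str | Path,
    barcode_tag: str = "CB",
) -> None:
    """Write reads as coordinate-sorted SAM (uniquely mapped, NH:i:1)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in reference.genome.items()],
    }
    rlen = reference.config.read_length
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        hdr = out.header
        for r in reads:
            a = pysam.AlignedSegment(header=hdr)
            a.query_name = r.qname
            a.flag = 16 if r.strand == "-" else 0
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigarstring = f"{rlen}M"
            a.set_tags([(barcode_tag, r.barcode, "Z"), ("NH", 1, "i")])
            out.write(a)


def write_cluster_table(cell_table: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tcluster\n")
        for bc in sorted(cell_table):
            fh.write(f"{bc}\t{cell_table[bc]}\n")


def gene_truth_table(reference: Reference) -> pd.DataFrame:
    rows = []
    for g in reference.genes:
        for k, site in enumerate(g.utr_sites, start=1):
            rows.append((g.gene_id, f"utr{k}", g.chrom, site, g.strand))
        if g.intronic_site is not None:
            rows.append((g.gene_id, "intronic", g.chrom, g.intronic_site, g.strand))
        rows.append((g.gene_id, "decoy", g.chrom, g.decoy_site, g.strand))
    return pd.DataFrame(
        rows, columns=["gene_id", "site_label", "chrom", "position", "strand"]
    )


def simulate_experiment(
    config: SimConfig, outdir: str | Path
) -> dict[str, object]:
    """Run the full generator and write FASTA/GTF/SAM/cluster/truth files.

    Returns a dict with the file paths plus the in-memory ``reference``,
    ``reads``, ``cell_table`` and ``read_truth`` objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    reference = simulate_reference(config, rng)
    reads, cell_table, read_truth = simulate_reads(config, reference, rng)

    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "sam": outdir / "reads.sam",
        "clusters": outdir / "clusters.tsv",
        "gene_truth": outdir / "truth_genes.tsv",
        "read_truth": outdir / "truth_reads.tsv",
    }
    write_fasta(reference, paths["fasta"])
    write_gtf(reference, paths["gtf"])
    write_sam(reads, reference, paths["sam"])
    write_cluster_table(cell_table, paths["clusters"])
    gene_truth_table(reference).to_csv(paths["gene_truth"], sep="\t", index=False)
    read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
    return {**paths, "reference": reference, "reads": reads,
            "cell_table": cell_table, "read_truth": read_truth}
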