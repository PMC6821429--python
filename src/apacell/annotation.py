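"""Strand-aware 3' UTR and intronic region construction from a GTF annotation.

3' tag scRNA-seq reads pile up at transcript 3' ends, so every downstream
step works on per-gene sets of disjoint 3' UTR regions (and, for intronic
polyadenylation, intronic regions that are free of any 3' UTR overlap).
Coordinates are 0-based half-open internally; GTF (1-based inclusive) is
converted at the parsing boundary and BED is written natively half-open.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class UTRRegion:
    """One merged, disjoint 3' UTR region of a gene.

    ``utr_id`` is ``"<gene_id>:<k>"`` with ``k`` serial 5'->3' in transcript
    orientation (k=1 is the most upstream region).
    """

    utr_id: str
    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class IntronRegion:
    """A merged intronic region of a gene, clipped free of all 3' UTRs."""

    intron_id: str
    gene_id: str
    interval: GenomicInterval


# ---------------------------------------------------------------------------
# Interval arithmetic (tested against a per-base set oracle)
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as maximal disjoint intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def subtract_intervals(
    intervals: Sequence[tuple[int, int]], mask: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Remove every base covered by ``mask`` from ``intervals`` (clipping,
    not whole-interval dropping)."""
    mask = merge_intervals(mask)
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        cur = s
        for ms, me in mask:
            if me <= cur:
                continue
            if ms >= e:
                break
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def intersect_intervals(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((s, e))
    return merge_intervals(out)


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------


@dataclass
class _Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr3: list[tuple[int, int]]


def _load_transcripts(gtf: str | Path) -> list[_Transcript]:
    db = gffutils.create_db(
        str(gtf),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx: dict[str, _Transcript] = {}
    wanted = ("exon", "CDS", "three_prime_utr", "three_prime_UTR")
    for feat in db.all_features():
        if feat.featuretype not in wanted:
            continue
        tids = feat.attributes.get("transcript_id")
        gids = feat.attributes.get("gene_id")
        if not tids or not gids:
            continue
        tid, gid = tids[0], gids[0]
        rec = tx.get(tid)
        if rec is None:
            rec = tx[tid] = _Transcript(
                tid, gid, feat.seqid, feat.strand, [], [], []
            )
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        if feat.featuretype == "exon":
            rec.exons.append(iv)
        elif feat.featuretype == "CDS":
            rec.cds.append(iv)
        else:
            rec.utr3.append(iv)
    return list(tx.values())


def _transcript_utr3(t: _Transcript) -> list[tuple[int, int]]:
    """Per-transcript 3' UTR intervals, truncated to the last exon."""
    if t.utr3:
        utr = merge_intervals(t.utr3)
    elif t.cds and t.exons:
        if t.strand == "+":
            cds_end = max(e for _, e in t.cds)
            utr = intersect_intervals(t.exons, [(cds_end, max(e for _, e in t.exons))])
        else:
            cds_start = min(s for s, _ in t.cds)
            utr = intersect_intervals(t.exons, [(min(s for s, _ in t.exons), cds_start)])
    else:
        return []
    if not t.exons:
        return utr
    exons = sorted(t.exons)
    last = exons[-1] if t.strand == "+" else exons[0]
    return intersect_intervals(utr, [last])


def _order_5p_to_3p(
    ivs: Sequence[tuple[int, int]], strand: str
) -> list[tuple[int, int]]:
    return sorted(ivs, reverse=(strand == "-"))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_utr_regions(annotation: str | Path | list[_Transcript]) -> list[UTRRegion]:
    """Build per-gene merged, disjoint 3' UTR regions.

    Per transcript, the 3' UTR is resolved from explicit three_prime_utr
    features or from the exon structure downstream of the CDS end, then
    truncated to the transcript's last (3'-most) exon; per gene, the union
    of transcript-level UTRs is merged into maximal disjoint regions and
    numbered 5'->3' in transcript orientation.
    """
    transcripts = (
        annotation
        if isinstance(annotation, list)
        else _load_transcripts(annotation)
    )
    per_gene: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, set[tuple[str, str]]] = defaultdict(set)
    n_skipped = 0
    for t in transcripts:
        utr = _transcript_utr3(t)
        if not utr:
            n_skipped += 1
            continue
        per_gene[t.gene_id].extend(utr)
        meta[t.gene_id].add((t.chrom, t.strand))
    if n_skipped:
        logger.info("skipped %d transcripts with no resolvable 3' UTR", n_skipped)

    regions: list[UTRRegion] = []
    for gene_id in sorted(per_gene):
        locs = meta[gene_id]
        if len({c for c, _ in locs}) > 1:
            logger.warning("gene %s spans multiple chromosomes; skipped", gene_id)
            continue
        if len({s for _, s in locs}) > 1:
            logger.warning("gene %s has contradictory strands; skipped", gene_id)
            continue
        (chrom, strand), = locs
        merged = merge_intervals(per_gene[gene_id])
        for k, (s, e) in enumerate(_order_5p_to_3p(merged, strand), start=1):
            regions.append(
                UTRRegion(
                    utr_id=f"{gene_id}:{k}",
                    gene_id=gene_id,
                    interval=GenomicInterval(chrom, s, e, strand),
                )
            )
    return regions


def build_intron_regions(
    annotation: str | Path | list[_Transcript], utr_regions: Sequence[UTRRegion]
) -> list[IntronRegion]:
    """Per-gene merged introns, with any overlap with any 3' UTR clipped out.

    Introns are the inter-exon gaps of each transcript; partial overlaps
    with UTR regions are clipped rather than removing the whole intron.
    """
    transcripts = (
        annotation
        if isinstance(annotation, list)
        else _load_transcripts(annotation)
    )
    per_gene: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for t in transcripts:
        exons = sorted(t.exons)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if e1 < s2:
                per_gene[t.gene_id].append((e1, s2))
        meta[t.gene_id].add((t.chrom, t.strand))

    utr_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for r in utr_regions:
        utr_by_chrom[r.interval.chrom].append((r.interval.start, r.interval.end))

    regions: list[IntronRegion] = []
    n_clipped = 0
    for gene_id in sorted(per_gene):
        locs = meta[gene_id]
        if len({c for c, _ in locs}) > 1 or len({s for _, s in locs}) > 1:
            logger.warning("gene %s is inconsistently placed; introns skipped", gene_id)
            continue
        (chrom, strand), = locs
        merged = merge_intervals(per_gene[gene_id])
        clipped = subtract_intervals(merged, utr_by_chrom.get(chrom, []))
        if clipped != merged:
            n_clipped += 1
        for k, (s, e) in enumerate(_order_5p_to_3p(clipped, strand), start=1):
            regions.append(
                IntronRegion(
                    intron_id=f"{gene_id}:I{k}",
                    gene_id=gene_id,
                    interval=GenomicInterval(chrom, s, e, strand),
                )
            )
    if n_clipped:
        logger.info("clipped UTR overlaps out of introns of %d genes", n_clipped)
    return regions


def write_bed(regions: Iterable[UTRRegion | IntronRegion], path: str | Path) -> None:
    """Write regions as BED6 (name = region ID, score = 0)."""
    with open(path, "w") as fh:
        for r in regions:
            iv = r.interval
            name = r.utr_id if isinstance(r, UTRRegion) else r.intron_id
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
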