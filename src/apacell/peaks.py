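"""Read pooling, strand-aware peak calling, peak assignment and bimodal
peak splitting for 3' tag scRNA-seq.

Reads from all cells of a cluster are pooled (pseudobulk); peaks are maximal
strand-specific intervals of nonzero footprint coverage (gaps up to
``max_gap`` bridged, pileups below ``min_reads`` discarded). Adjacent pA
sites closer than the typical fragment-length spread end up in one peak;
those are resolved by fitting a two-component Gaussian mixture to the
member-read 3'-end positions and splitting when the modes are separated by
more than ``sd_factor`` fitted standard deviations and at least
``min_separation`` nt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pysam
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .annotation import IntronRegion, UTRRegion

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class ReadRecord(NamedTuple):
    """A uniquely mapped read footprint with its cell/cluster provenance.

    ``three_prime_end`` is the 3'-terminal aligned base in transcript
    orientation: ``end - 1`` on '+', ``start`` on '-'.
    """

    chrom: str
    start: int
    end: int
    strand: str
    cell_barcode: str
    cluster: str
    three_prime_end: int


def make_read(
    chrom: str, start: int, end: int, strand: str, cell_barcode: str = "",
    cluster: str = "",
) -> ReadRecord:
    tpe = end - 1 if strand == "+" else start
    return ReadRecord(chrom, start, end, strand, cell_barcode, cluster, tpe)


@dataclass
class RawPeak:
    """A called coverage interval before region assignment."""

    chrom: str
    strand: str
    start: int
    end: int
    member_positions: np.ndarray  # sorted member-read 3'-end coordinates

    @property
    def n_members(self) -> int:
        return len(self.member_positions)


@dataclass
class Peak:
    """A called peak assigned to a UTR or intron region.

    ``peak_id`` is ``"<region_id>_<j>"`` where j=1 is the 5'-most peak of
    the region in transcript orientation.
    """

    peak_id: str
    region_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    member_positions: np.ndarray = field(repr=False)
    proximal_index: int = 0
    was_split: bool = False

    @property
    def three_prime_edge(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def n_members(self) -> int:
        return len(self.member_positions)


@dataclass(frozen=True)
class GaussianSplitModel:
    """Fitted two-component 1-D Gaussian mixture used to split a peak."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    w1: float
    w2: float
    boundary: float

    def __post_init__(self) -> None:
        if not self.mu1 < self.mu2:
            raise ValueError("component means must satisfy mu1 < mu2")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("mixing weights must sum to 1")
        if not self.mu1 < self.boundary < self.mu2:
            raise ValueError("split boundary must lie between the means")


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


def iter_alignments(
    path: str | Path, barcode_tag: str = "CB"
) -> Iterable[tuple[str, int, int, str, str | None]]:
    """Yield (chrom, start, end, strand, barcode) for uniquely mapped
    primary alignments in a SAM/BAM file; barcode None when the tag is
    missing."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.has_tag("NH") and aln.get_tag("NH") > 1:
                continue
            bc = aln.get_tag(barcode_tag) if aln.has_tag(barcode_tag) else None
            strand = "-" if aln.is_reverse else "+"
            yield (aln.reference_name, aln.reference_start, aln.reference_end,
                   strand, bc)


def pool_reads_by_cluster(
    alignments: str | Path | Iterable,
    cluster_assignment: Mapping[str, str],
    barcode_tag: str = "CB",
) -> tuple[dict[str, list[ReadRecord]], dict]:
    """Pool reads per cell cluster (pseudobulk).

    ``alignments`` is a SAM/BAM path or an iterable of
    (chrom, start, end, strand, barcode) tuples / ReadRecords. Reads whose
    barcode is missing or not in the assignment table are dropped and
    tallied. Raises ``ValueError`` if no read barcode intersects the table.
    """
    if isinstance(alignments, (str, Path)):
        alignments = iter_alignments(alignments, barcode_tag)
    pools: dict[str, list[ReadRecord]] = {
        c: [] for c in sorted(set(cluster_assignment.values()))
    }
    stats = {"n_total": 0, "n_missing_barcode": 0, "n_unassigned_barcode": 0}
    for rec in alignments:
        chrom, start, end, strand, bc = rec[:5]
        stats["n_total"] += 1
        if bc is None:
            stats["n_missing_barcode"] += 1
            continue
        cluster = cluster_assignment.get(bc)
        if cluster is None:
            stats["n_unassigned_barcode"] += 1
            continue
        pools[cluster].append(make_read(chrom, start, end, strand, bc, cluster))
    n_pooled = sum(len(v) for v in pools.values())
    if stats["n_total"] and n_pooled == 0:
        raise ValueError(
            "no read barcode matches the cluster assignment table "
            "(empty barcode intersection)"
        )
    stats["per_cluster"] = {c: len(v) for c, v in pools.items()}
    logger.info(
        "pooled %d reads into %d clusters (%d missing tag, %d unassigned)",
        n_pooled, len(pools), stats["n_missing_barcode"],
        stats["n_unassigned_barcode"],
    )
    return pools, stats


def load_cluster_table(path: str | Path) -> dict[str, str]:
    """Read a barcode -> cluster table (TSV/CSV, optional header)."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split("\t")
            if i == 0 and parts[0].lower() in {"barcode", "cell", "cell_barcode"}:
                continue
            table[parts[0]] = parts[1]
    return table


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------


def call_peaks(
    reads: Iterable[ReadRecord], min_reads: int = 5, max_gap: int = 0
) -> list[RawPeak]:
    """Call maximal strand-specific covered intervals from pooled reads.

    Intervals of nonzero footprint coverage separated by at most ``max_gap``
    bases are merged; intervals with fewer than ``min_reads`` member reads
    are discarded. Each surviving peak records its member-read 3'-end
    positions.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_key: dict[tuple[str, str], list[ReadRecord]] = {}
    for r in reads:
        by_key.setdefault((r.chrom, r.strand), []).append(r)

    peaks: list[RawPeak] = []
    for (chrom, strand), rs in sorted(by_key.items()):
        starts = np.fromiter((r.start for r in rs), int, len(rs))
        ends = np.fromiter((r.end for r in rs), int, len(rs))
        tpe = np.fromiter((r.three_prime_end for r in rs), int, len(rs))
        order = np.argsort(starts, kind="stable")
        starts, ends, tpe = starts[order], ends[order], tpe[order]
        cmax = np.maximum.accumulate(ends)
        breaks = np.flatnonzero(starts[1:] > cmax[:-1] + max_gap) + 1
        bounds = np.concatenate(([0], breaks, [len(rs)]))
        for i0, i1 in zip(bounds[:-1], bounds[1:]):
            if i1 - i0 < min_reads:
                continue
            peaks.append(
                RawPeak(
                    chrom=chrom,
                    strand=strand,
                    start=int(starts[i0]),
                    end=int(cmax[i1 - 1]),
                    member_positions=np.sort(tpe[i0:i1]),
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------


def assign_peaks(
    raw_peaks: Sequence[RawPeak],
    regions: Sequence[UTRRegion | IntronRegion],
) -> tuple[list[Peak], list[RawPeak]]:
    """Assign peaks to regions by same-strand overlap (>= 1 nt).

    Peaks are not clipped to region boundaries. A peak overlapping several
    regions goes to the one with the largest overlap (tie: lexicographically
    lower region ID, logged). Per region, peaks are numbered from 1 at the
    5'-most position in transcript orientation. Returns (assigned,
    unassigned).
    """
    by_key: dict[tuple[str, str], list] = {}
    for r in regions:
        iv = r.interval
        rid = r.utr_id if isinstance(r, UTRRegion) else r.intron_id
        by_key.setdefault((iv.chrom, iv.strand), []).append(
            (iv.start, iv.end, rid, r.gene_id)
        )
    for v in by_key.values():
        v.sort()

    per_region: dict[str, list[RawPeak]] = {}
    region_gene = {}
    unassigned: list[RawPeak] = []
    n_ties = 0
    for pk in raw_peaks:
        cands = []
        for rs, re_, rid, gid in by_key.get((pk.chrom, pk.strand), ()):
            ov = min(pk.end, re_) - max(pk.start, rs)
            if ov > 0:
                cands.append((ov, rid, gid))
        if not cands:
            unassigned.append(pk)
            continue
        best_ov = max(ov for ov, _, _ in cands)
        best = sorted(
            [(rid, gid) for ov, rid, gid in cands if ov == best_ov]
        )
        if len(best) > 1:
            n_ties += 1
        rid, gid = best[0]
        per_region.setdefault(rid, []).append(pk)
        region_gene[rid] = gid
    if n_ties:
        logger.info("%d peaks tied between regions; lower region ID chosen", n_ties)

    assigned: list[Peak] = []
    for rid in sorted(per_region):
        pks = per_region[rid]
        pks.sort(key=lambda p: p.start, reverse=(pks[0].strand == "-"))
        for j, pk in enumerate(pks, start=1):
            assigned.append(
                Peak(
                    peak_id=f"{rid}_{j}",
                    region_id=rid,
                    gene_id=region_gene[rid],
                    chrom=pk.chrom,
                    strand=pk.strand,
                    start=pk.start,
                    end=pk.end,
                    member_positions=pk.member_positions,
                    proximal_index=j,
                )
            )
    return assigned, unassigned


def renumber_peaks(peaks: Sequence[Peak]) -> list[Peak]:
    """Re-assign proximal indices/IDs per region (after splitting)."""
    out: list[Peak] = []
    by_region: dict[str, list[Peak]] = {}
    for p in peaks:
        by_region.setdefault(p.region_id, []).append(p)
    for rid in sorted(by_region):
        pks = by_region[rid]
        pks.sort(key=lambda p: p.start, reverse=(pks[0].strand == "-"))
        for j, p in enumerate(pks, start=1):
            p.proximal_index = j
            p.peak_id = f"{rid}_{j}"
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# Bimodal splitting
# ---------------------------------------------------------------------------


def _fit_two_gaussians(
    positions: np.ndarray, max_iter: int, tol: float, seed: int
) -> GaussianMixture:
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    x = positions.astype(float).reshape(-1, 1)
    q25, q75 = np.percentile(positions, [25, 75])
    var = max(float(np.var(positions)), 1.0)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        weights_init=np.array([0.5, 0.5]),
        means_init=np.array([[q25], [q75]]),
        precisions_init=np.array([[[1.0 / var]], [[1.0 / var]]]),
        max_iter=max_iter,
        tol=tol,
        reg_covar=1e-6,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # non-convergence is handled by leaving the peak unsplit
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(x)
    return gm


def _density_crossing(
    mu1: float, s1: float, w1: float, mu2: float, s2: float, w2: float
) -> float:
    """Coordinate in (mu1, mu2) where the weighted component densities are
    equal; midpoint fallback when no crossing exists in the open interval."""

    def f(x: float) -> float:
        return (np.log(w1) + norm.logpdf(x, mu1, s1)) - (
            np.log(w2) + norm.logpdf(x, mu2, s2)
        )

    lo, hi = mu1 + 1e-9, mu2 - 1e-9
    if f(lo) * f(hi) > 0:
        return 0.5 * (mu1 + mu2)
    return float(brentq(f, lo, hi))


def split_bimodal_peak(
    peak: Peak,
    min_split_reads: int = 20,
    min_separation: float = 75.0,
    sd_factor: float = 3.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[list[Peak], GaussianSplitModel | None]:
    """Split a peak covering two adjacent pA sites into two peaks.

    A two-component Gaussian mixture is fit by EM to the member-read 3'-end
    positions; the peak is split iff the component means are separated by
    more than ``sd_factor`` times the larger fitted standard deviation AND
    by at least ``min_separation`` nt. The split boundary is the coordinate
    between the means where the weighted component densities are equal;
    members are partitioned by position and each sub-peak spans the
    min..max of its members. Returns ([peak], None) when not split.
    """
    pos = peak.member_positions
    if len(pos) < min_split_reads or np.ptp(pos) < 1:
        return [peak], None
    try:
        gm = _fit_two_gaussians(pos, max_iter, tol, seed)
    except Exception as exc:  # pragma: no cover - sklearn numeric failure
        logger.warning("mixture fit failed for %s: %s", peak.peak_id, exc)
        return [peak], None
    if not gm.converged_:
        logger.info("EM did not converge for %s; left unsplit", peak.peak_id)
        return [peak], None
    order = np.argsort(gm.means_.ravel())
    mu1, mu2 = gm.means_.ravel()[order]
    s1, s2 = np.sqrt(gm.covariances_.ravel()[order])
    w1, w2 = gm.weights_[order]
    if min(s1, s2) < 1e-6:
        return [peak], None
    delta = mu2 - mu1
    if not (delta > sd_factor * max(s1, s2) and delta >= min_separation):
        return [peak], None
    boundary = _density_crossing(mu1, s1, w1, mu2, s2, w2)
    left = pos[pos < boundary]
    right = pos[pos >= boundary]
    if len(left) == 0 or len(right) == 0:
        return [peak], None
    model = GaussianSplitModel(
        mu1=float(mu1), mu2=float(mu2), sigma1=float(s1), sigma2=float(s2),
        w1=float(w1), w2=float(w2), boundary=float(boundary),
    )
    subs = []
    for members in (left, right):
        subs.append(
            Peak(
                peak_id=peak.peak_id,
                region_id=peak.region_id,
                gene_id=peak.gene_id,
                chrom=peak.chrom,
                strand=peak.strand,
                start=int(members.min()),
                end=int(members.max()) + 1,
                member_positions=members,
                was_split=True,
            )
        )
    return subs, model


def split_peaks(
    peaks: Sequence[Peak], **kwargs
) -> tuple[list[Peak], dict[str, GaussianSplitModel]]:
    """Apply ``split_bimodal_peak`` to every peak (recursively, so a peak
    covering three sites can resolve further) and renumber per region."""
    models: dict[str, GaussianSplitModel] = {}
    queue = list(peaks)
    done: list[Peak] = []
    while queue:
        pk = queue.pop()
        subs, model = split_bimodal_peak(pk, **kwargs)
        if model is None:
            done.append(pk)
        else:
            models[pk.peak_id] = model
            queue.extend(subs)
    n_split = sum(1 for p in done if p.was_split)
    if models:
        logger.info("split %d peaks into %d sub-peaks", len(models), n_split)
    return renumber_peaks(done), models


# ---------------------------------------------------------------------------
# Benchmarking against reference pA sites and PAS motifs
# ---------------------------------------------------------------------------


def read_site_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """Read single-base reference pA sites from BED6 (chrom, pos, strand)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            sites.append((f[0], int(f[1]), f[5] if len(f) > 5 else "+"))
    return sites


def peak_edge_distance(
    peaks: Sequence[Peak],
    reference_sites: str | Path | Sequence[tuple[str, int, str]],
) -> dict[str, int | None]:
    """Signed distance from each peak's 3' edge to the nearest same-strand
    reference site, in transcript orientation (positive = site downstream
    of the edge); None when the chromosome has no same-strand site."""
    if isinstance(reference_sites, (str, Path)):
        reference_sites = read_site_bed(reference_sites)
    by_key: dict[tuple[str, str], np.ndarray] = {}
    for chrom, pos, strand in reference_sites:
        by_key.setdefault((chrom, strand), []).append(pos)  # type: ignore[attr-defined]
    by_key = {k: np.sort(np.asarray(v)) for k, v in by_key.items()}

    out: dict[str, int | None] = {}
    for pk in peaks:
        sites = by_key.get((pk.chrom, pk.strand))
        if sites is None or len(sites) == 0:
            out[pk.peak_id] = None
            continue
        edge = pk.three_prime_edge
        i = int(np.argmin(np.abs(sites - edge)))
        d = int(sites[i]) - edge
        out[pk.peak_id] = d if pk.strand == "+" else -d
    return out


def fetch_sense(genome, chrom: str, start: int, end: int, strand: str) -> str:
    """Sense-strand sequence of [start, end), clipped to chromosome bounds."""
    n = len(genome[chrom])
    s, e = max(0, start), min(n, end)
    if (s, e) != (start, end):
        logger.debug("window %s:%d-%d clipped to chromosome", chrom, start, end)
    if s >= e:
        return ""
    seq = str(genome[chrom][s:e]).upper()
    return reverse_complement(seq) if strand == "-" else seq


PAS_HEXAMERS = ("AATAAA", "ATTAAA")


def scan_pas_motifs(
    peaks: Sequence[Peak], genome, upstream: int = 30, downstream: int = 120
) -> tuple[dict[str, bool], float]:
    """Scan for the canonical PAS hexamer AATAAA or its variant ATTAAA in
    the sense-strand window from ``upstream`` nt before to ``downstream``
    nt after each peak's 3' edge; returns per-peak hits and overall
    prevalence."""
    hits: dict[str, bool] = {}
    for pk in peaks:
        edge = pk.three_prime_edge
        if pk.strand == "+":
            seq = fetch_sense(genome, pk.chrom, edge - upstream, edge + downstream + 1, "+")
        else:
            seq = fetch_sense(genome, pk.chrom, edge - downstream, edge + upstream + 1, "-")
        hits[pk.peak_id] = any(h in seq for h in PAS_HEXAMERS)
    prevalence = sum(hits.values()) / len(hits) if hits else float("nan")
    return hits, prevalence
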