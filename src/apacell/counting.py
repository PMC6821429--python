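"""Peak-level read counting, CPM normalization, low-usage and
internal-priming filters, and read downsampling.

Internal priming: oligo-dT primers can anneal to genomically encoded
A-rich stretches instead of the poly(A) tail, creating pileups that mimic
pA sites. Such artifacts are recognized by an A-run in the genomic
sequence just downstream of the peak's 3' edge and removed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peaks import Peak, ReadRecord, fetch_sense

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Count matrix container
# ---------------------------------------------------------------------------


@dataclass
class PeakCountMatrix:
    """Raw read counts, peaks x clusters (or peaks x cells).

    ``counts``: integer DataFrame indexed by peak_id.
    ``peaks``: per-peak metadata (region_id, gene_id, proximal_index,
    chrom, start, end, strand, three_prime_edge) indexed by peak_id.
    """

    counts: pd.DataFrame
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate peak IDs in count matrix")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate column labels in count matrix")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self.peaks = self.peaks.loc[self.counts.index]

    def subset(self, peak_ids: Sequence[str]) -> "PeakCountMatrix":
        return PeakCountMatrix(
            self.counts.loc[peak_ids].copy(), self.peaks.loc[peak_ids].copy()
        )

    @property
    def clusters(self) -> list[str]:
        return list(self.counts.columns)


def peak_metadata(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [p.region_id for p in peaks],
            "gene_id": [p.gene_id for p in peaks],
            "proximal_index": [p.proximal_index for p in peaks],
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "strand": [p.strand for p in peaks],
            "three_prime_edge": [p.three_prime_edge for p in peaks],
            "n_members": [p.n_members for p in peaks],
            "was_split": [p.was_split for p in peaks],
        },
        index=pd.Index([p.peak_id for p in peaks], name="peak_id"),
    )


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def _assign_reads_to_peaks(
    peaks_sorted: list[Peak], reads: Sequence[ReadRecord]
) -> np.ndarray:
    """Index of the peak each read counts to (-1 = none).

    A read counts to the peak containing its 3' end; a read overlapping
    peaks without containing its 3' end in any counts to the 5'-most
    (proximal) overlapped peak. Peaks must be same-(chrom,strand), sorted
    by start, pairwise disjoint.
    """
    starts = np.array([p.start for p in peaks_sorted])
    ends = np.array([p.end for p in peaks_sorted])
    r_start = np.fromiter((r.start for r in reads), int, len(reads))
    r_end = np.fromiter((r.end for r in reads), int, len(reads))
    tpe = np.fromiter((r.three_prime_end for r in reads), int, len(reads))

    idx = np.searchsorted(starts, tpe, side="right") - 1
    idx_clip = np.clip(idx, 0, None)
    in_peak = (idx >= 0) & (tpe < ends[idx_clip])
    assigned = np.where(in_peak, idx_clip, -1)

    # fall back to footprint overlap for reads whose 3' end is in no peak
    strand = peaks_sorted[0].strand
    for i in np.flatnonzero(~in_peak):
        k1 = int(np.searchsorted(ends, r_start[i], side="right"))
        k2 = int(np.searchsorted(starts, r_end[i], side="left")) - 1
        if k1 > k2:
            continue
        assigned[i] = k1 if strand == "+" else k2
    return assigned


def count_reads(
    peaks: Sequence[Peak], pools: Mapping[str, Sequence[ReadRecord]]
) -> PeakCountMatrix:
    """Count reads per peak per cluster (columns may equally be cells).

    A read is counted to a peak iff its footprint overlaps the peak on the
    same strand; a read overlapping two peaks is counted to the peak
    containing its 3' end (tie broken toward the proximal peak). Each read
    is counted at most once.
    """
    groups: dict[tuple[str, str], list[Peak]] = {}
    for p in peaks:
        groups.setdefault((p.chrom, p.strand), []).append(p)
    for g in groups.values():
        g.sort(key=lambda p: p.start)

    columns = list(pools.keys())
    peak_ids = [p.peak_id for g in groups.values() for p in g]
    counts = pd.DataFrame(0, index=pd.Index(peak_ids, name="peak_id"),
                          columns=columns, dtype=int)
    for col, reads in pools.items():
        by_key: dict[tuple[str, str], list[ReadRecord]] = {}
        for r in reads:
            by_key.setdefault((r.chrom, r.strand), []).append(r)
        for key, rs in by_key.items():
            g = groups.get(key)
            if not g:
                continue
            assigned = _assign_reads_to_peaks(g, rs)
            hit = assigned[assigned >= 0]
            if len(hit):
                vals = np.bincount(hit, minlength=len(g))
                ids = [p.peak_id for p in g]
                counts.loc[ids, col] += vals
    meta = peak_metadata(sorted(
        peaks, key=lambda p: (p.chrom, p.strand, p.start)))
    return PeakCountMatrix(counts.loc[meta.index], meta)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per column; a zero-total column is an error."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"zero-total column(s) in count matrix: {', '.join(map(str, zero.index))}"
        )
    return counts / totals * 1e6


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

_FILTER_PARAMS = {
    # min total CPM (strict >), min total raw count (>=), A-run length,
    # downstream window (1-based nt from the 3' edge, inclusive)
    "utr": dict(min_cpm=10.0, min_count=None, a_run=8, window=(10, 140)),
    "intron": dict(min_cpm=10.0, min_count=50, a_run=7, window=(1, 200)),
}


def downstream_window_seq(
    genome, chrom: str, edge: int, strand: str, window: tuple[int, int]
) -> str:
    """Sense-strand genomic sequence ``window[0]``..``window[1]`` nt
    downstream of a peak's 3' edge (both offsets inclusive)."""
    w0, w1 = window
    if strand == "+":
        return fetch_sense(genome, chrom, edge + w0, edge + w1 + 1, "+")
    return fetch_sense(genome, chrom, edge - w1, edge - w0 + 1, "-")


def has_a_run(seq: str, min_len: int) -> bool:
    return re.search("A" * min_len, seq.upper()) is not None


def filter_peaks(
    matrix: PeakCountMatrix,
    genome,
    kind: str = "utr",
    min_cpm: float | None = None,
    min_count: int | None = None,
    a_run: int | None = None,
    window: tuple[int, int] | None = None,
) -> tuple[PeakCountMatrix, pd.DataFrame]:
    """Apply the low-usage then the internal-priming filter.

    kind='utr': keep peaks with a total CPM sum over clusters > 10, then
    drop peaks with >= 8 consecutive As in the sense sequence 10-140 nt
    downstream of the 3' edge. kind='intron': keep peaks with a total raw
    count >= 50 AND total CPM >= 10, then drop peaks with >= 7 consecutive
    As 1-200 nt downstream. Returns the filtered matrix and a removal log
    with reasons {low_cpm, low_count, a_run}.
    """
    if kind not in _FILTER_PARAMS:
        raise ValueError(f"kind must be 'utr' or 'intron', got {kind!r}")
    p = dict(_FILTER_PARAMS[kind])
    if min_cpm is not None:
        p["min_cpm"] = min_cpm
    if min_count is not None:
        p["min_count"] = min_count
    if a_run is not None:
        p["a_run"] = a_run
    if window is not None:
        p["window"] = window

    cpm_total = cpm(matrix.counts).sum(axis=1)
    count_total = matrix.counts.sum(axis=1)
    removed: list[tuple[str, str]] = []
    kept: list[str] = []
    for pid in matrix.counts.index:
        if p["min_count"] is not None and count_total[pid] < p["min_count"]:
            removed.append((pid, "low_count"))
        elif kind == "utr" and not cpm_total[pid] > p["min_cpm"]:
            removed.append((pid, "low_cpm"))
        elif kind == "intron" and cpm_total[pid] < p["min_cpm"]:
            removed.append((pid, "low_cpm"))
        else:
            kept.append(pid)

    surviving: list[str] = []
    for pid in kept:
        row = matrix.peaks.loc[pid]
        seq = downstream_window_seq(
            genome, row["chrom"], int(row["three_prime_edge"]), row["strand"],
            p["window"],
        )
        if has_a_run(seq, p["a_run"]):
            removed.append((pid, "a_run"))
        else:
            surviving.append(pid)

    log = pd.DataFrame(removed, columns=["peak_id", "reason"])
    if len(log):
        coords = matrix.peaks.loc[
            log["peak_id"], ["chrom", "strand", "three_prime_edge"]
        ].reset_index(drop=True)
        log = pd.concat([log, coords], axis=1)
    logger.info(
        "%s filter: kept %d / %d peaks (%s)", kind, len(surviving),
        len(matrix.counts),
        ", ".join(f"{r}={n}" for r, n in log["reason"].value_counts().items())
        or "none removed",
    )
    return matrix.subset(surviving), log


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------


def downsample(
    reads: Sequence[ReadRecord], fraction: float, seed: int
) -> list[ReadRecord]:
    """Retain each read independently with probability ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_counts(
    matrix: PeakCountMatrix, prefix: str | Path, fmt: str = "tsv"
) -> None:
    """Write the count matrix as TSV, or MatrixMarket with separate
    row/column label files."""
    prefix = Path(prefix)
    if fmt == "tsv":
        matrix.counts.to_csv(prefix.with_suffix(".tsv"), sep="\t")
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(matrix.counts.values))
        prefix.with_suffix(".rows.txt").write_text(
            "\n".join(matrix.counts.index) + "\n")
        prefix.with_suffix(".cols.txt").write_text(
            "\n".join(map(str, matrix.counts.columns)) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
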