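"""Differential alternative-polyadenylation statistics.

Per multi-peak 3' UTR, differential pA-site usage between cell clusters is
tested with a Pearson chi-squared test of independence on the raw peak
counts, with Benjamini-Hochberg FDR correction across UTRs. Relative
proximal usage is summarized by the proximal polyA usage index

    proximal PUI = log2((C1 + 1) / <C + 1>)

with C1 the proximal-peak count and <.> the geometric mean over all peaks
of the UTR (pseudocount 1 throughout); higher PUI in cluster A than B means
3' UTR shortening in A. Intronic pA usage is tested per intronic peak
against the summed counts CU of the same gene's downstream 3' UTR peaks,
with intronic PUI = log2((Ci + 1) / (CU + 1)).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counting import PeakCountMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Usage indices
# ---------------------------------------------------------------------------


def proximal_pui(counts: Sequence[float] | np.ndarray) -> float:
    """log2((C1+1)/geometric mean(C+1)) over the UTR's peaks, proximal first."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("proximal PUI needs >= 2 peaks")
    if (c < 0).any():
        raise ValueError("negative counts")
    logs = np.log2(c + 1.0)
    return float(logs[0] - logs.mean())


def intronic_pui(ci: float, cu: float) -> float:
    """log2((Ci+1)/(CU+1)): intronic-peak count vs summed downstream 3' UTR
    counts of the same gene."""
    if ci < 0 or cu < 0:
        raise ValueError("negative counts")
    return float(np.log2((ci + 1.0) / (cu + 1.0)))


# ---------------------------------------------------------------------------
# Chi-squared machinery
# ---------------------------------------------------------------------------


def _chi2_table(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-squared on a table with zero-total columns dropped.

    Returns (chi2, p, testable); testable is False when fewer than two
    nonzero rows or columns remain.
    """
    t = np.asarray(table, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    t = t[t.sum(axis=1) > 0, :] if t.size else t
    if t.shape[0] < 2 or t.shape[1] < 2:
        return np.nan, np.nan, False
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p), True


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _min_expected(table: np.ndarray) -> float:
    t = np.asarray(table, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    t = t[t.sum(axis=1) > 0, :] if t.size else t
    if t.shape[0] < 2 or t.shape[1] < 2:
        return np.nan
    exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
    return float(exp.min())


# ---------------------------------------------------------------------------
# Differential 3' UTR usage
# ---------------------------------------------------------------------------


def utr_count_tables(matrix: PeakCountMatrix) -> dict[str, pd.DataFrame]:
    """Per-UTR peak x cluster count tables for UTRs with >= 2 peaks after
    filtering, rows ordered by proximal index."""
    tables: dict[str, pd.DataFrame] = {}
    meta = matrix.peaks
    for rid, sub in meta.groupby("region_id", sort=True):
        if len(sub) < 2:
            continue
        sub = sub.sort_values("proximal_index")
        tables[str(rid)] = matrix.counts.loc[sub.index]
    return tables


def test_differential_usage(
    tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    cluster_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Chi-squared + BH differential pA-site usage across clusters.

    One test per multi-peak UTR on its raw peaks x clusters count table;
    zero-total columns are dropped, tables left with fewer than two nonzero
    rows or two columns are untestable (excluded from the FDR). For
    two-peak UTRs significant at ``alpha`` and a designated
    ``cluster_pair`` (A, B), the direction is called from the proximal PUI:
    PUI_A > PUI_B -> shortened_in_A.
    """
    rows = []
    for utr_id, tab in tables.items():
        vals = tab.values
        chi2, p, testable = _chi2_table(vals)
        row = {
            "utr_id": utr_id,
            "n_peaks": tab.shape[0],
            "chi2": chi2,
            "p": p,
            "testable": testable,
            "min_expected": _min_expected(vals),
        }
        for cl in tab.columns:
            row[f"pui_{cl}"] = proximal_pui(tab[cl].values)
        rows.append(row)
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["q"] = np.nan
    tested = res["testable"].values
    res.loc[tested, "q"] = bh_qvalues(res.loc[tested, "p"].values)
    res["significant"] = res["q"] < alpha

    res["direction"] = "NA"
    if cluster_pair is not None:
        a, b = cluster_pair
        two = res["significant"] & (res["n_peaks"] == 2)
        pa, pb = res[f"pui_{a}"], res[f"pui_{b}"]
        res.loc[two & (pa > pb), "direction"] = f"shortened_in_{a}"
        res.loc[two & (pa < pb), "direction"] = f"lengthened_in_{a}"
    n_sig = int(res["significant"].sum())
    logger.info("differential usage: %d / %d UTRs significant (q < %g)",
                n_sig, int(tested.sum()), alpha)
    return res


def classify_direction(
    counts_a: Sequence[float], counts_b: Sequence[float],
) -> str:
    """Shortening/lengthening call for a two-peak UTR between clusters A, B."""
    ca, cb = np.asarray(counts_a), np.asarray(counts_b)
    if ca.size != 2 or cb.size != 2:
        raise ValueError("direction calls are defined for exactly two peaks")
    pa, pb = proximal_pui(ca), proximal_pui(cb)
    if pa > pb:
        return "shortened_in_A"
    if pa < pb:
        return "lengthened_in_A"
    return "NA"


def binomial_direction_test(n_short: int, n_long: int) -> tuple[float, str]:
    """One-tailed binomial test of a global shortening/lengthening excess.

    p = P(X >= max(n_short, n_long)) with X ~ Binomial(n_short+n_long, 0.5);
    returns (p, tail) with tail the direction of the excess.
    """
    if n_short < 0 or n_long < 0:
        raise ValueError("negative counts")
    n = n_short + n_long
    if n < 1:
        raise ValueError("need at least one direction call")
    k = max(n_short, n_long)
    p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    return float(p), "shortening" if n_short >= n_long else "lengthening"


def compare_pui_distributions(
    groups: Sequence[Sequence[float]], alternative: str = "two-sided"
) -> float:
    """Rank test on PUI distributions: Wilcoxon rank-sum for two groups
    (one-tailed when a direction is pre-registered via ``alternative``),
    Kruskal-Wallis for more."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs >= 1 value")
    if len(groups) == 2:
        return float(
            stats.mannwhitneyu(groups[0], groups[1], alternative=alternative).pvalue
        )
    if alternative != "two-sided":
        raise ValueError("one-tailed alternatives apply to two groups only")
    res = stats.kruskal(*groups)
    # heavy ties can push the H statistic to -0.0 and its p to NaN
    if np.isnan(res.pvalue) and res.statistic <= 0:
        return 1.0
    return float(res.pvalue)


def per_peak_tests(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-peak 2 x K chi-squared tests within one (>2-peak) UTR.

    Each peak's counts are tested against the summed counts of the UTR's
    other peaks across clusters; BH correction within the UTR.
    """
    vals = table.values.astype(float)
    total = vals.sum(axis=0)
    rows = []
    for j, pid in enumerate(table.index):
        two_row = np.vstack([vals[j], total - vals[j]])
        chi2, p, testable = _chi2_table(two_row)
        rows.append({"peak_id": pid, "chi2": chi2, "p": p, "testable": testable})
    res = pd.DataFrame(rows)
    res["q"] = np.nan
    tested = res["testable"].values
    res.loc[tested, "q"] = bh_qvalues(res.loc[tested, "p"].values)
    res["significant"] = res["q"] < alpha
    return res


# ---------------------------------------------------------------------------
# Intronic pA usage
# ---------------------------------------------------------------------------


def _downstream_utr_counts(
    intronic_row: pd.Series, utr_matrix: PeakCountMatrix
) -> pd.Series | None:
    """Summed counts of same-gene 3' UTR peaks downstream (3', in
    transcript orientation) of the intronic peak; None when there are no
    downstream UTR peaks."""
    gene = intronic_row["gene_id"]
    edge = int(intronic_row["three_prime_edge"])
    strand = intronic_row["strand"]
    meta = utr_matrix.peaks
    same_gene = meta[meta["gene_id"] == gene]
    if strand == "+":
        down = same_gene[same_gene["start"] > edge]
    else:
        down = same_gene[same_gene["end"] <= edge]
    if down.empty:
        return None
    return utr_matrix.counts.loc[down.index].sum(axis=0)


def test_intronic_usage(
    intronic_matrix: PeakCountMatrix,
    utr_matrix: PeakCountMatrix,
    alpha: float = 0.05,
    cluster_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Differential intronic vs downstream-3'-UTR pA usage across clusters.

    Per intronic peak, a 2 x K chi-squared on [Ci; CU] with BH correction
    across intronic peaks; direction (for ``cluster_pair`` (A, B)) from the
    intronic PUI: higher in A -> up_in_A.
    """
    rows = []
    n_untestable = 0
    for pid, meta_row in intronic_matrix.peaks.iterrows():
        ci = intronic_matrix.counts.loc[pid]
        cu = _downstream_utr_counts(meta_row, utr_matrix)
        if cu is None or cu.sum() == 0:
            n_untestable += 1
            continue
        cu = cu.reindex(ci.index).fillna(0)
        table = np.vstack([ci.values, cu.values])
        chi2, p, testable = _chi2_table(table)
        row = {
            "intronic_peak_id": pid,
            "gene_id": meta_row["gene_id"],
            "chi2": chi2,
            "p": p,
            "testable": testable,
        }
        for cl in ci.index:
            row[f"Ci_{cl}"] = int(ci[cl])
            row[f"CU_{cl}"] = int(cu[cl])
            row[f"ipui_{cl}"] = intronic_pui(ci[cl], cu[cl])
        rows.append(row)
    if n_untestable:
        logger.info("%d intronic peaks without downstream UTR counts "
                    "(untestable)", n_untestable)
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["q"] = np.nan
    tested = res["testable"].values
    res.loc[tested, "q"] = bh_qvalues(res.loc[tested, "p"].values)
    res["significant"] = res["q"] < alpha
    res["direction"] = "NA"
    if cluster_pair is not None:
        a, b = cluster_pair
        sig = res["significant"]
        res.loc[sig & (res[f"ipui_{a}"] > res[f"ipui_{b}"]), "direction"] = f"up_in_{a}"
        res.loc[sig & (res[f"ipui_{a}"] < res[f"ipui_{b}"]), "direction"] = f"down_in_{a}"
    return res


# ---------------------------------------------------------------------------
# Per-cell analysis
# ---------------------------------------------------------------------------


def per_cell_mean_pui(cell_matrix: PeakCountMatrix) -> pd.Series:
    """Mean proximal PUI per cell over multi-peak UTRs covered by >= 1 read
    in that cell; NaN for cells with no qualifying UTR."""
    cells = cell_matrix.counts.columns
    sums = pd.Series(0.0, index=cells)
    n = pd.Series(0, index=cells)
    meta = cell_matrix.peaks
    for rid, sub in meta.groupby("region_id", sort=True):
        if len(sub) < 2:
            continue
        sub = sub.sort_values("proximal_index")
        m = cell_matrix.counts.loc[sub.index].values.astype(float)
        covered = m.sum(axis=0) >= 1
        logs = np.log2(m + 1.0)
        pui = logs[0] - logs.mean(axis=0)
        sums[covered] += pui[covered]
        n[covered] += 1
    out = sums / n.replace(0, np.nan)
    out.name = "mean_proximal_pui"
    return out
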