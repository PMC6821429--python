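"""Differential APA statistics: PUI formulas, chi-squared and BH against
from-scratch oracles, direction calls, rank/binomial tests, intronic usage
and per-cell mean PUI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

from apacell.apa_stats import (
    bh_qvalues,
    binomial_direction_test,
    classify_direction,
    compare_pui_distributions,
    intronic_pui,
    per_cell_mean_pui,
    per_peak_tests,
    proximal_pui,
    test_differential_usage as differential_usage,
    test_intronic_usage as intronic_usage,
    utr_count_tables,
)
from apacell.counting import PeakCountMatrix, peak_metadata
from test_counting import mk_peak


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def chi2_oracle(table):
    """Pearson chi-squared from first principles: chi2 = sum (O-E)^2 / E."""
    t = np.asarray(table, float)
    t = t[:, t.sum(0) > 0]
    t = t[t.sum(1) > 0, :]
    exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
    stat = ((t - exp) ** 2 / exp).sum()
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, chi2_dist.sf(stat, dof)


def bh_oracle(p):
    """BH step-up adjusted p-values from the definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# PUI formulas
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,expected",
    [
        ((3, 3), 0.0),
        ((7, 1), 1.0),  # log2(8/sqrt(8*2))
        ((0, 0, 0), 0.0),
        ((1, 1), np.log2(2) - np.log2(2)),
        ((15, 3), 1.0),  # log2(16/sqrt(16*4))
        ((63, 0), 3.0),  # log2(64/sqrt(64*1))
    ],
)
def test_proximal_pui_formula(counts, expected):
    assert proximal_pui(counts) == pytest.approx(expected, abs=1e-12)


def test_proximal_pui_matches_definition_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(30):
        c = rng.integers(0, 500, rng.integers(2, 5))
        gm = np.exp(np.mean(np.log(c + 1.0)))
        assert proximal_pui(c) == pytest.approx(
            np.log2((c[0] + 1) / gm), abs=1e-12)


def test_proximal_pui_needs_two_peaks():
    with pytest.raises(ValueError):
        proximal_pui([5])


def test_proximal_pui_monotone_in_proximal_count():
    vals = [proximal_pui((c1, 10, 20)) for c1 in range(0, 50)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_two_peak_pui_identity():
    # for two peaks: PUI = 0.5 * log2((C1+1)/(C2+1))
    rng = np.random.default_rng(1)
    for _ in range(20):
        c1, c2 = rng.integers(0, 1000, 2)
        assert proximal_pui((c1, c2)) == pytest.approx(
            0.5 * np.log2((c1 + 1) / (c2 + 1)), abs=1e-12)


@pytest.mark.parametrize(
    "ci,cu,expected", [(5, 5, 0.0), (3, 7, -1.0), (0, 0, 0.0), (7, 3, 1.0)]
)
def test_intronic_pui_formula(ci, cu, expected):
    assert intronic_pui(ci, cu) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Chi-squared differential usage
# ---------------------------------------------------------------------------


def tables_from(arrays, clusters=("a", "b")):
    return {
        f"u{i}": pd.DataFrame(np.asarray(t),
                              index=[f"u{i}_p{j+1}" for j in range(len(t))],
                              columns=list(clusters))
        for i, t in enumerate(arrays)
    }


def test_perfect_independence_gives_p_one():
    res = differential_usage(tables_from([[[50, 50], [50, 50]]]))
    assert res["chi2"].iloc[0] == pytest.approx(0.0)
    assert res["p"].iloc[0] == pytest.approx(1.0)


def test_chi2_matches_from_scratch_oracle():
    rng = np.random.default_rng(2)
    arrays = [rng.integers(1, 200, (rng.integers(2, 4), 2)) for _ in range(50)]
    res = differential_usage(tables_from(arrays))
    for i, t in enumerate(arrays):
        stat, p = chi2_oracle(t)
        row = res[res["utr_id"] == f"u{i}"].iloc[0]
        assert row["chi2"] == pytest.approx(stat, rel=1e-12)
        assert row["p"] == pytest.approx(p, rel=1e-9)


def test_zero_cluster_column_dropped_and_untestable_excluded():
    res = differential_usage(
        tables_from([[[10, 0], [20, 0]], [[30, 10], [10, 30]]]))
    assert not res[res["utr_id"] == "u0"]["testable"].iloc[0]
    assert np.isnan(res[res["utr_id"] == "u0"]["q"].iloc[0])
    assert res[res["utr_id"] == "u1"]["testable"].iloc[0]


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.random(rng.integers(1, 50))
        assert np.allclose(bh_qvalues(p), bh_oracle(p), atol=1e-12)


def test_null_tables_are_controlled():
    rng = np.random.default_rng(4)
    arrays = [
        np.stack([rng.multinomial(300, [0.4, 0.6]),
                  rng.multinomial(300, [0.4, 0.6])], axis=1)
        for _ in range(100)
    ]
    res = differential_usage(tables_from(arrays))
    assert (res["p"] < 0.05).mean() <= 0.12  # ~5% expected
    assert res["significant"].sum() <= 1


# ---------------------------------------------------------------------------
# Direction calls and global tests
# ---------------------------------------------------------------------------


def test_direction_from_pui_comparison():
    assert classify_direction((80, 20), (20, 80)) == "shortened_in_A"
    assert classify_direction((20, 80), (80, 20)) == "lengthened_in_A"
    assert classify_direction((50, 50), (50, 50)) == "NA"
    with pytest.raises(ValueError):
        classify_direction((1, 2, 3), (1, 2, 3))


@pytest.mark.parametrize(
    "n_short,n_long,expected",
    [(10, 0, 2.0 ** -10), (1, 0, 0.5),
     (5, 5, sum(__import__("math").comb(10, k) for k in range(5, 11)) / 2 ** 10)],
)
def test_binomial_direction_test(n_short, n_long, expected):
    p, _ = binomial_direction_test(n_short, n_long)
    assert p == pytest.approx(expected, rel=1e-9)


def test_binomial_direction_reports_tail():
    assert binomial_direction_test(10, 2)[1] == "shortening"
    assert binomial_direction_test(2, 10)[1] == "lengthening"


def test_rank_tests_two_and_many_groups():
    rng = np.random.default_rng(5)
    same = rng.normal(0, 1, 200)
    assert compare_pui_distributions([same, same]) > 0.9
    shifted = rng.normal(2, 1, 200)
    assert compare_pui_distributions([same, shifted]) < 1e-6
    assert compare_pui_distributions([same, same, same]) > 0.9
    with pytest.raises(ValueError):
        compare_pui_distributions([same, []])


def test_one_tailed_rank_test_direction():
    rng = np.random.default_rng(6)
    lo, hi = rng.normal(0, 1, 100), rng.normal(1, 1, 100)
    assert compare_pui_distributions([hi, lo], alternative="greater") < 0.01
    assert compare_pui_distributions([hi, lo], alternative="less") > 0.9


# ---------------------------------------------------------------------------
# Per-peak tests
# ---------------------------------------------------------------------------


def test_per_peak_tests_localize_the_shifting_peak():
    rng = np.random.default_rng(7)
    a = rng.multinomial(500, [0.5, 0.3, 0.2])
    b = rng.multinomial(500, [0.2, 0.45, 0.35])  # peak 1 shifts most
    table = pd.DataFrame(np.stack([a, b], 1), index=["p1", "p2", "p3"],
                         columns=["a", "b"])
    res = per_peak_tests(table).set_index("peak_id")
    assert res.loc["p1", "significant"]


def test_proportional_peaks_not_significant():
    table = pd.DataFrame([[100, 200], [50, 100], [25, 50]],
                         index=["p1", "p2", "p3"], columns=["a", "b"])
    res = per_peak_tests(table)
    assert (res["p"] > 0.9).all()


def test_two_peak_case_collapses_to_global_test():
    table = pd.DataFrame([[80, 30], [20, 70]], index=["p1", "p2"],
                         columns=["a", "b"])
    pp = per_peak_tests(table)
    glob = differential_usage({"u": table})
    assert pp["chi2"].iloc[0] == pytest.approx(glob["chi2"].iloc[0], rel=1e-12)
    assert pp["p"].iloc[0] == pytest.approx(glob["p"].iloc[0], rel=1e-9)


# ---------------------------------------------------------------------------
# Intronic usage
# ---------------------------------------------------------------------------


def intronic_fixture(ci_counts, strand="+"):
    """One gene: an intronic peak plus two downstream UTR peaks."""
    clusters = ["a", "b"]
    if strand == "+":
        ipk = mk_peak("g1:I1_1", 100, 200, region="g1:I1")
        u1 = mk_peak("g1:1_1", 1000, 1100)
        u2 = mk_peak("g1:1_2", 1300, 1400)
    else:
        ipk = mk_peak("g1:I1_1", 1000, 1100, strand="-", region="g1:I1")
        u1 = mk_peak("g1:1_1", 500, 600, strand="-")
        u2 = mk_peak("g1:1_2", 200, 300, strand="-")
    im = PeakCountMatrix(
        pd.DataFrame([ci_counts], index=["g1:I1_1"], columns=clusters),
        peak_metadata([ipk]))
    um = PeakCountMatrix(
        pd.DataFrame([[50, 50], [50, 50]], index=["g1:1_1", "g1:1_2"],
                     columns=clusters),
        peak_metadata([u1, u2]))
    return im, um


def test_proportional_intronic_usage_not_significant():
    im, um = intronic_fixture([10, 10])
    res = intronic_usage(im, um, cluster_pair=("a", "b"))
    assert res["p"].iloc[0] > 0.9
    assert res["CU_a"].iloc[0] == 100


def test_elevated_intronic_usage_detected_with_direction():
    im, um = intronic_fixture([10, 100])
    res = intronic_usage(im, um, cluster_pair=("a", "b"))
    stat, p = chi2_oracle([[10, 100], [100, 100]])
    assert res["chi2"].iloc[0] == pytest.approx(stat, rel=1e-12)
    assert res["significant"].iloc[0]
    assert res["direction"].iloc[0] == "down_in_a"  # up in cluster b


def test_minus_strand_downstream_means_lower_coordinates():
    im, um = intronic_fixture([10, 100], strand="-")
    res = intronic_usage(im, um, cluster_pair=("a", "b"))
    # both UTR peaks are genomically below the intronic peak -> CU = 100
    assert res["CU_a"].iloc[0] == 100
    # flip: intronic peak below the UTR peaks -> nothing downstream
    im2, um2 = intronic_fixture([10, 100], strand="-")
    im2.peaks.loc["g1:I1_1", ["start", "end", "three_prime_edge"]] = [0, 100, 0]
    res2 = intronic_usage(im2, um2)
    assert res2.empty


# ---------------------------------------------------------------------------
# Per-cell mean PUI
# ---------------------------------------------------------------------------


def test_per_cell_mean_pui_formula_and_missing():
    peaks = [mk_peak("g1:1_1", 0, 10), mk_peak("g1:1_2", 20, 30),
             mk_peak("g2:1_1", 40, 50, region="g2:1"),
             mk_peak("g2:1_2", 60, 70, region="g2:1")]
    counts = pd.DataFrame(
        {"cell1": [1, 0, 1, 0], "cell2": [0, 0, 0, 0]},
        index=[p.peak_id for p in peaks])
    m = PeakCountMatrix(counts, peak_metadata(peaks))
    res = per_cell_mean_pui(m)
    assert res["cell1"] == pytest.approx(0.5)  # mean of log2(2/sqrt(2))
    assert np.isnan(res["cell2"])


def test_per_cell_mean_pui_separates_simulated_cell_types():
    rng = np.random.default_rng(8)
    n_utr, n_cells = 30, 60
    peaks, rows = [], []
    for g in range(n_utr):
        peaks += [mk_peak(f"g{g}:1_1", g * 100, g * 100 + 10,
                          region=f"g{g}:1"),
                  mk_peak(f"g{g}:1_2", g * 100 + 20, g * 100 + 30,
                          region=f"g{g}:1")]
    cols = {}
    for i in range(n_cells):
        shortened = i < n_cells // 2
        p = 0.8 if shortened else 0.2
        col = []
        for g in range(n_utr):
            n = rng.poisson(3)
            k = rng.binomial(n, p)
            col += [k, n - k]
        cols[f"cell{i}"] = col
    m = PeakCountMatrix(
        pd.DataFrame(cols, index=[p.peak_id for p in peaks]),
        peak_metadata(peaks))
    res = per_cell_mean_pui(m)
    short = res[[f"cell{i}" for i in range(n_cells // 2)]]
    long = res[[f"cell{i}" for i in range(n_cells // 2, n_cells)]]
    assert compare_pui_distributions(
        [short.dropna(), long.dropna()]) < 1e-4
    assert short.mean() > long.mean()


# ---------------------------------------------------------------------------
# utr_count_tables
# ---------------------------------------------------------------------------


def test_utr_count_tables_orders_rows_by_proximal_index():
    peaks = [mk_peak("g1:1_2", 300, 400), mk_peak("g1:1_1", 100, 200),
             mk_peak("g2:1_1", 0, 10, region="g2:1")]
    counts = pd.DataFrame({"a": [3, 1, 9]},
                          index=["g1:1_2", "g1:1_1", "g2:1_1"])
    tables = utr_count_tables(PeakCountMatrix(counts, peak_metadata(peaks)))
    assert list(tables) == ["g1:1"]  # single-peak UTRs excluded
    assert list(tables["g1:1"].index) == ["g1:1_1", "g1:1_2"]
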