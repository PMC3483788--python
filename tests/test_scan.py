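"""Hypergeometric tails and the signed enrichment landscape."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from seedscape.diffexpr import RankedGeneList
from seedscape.scan import (
    EnrichmentLandscape,
    ScanConfig,
    SeedEnrichmentScan,
    hypergeom_tail,
    peak_words,
    signed_landscape_matrix,
)
from seedscape.utrs import UtrRecord, WordCountTable, count_words, fit_markov


def oracle_tail(k: int, K: int, n: int, N: int, tail: str) -> float:
    """Exact tail by enumerating ball counts with integer arithmetic."""
    lo, hi = max(0, n - (N - K)), min(K, n)
    total = comb(N, n)
    rng = range(k, hi + 1) if tail == "enrichment" else range(lo, k + 1)
    return float(sum(Fraction(comb(K, i) * comb(N - K, n - i), total) for i in rng))


def test_hypergeom_tail_enumeration_example():
    # drawing 5 of 10 with 4 special: all 4 special in the draw
    assert hypergeom_tail(4, 4, 5, 10) == pytest.approx(6 / 252, rel=1e-12)


def test_hypergeom_tail_trivial_bounds():
    assert hypergeom_tail(0, 3, 4, 10, "enrichment") == pytest.approx(1.0)
    assert hypergeom_tail(5, 5, 10, 10, "enrichment") == pytest.approx(1.0)  # full draw
    assert hypergeom_tail(3, 3, 4, 10, "depletion") == pytest.approx(1.0)


def test_hypergeom_tail_parameter_validation():
    with pytest.raises(ValueError):
        hypergeom_tail(5, 4, 5, 10)
    with pytest.raises(ValueError):
        hypergeom_tail(1, 11, 5, 10)
    with pytest.raises(ValueError):
        hypergeom_tail(1, 4, 5, 10, tail="sideways")


def test_hypergeom_tail_full_grid_small_n():
    """Both tails agree with the exact enumeration oracle for all N <= 8."""
    for N in range(1, 9):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(max(0, n - (N - K)), min(K, n) + 1):
                    for tail in ("enrichment", "depletion"):
                        assert hypergeom_tail(k, K, n, N, tail) == pytest.approx(
                            oracle_tail(k, K, n, N, tail), rel=1e-10, abs=1e-14
                        )


def _four_utr_setup():
    """Four 10-nt UTRs (4 word positions each), word once in UTR1 and UTR2."""
    w = "GTGCCTT"
    filler = "AAA"
    utrs = [
        UtrRecord("g1", w + filler),
        UtrRecord("g2", w + filler),
        UtrRecord("g3", "ACA" + "CACAGAC"),
        UtrRecord("g4", "TCT" + "CTCTGTC"),
    ]
    counts = count_words(utrs, [w])
    ranked = RankedGeneList(
        ["g1", "g2", "g3", "g4"],
        pd.Series([-2.0, -1.0, 1.0, 2.0], index=["g1", "g2", "g3", "g4"]),
    )
    return utrs, counts, ranked, w


def test_scan_landscape_worked_example():
    """k=2, n=8, K=2, N=16 at the first bin: P = 3003/12870, signed +0.632."""
    _, counts, ranked, w = _four_utr_setup()
    assert (counts.total_positions == 4).all()
    assert counts.aggregate_counts()[w] == 2
    cfg = ScanConfig(bin_step=2, markov_order=0)
    land = SeedEnrichmentScan(ranked, counts, cfg).fit()
    expected_p = 3003 / 12870
    assert land.values.loc[w, 2] == pytest.approx(-np.log10(expected_p), rel=1e-9)
    assert list(land.bin_sizes) == [2, 4]


def test_scan_final_bin_is_full_list_and_value_zero():
    _, counts, ranked, w = _four_utr_setup()
    cfg = ScanConfig(bin_step=3, markov_order=0)  # 4 genes -> bins 3, 4 (partial)
    land = SeedEnrichmentScan(ranked, counts, cfg).fit()
    assert list(land.bin_sizes) == [3, 4]
    # at bin == universe both tails include the whole mass
    assert land.values.loc[w, 4] == pytest.approx(0.0, abs=1e-9)


def test_scan_missing_gene_in_counts_raises():
    _, counts, _, _ = _four_utr_setup()
    ranked = RankedGeneList(["g1", "gX"], pd.Series([-1.0, 1.0], index=["g1", "gX"]))
    with pytest.raises(ValueError, match="without a 3'UTR"):
        SeedEnrichmentScan(ranked, counts, ScanConfig(bin_step=1, markov_order=0))


def test_scan_markov_requires_matching_background():
    utrs, counts, ranked, _ = _four_utr_setup()
    with pytest.raises(ValueError, match="background"):
        SeedEnrichmentScan(ranked, counts, ScanConfig(bin_step=2, markov_order=2))
    bg1 = fit_markov(utrs, 1)
    with pytest.raises(ValueError, match="order"):
        SeedEnrichmentScan(ranked, counts, ScanConfig(bin_step=2, markov_order=2), bg1)


def test_scan_nesting_invariants():
    """Cumulative k and n never decrease with bin size; k <= min(K, n)."""
    rng = np.random.default_rng(0)
    n_genes = 60
    counts = rng.poisson(0.5, size=(n_genes, 3))
    totals = rng.integers(50, 100, size=n_genes)
    csum = np.cumsum(counts, axis=0)
    tsum = np.cumsum(totals)
    assert (np.diff(csum, axis=0) >= 0).all() and (np.diff(tsum) >= 0).all()
    bins = np.arange(5, n_genes + 1, 5)
    signed = signed_landscape_matrix(counts, totals, bins)
    assert np.isfinite(signed).all()


def test_scan_reversed_ranking_mirrors_structure():
    """Reversing the ranking swaps which end shows the enrichment peak."""
    rng = np.random.default_rng(1)
    n_genes = 200
    counts = np.zeros((n_genes, 1), dtype=int)
    counts[:20, 0] = rng.poisson(3, 20) + 1  # word piled at the top
    totals = np.full(n_genes, 300)
    bins = np.arange(20, n_genes + 1, 20)
    fwd = signed_landscape_matrix(counts, totals, bins)
    rev = signed_landscape_matrix(counts[::-1], totals[::-1], bins)
    assert fwd.max() > 3  # enrichment peak on the leading (down) end
    assert rev[0, np.argmax(np.abs(rev[0, :-1]))] < 0  # depletion early when reversed


def test_scan_zero_total_bin_records_zero():
    counts = np.array([[0], [0], [2], [1]])
    totals = np.array([0, 0, 10, 10])
    signed = signed_landscape_matrix(counts, totals, np.array([2, 4]))
    assert signed[0, 0] == 0.0


def test_markov_correction_consistent_on_uniform_background():
    """On composition-neutral sequence K* ~ K, so the corrected landscape
    stays close to the plain hypergeometric one."""
    rng = np.random.default_rng(5)
    utrs = [
        UtrRecord(f"g{i:03d}", "".join(rng.choice(list("ACGT"), size=1500)))
        for i in range(200)
    ]
    word = "ATTTAAT"
    counts = count_words(utrs, [word])
    ranked = RankedGeneList(
        [u.gene_id for u in utrs],
        pd.Series(np.arange(200, dtype=float), index=[u.gene_id for u in utrs]),
    )
    plain = SeedEnrichmentScan(ranked, counts, ScanConfig(bin_step=40, markov_order=0)).fit()
    bg = fit_markov(utrs, 4)
    corr = SeedEnrichmentScan(ranked, counts, ScanConfig(bin_step=40, markov_order=4), bg).fit()
    assert corr.K_effective is not None
    N = counts.aggregate_total
    assert corr.K_effective[word] == pytest.approx(N * 4.0**-7, rel=0.3)
    assert corr.K_effective[word] == pytest.approx(
        counts.aggregate_counts()[word], rel=0.6
    )
    assert np.isfinite(corr.values.to_numpy()).all()
    # here K* < empirical K, so every bin looks (weakly) more enriched
    if corr.K_effective[word] < counts.aggregate_counts()[word]:
        inner = slice(0, len(corr.bin_sizes) - 1)  # final bin pinned near 0
        assert (
            corr.values.loc[word].to_numpy()[inner]
            >= plain.values.loc[word].to_numpy()[inner] - 1e-9
        ).all()


def test_markov_correction_shifts_baseline_expectation():
    """Raising the expected whole-list count makes a leading-bin excess
    less surprising: the enrichment peak shrinks monotonically in K*."""
    rng = np.random.default_rng(6)
    counts = np.zeros((100, 1), dtype=int)
    counts[:10, 0] = 4  # word piled into the leading bin
    counts[10:, 0] = rng.poisson(0.2, 90)
    totals = np.full(100, 400)
    bins = np.arange(10, 101, 10)
    K_emp = int(counts.sum())
    peaks = []
    for K_eff in (K_emp, 2 * K_emp, 4 * K_emp):
        signed = signed_landscape_matrix(counts, totals, bins, np.array([K_eff]))
        peaks.append(signed[0].max())
    assert peaks[0] > peaks[1] > peaks[2]


def test_peak_words_planted_dominates(scenario, scenario_counts, mimic_ranking):
    utrs, lex = scenario.utrs, scenario.lexicon
    bg = fit_markov(utrs, 4)
    land = SeedEnrichmentScan(
        mimic_ranking, scenario_counts, ScanConfig(), bg, lex
    ).fit()
    top = land.peak_words(3)
    planted = scenario.truth.planted_words[scenario.planted_mirna]
    assert top.index[0] == planted
    assert scenario.planted_mirna in top.loc[planted, "mirna_ids"]
    assert len(land.peak_words(0)) == 0
    # summary text mentions the planted word
    assert planted in land.summary()


def test_peak_words_null_below_bonferroni():
    """With no planted structure the extreme word stays under the line."""
    rng = np.random.default_rng(7)
    n_genes, n_words = 300, 20
    counts = pd.DataFrame(
        rng.poisson(0.3, size=(n_genes, n_words)),
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"W{j:02d}" for j in range(n_words)],
    )
    tab = WordCountTable(counts, pd.Series(500, index=counts.index), 7)
    order = list(counts.index)
    rng.shuffle(order)
    ranked = RankedGeneList(order, pd.Series(np.arange(n_genes, dtype=float), index=order))
    land = SeedEnrichmentScan(ranked, tab, ScanConfig(bin_step=30, markov_order=0)).fit()
    top = peak_words(land, 1)
    assert abs(top["peak_signed_log10_p"].iloc[0]) < land.bonferroni_line()


def test_landscape_plot_smoke(tmp_path, scenario, scenario_counts, mimic_ranking):
    import matplotlib

    matplotlib.use("Agg")
    bg = fit_markov(scenario.utrs, 4)
    land = SeedEnrichmentScan(
        mimic_ranking, scenario_counts, ScanConfig(), bg, scenario.lexicon
    ).fit()
    ax = land.plot(highlight=[land.peak_words(1).index[0]])
    ax.figure.savefig(tmp_path / "landscape.png", dpi=60)
    assert (tmp_path / "landscape.png").stat().st_size > 0
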