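"""Moderated t, BH adjustment, probe collapse and ranking."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from seedscape.diffexpr import (
    DifferentialExpression,
    ExpressionMatrix,
    best_probe_per_gene,
    bh_adjust,
    detection_filter,
    rank_genes,
)


def _two_group(n_genes=300, n_a=4, n_b=4, shift_first=0, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(8, 1.5, (n_genes, 1)) + rng.normal(0, 0.5, (n_genes, n_a + n_b))
    vals[:shift_first, :n_a] += delta
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    df = pd.DataFrame(vals, index=[f"g{i:04d}" for i in range(n_genes)], columns=cols)
    cond = {c: ("A" if c.startswith("a") else "B") for c in cols}
    return ExpressionMatrix(df, cond)


# ---------------------------------------------------------------- BH

def test_bh_adjust_hand_worked_example():
    out = bh_adjust([0.005, 0.01, 0.03, 0.04])
    assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])


def test_bh_adjust_degenerate_cases():
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    assert np.allclose(bh_adjust([0.3]), [0.3])
    assert bh_adjust([]).size == 0


def test_bh_adjust_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=50))
def test_bh_adjust_matches_reference_and_dominates_p(pvals):
    ours = bh_adjust(pvals)
    ref = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(ours, ref, atol=0, rtol=0)
    assert (ours >= np.asarray(pvals) - 1e-15).all()
    assert (ours <= 1.0).all()


# ---------------------------------------------------------------- moderated t

def test_moderated_t_identical_group_means_gives_null():
    df = pd.DataFrame(
        {"a0": [1.0, 5], "a1": [2.0, 6], "b0": [1.0, 5], "b1": [2.0, 6]},
        index=["g1", "g2"],
    )
    em = ExpressionMatrix(df, {"a0": "A", "a1": "A", "b0": "B", "b1": "B"})
    res = DifferentialExpression(em).fit(("A", "B"), d0=0)
    assert np.allclose(res.table["t"], 0)
    assert np.allclose(res.table["p_value"], 1)


def test_moderated_t_zero_variance_needs_shrinkage():
    df = pd.DataFrame({"a0": [1.0], "a1": [1.0], "b0": [2.0], "b1": [2.0]}, index=["g"])
    em = ExpressionMatrix(df, {"a0": "A", "a1": "A", "b0": "B", "b1": "B"})
    with pytest.raises(ValueError, match="zero residual variance"):
        DifferentialExpression(em).fit(("A", "B"), d0=0)
    res = DifferentialExpression(em).fit(("A", "B"), d0=2.0, s0_2=0.5)
    assert np.isfinite(res.table["t"]).all() and abs(res.table["t"].iloc[0]) > 0


def test_moderated_t_d0_zero_equals_classical_pooled_t():
    em = _two_group(seed=3)
    res = DifferentialExpression(em).fit(("A", "B"), d0=0)
    xa = em.values[[c for c in em.values if c.startswith("a")]].to_numpy()
    xb = em.values[[c for c in em.values if c.startswith("b")]].to_numpy()
    t_ref, p_ref = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    assert np.allclose(res.table["t"], t_ref)
    assert np.allclose(res.table["p_value"], p_ref)


def test_moderated_t_null_type_i_error_calibrated():
    """On 500 null genes the p < 0.05 fraction sits in the binomial band."""
    em = _two_group(n_genes=500, seed=4)
    res = DifferentialExpression(em).fit(("A", "B"))
    frac = (res.table["p_value"] < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / 500)
    assert frac == pytest.approx(0.05, abs=3 * se)


def test_moderated_t_matches_limma_ebayes():
    """Independent cross-check against the Bioconductor implementation."""
    em = _two_group(n_genes=200, shift_first=20, delta=1.0, seed=42)
    res = DifferentialExpression(em).fit(("A", "B"))
    mat_path, ref_path = "/tmp/seedscape_limma_mat.tsv", "/tmp/seedscape_limma_ref.tsv"
    em.values.to_csv(mat_path, sep="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim('{mat_path}', row.names=1))
        design <- cbind(A=as.integer(startsWith(colnames(m),'a')),
                        B=as.integer(startsWith(colnames(m),'b')))
        fit <- eBayes(contrasts.fit(lmFit(m, design), makeContrasts(A-B, levels=design)))
        write.table(data.frame(t=fit$t[,1], p=fit$p.value[,1]),
                    '{ref_path}', sep='\\t', quote=FALSE)
    """)
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    ref = pd.read_csv(ref_path, sep="\t", index_col=0)
    assert np.allclose(res.table["t"], ref["t"], rtol=1e-6)
    assert np.allclose(res.table["p_value"], ref["p"], rtol=1e-6)


def test_moderated_t_requires_two_samples_per_group():
    em = _two_group(n_a=4, n_b=4)
    model = DifferentialExpression(em)
    with pytest.raises(ValueError, match=">= 2 samples"):
        model.fit(("A", "missing"))


def test_de_results_invariants(mimic_de):
    tab = mimic_de.table
    assert (tab["adjusted_p"] >= tab["p_value"] - 1e-15).all()
    assert (tab["adjusted_p"] <= 1).all()
    # adjusted p is non-decreasing in p rank
    ordered = tab.sort_values("p_value")["adjusted_p"].to_numpy()
    assert (np.diff(ordered) >= -1e-12).all()


# ---------------------------------------------------------------- filters

def test_detection_filter_threshold_semantics():
    em = _two_group(n_genes=6)
    em.detection_p = pd.Series(
        [0.0, 0.005, 0.01, 0.02, 0.5, 0.0099], index=em.values.index
    )
    uni = detection_filter(em, alpha=0.01)
    assert uni == {"g0000", "g0001", "g0005"}  # strict <


def test_detection_filter_all_detected_and_none_detected():
    em = _two_group(n_genes=5)
    em.detection_p = pd.Series(0.0, index=em.values.index)
    assert detection_filter(em) == set(em.values.index)
    em.detection_p = pd.Series(0.5, index=em.values.index)
    with pytest.warns(UserWarning, match="every gene"):
        assert detection_filter(em) == set()


def test_detection_filter_missing_values_instructs():
    em = _two_group(n_genes=5)
    with pytest.raises(ValueError, match="no-detection-filter"):
        detection_filter(em)


def test_best_probe_per_gene_rules():
    rows = pd.DataFrame(
        {
            "probe_id": ["p2", "p1", "p3", "p5", "p4"],
            "gene_id": ["gA", "gA", "gB", "gC", "gC"],
            "adjusted_p": [0.2, 0.01, 0.3, 0.07, 0.07],
            "t": [1.0, -2.0, 0.5, 1.1, 1.2],
        }
    )
    out = best_probe_per_gene(rows)
    assert out.loc["gA", "probe_id"] == "p1"  # smallest adjusted p wins
    assert out.loc["gB", "probe_id"] == "p3"  # singleton unchanged
    assert out.loc["gC", "probe_id"] == "p4"  # tie -> lexicographic probe id
    assert len(out) == 3


# ---------------------------------------------------------------- ranking

def test_rank_genes_order_and_ties():
    tab = pd.DataFrame(
        {
            "logFC": [0.1, -1, 0.2, 0.0],
            "t": [0.0, -2.0, 3.0, 0.0],
            "p_value": [1, 0.1, 0.01, 1],
            "adjusted_p": [1, 0.2, 0.04, 1],
        },
        index=["gz", "gm", "gu", "ga"],
    )
    from seedscape.diffexpr import DEResults

    de = DEResults(tab, ("A", "B"), 0, 0, 6)
    ranked = rank_genes(de)
    assert ranked.gene_ids == ["gm", "ga", "gz", "gu"]  # ties alphabetical
    # permuting input leaves the ranking unchanged
    de2 = DEResults(tab.iloc[[2, 0, 3, 1]], ("A", "B"), 0, 0, 6)
    assert rank_genes(de2).gene_ids == ranked.gene_ids
    assert rank_genes(de, restrict_to={"gm", "gu"}).gene_ids == ["gm", "gu"]


def test_rank_genes_nan_statistic_raises():
    from seedscape.diffexpr import DEResults

    tab = pd.DataFrame(
        {"logFC": [0.0], "t": [np.nan], "p_value": [1.0], "adjusted_p": [1.0]},
        index=["gx"],
    )
    with pytest.raises(ValueError, match="gx"):
        rank_genes(DEResults(tab, ("A", "B"), 0, 0, 6))


def test_expression_matrix_validation():
    df = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
    with pytest.raises(ValueError, match="without condition"):
        ExpressionMatrix(df, {"s1": "A"})
    df_nan = pd.DataFrame({"s1": [np.nan], "s2": [2.0]}, index=["g"])
    with pytest.raises(ValueError, match="missing"):
        ExpressionMatrix(df_nan, {"s1": "A", "s2": "B"})
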