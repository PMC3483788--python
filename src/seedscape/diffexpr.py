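"""Differential expression: moderated t, BH adjustment, gene ranking.

The centrepiece is :class:`DifferentialExpression`, a model object built
from a normalised log2 expression matrix and a sample->condition design.
``fit(contrast)`` performs a two-group comparison per gene with
empirical-Bayes variance shrinkage: the gene-wise residual variance
s_g^2 (d_g = nA + nB - 2 df) is shrunk toward a prior s0^2 with d0 prior
df,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g    = (meanA - meanB) / (s~_g * sqrt(1/nA + 1/nB))

and two-sided P-values come from a t distribution with d0 + d_g df.
d0 and s0 are estimated by moment matching on log sample variances
(scaled-F / log-chi-square theory, digamma/trigamma inversion); with
d0 = 0 the statistic reduces to the classical pooled two-sample t.

P-values are adjusted with the Benjamini-Hochberg step-up procedure,
and genes are ranked most-downregulated first by the t statistic — the
ordering the seed-enrichment landscape scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ExpressionMatrix",
    "DifferentialExpression",
    "DEResults",
    "RankedGeneList",
    "bh_adjust",
    "detection_filter",
    "best_probe_per_gene",
    "rank_genes",
]


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("P-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] / (np.arange(1, m + 1) / m)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with condition labels.

    `detection_p` optionally carries per-gene, per-condition detection
    P-values (minimum over samples of a condition is what the filter
    uses; a plain per-gene Series is also accepted).
    """

    values: pd.DataFrame
    conditions: Mapping[str, str]
    detection_p: pd.DataFrame | pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition labels: {missing}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]


def detection_filter(
    matrix: ExpressionMatrix,
    alpha: float = 0.01,
    conditions: Sequence[str] | None = None,
) -> set[str]:
    """Detected-gene universe: detection P < alpha in >= 1 contrasted condition.

    This set is the background universe for downstream overlap tests.
    Strict inequality; raises when no detection P-values are attached.
    """
    det = matrix.detection_p
    if det is None:
        raise ValueError(
            "no detection P-values on this matrix; pass detection values or "
            "disable the detection filter (--no-detection-filter)"
        )
    if isinstance(det, pd.Series):
        hit = det < alpha
    else:
        cols = list(det.columns if conditions is None else conditions)
        hit = (det[cols] < alpha).any(axis=1)
    universe = set(matrix.gene_ids[hit.reindex(matrix.gene_ids, fill_value=False)])
    if not universe:
        warnings.warn("detection filter removed every gene", stacklevel=2)
    return universe


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for all x > 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / np.maximum(y, 1e-12) < 1e-10):
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match d0, s0^2 from gene-wise variances with `df` residual df.

    Works on z = log s2: E z = log s0^2 + psi(d_g/2) - psi(d0/2)
    + log(d0/d_g) terms; var z = psi'(d_g/2) + psi'(d0/2).  Genes with
    zero variance are dropped from estimation (but still shrunk).
    Returns (inf, mean) when the log-variances underdisperse the
    theoretical chi-square spread (no evidence of variance heterogeneity).
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return 0.0, float(s2.mean()) if s2.size else 0.0
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        # variances are homogeneous: infinite prior df, all genes share s0
        s0_2 = float(np.exp(emean))
        return float("inf"), s0_2
    d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_2


@dataclass
class DEResults:
    """Per-gene differential-expression results for one contrast.

    `table` columns: logFC (A - B), t, p_value, adjusted_p. The
    shrinkage hyperparameters actually used are exposed as d0 / s0_2.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    d0: float
    s0_2: float
    df_residual: float

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def significant(self, alpha: float = 0.05, direction: str | None = None) -> pd.DataFrame:
        sel = self.table["adjusted_p"] < alpha
        if direction == "down":
            sel &= self.table["logFC"] < 0
        elif direction == "up":
            sel &= self.table["logFC"] > 0
        elif direction is not None:
            raise ValueError("direction must be 'down', 'up' or None")
        return self.table[sel]

    def summary(self, top: int = 10) -> str:
        a, b = self.contrast
        t = self.table
        lines = [
            "Differential expression (moderated t)",
            f"  contrast:        {a} - {b}",
            f"  genes:           {len(t)}",
            f"  prior df d0:     {self.d0:.4g}",
            f"  prior var s0^2:  {self.s0_2:.4g}",
            f"  residual df:     {self.df_residual:.4g}",
            f"  adj. P < 0.05:   {(t['adjusted_p'] < 0.05).sum()}"
            f" ({(t['adjusted_p'] < 0.05).mean() * 100:.1f}%)",
            "",
            t.reindex(t["adjusted_p"].sort_values().index).head(top).to_string(),
        ]
        return "\n".join(lines)


class DifferentialExpression:
    """Two-group moderated-t model over an expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Normalised log2 expression with sample condition labels.
    """

    def __init__(self, matrix: ExpressionMatrix):
        self.matrix = matrix

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        conditions: Mapping[str, str],
        detection_p: pd.DataFrame | pd.Series | None = None,
    ) -> "DifferentialExpression":
        return cls(ExpressionMatrix(values, conditions, detection_p))

    def fit(
        self,
        contrast: tuple[str, str],
        d0: float | None = None,
        s0_2: float | None = None,
    ) -> DEResults:
        """Fit the contrast `conditionA - conditionB`.

        `d0`/`s0_2` override the empirical-Bayes prior (d0 = 0 gives the
        classical pooled t).  A zero-variance gene with d0 = 0 is an
        error; any d0 > 0 regularises it to a finite statistic.
        """
        cond_a, cond_b = contrast
        cols_a = self.matrix.samples_for(cond_a)
        cols_b = self.matrix.samples_for(cond_b)
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValueError(
                f"need >= 2 samples per condition, got {len(cols_a)} "
                f"{cond_a!r} and {len(cols_b)} {cond_b!r}"
            )
        xa = self.matrix.values[cols_a].to_numpy(float)
        xb = self.matrix.values[cols_b].to_numpy(float)
        na, nb = xa.shape[1], xb.shape[1]
        dg = na + nb - 2
        diff = xa.mean(axis=1) - xb.mean(axis=1)
        ssq = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (xb - xb.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        s2 = ssq / dg

        if d0 is None:
            d0_est, s0_est = _fit_variance_prior(s2, dg)
        else:
            d0_est, s0_est = float(d0), float(s0_2 if s0_2 is not None else 0.0)
        if d0_est > 0 and s0_est <= 0:
            raise ValueError("s0_2 must be positive when d0 > 0")

        if np.isinf(d0_est):
            s2_post = np.full_like(s2, s0_est)
            df_total = np.inf
        elif d0_est == 0:
            if np.any(s2 == 0):
                bad = list(self.matrix.gene_ids[s2 == 0][:5])
                raise ValueError(
                    f"zero residual variance with d0 = 0 for genes {bad}; "
                    "use d0 > 0 to regularise"
                )
            s2_post = s2
            df_total = float(dg)
        else:
            s2_post = (d0_est * s0_est + dg * s2) / (d0_est + dg)
            df_total = d0_est + dg

        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.minimum(p, 1.0)
        table = pd.DataFrame(
            {
                "logFC": diff,
                "t": t,
                "p_value": p,
                "adjusted_p": bh_adjust(p),
            },
            index=self.matrix.gene_ids,
        )
        return DEResults(
            table=table,
            contrast=(cond_a, cond_b),
            d0=d0_est,
            s0_2=s0_est,
            df_residual=float(dg),
        )


def best_probe_per_gene(probe_results: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene.

    Expects columns probe_id, gene_id, adjusted_p (other columns carried
    through).  Keeps the probe with the smallest adjusted P; ties break
    by lexicographically smaller probe_id.
    """
    required = {"probe_id", "gene_id", "adjusted_p"}
    missing = required - set(probe_results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = probe_results.sort_values(
        ["gene_id", "adjusted_p", "probe_id"], kind="mergesort"
    )
    return df.groupby("gene_id", sort=True).head(1).set_index("gene_id")


@dataclass
class RankedGeneList:
    """Genes ordered most-downregulated first by a ranking statistic."""

    gene_ids: list[str]
    statistic: pd.Series

    def __post_init__(self) -> None:
        if list(self.statistic.index) != self.gene_ids:
            self.statistic = self.statistic.reindex(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def reversed(self) -> "RankedGeneList":
        """The upregulated-end-first ordering (for trailing-end scans)."""
        return RankedGeneList(self.gene_ids[::-1], self.statistic.iloc[::-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "statistic": self.statistic.to_numpy()}
        )


def rank_genes(de: DEResults, restrict_to: set[str] | None = None) -> RankedGeneList:
    """Order genes by ascending moderated t (most downregulated first).

    Ties break alphabetically by gene id, so the ordering is independent
    of input order.  `restrict_to` drops genes outside a universe (e.g.
    genes without a 3'UTR, which are excluded from the scan).
    """
    t = de.table["t"]
    if t.isna().any():
        bad = list(t.index[t.isna()][:10])
        raise ValueError(f"NaN ranking statistic for genes {bad}")
    if restrict_to is not None:
        t = t[t.index.isin(restrict_to)]
    ordered = t.iloc[np.lexsort((t.index.to_numpy(), t.to_numpy()))]
    return RankedGeneList(list(ordered.index), ordered)
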