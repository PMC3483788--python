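"""Ranked-list word-enrichment landscapes (Sylamer-style analysis).

Given genes ordered most-downregulated to most-upregulated and per-gene
word counts over their 3'UTRs, the scan grows a *leading bin* of the
ranking in fixed increments and, at each bin size, tests every lexicon
word with a hypergeometric tail: the urn contains all word positions of
the whole list (N, of which K spell the word), the draw is the word
positions of the leading bin (n, of which k spell the word).  The
landscape records, per word and bin, the signed value

    +|log10 P_enrichment|  if the enrichment tail P(X >= k) is smaller,
    -|log10 P_depletion|   if the depletion tail P(X <= k) is smaller,

so a word whose sites pile up among downregulated transcripts rises as a
positive peak early in the ranking.  An optional Markov background
(order 4 by default) replaces the empirical whole-list count K with the
composition-expected count K* = round(p_word * N), removing biases a
word inherits from mono- through 4-mer composition.

All tails are evaluated in log space; totals accumulate over word
positions (not sequences), so bin statistics are additive and nested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .diffexpr import RankedGeneList
from .seeds import SeedLexicon
from .utrs import MarkovModel, WordCountTable, markov_word_probability

__all__ = [
    "ScanConfig",
    "EnrichmentLandscape",
    "SeedEnrichmentScan",
    "hypergeom_tail",
    "hypergeom_log10_tail",
    "peak_words",
]

_LN10 = np.log(10.0)


def _check_params(k, K, n, N) -> None:
    k, K, n, N = (np.asarray(x) for x in (k, K, n, N))
    if np.any(K > N) or np.any(n > N):
        raise ValueError("require K <= N and n <= N")
    if np.any(k < 0) or np.any(k > np.minimum(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")


def _log10_both_tails(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """(log10 P(X >= k), log10 P(X <= k)) by summation over the support.

    The log pmf over the whole support comes from gammaln; each tail is
    a logsumexp of its side.  Exact to floating precision — scipy's
    generic discrete sf is prohibitively slow at the problem sizes a
    landscape scan hits (word-position universes in the millions).
    """
    lo = max(0, n - (N - K))
    hi = min(K, n)
    i = np.arange(lo, hi + 1)
    lg = special.gammaln
    logpmf = (
        lg(K + 1) - lg(i + 1) - lg(K - i + 1)
        + lg(N - K + 1) - lg(n - i + 1) - lg(N - K - n + i + 1)
        - (lg(N + 1) - lg(n + 1) - lg(N - n + 1))
    )
    j = k - lo
    upper = special.logsumexp(logpmf[j:])
    lower = special.logsumexp(logpmf[: j + 1])
    # each tail includes the point mass, so both are <= 0 up to roundoff
    return float(min(upper, 0.0) / _LN10), float(min(lower, 0.0) / _LN10)


def hypergeom_log10_tail(k, K, n, N, tail: str = "enrichment"):
    """log10 of a hypergeometric tail, computed in log space.

    X ~ Hypergeometric(N population, K successes, n draws).
    tail="enrichment": P(X >= k); tail="depletion": P(X <= k).
    Scalar parameters or broadcastable arrays.
    """
    if tail not in ("enrichment", "depletion"):
        raise ValueError("tail must be 'enrichment' or 'depletion'")
    _check_params(k, K, n, N)
    k_a, K_a, n_a, N_a = np.broadcast_arrays(
        *(np.asarray(x, dtype=np.int64) for x in (k, K, n, N))
    )
    out = np.empty(k_a.shape, dtype=float)
    it = np.nditer([k_a, K_a, n_a, N_a], flags=["multi_index"])
    for kv, Kv, nv, Nv in it:
        enr, dep = _log10_both_tails(int(kv), int(Kv), int(nv), int(Nv))
        out[it.multi_index] = enr if tail == "enrichment" else dep
    return out if out.shape else float(out)


def hypergeom_tail(k: int, K: int, n: int, N: int, tail: str = "enrichment") -> float:
    """Hypergeometric tail probability (see :func:`hypergeom_log10_tail`)."""
    return float(10.0 ** hypergeom_log10_tail(k, K, n, N, tail))


@dataclass
class ScanConfig:
    """Parameters of the landscape scan.

    bin_step: ranked-list positions added per step (genes). word_length
    must exceed markov_order; markov_order 0 disables the composition
    correction and gives the plain hypergeometric on empirical counts.
    """

    word_length: int = 7
    bin_step: int = 100
    markov_order: int = 4
    tail: str = "both"

    def __post_init__(self) -> None:
        if self.bin_step < 1:
            raise ValueError("bin_step must be >= 1")
        if self.markov_order < 0:
            raise ValueError("markov_order must be >= 0")
        if self.word_length <= self.markov_order:
            raise ValueError("word_length must exceed markov_order")


def signed_landscape_matrix(
    count_mat: np.ndarray,
    totals: np.ndarray,
    bin_sizes: np.ndarray,
    K_eff: np.ndarray | None = None,
) -> np.ndarray:
    """Signed log10 landscape values for pre-ordered counts.

    count_mat: (genes x words) occurrence counts in ranking order;
    totals: per-gene countable word positions; bin_sizes: leading-bin
    gene counts; K_eff: per-word whole-list success counts (defaults to
    the empirical column sums).  Returns (words x bins).  Bins with zero
    total positions get signed value 0.  Where an adjusted K_eff places
    the observed k outside the hypergeometric support, k is clamped to
    the support so values stay finite.
    """
    csum = np.cumsum(count_mat, axis=0)  # genes x words
    tsum = np.cumsum(totals)
    idx = bin_sizes - 1
    k = csum[idx, :].T.astype(np.int64)  # words x bins
    n = tsum[idx].astype(np.int64)  # bins
    N = int(tsum[-1])
    K = count_mat.sum(axis=0).astype(np.int64) if K_eff is None else np.asarray(K_eff, dtype=np.int64)
    n_b = np.broadcast_to(n, k.shape)
    K_b = np.broadcast_to(K[:, None], k.shape)
    lo = np.maximum(0, n_b - (N - K_b))
    hi = np.minimum(n_b, K_b)
    k_c = np.clip(k, lo, hi)
    signed = np.empty(k.shape, dtype=float)
    for w in range(k.shape[0]):
        for b in range(k.shape[1]):
            lp_enr, lp_dep = _log10_both_tails(
                int(k_c[w, b]), int(K_b[w, b]), int(n_b[w, b]), N
            )
            signed[w, b] = -lp_enr if lp_enr <= lp_dep else lp_dep
    signed[:, n == 0] = 0.0
    return signed


@dataclass
class EnrichmentLandscape:
    """Results object: per word x leading-bin signed log10 P-values.

    `values` is a words x bins DataFrame (columns = bin sizes in genes).
    Positive = enrichment at the downregulated end of the ranking,
    negative = depletion.
    """

    values: pd.DataFrame
    bin_sizes: np.ndarray
    config: ScanConfig
    lexicon: SeedLexicon | None = None
    K_effective: pd.Series | None = None

    @property
    def words(self) -> list[str]:
        return list(self.values.index)

    def bonferroni_line(self, alpha: float = 0.05) -> float:
        """-log10 of alpha Bonferroni-corrected over words x bins."""
        return float(-np.log10(alpha / self.values.size))

    def peak_table(self) -> pd.DataFrame:
        """Per word: most extreme signed value and the bin where it occurs."""
        arr = self.values.to_numpy()
        j = np.abs(arr).argmax(axis=1)
        peaks = arr[np.arange(arr.shape[0]), j]
        out = pd.DataFrame(
            {
                "word": self.values.index,
                "peak_signed_log10_p": peaks,
                "peak_bin": self.bin_sizes[j],
            }
        ).set_index("word")
        if self.lexicon is not None:
            rna = {w: w.replace("T", "U") for w in out.index}
            out["mirna_ids"] = [
                ",".join(sorted(self.lexicon.words[rna[w]].mirna_ids))
                if rna[w] in self.lexicon.words
                else ""
                for w in out.index
            ]
        return out

    def peak_words(self, top: int = 10) -> pd.DataFrame:
        """Words ranked by most extreme |signed value| (see peak_table)."""
        return peak_words(self, top)

    def to_long_frame(self) -> pd.DataFrame:
        long = self.values.copy()
        long.columns = self.bin_sizes
        long = long.stack().rename("signed_log10_p").reset_index()
        long.columns = ["word", "bin_size", "signed_log10_p"]
        return long

    def summary(self, top: int = 5) -> str:
        pk = self.peak_words(top)
        lines = [
            "Seed-word enrichment landscape",
            f"  words:            {len(self.words)}",
            f"  bins:             {len(self.bin_sizes)} (step {self.config.bin_step},"
            f" full list {int(self.bin_sizes[-1])} genes)",
            f"  Markov order:     {self.config.markov_order}",
            f"  Bonferroni line:  {self.bonferroni_line():.2f} (-log10, alpha 0.05)",
            "",
            pk.to_string(),
        ]
        return "\n".join(lines)

    def plot(self, ax=None, highlight: Iterable[str] = (), alpha_line: float | None = 0.05):
        """Landscape plot: x = ranked position, y = signed log10 P.

        Grey lines for every word, coloured lines for `highlight` words
        (DNA or RNA spelling), optional Bonferroni significance lines.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        highlight = {w.replace("U", "T") for w in highlight}
        x = self.bin_sizes
        for w in self.words:
            if w not in highlight:
                ax.plot(x, self.values.loc[w], color="0.75", lw=0.6, zorder=1)
        for w in sorted(highlight & set(self.words)):
            ax.plot(x, self.values.loc[w], lw=1.8, zorder=2, label=w.replace("T", "U"))
        if alpha_line is not None:
            b = self.bonferroni_line(alpha_line)
            ax.axhline(b, ls="--", color="k", lw=0.8)
            ax.axhline(-b, ls="--", color="k", lw=0.8)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("3'UTRs sorted from most down- to most upregulated")
        ax.set_ylabel("signed log10 P")
        if highlight:
            ax.legend(fontsize=8)
        return ax


class SeedEnrichmentScan:
    """Model object tying a ranking, a count table and a background together.

    Parameters
    ----------
    ranked : RankedGeneList
        Most-downregulated-first ordering; every gene must have counts
        (drop UTR-less genes from the ranking beforehand).
    counts : WordCountTable
        Per-gene occurrence counts of the lexicon words.
    config : ScanConfig
    background : MarkovModel, optional
        Required when config.markov_order > 0; its order must match.
    """

    def __init__(
        self,
        ranked: RankedGeneList,
        counts: WordCountTable,
        config: ScanConfig | None = None,
        background: MarkovModel | None = None,
        lexicon: SeedLexicon | None = None,
    ):
        self.config = config or ScanConfig()
        missing = [g for g in ranked.gene_ids if g not in counts.total_positions.index]
        if missing:
            raise ValueError(
                f"{len(missing)} ranked genes missing from the count table "
                f"(first: {missing[:5]}); exclude genes without a 3'UTR"
            )
        if self.config.markov_order > 0:
            if background is None:
                raise ValueError("markov_order > 0 requires a fitted background model")
            if background.order != self.config.markov_order:
                raise ValueError(
                    f"background order {background.order} != configured "
                    f"markov_order {self.config.markov_order}"
                )
        self.ranked = ranked
        self.counts = counts
        self.background = background
        self.lexicon = lexicon

    def _bin_sizes(self) -> np.ndarray:
        n = len(self.ranked)
        step = self.config.bin_step
        sizes = list(range(step, n + 1, step))
        if not sizes or sizes[-1] != n:
            sizes.append(n)  # final partial bin ends the landscape at the full list
        return np.asarray(sizes, dtype=np.int64)

    def fit(self) -> EnrichmentLandscape:
        order = self.ranked.gene_ids
        count_mat = self.counts.counts.loc[order].to_numpy(np.int64)
        totals = self.counts.total_positions.loc[order].to_numpy(np.int64)
        words = list(self.counts.counts.columns)
        if not words:
            raise ValueError("count table has no words")
        bins = self._bin_sizes()
        N = int(totals.sum())
        K_eff = None
        if self.config.markov_order > 0:
            probs = np.array(
                [markov_word_probability(self.background, w) for w in words]
            )
            K_eff = np.clip(np.rint(probs * N).astype(np.int64), 1, N)
        signed = signed_landscape_matrix(count_mat, totals, bins, K_eff)
        values = pd.DataFrame(signed, index=pd.Index(words, name="word"), columns=bins)
        return EnrichmentLandscape(
            values=values,
            bin_sizes=bins,
            config=self.config,
            lexicon=self.lexicon,
            K_effective=None
            if K_eff is None
            else pd.Series(K_eff, index=words, name="K_effective"),
        )


def peak_words(landscape: EnrichmentLandscape, top: int = 10) -> pd.DataFrame:
    """Words ranked by most extreme |signed landscape value|.

    Ties break by word so the ordering is deterministic; `top` rows are
    returned (0 -> empty).  To interrogate the upregulated end of a
    ranking, scan the reversed ranking and call this on that landscape.
    """
    pk = landscape.peak_table()
    pk = pk.assign(_abs=pk["peak_signed_log10_p"].abs())
    pk = pk.sort_values(["_abs", "word"], ascending=[False, True], kind="mergesort")
    return pk.drop(columns="_abs").head(top)
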