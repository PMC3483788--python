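"""3'UTR storage, low-complexity masking, word counting, Markov background.

The hypergeometric machinery downstream treats *word positions* (7-nt
windows of unmasked sequence) as the balls of the urn, so this module's
job is to report, per gene, (a) how many countable windows there are and
(b) how many of them spell each lexicon word.  Overlapping occurrences
count; a window is countable only if it contains no masked base and no
ambiguous base (N).

Masking has two parts, mirroring common practice for composition-bias
removal before motif statistics:

* a DUST-style low-complexity score over sliding windows (triplet
  over-representation), and
* redundancy masking of exact long k-mers shared by many distinct UTRs
  (repeats that survive per-sequence complexity filters).

A fitted Markov model of order m holds exhaustive m-mer and (m+1)-mer
counts over the unmasked sequence universe and yields per-position word
probabilities used for composition correction of expected word counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UtrRecord",
    "WordCountTable",
    "MarkovModel",
    "mask_low_complexity",
    "mask_redundant",
    "count_words",
    "fit_markov",
    "markov_word_probability",
]

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3; anything else (N, masked placeholder) -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[arr]


def _normalize_intervals(
    intervals: Sequence[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Clip to [0, length), drop empties, merge overlaps/adjacency."""
    clipped = sorted(
        (max(0, s), min(length, e)) for s, e in intervals if min(length, e) > max(0, s)
    )
    merged: list[tuple[int, int]] = []
    for s, e in clipped:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class UtrRecord:
    """A 3'UTR sequence with masked intervals (0-based, half-open)."""

    gene_id: str
    sequence: str
    transcript_id: str | None = None
    mask: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        self.mask = _normalize_intervals(self.mask, len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def mask_array(self) -> np.ndarray:
        """Boolean array: True where the base is masked or ambiguous."""
        bad = _encode(self.sequence) < 0
        for s, e in self.mask:
            bad[s:e] = True
        return bad

    def masked_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        return float(self.mask_array().mean())


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def _dust_scores(codes: np.ndarray, window: int) -> np.ndarray:
    """DUST-style score per window start: 10 * sum c(c-1)/2 / (n_triplets-1).

    c are counts of each of the 64 overlapping triplets in the window; a
    homopolymer scores ~10*(n-1)/2 while random sequence hovers around 5.
    Windows containing ambiguous bases score 0 (they are already
    uncountable downstream).
    """
    n = len(codes)
    if n < window:
        window = n
    tri_n = window - 2
    if tri_n < 2:
        return np.zeros(max(0, n - window + 1))
    valid = codes >= 0
    tri_codes = np.where(
        valid[:-2] & valid[1:-1] & valid[2:],
        codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:],
        64,  # sentinel bucket for ambiguous triplets
    )
    scores = np.zeros(n - window + 1)
    counts = np.zeros(65, dtype=np.int64)
    pair_sum = 0  # running sum of c*(c-1)/2 over real triplets
    for i in range(tri_n):
        c = tri_codes[i]
        if c < 64:
            pair_sum += counts[c]
        counts[c] += 1
    scores[0] = pair_sum
    for start in range(1, n - window + 1):
        out_c = tri_codes[start - 1]
        counts[out_c] -= 1
        if out_c < 64:
            pair_sum -= counts[out_c]
        in_c = tri_codes[start + tri_n - 1]
        if in_c < 64:
            pair_sum += counts[in_c]
        counts[in_c] += 1
        scores[start] = pair_sum
    ambiguous = np.zeros(n - window + 1, dtype=bool)
    if (~valid).any():
        bad = (~valid).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(bad)])
        ambiguous = (cs[window:] - cs[: n - window + 1]) > 0
    scores = 10.0 * scores / (tri_n - 1)
    scores[ambiguous] = 0.0
    return scores


def mask_low_complexity(
    record: UtrRecord, threshold: float = 20.0, window: int = 64
) -> UtrRecord:
    """Extend a record's mask with low-complexity windows (DUST-style).

    Any full window whose triplet score exceeds `threshold` is masked.
    The sequence text is unchanged and the operation is idempotent
    (scores ignore existing masks; re-masking the same windows merges).
    The default threshold corresponds to the conventional DUST level 20.
    """
    if window < 4:
        raise ValueError(f"window must be >= 4, got {window}")
    if not record.sequence:
        raise ValueError(f"gene {record.gene_id!r}: empty sequence")
    codes = _encode(record.sequence)
    eff_window = min(window, len(codes))
    scores = _dust_scores(codes, eff_window)
    new = [
        (i, i + eff_window) for i in range(len(scores)) if scores[i] > threshold
    ]
    return replace(record, mask=record.mask + new)


def mask_redundant(
    utrs: Sequence[UtrRecord], kmer: int = 30, max_utrs: int = 5
) -> list[UtrRecord]:
    """Mask exact `kmer`-mers occurring in more than `max_utrs` distinct UTRs.

    Approximates redundancy purging of repetitive fragments shared across
    the UTR set (transposon remnants and the like) that per-sequence
    complexity scores miss.
    """
    if kmer < 7:
        raise ValueError(f"kmer must be >= 7, got {kmer}")
    seen: dict[str, set[int]] = {}
    for idx, rec in enumerate(utrs):
        s = rec.sequence
        for i in range(len(s) - kmer + 1):
            seen.setdefault(s[i : i + kmer], set()).add(idx)
    repeats = {w for w, owners in seen.items() if len(owners) > max_utrs}
    if not repeats:
        return list(utrs)
    out = []
    for rec in utrs:
        s = rec.sequence
        new = [
            (i, i + kmer)
            for i in range(len(s) - kmer + 1)
            if s[i : i + kmer] in repeats
        ]
        out.append(replace(rec, mask=rec.mask + new))
    return out


# ---------------------------------------------------------------------------
# Word counting
# ---------------------------------------------------------------------------

def _window_codes(rec: UtrRecord, k: int) -> np.ndarray:
    """Base-4 codes of countable k-windows; uncountable windows get -1."""
    n = len(rec.sequence)
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = _encode(rec.sequence)
    bad = rec.mask_array()
    codes = np.where(bad, -1, codes)
    ok = codes >= 0
    wcodes = np.zeros(n - k + 1, dtype=np.int64)
    wok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        wcodes = wcodes * 4 + np.where(ok[j : n - k + 1 + j], codes[j : n - k + 1 + j], 0)
        wok &= ok[j : n - k + 1 + j]
    wcodes[~wok] = -1
    return wcodes


def word_code(word: str) -> int:
    codes = _encode(word)
    if (codes < 0).any():
        raise ValueError(f"word {word!r} contains non-ACGT letters")
    code = 0
    for c in codes:
        code = code * 4 + int(c)
    return code


@dataclass
class WordCountTable:
    """Per-gene overlapping-occurrence counts for a fixed word set.

    `counts` is a genes x words integer DataFrame (index gene_id, columns
    DNA-alphabet words); `total_positions` the per-gene number of
    countable windows.  Aggregate totals are sums over genes.
    """

    counts: pd.DataFrame
    total_positions: pd.Series
    word_length: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def words(self) -> list[str]:
        return list(self.counts.columns)

    def aggregate_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def aggregate_total(self) -> int:
        return int(self.total_positions.sum())

    def site_count(self, gene_id: str, words: Iterable[str]) -> int:
        """Total occurrences in `gene_id` over `words` (DNA alphabet)."""
        cols = [w for w in words if w in self.counts.columns]
        if not cols:
            return 0
        return int(self.counts.loc[gene_id, cols].sum())

    def to_long_frame(self) -> pd.DataFrame:
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_0": "gene_id", "level_1": "word"})
        )
        long.columns = ["gene_id", "word", "count"]
        long["total_positions"] = long["gene_id"].map(self.total_positions).astype(int)
        return long


def count_words(
    utrs: Sequence[UtrRecord],
    words: Iterable[str],
    word_length: int = 7,
) -> WordCountTable:
    """Count overlapping occurrences of each word per UTR.

    `words` are DNA-alphabet strings of length `word_length` (a
    :class:`~seedscape.seeds.SeedLexicon` supplies them via
    ``lexicon.dna_words()``).  A window is countable iff fully unmasked
    and unambiguous; genes shorter than the word length get zero totals.
    Ambiguous bases (N) are treated as masked.
    """
    words = list(dict.fromkeys(words))
    for w in words:
        if len(w) != word_length:
            raise ValueError(
                f"word {w!r} has length {len(w)}, expected {word_length}"
            )
    wcode_index = {word_code(w): j for j, w in enumerate(words)}
    genes: list[str] = []
    totals = np.zeros(len(utrs), dtype=np.int64)
    mat = np.zeros((len(utrs), len(words)), dtype=np.int64)
    for i, rec in enumerate(utrs):
        genes.append(rec.gene_id)
        wc = _window_codes(rec, word_length)
        countable = wc[wc >= 0]
        totals[i] = countable.size
        if countable.size and words:
            binc = np.bincount(countable, minlength=4**word_length)
            for code, j in wcode_index.items():
                mat[i, j] = binc[code]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene_id among UTR records")
    return WordCountTable(
        counts=pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=words),
        total_positions=pd.Series(totals, index=genes, name="total_positions"),
        word_length=word_length,
    )


# ---------------------------------------------------------------------------
# Markov background
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    """Order-m background: exhaustive m-mer and (m+1)-mer counts.

    Counts are over countable (unmasked, unambiguous) windows of the UTR
    universe.  For m = 0 the "m-mer counts" collapse to the total number
    of countable single positions.
    """

    order: int
    mer_counts: np.ndarray  # length 4**order (order 0 -> length 1 = total)
    mer1_counts: np.ndarray  # length 4**(order+1)

    @property
    def total_mers(self) -> int:
        return int(self.mer_counts.sum())

    def mer_count(self, mer: str) -> int:
        if len(mer) != self.order:
            raise ValueError(f"need a {self.order}-mer, got {mer!r}")
        return int(self.mer_counts[word_code(mer)]) if self.order else self.total_mers

    def mer1_count(self, mer: str) -> int:
        if len(mer) != self.order + 1:
            raise ValueError(f"need a {self.order + 1}-mer, got {mer!r}")
        return int(self.mer1_counts[word_code(mer)])


def fit_markov(utrs: Sequence[UtrRecord], order: int = 4) -> MarkovModel:
    """Fit an order-`order` Markov background over the unmasked universe."""
    if order < 0:
        raise ValueError("order must be >= 0")
    m_counts = np.zeros(max(1, 4**order), dtype=np.int64)
    m1_counts = np.zeros(4 ** (order + 1), dtype=np.int64)
    for rec in utrs:
        if order > 0:
            wc = _window_codes(rec, order)
            wc = wc[wc >= 0]
            if wc.size:
                m_counts += np.bincount(wc, minlength=4**order)
        else:
            wc = _window_codes(rec, 1)
            m_counts[0] += int((wc >= 0).sum())
        wc1 = _window_codes(rec, order + 1)
        wc1 = wc1[wc1 >= 0]
        if wc1.size:
            m1_counts += np.bincount(wc1, minlength=4 ** (order + 1))
    if m1_counts.sum() == 0:
        raise ValueError(
            f"insufficient unmasked sequence to fit an order-{order} model"
        )
    return MarkovModel(order=order, mer_counts=m_counts, mer1_counts=m1_counts)


def markov_word_probability(model: MarkovModel, word: str) -> float:
    """Per-position probability of `word` under the fitted Markov chain.

    Standard factorisation: P(w) = P(w[0:m]) * prod_i P(w[i+m] | w[i:i+m])
    with transition probabilities C_{m+1}/C_m and the initial probability
    C_m / total.  Algebraically this is the ratio of (m+1)-mer count
    products to inner m-mer count products, normalised per position.
    Raises if any required sub-word count is zero.
    """
    m = model.order
    L = len(word)
    if L <= m:
        raise ValueError(f"word length {L} must exceed model order {m}")
    if m == 0:
        total = model.total_mers
        p = 1.0
        for ch in word:
            c = model.mer1_counts[word_code(ch)]
            if c == 0:
                raise ValueError(f"zero background count for sub-word {ch!r}")
            p *= c / total
        return float(p)
    first = word[:m]
    c_first = model.mer_counts[word_code(first)]
    if c_first == 0:
        raise ValueError(f"zero background count for sub-word {first!r}")
    p = c_first / model.total_mers
    for i in range(L - m):
        num = model.mer1_counts[word_code(word[i : i + m + 1])]
        den = model.mer_counts[word_code(word[i : i + m])]
        if num == 0:
            raise ValueError(
                f"zero background count for sub-word {word[i:i + m + 1]!r}"
            )
        if den == 0:
            raise ValueError(f"zero background count for sub-word {word[i:i + m]!r}")
        p *= num / den
    return float(min(p, 1.0))
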