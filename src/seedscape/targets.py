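"""Putative direct miRNA target calling from a mimic-vs-inhibitor contrast.

A gene is called a putative direct target of a transfected miRNA when it
is downregulated under the mimic (adjusted P < alpha and negative log
fold change in the mimic-vs-inhibitor, or mimic-vs-mock, contrast) and
its 3'UTR carries at least one seed-matching site of that miRNA —
either site type counts.  Genes without a 3'UTR are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diffexpr import DEResults
from .seeds import SeedLexicon, SiteType
from .utrs import WordCountTable

__all__ = ["TargetCallSet", "call_targets"]


@dataclass
class TargetCallSet:
    """Putative direct targets of one miRNA at a given threshold.

    `table` rows are the targets; columns: adjusted_p, logFC, per-site-
    type seed counts (n_sites_7_2, n_sites_7_1A) and their total.
    """

    mirna_id: str
    alpha: float
    table: pd.DataFrame
    words: list[str] = field(default_factory=list)

    @property
    def targets(self) -> set[str]:
        return set(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def summary(self, top: int = 10) -> str:
        lines = [
            f"Putative direct targets of {self.mirna_id}",
            f"  seed words:   {', '.join(w.replace('T', 'U') for w in self.words)}",
            f"  adjusted P <  {self.alpha}",
            f"  targets:      {len(self)}",
            "",
            self.table.sort_values("adjusted_p").head(top).to_string(),
        ]
        return "\n".join(lines)


def call_targets(
    de: DEResults,
    counts: WordCountTable,
    lexicon: SeedLexicon,
    mirna_id: str,
    alpha: float = 0.05,
) -> TargetCallSet:
    """Call putative direct targets of `mirna_id`.

    `de` must be the mimic-vs-inhibitor (or mimic-vs-mock) contrast for
    that miRNA, with the mimic as the first condition so direct targets
    have negative logFC.  Lowering `alpha` never adds targets.
    """
    by_type = lexicon.words_for_by_type(mirna_id)
    all_words = sorted(set(by_type[SiteType.SEVEN_2]) | set(by_type[SiteType.SEVEN_1A]))
    if not all_words:
        raise ValueError(
            f"miRNA {mirna_id!r} has no (non-excluded) words in the lexicon"
        )
    dna = {w: w.replace("U", "T") for w in all_words}
    with_utr = de.table.index.intersection(counts.counts.index)
    tab = de.table.loc[with_utr]

    def type_counts(site_type: SiteType) -> pd.Series:
        cols = [dna[w] for w in by_type[site_type] if dna[w] in counts.counts.columns]
        if not cols:
            return pd.Series(0, index=with_utr, dtype=int)
        return counts.counts.loc[with_utr, cols].sum(axis=1)

    n72 = type_counts(SiteType.SEVEN_2)
    n71a = type_counts(SiteType.SEVEN_1A)
    n_sites = n72 + n71a
    sel = (tab["adjusted_p"] < alpha) & (tab["logFC"] < 0) & (n_sites >= 1)
    out = tab.loc[sel, ["adjusted_p", "logFC"]].copy()
    out["n_sites_7_2"] = n72[sel]
    out["n_sites_7_1A"] = n71a[sel]
    out["n_sites_total"] = n_sites[sel]
    return TargetCallSet(
        mirna_id=mirna_id,
        alpha=alpha,
        table=out.sort_values(["adjusted_p", "logFC"], kind="mergesort"),
        words=[dna[w] for w in all_words],
    )
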