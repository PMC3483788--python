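"""Seed-matching-site derivation from mature miRNA sequences.

A miRNA recognises its targets chiefly through its *seed* (bases 2-8 from
the 5' end).  The two canonical 7-nt sites in a 3'UTR are the sequence
complementary to bases 2-8 ("7(2)", elsewhere called 7mer-m8) and the
sequence complementary to bases 2-7 followed by an adenine opposite
position 1 ("7(1A)", 7mer-A1).  This module derives both site words for
every miRNA, merges identical words across miRNAs, and removes words that
cannot be attributed to miRNA action because they coincide with the
polyadenylation signal neighbourhood (CAAUAAA, UAUUUAU, UCAAUAA by
default).

Sequences are stored internally in DNA alphabet (U -> T on ingestion);
words are rendered back as RNA for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SiteType",
    "MatureMiRNA",
    "SeedSite",
    "SeedLexicon",
    "AlphabetError",
    "reverse_complement",
    "derive_seed_sites",
    "build_lexicon",
    "DEFAULT_EXCLUSION_WORDS",
]

#: Seed-site words indistinguishable from polyadenylation-signal variants.
DEFAULT_EXCLUSION_WORDS = frozenset({"CAAUAAA", "UAUUUAU", "UCAAUAA"})

_COMPLEMENT = {
    "RNA": str.maketrans("ACGU", "UGCA"),
    "DNA": str.maketrans("ACGT", "TGCA"),
}
_VALID = {"RNA": set("ACGU"), "DNA": set("ACGT")}


class AlphabetError(ValueError):
    """A sequence contains a letter outside the declared alphabet."""


class SiteType(str, Enum):
    SEVEN_2 = "7(2)"
    SEVEN_1A = "7(1A)"


def _validate(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    valid = _VALID[alphabet]
    for i, ch in enumerate(seq):
        if ch not in valid:
            raise AlphabetError(
                f"invalid {alphabet} letter {ch!r} at position {i}"
            )
    return seq


def reverse_complement(seq: str, alphabet: str = "RNA") -> str:
    """Reverse complement of `seq` in the stated alphabet ("RNA" or "DNA").

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if alphabet not in _COMPLEMENT:
        raise ValueError(f"alphabet must be 'RNA' or 'DNA', got {alphabet!r}")
    seq = _validate(seq, alphabet)
    return seq.translate(_COMPLEMENT[alphabet])[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: id and 5'->3' RNA sequence (T normalised to U)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        _validate(seq, "RNA")
        if not seq:
            raise ValueError(f"miRNA {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", seq)


@dataclass
class SeedSite:
    """A 7-nt seed-matching word with provenance.

    `site_types` records which site type(s) produced the word for each
    source miRNA (identical words from different miRNAs are merged).
    """

    word: str
    site_types: set[SiteType]
    mirna_ids: set[str]

    def __post_init__(self) -> None:
        if len(self.word) != 7:
            raise ValueError(f"seed word must be 7 nt, got {self.word!r}")


def derive_seed_sites(mirna: MatureMiRNA) -> list[SeedSite]:
    """Derive the 7(2) and 7(1A) seed-matching site words for one miRNA.

    7(2): reverse complement of miRNA bases 2-8 (1-based, 5' end).
    7(1A): reverse complement of bases 2-7, followed by "A" (the adenine
    opposite miRNA position 1).
    """
    seq = mirna.sequence
    if len(seq) < 8:
        raise ValueError(
            f"miRNA {mirna.id!r}: sequence length {len(seq)} < 8, "
            "cannot derive seed sites"
        )
    seven_2 = reverse_complement(seq[1:8], "RNA")
    seven_1a = reverse_complement(seq[1:7], "RNA") + "A"
    return [
        SeedSite(seven_2, {SiteType.SEVEN_2}, {mirna.id}),
        SeedSite(seven_1a, {SiteType.SEVEN_1A}, {mirna.id}),
    ]


@dataclass
class SeedLexicon:
    """Deduplicated seed-site words with the exclusion record.

    `words` maps each retained 7-mer (RNA alphabet) to its merged
    :class:`SeedSite`; `excluded` maps each exclusion-list word that was
    actually derived to its (merged) site, kept for reporting.
    """

    words: dict[str, SeedSite] = field(default_factory=dict)
    excluded: dict[str, SeedSite] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.words

    @property
    def n_distinct_before_exclusion(self) -> int:
        return len(self.words) + len(self.excluded)

    def words_for(self, mirna_id: str) -> list[str]:
        """Retained words derived from `mirna_id` (excluded words omitted)."""
        return sorted(
            w for w, s in self.words.items() if mirna_id in s.mirna_ids
        )

    def words_for_by_type(self, mirna_id: str) -> dict[SiteType, list[str]]:
        out: dict[SiteType, list[str]] = {t: [] for t in SiteType}
        for w, s in self.words.items():
            if mirna_id in s.mirna_ids:
                for t in s.site_types:
                    out[t].append(w)
        return out

    def dna_words(self) -> list[str]:
        """Retained words in DNA alphabet (U -> T), for UTR counting."""
        return sorted(w.replace("U", "T") for w in self.words)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for flag, table in ((False, self.words), (True, self.excluded)):
            for w in sorted(table):
                s = table[w]
                rows.append(
                    {
                        "word": w,
                        "site_types": ",".join(
                            sorted(t.value for t in s.site_types)
                        ),
                        "mirna_ids": ",".join(sorted(s.mirna_ids)),
                        "excluded": flag,
                    }
                )
        return pd.DataFrame(
            rows, columns=["word", "site_types", "mirna_ids", "excluded"]
        )


def build_lexicon(
    mirnas: Iterable[MatureMiRNA],
    exclusion_words: Iterable[str] | None = DEFAULT_EXCLUSION_WORDS,
) -> SeedLexicon:
    """Assemble the exclusion-filtered seed-site lexicon over all miRNAs.

    Identical words from different miRNAs are merged (union of ids and
    site types).  `exclusion_words` defaults to the three polyA-like
    words; pass an empty set (or None) to keep everything.  Duplicate
    miRNA ids with differing sequences raise; identical records are
    deduplicated silently.  The result is independent of input order.
    """
    mirnas = list(mirnas)
    if not mirnas:
        raise ValueError("mirnas must be non-empty")
    seen: dict[str, str] = {}
    unique: list[MatureMiRNA] = []
    for m in mirnas:
        if m.id in seen:
            if seen[m.id] != m.sequence:
                raise ValueError(
                    f"duplicate miRNA id {m.id!r} with conflicting sequences"
                )
            continue
        seen[m.id] = m.sequence
        unique.append(m)

    exclusion = frozenset() if exclusion_words is None else frozenset(exclusion_words)
    merged: dict[str, SeedSite] = {}
    for m in sorted(unique, key=lambda x: x.id):
        try:
            sites = derive_seed_sites(m)
        except ValueError as err:
            raise ValueError(f"miRNA {m.id!r}: {err}") from err
        for site in sites:
            if site.word in merged:
                merged[site.word].mirna_ids |= site.mirna_ids
                merged[site.word].site_types |= site.site_types
            else:
                merged[site.word] = site

    lex = SeedLexicon()
    for w, s in merged.items():
        (lex.excluded if w in exclusion else lex.words)[w] = s
    return lex


def lexicon_from_frame(frame: pd.DataFrame) -> SeedLexicon:
    """Rebuild a :class:`SeedLexicon` from its `to_frame` representation."""
    lex = SeedLexicon()
    by_value = {t.value: t for t in SiteType}
    for row in frame.itertuples(index=False):
        site = SeedSite(
            word=row.word,
            site_types={by_value[v] for v in str(row.site_types).split(",")},
            mirna_ids=set(str(row.mirna_ids).split(",")),
        )
        flag = row.excluded in (True, "True", "true", 1, "1")
        (lex.excluded if flag else lex.words)[row.word] = site
    return lex
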