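"""Microarray probe-to-transcript resolution.

Probes (short, ~50 nt) are matched to transcripts by the length of the
longest run of consecutive perfect matches — the longest exact common
substring between the probe (either strand) and the transcript.  A
candidate needs at least 30 consecutive matches.  When several
transcripts tie on score, a fixed preference cascade resolves the
ambiguity: manually curated (Vega) source first, then biotype
(protein coding > pseudogene > other > nonsense-mediated decay), then
longest 3'UTR, then longest cDNA, then transcript id.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import pandas as pd

from .seeds import reverse_complement

__all__ = [
    "Source",
    "Biotype",
    "TranscriptMeta",
    "AlignmentCandidate",
    "longest_common_substring",
    "align_probe",
    "resolve_probe_mapping",
    "map_probes",
]


class Source(IntEnum):
    """Annotation source preference (lower = preferred)."""

    VEGA = 0
    ENSEMBL_CORE = 1
    OTHER = 2


class Biotype(IntEnum):
    """Biotype preference (lower = preferred); NMD has lowest preference."""

    PROTEIN_CODING = 0
    PSEUDOGENE = 1
    OTHER = 2
    NMD = 3


@dataclass(frozen=True)
class TranscriptMeta:
    transcript_id: str
    gene_id: str
    source: Source = Source.ENSEMBL_CORE
    biotype: Biotype = Biotype.PROTEIN_CODING
    utr_length: int = 0
    cdna_length: int = 0


@dataclass(frozen=True)
class AlignmentCandidate:
    probe_id: str
    match_score: int
    meta: TranscriptMeta

    def sort_key(self) -> tuple:
        """Total order implementing the preference cascade (best first)."""
        m = self.meta
        return (
            -self.match_score,
            int(m.source),
            int(m.biotype),
            -m.utr_length,
            -m.cdna_length,
            m.transcript_id,
        )


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact common substring of `a` and `b`.

    Binary search over the length; feasibility is checked by hashing all
    windows of `a` into a set and sliding over `b` — fast when `a` is a
    short probe.
    """
    if not a or not b:
        return 0
    lo, hi = 0, min(len(a), len(b))

    def feasible(L: int) -> bool:
        if L == 0:
            return True
        windows = {a[i : i + L] for i in range(len(a) - L + 1)}
        return any(b[j : j + L] in windows for j in range(len(b) - L + 1))

    while lo < hi:
        mid = (lo + hi + 1) // 2
        if feasible(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def align_probe(
    probe_id: str,
    probe_seq: str,
    transcripts: Sequence[tuple[str, TranscriptMeta]] | Sequence[tuple[str, str, TranscriptMeta]],
    min_match: int = 30,
    both_strands: bool = True,
) -> list[AlignmentCandidate]:
    """Score a probe against transcripts; keep runs of >= `min_match`.

    `transcripts` is a sequence of (sequence, meta) pairs.  Both strands
    of the probe are tried (probe orientation varies by platform) and
    the better score kept.
    """
    probe_seq = probe_seq.upper().replace("U", "T")
    if len(probe_seq) < min_match:
        raise ValueError(
            f"probe {probe_id!r} length {len(probe_seq)} < minimum match {min_match}"
        )
    strands = [probe_seq]
    if both_strands:
        strands.append(reverse_complement(probe_seq, "DNA"))
    out = []
    for entry in transcripts:
        seq, meta = entry[-2] if len(entry) == 3 else entry[0], entry[-1]
        seq = seq.upper().replace("U", "T")
        score = max(longest_common_substring(s, seq) for s in strands)
        if score >= min_match:
            out.append(AlignmentCandidate(probe_id, score, meta))
    return out


def resolve_probe_mapping(
    candidates: Sequence[AlignmentCandidate],
) -> AlignmentCandidate | None:
    """Pick the unique best candidate via the preference cascade.

    Returns None for an empty candidate list (probe unmapped, excluded
    downstream).  The result is independent of input order.
    """
    if not candidates:
        return None
    return min(candidates, key=AlignmentCandidate.sort_key)


def map_probes(
    probes: Sequence[tuple[str, str]],
    transcripts: Sequence[tuple[str, TranscriptMeta]],
    min_match: int = 30,
) -> pd.DataFrame:
    """Resolve every probe; returns probe_id, transcript_id, gene_id, score."""
    rows = []
    for probe_id, probe_seq in probes:
        chosen = resolve_probe_mapping(
            align_probe(probe_id, probe_seq, transcripts, min_match=min_match)
        )
        if chosen is not None:
            rows.append(
                {
                    "probe_id": probe_id,
                    "transcript_id": chosen.meta.transcript_id,
                    "gene_id": chosen.meta.gene_id,
                    "match_score": chosen.match_score,
                }
            )
    return pd.DataFrame(
        rows, columns=["probe_id", "transcript_id", "gene_id", "match_score"]
    )
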