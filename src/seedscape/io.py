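"""Format readers and writers shared by the library and the CLI.

Interchange conventions: FASTA for sequences (Biopython parsing; wrapped
lines and CRLF tolerated; duplicate ids rejected), tab-delimited tables
with a header row for everything tabular, one-gene-id-per-line text for
gene sets, YAML for the sample design.  UTR FASTA headers are
``gene_id|transcript_id`` with the second token optional.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .diffexpr import ExpressionMatrix, RankedGeneList
from .seeds import MatureMiRNA, SeedLexicon, lexicon_from_frame
from .utrs import UtrRecord, WordCountTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_mirna_fasta",
    "read_utr_fasta",
    "read_gene_set",
    "write_gene_set",
    "read_tsv",
    "write_tsv",
    "read_expression",
    "read_lexicon_tsv",
    "write_lexicon_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_ranking_tsv",
    "write_ranking_tsv",
    "read_mask_file",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    return [MatureMiRNA(rid, seq) for rid, seq in read_fasta(path).items()]


def read_utr_fasta(path: str | Path) -> list[UtrRecord]:
    out = []
    seen = set()
    for rid, seq in read_fasta(path).items():
        gene_id, _, transcript_id = rid.partition("|")
        if gene_id in seen:
            raise ValueError(f"{path}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        out.append(UtrRecord(gene_id=gene_id, transcript_id=transcript_id or None, sequence=seq))
    return out


def read_gene_set(path: str | Path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed TSV ({err})") from err


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_expression(
    matrix_path: str | Path,
    design_path: str | Path,
    detection_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Expression TSV (gene_id + sample columns) with a YAML design.

    The design maps sample name -> condition label; the optional
    detection TSV has gene_id plus one column (per-gene) or one column
    per condition.
    """
    values = read_tsv(matrix_path, index_col=0)
    design = yaml.safe_load(Path(design_path).read_text())
    if not isinstance(design, Mapping):
        raise ValueError(f"{design_path}: design must map sample -> condition")
    det = None
    if detection_path is not None:
        det_frame = read_tsv(detection_path, index_col=0)
        det = det_frame.iloc[:, 0] if det_frame.shape[1] == 1 else det_frame
    return ExpressionMatrix(values, dict(design), det)


def write_lexicon_tsv(lexicon: SeedLexicon, path: str | Path) -> None:
    write_tsv(lexicon.to_frame(), path)


def read_lexicon_tsv(path: str | Path) -> SeedLexicon:
    return lexicon_from_frame(read_tsv(path))


def write_counts_tsv(counts: WordCountTable, path: str | Path) -> None:
    write_tsv(counts.to_long_frame(), path)


def read_counts_tsv(path: str | Path) -> WordCountTable:
    long = read_tsv(path)
    wide = long.pivot(index="gene_id", columns="word", values="count").fillna(0).astype(int)
    wide.columns.name = None
    totals = long.drop_duplicates("gene_id").set_index("gene_id")["total_positions"]
    word_length = len(str(long["word"].iloc[0])) if len(long) else 7
    return WordCountTable(
        counts=wide,
        total_positions=totals.reindex(wide.index).astype(int),
        word_length=word_length,
    )


def write_ranking_tsv(ranked: RankedGeneList, path: str | Path) -> None:
    write_tsv(ranked.to_frame(), path)


def read_ranking_tsv(path: str | Path) -> RankedGeneList:
    frame = read_tsv(path)
    stat = pd.Series(frame["statistic"].to_numpy(), index=frame["gene_id"])
    return RankedGeneList(list(frame["gene_id"]), stat)


def read_mask_file(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED-like mask: gene_id <tab> start <tab> end (0-based half-open)."""
    out: dict[str, list[tuple[int, int]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: expected gene_id, start, end")
        try:
            s, e = int(parts[1]), int(parts[2])
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: non-integer interval") from err
        out.setdefault(parts[0], []).append((s, e))
    return out
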