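"""End-to-end pipeline: lexicon -> count -> rank -> scan -> targets -> overlap.

Each stage is also runnable standalone (library calls or CLI commands);
`run_pipeline` chains them on files, logging per-stage parameters and
input hashes so a run is fully reproducible from its log.  With a fixed
configuration and seed the outputs are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as sio
from .diffexpr import DifferentialExpression, rank_genes
from .overlap import enrichment_panel
from .scan import ScanConfig, SeedEnrichmentScan
from .seeds import build_lexicon
from .targets import call_targets
from .utrs import count_words, fit_markov, mask_low_complexity, mask_redundant

logger = logging.getLogger("seedscape")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run."""

    mirna_fasta: Path
    utr_fasta: Path
    matrix: Path
    design: Path
    out_dir: Path
    detection: Path | None = None
    contrast: tuple[str, str] = ("mimic", "inhibitor")
    stress_contrast: tuple[str, str] | None = ("stress", "mock")
    mirna_ids: list[str] = field(default_factory=list)
    target_alpha: float = 0.05
    response_alpha: float = 0.05
    detection_alpha: float = 0.01
    bin_step: int = 100
    markov_order: int = 4
    auto_mask: bool = False
    seed: int = 0

    def validate(self) -> None:
        for p in (self.mirna_fasta, self.utr_fasta, self.matrix, self.design):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.bin_step < 1 or self.markov_order < 0:
            raise ValueError("bin_step >= 1 and markov_order >= 0 required")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns {stage: output path}."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "inputs": {
            name: _hash_file(getattr(config, name))
            for name in ("mirna_fasta", "utr_fasta", "matrix", "design")
        },
        "parameters": {
            "contrast": list(config.contrast),
            "target_alpha": config.target_alpha,
            "bin_step": config.bin_step,
            "markov_order": config.markov_order,
            "auto_mask": config.auto_mask,
            "seed": config.seed,
        },
    }
    outputs: dict[str, Path] = {}

    logger.info("stage lexicon: %s", config.mirna_fasta)
    mirnas = sio.read_mirna_fasta(config.mirna_fasta)
    lexicon = build_lexicon(mirnas)
    outputs["lexicon"] = out / "lexicon.tsv"
    sio.write_lexicon_tsv(lexicon, outputs["lexicon"])

    logger.info("stage count: %s", config.utr_fasta)
    utrs = sio.read_utr_fasta(config.utr_fasta)
    if config.auto_mask:
        utrs = mask_redundant([mask_low_complexity(u) for u in utrs])
    counts = count_words(utrs, lexicon.dna_words())
    outputs["counts"] = out / "counts.tsv"
    sio.write_counts_tsv(counts, outputs["counts"])

    logger.info("stage rank: contrast %s - %s", *config.contrast)
    matrix = sio.read_expression(config.matrix, config.design, config.detection)
    model = DifferentialExpression(matrix)
    de = model.fit(config.contrast)
    outputs["de"] = out / "de.tsv"
    sio.write_tsv(de.table.rename_axis("gene_id").reset_index(), outputs["de"])
    with_utr = {u.gene_id for u in utrs}
    ranked = rank_genes(de, restrict_to=with_utr)
    outputs["ranking"] = out / "ranking.tsv"
    sio.write_ranking_tsv(ranked, outputs["ranking"])

    logger.info("stage scan: bin_step %d, markov %d", config.bin_step, config.markov_order)
    background = fit_markov(utrs, config.markov_order) if config.markov_order else None
    scan_cfg = ScanConfig(bin_step=config.bin_step, markov_order=config.markov_order)
    landscape = SeedEnrichmentScan(ranked, counts, scan_cfg, background, lexicon).fit()
    outputs["landscape"] = out / "landscape.tsv"
    sio.write_tsv(landscape.to_long_frame(), outputs["landscape"])
    outputs["peaks"] = out / "peaks.tsv"
    sio.write_tsv(landscape.peak_words(len(landscape.words)).reset_index(), outputs["peaks"])

    mirna_ids = config.mirna_ids or [mirnas[0].id]
    target_sets = {}
    for mid in mirna_ids:
        logger.info("stage targets: %s", mid)
        ts = call_targets(de, counts, lexicon, mid, alpha=config.target_alpha)
        target_sets[mid] = ts.targets
        path = out / f"targets_{mid}.tsv"
        sio.write_tsv(ts.table.rename_axis("gene_id").reset_index(), path)
        outputs[f"targets_{mid}"] = path

    if config.stress_contrast is not None:
        logger.info("stage overlap: stress contrast %s - %s", *config.stress_contrast)
        stress_de = model.fit(config.stress_contrast)
        universe = set(matrix.gene_ids)
        if matrix.detection_p is not None:
            from .diffexpr import detection_filter

            universe = detection_filter(matrix, config.detection_alpha)
        response = {
            "stress_up": set(stress_de.significant(config.response_alpha, "up").index),
            "stress_down": set(stress_de.significant(config.response_alpha, "down").index),
        }
        panel = enrichment_panel(target_sets, response, universe)
        outputs["overlap"] = out / "overlap.tsv"
        sio.write_tsv(panel, outputs["overlap"])

    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    outputs["provenance"] = prov_path
    return outputs
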