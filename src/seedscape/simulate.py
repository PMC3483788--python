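"""Synthetic miRNAs, 3'UTRs and expression matrices with known ground truth.

The generator emulates the structure of a miRNA transfection experiment
in primary neurons: mature miRNA sequences; 3'UTR sets in which chosen
genes carry planted seed-matching sites; and log2 expression matrices
for mimic / inhibitor / mock / stress arms where planted targets are
suppressed by the mimic (and mildly de-repressed by the inhibitor) and a
stress-responsive gene set is induced.  The coupling fraction `rho`
controls how much of the stress-induced set is drawn from seed-carrying
target genes, dialing the headline phenomenon — stress-induced
transcripts enriched in seed sites — from chance level to strong.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .seeds import MatureMiRNA, SeedLexicon, build_lexicon, derive_seed_sites
from .utrs import UtrRecord

__all__ = [
    "SimulationTruth",
    "ScenarioData",
    "gen_mirnas",
    "gen_utrs",
    "gen_expression",
    "paper_scenario",
]

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    seed: int
    planted_words: dict[str, str] = field(default_factory=dict)  # mirna -> DNA word
    planted_sites: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    target_genes: dict[str, list[str]] = field(default_factory=dict)
    stress_up: list[str] = field(default_factory=list)
    stress_down: list[str] = field(default_factory=list)
    effects: dict[str, float] = field(default_factory=dict)


def gen_mirnas(n: int, length: int = 22, seed: int = 0) -> list[MatureMiRNA]:
    """`n` i.i.d. uniform-RNA mature miRNAs, ids syn-miR-1..n.

    No two share a 7(2) seed word (collisions are resampled, bounded
    retries) so each miRNA's primary word is uniquely attributable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 8:
        raise ValueError("length must be >= 8")
    rng = np.random.default_rng(seed)
    out: list[MatureMiRNA] = []
    seen_words: set[str] = set()
    for i in range(n):
        for attempt in range(1000):
            seq = "".join(rng.choice(_RNA, size=length))
            m = MatureMiRNA(f"syn-miR-{i + 1}", seq)
            w72 = derive_seed_sites(m)[0].word
            if w72 not in seen_words:
                seen_words.add(w72)
                out.append(m)
                break
        else:
            raise RuntimeError(
                f"could not draw {n} miRNAs with distinct 7(2) words"
            )
    return out


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_DNA, size=length, p=p))


def gen_utrs(
    n_genes: int,
    length_dist: tuple[float, float] = (800.0, 400.0),
    gc: float = 0.42,
    plant: Mapping[str, tuple[Sequence[str], int]] | None = None,
    mirnas: Sequence[MatureMiRNA] = (),
    min_length: int = 60,
    seed: int = 0,
) -> tuple[list[UtrRecord], SimulationTruth]:
    """Random-composition 3'UTRs with planted seed sites.

    `plant` maps a miRNA id to (genes to plant in, sites per gene); the
    planted word is that miRNA's 7(2) seed-matching site, inserted by
    overwriting the background at uniformly drawn non-overlapping
    positions (exact positions recorded in the truth).  Lengths are
    Normal(`length_dist`) clipped at `min_length`; gene ids g0001...
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    gene_ids = [f"g{str(i + 1).zfill(width)}" for i in range(n_genes)]
    lengths = np.maximum(
        min_length, rng.normal(length_dist[0], length_dist[1], n_genes).astype(int)
    )
    seqs = {g: list(_random_seq(rng, int(L), gc)) for g, L in zip(gene_ids, lengths)}

    truth = SimulationTruth(seed=seed)
    words = {m.id: derive_seed_sites(m)[0].word.replace("U", "T") for m in mirnas}
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    if plant:
        gene_set = set(gene_ids)
        for mirna_id, (genes, n_sites) in plant.items():
            if mirna_id not in words:
                raise ValueError(f"unknown miRNA id {mirna_id!r} in plant map")
            if n_sites < 1:
                raise ValueError("sites per gene must be >= 1")
            word = words[mirna_id]
            truth.planted_words[mirna_id] = word
            truth.target_genes[mirna_id] = list(genes)
            sites: list[tuple[str, int]] = []
            for g in genes:
                if g not in gene_set:
                    raise ValueError(f"planted gene {g!r} not among generated genes")
                L = len(seqs[g])
                for _ in range(n_sites):
                    pos = _place_site(rng, L, len(word), occupied[g])
                    if pos is None:
                        raise ValueError(
                            f"gene {g!r} (length {L}) too short to host "
                            f"{n_sites} non-overlapping sites"
                        )
                    seqs[g][pos : pos + len(word)] = list(word)
                    occupied[g].append((pos, pos + len(word)))
                    sites.append((g, pos))
            truth.planted_sites[mirna_id] = sites
    utrs = [UtrRecord(gene_id=g, sequence="".join(seqs[g])) for g in gene_ids]
    return utrs, truth


def _place_site(
    rng: np.random.Generator,
    length: int,
    word_len: int,
    occupied: list[tuple[int, int]],
    max_tries: int = 200,
) -> int | None:
    if length < word_len:
        return None
    for _ in range(max_tries):
        pos = int(rng.integers(0, length - word_len + 1))
        if all(pos + word_len <= s or pos >= e for s, e in occupied):
            return pos
    return None


def gen_expression(
    gene_ids: Sequence[str],
    replicates: Mapping[str, int] | None = None,
    target_genes: Mapping[str, Sequence[str]] | None = None,
    stress_up: Sequence[str] = (),
    stress_down: Sequence[str] = (),
    target_effect: float = -1.5,
    inhibitor_effect: float | None = None,
    stress_effect: float = 1.5,
    noise_sd: float = 0.5,
    baseline: tuple[float, float] = (8.0, 1.5),
    dropout_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Log2 expression for mimic/inhibitor/mock/stress arms.

    Per-gene baseline means ~ Normal(*baseline*); arm effects are
    additive on log2 scale; i.i.d. Gaussian noise per sample.  Planted
    targets (union over miRNAs in `target_genes`) get `target_effect`
    (negative) in the mimic arm and `inhibitor_effect` (default
    -target_effect/2, positive: weaker de-repression) in the inhibitor
    arm; `stress_up`/`stress_down` genes get +/- `stress_effect` in the
    stress arm.  Detection P is 0 for all genes except a
    `dropout_fraction` random subset set to 0.5 (undetected).
    """
    replicates = dict(replicates or {"mimic": 4, "inhibitor": 4, "mock": 4, "stress": 4})
    for arm, r in replicates.items():
        if r < 2:
            raise ValueError(f"arm {arm!r}: need >= 2 replicates, got {r}")
    if not 0.0 <= dropout_fraction <= 1.0:
        raise ValueError("dropout_fraction must be in [0, 1]")
    if inhibitor_effect is None:
        inhibitor_effect = -target_effect / 2.0
    rng = np.random.default_rng(seed)
    genes = list(gene_ids)
    idx = {g: i for i, g in enumerate(genes)}
    base = rng.normal(baseline[0], baseline[1], len(genes))

    arm_shift = {arm: np.zeros(len(genes)) for arm in replicates}
    all_targets = sorted({g for gs in (target_genes or {}).values() for g in gs})
    if "mimic" in arm_shift:
        for g in all_targets:
            arm_shift["mimic"][idx[g]] += target_effect
    if "inhibitor" in arm_shift:
        for g in all_targets:
            arm_shift["inhibitor"][idx[g]] += inhibitor_effect
    if "stress" in arm_shift:
        for g in stress_up:
            arm_shift["stress"][idx[g]] += stress_effect
        for g in stress_down:
            arm_shift["stress"][idx[g]] -= stress_effect

    cols, conditions, data = [], {}, []
    for arm in sorted(replicates):
        for r in range(replicates[arm]):
            name = f"{arm}_{r + 1}"
            cols.append(name)
            conditions[name] = arm
            data.append(base + arm_shift[arm] + rng.normal(0.0, noise_sd, len(genes)))
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)

    det = pd.Series(0.0, index=genes)
    if dropout_fraction > 0:
        n_drop = int(round(dropout_fraction * len(genes)))
        drop = rng.choice(len(genes), size=n_drop, replace=False)
        det.iloc[drop] = 0.5

    truth = SimulationTruth(
        seed=seed,
        target_genes={m: list(gs) for m, gs in (target_genes or {}).items()},
        stress_up=list(stress_up),
        stress_down=list(stress_down),
        effects={
            "target_effect": target_effect,
            "inhibitor_effect": inhibitor_effect,
            "stress_effect": stress_effect,
            "noise_sd": noise_sd,
        },
    )
    return ExpressionMatrix(values, conditions, det), truth


@dataclass
class ScenarioData:
    """A complete simulated study: sequences, lexicon, expression, truth.

    Each transfected miRNA has its own mimic/inhibitor arm pair (the
    planted miRNA uses the plain ``mimic``/``inhibitor`` arms, controls
    get ``mimic_<id>``/``inhibitor_<id>`` null arms), mirroring a
    transfection panel where every miRNA is assayed in its own cultures.
    """

    mirnas: list[MatureMiRNA]
    lexicon: SeedLexicon
    utrs: list[UtrRecord]
    expression: ExpressionMatrix
    truth: SimulationTruth
    planted_mirna: str
    control_mirnas: list[str]

    def contrast_for(self, mirna_id: str) -> tuple[str, str]:
        """The mimic-vs-inhibitor contrast for one transfected miRNA."""
        if mirna_id == self.planted_mirna:
            return ("mimic", "inhibitor")
        if mirna_id in self.control_mirnas:
            return (f"mimic_{mirna_id}", f"inhibitor_{mirna_id}")
        raise KeyError(f"{mirna_id!r} was not transfected in this scenario")


def paper_scenario(
    seed: int = 0,
    n_genes: int = 2000,
    n_mirnas: int = 25,
    n_targets: int = 100,
    sites_per_target: int = 1,
    target_effect: float = -1.5,
    stress_effect: float = 1.5,
    noise_sd: float = 0.5,
    replicates: int = 4,
    rho: float = 0.8,
    stress_set_size: int = 100,
    utr_length: tuple[float, float] = (800.0, 400.0),
    gc: float = 0.42,
) -> ScenarioData:
    """The study-condition preset used throughout the test-bench.

    One planted miRNA (syn-miR-1) with `n_targets` seed-carrying target
    genes suppressed by its mimic; two control miRNAs (syn-miR-2/3) with
    no planted signal; decoy miRNAs filling the lexicon.  The stress-up
    set (size `stress_set_size`) draws a fraction `rho` of its genes
    from the planted targets, the rest (plus the stress-down set) from
    untargeted genes.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2026]))
    sub = rng.integers(0, 2**31 - 1, size=3)
    mirnas = gen_mirnas(n_mirnas, seed=int(sub[0]))
    planted = mirnas[0].id
    controls = [m.id for m in mirnas[1:3]]
    lexicon = build_lexicon(mirnas)

    width = max(4, len(str(n_genes)))
    gene_ids = [f"g{str(i + 1).zfill(width)}" for i in range(n_genes)]
    target_idx = rng.choice(n_genes, size=n_targets, replace=False)
    targets = [gene_ids[i] for i in target_idx]
    utrs, utr_truth = gen_utrs(
        n_genes,
        length_dist=utr_length,
        gc=gc,
        plant={planted: (targets, sites_per_target)},
        mirnas=mirnas,
        seed=int(sub[1]),
    )

    n_coupled = int(round(rho * stress_set_size))
    coupled = list(rng.choice(targets, size=min(n_coupled, len(targets)), replace=False))
    non_targets = [g for g in gene_ids if g not in set(targets)]
    free = list(
        rng.choice(non_targets, size=(stress_set_size - len(coupled)) + stress_set_size, replace=False)
    )
    stress_up = sorted(coupled + free[: stress_set_size - len(coupled)])
    stress_down = sorted(free[stress_set_size - len(coupled) :])

    arms = ["mimic", "inhibitor", "mock", "stress"]
    for c in controls:  # null transfection arms for the control miRNAs
        arms += [f"mimic_{c}", f"inhibitor_{c}"]
    expression, truth = gen_expression(
        gene_ids,
        replicates={a: replicates for a in arms},
        target_genes={planted: targets},
        stress_up=stress_up,
        stress_down=stress_down,
        target_effect=target_effect,
        stress_effect=stress_effect,
        noise_sd=noise_sd,
        seed=int(sub[2]),
    )
    truth.planted_words = utr_truth.planted_words
    truth.planted_sites = utr_truth.planted_sites
    return ScenarioData(
        mirnas=mirnas,
        lexicon=lexicon,
        utrs=utrs,
        expression=expression,
        truth=truth,
        planted_mirna=planted,
        control_mirnas=controls,
    )
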