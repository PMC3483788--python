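"""Hypergeometric overlap of gene sets against a declared universe.

Used to ask whether the putative targets of a miRNA are over-represented
among stress-induced (or stress-reduced) genes: both sets are first
restricted to the detected-gene universe of size N, the overlap k of A
(|A| genes) and B (|B| genes) is scored with the enrichment tail
P(X >= k) of Hypergeometric(N, |A|, |B|), and fold enrichment is
k / (|A|*|B|/N).  Panels of such tests get a BH adjustment across the
batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust
from .scan import hypergeom_tail
from .targets import TargetCallSet

__all__ = ["OverlapResult", "overlap_test", "enrichment_panel"]


@dataclass
class OverlapResult:
    """One set-vs-set hypergeometric test restricted to a universe."""

    set_a_name: str
    set_b_name: str
    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    fold_enrichment: float
    p_enrichment: float
    p_depletion: float
    adjusted_p: float | None = None
    testable: bool = True

    @property
    def log2_fold(self) -> float:
        if self.fold_enrichment <= 0:
            return float("-inf")
        return float(np.log2(self.fold_enrichment))

    def as_dict(self) -> dict:
        return {
            "set_a": self.set_a_name,
            "set_b": self.set_b_name,
            "universe_size": self.universe_size,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "overlap": self.overlap,
            "fold_enrichment": self.fold_enrichment,
            "log2_fold": self.log2_fold,
            "p_enrichment": self.p_enrichment,
            "p_depletion": self.p_depletion,
            "adjusted_p": self.adjusted_p,
            "testable": self.testable,
        }


def _restrict(name: str, genes: Iterable[str], universe: set[str]) -> set[str]:
    s = set()
    n_dup = 0
    for g in genes:
        if g in s:
            n_dup += 1
        s.add(g)
    if n_dup:
        warnings.warn(f"set {name!r}: {n_dup} duplicate gene ids removed", stacklevel=3)
    outside = len(s - universe)
    if outside:
        warnings.warn(
            f"set {name!r}: {outside} genes outside the universe dropped",
            stacklevel=3,
        )
    return s & universe


def overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    set_a_name: str = "A",
    set_b_name: str = "B",
) -> OverlapResult:
    """Hypergeometric overlap of two gene sets within a universe.

    Both sets are intersected with the universe first; genes outside it
    (and duplicates) are dropped with a warning.  p_enrichment is
    P(X >= k), p_depletion P(X <= k).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    a = _restrict(set_a_name, set_a, uni)
    b = _restrict(set_b_name, set_b, uni)
    N, ka, kb = len(uni), len(a), len(b)
    k = len(a & b)
    expected = ka * kb / N
    fold = k / expected if expected > 0 else 0.0
    if ka == 0 or kb == 0:
        p_enr = p_dep = 1.0
    else:
        p_enr = hypergeom_tail(k, ka, kb, N, "enrichment")
        p_dep = hypergeom_tail(k, ka, kb, N, "depletion")
    return OverlapResult(
        set_a_name=set_a_name,
        set_b_name=set_b_name,
        universe_size=N,
        size_a=ka,
        size_b=kb,
        overlap=k,
        fold_enrichment=fold,
        p_enrichment=p_enr,
        p_depletion=p_dep,
        testable=ka > 0 and kb > 0,
    )


def enrichment_panel(
    target_sets: Sequence[TargetCallSet] | Mapping[str, Iterable[str]],
    response_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Overlap panel: every target set against every response set.

    `response_sets` maps names like "KCl_up" / "KCl_down" to gene sets.
    Untestable cells (a set empty after universe restriction) are kept
    as rows with testable=False and excluded from the BH batch.  Returns
    a tidy DataFrame with log2 fold enrichment for bar-plot parity.
    """
    uni = set(universe)
    if isinstance(target_sets, Mapping):
        tsets = {name: set(genes) for name, genes in target_sets.items()}
    else:
        tsets = {ts.mirna_id: ts.targets for ts in target_sets}
    rows: list[OverlapResult] = []
    for a_name, a_genes in tsets.items():
        for b_name, b_genes in response_sets.items():
            rows.append(overlap_test(a_genes, b_genes, uni, a_name, b_name))
    testable = [r for r in rows if r.testable]
    if testable:
        adj = bh_adjust([r.p_enrichment for r in testable])
        for r, q in zip(testable, adj):
            r.adjusted_p = float(q)
    return pd.DataFrame([r.as_dict() for r in rows])
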