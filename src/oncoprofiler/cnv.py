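"""Summaries of GISTIC2.0 thresholded copy-number categories.

Each gene in each sample carries one of five categories: -2 homozygous
deletion, -1 heterozygous deletion, 0 normal copy number, +1 low-level
gain, +2 high-level amplification. The global profile reports, per gene
and entity, the fraction of tumor samples whose category falls in a chosen
subset of the four altered categories (default: any gain or loss); bar
plots resolve the same counts per category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import CnvMatrix

__all__ = ["CATEGORIES", "ALTERED", "CnvProfile", "cnv_profile", "global_cnv_profile", "category_bars"]

CATEGORIES: tuple[int, ...] = (-2, -1, 0, 1, 2)
ALTERED: frozenset[int] = frozenset({-2, -1, 1, 2})


@dataclass(frozen=True)
class CnvProfile:
    """Category tally of one gene over the tumor samples of one entity."""

    entity: str
    gene: str
    n_samples: int
    counts: dict[int, int]

    def altered_fraction(self, subset: Iterable[int] = ALTERED) -> float:
        subset = frozenset(subset)
        if 0 in subset:
            raise ValueError("category 0 (normal copy number) is not an alteration")
        bad = subset - ALTERED
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)}")
        return sum(self.counts[c] for c in subset) / self.n_samples


def cnv_profile(matrix: CnvMatrix, gene: str) -> CnvProfile:
    """Tally categories of one gene over the entity's tumor samples."""
    if gene not in matrix.categories.index:
        raise KeyError(f"gene {gene!r} absent from CNV matrix")
    tumor_cols = [b.raw for b in matrix.samples if b.is_tumor()]
    row = matrix.categories.loc[gene, tumor_cols].to_numpy()
    counts = {c: int((row == c).sum()) for c in CATEGORIES}
    return CnvProfile(
        entity=matrix.entity, gene=gene, n_samples=len(tumor_cols), counts=counts
    )


def global_cnv_profile(
    matrices: Mapping[str, CnvMatrix],
    genes: Sequence[str],
    subset: Iterable[int] = ALTERED,
) -> pd.DataFrame:
    """Gene x entity matrix of altered fractions over the chosen categories."""
    subset = frozenset(subset)
    data = {
        entity: [cnv_profile(m, g).altered_fraction(subset) for g in genes]
        for entity, m in matrices.items()
    }
    return pd.DataFrame(data, index=pd.Index(list(genes), name="gene"))


def category_bars(
    profile: CnvProfile, as_fraction: bool = False
) -> list[tuple[int, float | int]]:
    """Per-category series ordered -2..2, as counts or cohort fractions."""
    if as_fraction:
        return [(c, profile.counts[c] / profile.n_samples) for c in CATEGORIES]
    return [(c, profile.counts[c]) for c in CATEGORIES]
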