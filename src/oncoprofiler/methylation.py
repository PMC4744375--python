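"""Differential methylation per (gene, region) within one entity.

Two modes mirror the availability of matched normals on the 450k platform:

* paired — tumor/normal pairs from the same participant only; a Wilcoxon
  signed-rank test on the per-pair beta differences;
* unpaired — all tumor vs all normal samples of the entity; a Wilcoxon
  rank-sum test.

Raw p-values are Benjamini-Hochberg adjusted jointly across every
(gene, region) test of one invocation. The effect size is delta-beta,
mean(tumor betas) - mean(normal betas); its sign — never the p-value —
determines the hyper/hypo direction, since p-values carry no direction.

Exact null distributions are used where they are cheap and valid (paired:
n <= 25 nonzero differences without ties in |d|; unpaired: m + n <= 20
without ties); otherwise the normal approximation with continuity and tie
corrections applies. Zero differences are dropped before ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import MethylationTable, SampleBarcode

__all__ = [
    "SamplePairing",
    "MethylationResult",
    "build_pairing",
    "wilcoxon_paired",
    "wilcoxon_unpaired",
    "bh_adjust",
    "differential_methylation",
    "delta_histogram",
]

#: below this many informative pairs a paired test is flagged underpowered
MIN_INFORMATIVE_PAIRS = 5


@dataclass(frozen=True)
class SamplePairing:
    """Tumor/normal pairs of one entity, keyed by participant."""

    entity: str
    pairs: tuple[tuple[str, str], ...]
    unpaired_tumors: tuple[str, ...]
    unpaired_normals: tuple[str, ...]


@dataclass(slots=True)
class MethylationResult:
    entity: str
    gene: str
    region: str
    mode: str
    n_tumor: int
    n_normal: int
    p_raw: float | None
    p_adj: float | None
    delta_beta: float | None
    direction: str  # hyper | hypo | none
    degenerate: bool = False
    underpowered: bool = False


def build_pairing(samples: Iterable[SampleBarcode], entity: str = "") -> SamplePairing:
    """Match tumor and normal samples of the same participant.

    Each participant contributes at most one pair; with multiple tumor or
    normal aliquots the lexicographically smallest sample key wins, so the
    pairing is deterministic. Leftover samples land in the unpaired lists.
    """
    tumors: dict[str, str] = {}
    normals: dict[str, str] = {}
    for b in samples:
        if b.is_tumor():
            bucket = tumors
        elif b.is_normal():
            bucket = normals
        else:
            continue
        pid = b.participant_id
        if pid not in bucket or b.sample_key < bucket[pid]:
            bucket[pid] = b.sample_key
    pairs = tuple(
        (tumors[pid], normals[pid]) for pid in sorted(tumors) if pid in normals
    )
    paired_pids = {pid for pid in tumors if pid in normals}
    return SamplePairing(
        entity=entity,
        pairs=pairs,
        unpaired_tumors=tuple(
            tumors[pid] for pid in sorted(tumors) if pid not in paired_pids
        ),
        unpaired_normals=tuple(
            normals[pid] for pid in sorted(normals) if pid not in paired_pids
        ),
    )


def wilcoxon_paired(differences: Sequence[float]) -> tuple[float, bool, bool]:
    """Two-sided Wilcoxon signed-rank p-value on paired differences.

    Returns ``(p, degenerate, underpowered)``. Zero differences are dropped
    before ranking; if all differences are zero the test is degenerate and
    p = 1. Exact null for n <= 25 without ties in |d|, otherwise the normal
    approximation with continuity and tie corrections.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    nonzero = d[d != 0]
    n = nonzero.size
    if n == 0:
        return 1.0, True, True
    underpowered = n < MIN_INFORMATIVE_PAIRS
    absd = np.abs(nonzero)
    no_ties = np.unique(absd).size == n
    method = "exact" if (n <= 25 and no_ties) else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", alternative="two-sided",
        correction=True, method=method,
    )
    return float(res.pvalue), False, underpowered


def wilcoxon_unpaired(
    tumor_values: Sequence[float], normal_values: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for m + n <= 20 without ties, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(tumor_values, dtype=float)
    y = np.asarray(normal_values, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min over j >= i (by ascending p) of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_methylation(
    table: MethylationTable,
    genes: Sequence[str] | None = None,
    mode: str = "paired",
) -> list[MethylationResult]:
    """Test every (gene, region) of an entity for differential methylation.

    The BH family is all (gene, region) tests of this invocation; rows with
    insufficient data are reported with missing p and excluded from the
    family. delta-beta and direction are filled regardless, whenever both
    group means exist.
    """
    if mode not in ("paired", "unpaired"):
        raise ValueError(f"unknown mode {mode!r}")
    pairing = build_pairing(table.samples, entity=table.entity)
    key_to_col = {b.sample_key: b.raw for b in table.samples}

    betas = table.betas
    if genes is not None:
        have = set(betas.index.get_level_values("gene"))
        missing = [g for g in genes if g not in have]
        if missing:
            raise KeyError(f"gene(s) absent from methylation table: {missing}")
        betas = betas.loc[betas.index.get_level_values("gene").isin(set(genes))]

    if mode == "paired":
        if not pairing.pairs:
            raise ValueError(
                f"entity {table.entity!r}: no tumor/normal pairs for paired mode"
            )
        t_cols = [key_to_col[t] for t, _ in pairing.pairs]
        n_cols = [key_to_col[n] for _, n in pairing.pairs]
    else:
        t_keys = [t for t, _ in pairing.pairs] + list(pairing.unpaired_tumors)
        n_keys = [n for _, n in pairing.pairs] + list(pairing.unpaired_normals)
        if not t_keys or not n_keys:
            raise ValueError(
                f"entity {table.entity!r}: unpaired mode needs both tumor and "
                f"normal samples"
            )
        t_cols = [key_to_col[k] for k in sorted(t_keys)]
        n_cols = [key_to_col[k] for k in sorted(n_keys)]

    results: list[MethylationResult] = []
    testable: list[int] = []
    p_raw_list: list[float] = []
    col_pos = {c: i for i, c in enumerate(betas.columns)}
    arr = betas.to_numpy(dtype=float)
    t_pos = np.array([col_pos[c] for c in t_cols], dtype=int)
    n_pos = np.array([col_pos[c] for c in n_cols], dtype=int)
    for ri, (gene, region) in enumerate(betas.index):
        t_vals = arr[ri, t_pos]
        n_vals = arr[ri, n_pos]
        if mode == "paired":
            ok = ~np.isnan(t_vals) & ~np.isnan(n_vals)
            t_use, n_use = t_vals[ok], n_vals[ok]
            n_tumor = n_normal = int(ok.sum())
        else:
            t_use, n_use = t_vals[~np.isnan(t_vals)], n_vals[~np.isnan(n_vals)]
            n_tumor, n_normal = t_use.size, n_use.size

        if t_use.size and n_use.size:
            delta = float(t_use.mean() - n_use.mean())
            direction = "hyper" if delta > 0 else ("hypo" if delta < 0 else "none")
        else:
            delta, direction = None, "none"

        degenerate = underpowered = False
        if mode == "paired" and n_tumor >= 1:
            p, degenerate, underpowered = wilcoxon_paired(t_use - n_use)
        elif mode == "unpaired" and n_tumor >= 1 and n_normal >= 1:
            p = wilcoxon_unpaired(t_use, n_use)
            underpowered = min(n_tumor, n_normal) < MIN_INFORMATIVE_PAIRS
        else:
            p = None

        res = MethylationResult(
            entity=table.entity,
            gene=gene,
            region=region,
            mode=mode,
            n_tumor=n_tumor,
            n_normal=n_normal,
            p_raw=p,
            p_adj=None,
            delta_beta=delta,
            direction=direction,
            degenerate=degenerate,
            underpowered=underpowered,
        )
        if p is not None:
            testable.append(len(results))
            p_raw_list.append(p)
        results.append(res)

    if p_raw_list:
        adjusted = bh_adjust(p_raw_list)
        for idx, q in zip(testable, adjusted):
            results[idx].p_adj = float(q)
    return results


def delta_histogram(
    table: MethylationTable,
    gene: str,
    region: str,
    pairing: SamplePairing | None = None,
    bin_width: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-pair tumor-normal beta differences.

    Returns ``(bin_edges, counts)`` with bins of the given width spanning
    [-1, 1]; counts sum to the number of pairs with a non-missing
    difference. A two-sided spread of mass diagnoses a gene that is both
    hyper- and hypomethylated across the cohort.
    """
    if pairing is None:
        pairing = build_pairing(table.samples, entity=table.entity)
    if not pairing.pairs:
        raise ValueError(f"entity {table.entity!r}: no tumor/normal pairs")
    key_to_col = {b.sample_key: b.raw for b in table.samples}
    row = table.betas.loc[(gene, region)]
    diffs = np.array(
        [
            row[key_to_col[t]] - row[key_to_col[n]]
            for t, n in pairing.pairs
        ],
        dtype=float,
    )
    diffs = diffs[~np.isnan(diffs)]
    nbins = int(round(2.0 / bin_width))
    edges = np.linspace(-1.0, 1.0, nbins + 1)
    counts, _ = np.histogram(diffs, bins=edges)
    return edges, counts
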