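"""Relative expression of a gene in each tumor sample of an entity.

Because matched normals are scarce in RNA-Seq cohorts, a sample's
expression is scored against the *remaining* tumor samples of the same
entity (leave-one-out). Two scores are available:

* z-score — (x_s - mean(ref)) / sd(ref), sd with the n-1 denominator;
* fold change — (x_s + eps) / (mean(ref) + eps), default pseudocount 1.

A call at threshold t is *over* when score >= t, *under* when score <= -t
(z-score) or <= 1/t (fold change, symmetric on the ratio scale), else
*neutral*. A zero-spread reference yields a degenerate flag rather than an
infinite score, and degenerate records are excluded from calls.

Values are scored on the RSEM normalized scale; ``log2=True`` applies
log2(x+1) before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import ExpressionMatrix

__all__ = [
    "Call",
    "RelativeExpression",
    "EntityExpressionSummary",
    "zscore_relative",
    "fold_change_relative",
    "loo_zscores",
    "expression_calls",
    "calls_to_frame",
    "waterfall_data",
    "entity_boxplot_summary",
]


class Call(str, Enum):
    OVER = "over"
    UNDER = "under"
    NEUTRAL = "neutral"


@dataclass(frozen=True, slots=True)
class RelativeExpression:
    entity: str
    gene: str
    sample: str
    raw_value: float
    score: float
    method: str
    call: Call
    degenerate: bool = False


@dataclass(frozen=True, slots=True)
class EntityExpressionSummary:
    """Box-plot five-number summary plus call counts for one (entity, gene)."""

    entity: str
    gene: str
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_over: int
    n_under: int


def zscore_relative(values: Sequence[float], sample_index: int) -> float:
    """Leave-one-out z-score of one sample against the rest.

    Returns NaN (degenerate) when the reference has zero spread. Requires
    at least 3 samples so the reference sd is defined.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError(f"need >=3 samples for a leave-one-out z-score, got {n}")
    ref = np.delete(values, sample_index)
    sd = ref.std(ddof=1)
    if sd == 0:
        return math.nan
    return float((values[sample_index] - ref.mean()) / sd)


def fold_change_relative(
    values: Sequence[float], sample_index: int, pseudocount: float = 1.0
) -> float:
    """Leave-one-out fold change (x_s + eps) / (mean(ref) + eps)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError(f"need >=3 samples, got {values.size}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ref_mean = np.delete(values, sample_index).mean()
    denom = ref_mean + pseudocount
    if denom == 0:
        raise ValueError("reference mean plus pseudocount is zero")
    return float((values[sample_index] + pseudocount) / denom)


def loo_zscores(row: np.ndarray) -> np.ndarray:
    """Vectorized leave-one-out z-scores for every entry of one gene row.

    Centering the row first keeps the running-sum formulation stable; the
    leave-one-out score itself is invariant under location shifts.
    """
    x = np.asarray(row, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need >=3 samples, got {n}")
    x0 = x
    x = x - x.mean()
    s, ss = x.sum(), (x * x).sum()
    mean_ref = (s - x) / (n - 1)
    var_ref = (ss - x * x - (n - 1) * mean_ref**2) / (n - 2)
    sd_ref = np.sqrt(np.clip(var_ref, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean_ref) / sd_ref
    z[sd_ref == 0] = np.nan
    # the running-sum form cancels catastrophically when the reference
    # spread is tiny relative to the row scale; recompute those few
    # entries directly on the uncentered values (whose tiny differences
    # centering destroys), so zero-spread references stay exactly NaN
    for i in np.nonzero(var_ref <= ss / (n - 1) * 1e-6)[0]:
        ref = np.delete(x0, i)
        v = ref.var(ddof=1)
        # a spread below the square of float rounding on the reference's
        # own scale is indistinguishable from zero
        z[i] = (
            np.nan
            if v <= (ref * ref).mean() * 1e-24
            else (x0[i] - ref.mean()) / np.sqrt(v)
        )
    return z


def _classify(score: float, method: str, threshold: float) -> Call:
    if math.isnan(score):
        return Call.NEUTRAL
    if method == "zscore":
        if score >= threshold:
            return Call.OVER
        if score <= -threshold:
            return Call.UNDER
    else:
        if score >= threshold:
            return Call.OVER
        if score <= 1.0 / threshold:
            return Call.UNDER
    return Call.NEUTRAL


def expression_calls(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    method: str = "zscore",
    threshold: float = 2.0,
    pseudocount: float = 1.0,
    log2: bool = False,
) -> list[RelativeExpression]:
    """Score and classify every (gene, tumor sample) of an entity.

    Normal samples (barcode type 10-19) are excluded from both the focal
    and the reference sets.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if method not in ("zscore", "foldchange"):
        raise ValueError(f"unknown method {method!r}")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"gene(s) absent from expression matrix: {missing}")

    tumor_cols = [b.raw for b in matrix.samples if b.is_tumor()]
    tumor_keys = {b.raw: b.sample_key for b in matrix.samples if b.is_tumor()}
    if len(tumor_cols) < 3:
        raise ValueError("need >=3 tumor samples")
    sub = matrix.values.loc[list(genes), tumor_cols]
    raw = sub.to_numpy(dtype=float)
    scored = np.log2(raw + 1.0) if log2 else raw

    out: list[RelativeExpression] = []
    n = len(tumor_cols)
    for gi, gene in enumerate(genes):
        row = scored[gi]
        if method == "zscore":
            scores = loo_zscores(row)
        else:
            s = row.sum()
            mean_ref = (s - row) / (n - 1)
            denom = mean_ref + pseudocount
            if (denom == 0).any():
                raise ValueError(
                    f"gene {gene!r}: reference mean plus pseudocount is zero"
                )
            scores = (row + pseudocount) / denom
        for ci, col in enumerate(tumor_cols):
            score = float(scores[ci])
            degenerate = math.isnan(score)
            out.append(
                RelativeExpression(
                    entity=matrix.entity,
                    gene=gene,
                    sample=tumor_keys[col],
                    raw_value=float(raw[gi, ci]),
                    score=score,
                    method=method,
                    call=_classify(score, method, threshold),
                    degenerate=degenerate,
                )
            )
    return out


def calls_to_frame(calls: Iterable[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entity": [c.entity for c in calls],
            "gene": [c.gene for c in calls],
            "sample": [c.sample for c in calls],
            "raw_value": [c.raw_value for c in calls],
            "score": [c.score for c in calls],
            "method": [c.method for c in calls],
            "call": [c.call.value for c in calls],
            "degenerate": [c.degenerate for c in calls],
        }
    )


def waterfall_data(
    calls: Iterable[RelativeExpression], axis: str = "entity_centric"
) -> dict[str, list[RelativeExpression]]:
    """Waterfall series: per panel, non-neutral calls by descending score.

    Panels are entities (``entity_centric``) or genes (``gene_centric``);
    ties in score break on the sample key for a stable order.
    """
    if axis not in ("entity_centric", "gene_centric"):
        raise ValueError(f"unknown axis {axis!r}")
    panels: dict[str, list[RelativeExpression]] = {}
    for c in calls:
        if c.call is Call.NEUTRAL:
            continue
        key = c.entity if axis == "entity_centric" else c.gene
        panels.setdefault(key, []).append(c)
    for series in panels.values():
        series.sort(key=lambda c: (-c.score, c.sample))
    return panels


def entity_summaries(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    threshold: float = 2.0,
    method: str = "zscore",
    log2: bool = False,
    calls: Iterable[RelativeExpression] | None = None,
) -> list[EntityExpressionSummary]:
    """Box-plot summaries for many genes at once.

    Reuses already-computed calls when given; otherwise computes them.
    """
    if calls is None:
        calls = expression_calls(matrix, genes, method=method, threshold=threshold, log2=log2)
    over: dict[str, int] = {}
    under: dict[str, int] = {}
    for c in calls:
        if c.call is Call.OVER:
            over[c.gene] = over.get(c.gene, 0) + 1
        elif c.call is Call.UNDER:
            under[c.gene] = under.get(c.gene, 0) + 1
    tumor_cols = [b.raw for b in matrix.samples if b.is_tumor()]
    raw = matrix.values.loc[list(genes), tumor_cols].to_numpy(dtype=float)
    out = []
    q1s, meds, q3s = np.percentile(raw, [25, 50, 75], axis=1)
    for gi, gene in enumerate(genes):
        values = raw[gi]
        q1, med, q3 = q1s[gi], meds[gi], q3s[gi]
        iqr = q3 - q1
        out.append(
            EntityExpressionSummary(
                entity=matrix.entity,
                gene=gene,
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                whisker_low=float(values[values >= q1 - 1.5 * iqr].min()),
                whisker_high=float(values[values <= q3 + 1.5 * iqr].max()),
                n_over=over.get(gene, 0),
                n_under=under.get(gene, 0),
            )
        )
    return out


def entity_boxplot_summary(
    matrix: ExpressionMatrix,
    gene: str,
    threshold: float = 2.0,
    method: str = "zscore",
    log2: bool = False,
) -> EntityExpressionSummary:
    """Box-plot summary of a gene's raw expression over the entity's tumors.

    Quartiles use linear interpolation; whiskers reach the most extreme
    points within 1.5 IQR of the quartiles. Over/under counts come from
    leave-one-out calls at the given threshold.
    """
    calls = expression_calls(matrix, [gene], method=method, threshold=threshold, log2=log2)
    values = np.array([c.raw_value for c in calls])
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    in_low = values[values >= q1 - 1.5 * iqr]
    in_high = values[values <= q3 + 1.5 * iqr]
    return EntityExpressionSummary(
        entity=matrix.entity,
        gene=gene,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(in_low.min()),
        whisker_high=float(in_high.max()),
        n_over=sum(c.call is Call.OVER for c in calls),
        n_under=sum(c.call is Call.UNDER for c in calls),
    )
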