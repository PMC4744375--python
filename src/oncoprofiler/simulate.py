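"""Seeded, format-faithful synthetic multi-omics cohorts.

Stands in for a Firehose bulk download: one cohort yields a MAF, a GISTIC
thresholded copy-number table, an RSEM expression matrix and a probe-level
450k methylation table, all over one coherent barcode roster, plus a
machine-readable truth sidecar recording every planted parameter and every
sampled ground-truth event. Identical spec and seed reproduce the files
byte for byte.

Generative model, per gene:

* mutation — each tumor sample mutated with probability ``mutation_rate``;
  the variant class of a mutated sample is drawn from
  ``variant_class_weights``;
* copy number — each tumor sample's category drawn from the 5-simplex
  ``cnv_category_probs`` over (-2, -1, 0, +1, +2); normal samples sit at 0;
* expression — log-normal (RSEM values are non-negative and right-skewed):
  value = exp(mu + sigma * z); planted outliers add an offset to z for one
  tumor sample;
* methylation — per region, probe betas drawn from a Beta distribution
  with the planted mean (tumor mean = baseline + delta, clipped into the
  open unit interval; clipping is recorded in the sidecar) and a common
  concentration.

One RNG stream per data type is derived from the master seed, so adding a
data type never perturbs the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import formats
from .formats import (
    CnvMatrix,
    ExpressionMatrix,
    MethylationTable,
    MutationRecord,
    SampleBarcode,
    METHYLATION_REGIONS,
    parse_barcode,
)

__all__ = [
    "GeneSpec",
    "CohortSpec",
    "CohortData",
    "TruthCheckReport",
    "load_spec",
    "simulate_cohort",
    "generate",
    "truth_check",
    "FILE_NAMES",
]

FILE_NAMES = {
    "maf": "mutations.maf.txt",
    "cnv": "all_thresholded.by_genes.txt",
    "rsem": "rsem_normalized.txt",
    "meth": "methylation_450k.txt",
    "roster": "roster.txt",
    "truth": "truth.json",
}

_DEFAULT_CLASS_WEIGHTS = {
    "Missense_Mutation": 0.55,
    "Nonsense_Mutation": 0.15,
    "Frame_Shift_Del": 0.08,
    "Frame_Shift_Ins": 0.07,
    "Splice_Site": 0.07,
    "Silent": 0.08,
}

# beta-distribution means are kept inside the open unit interval
_MEAN_EPS = 1e-3


class SpecValidationError(ValueError):
    """Raised before any file is written when a cohort spec is invalid."""


@dataclass
class GeneSpec:
    """Planted per-gene parameters across the four data types."""

    symbol: str
    gene_id: int
    mutation_rate: float = 0.05
    variant_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_WEIGHTS)
    )
    cnv_category_probs: tuple[float, ...] = (0.02, 0.08, 0.80, 0.08, 0.02)
    expr_log_mean: float = 6.0
    expr_log_sd: float = 0.5
    expr_outliers: tuple[tuple[int, float], ...] = ()
    meth_baseline: dict[str, float] | float = 0.30
    meth_delta: dict[str, float] | float = 0.0
    meth_concentration: float = 50.0

    def baseline_for(self, region: str) -> float:
        if isinstance(self.meth_baseline, Mapping):
            return float(self.meth_baseline.get(region, 0.30))
        return float(self.meth_baseline)

    def delta_for(self, region: str) -> float:
        if isinstance(self.meth_delta, Mapping):
            return float(self.meth_delta.get(region, 0.0))
        return float(self.meth_delta)


@dataclass
class CohortSpec:
    """A declarative description of one synthetic entity."""

    entity: str
    n_participants: int
    genes: list[GeneSpec]
    normal_fraction: float = 0.5
    probes_per_region: int = 2
    meth_missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise SpecValidationError("n_participants must be >= 1")
        if not self.genes:
            raise SpecValidationError("at least one gene required")
        if not 0.0 <= self.normal_fraction <= 1.0:
            raise SpecValidationError("normal_fraction must lie in [0, 1]")
        if not 0.0 <= self.meth_missing_rate < 1.0:
            raise SpecValidationError("meth_missing_rate must lie in [0, 1)")
        if self.probes_per_region < 1:
            raise SpecValidationError("probes_per_region must be >= 1")
        seen: set[str] = set()
        for g in self.genes:
            if g.symbol in seen:
                raise SpecValidationError(f"duplicate gene symbol {g.symbol!r}")
            seen.add(g.symbol)
            if not 0.0 <= g.mutation_rate <= 1.0:
                raise SpecValidationError(f"{g.symbol}: mutation_rate outside [0, 1]")
            if len(g.cnv_category_probs) != 5:
                raise SpecValidationError(f"{g.symbol}: cnv_category_probs must have 5 entries")
            probs = np.asarray(g.cnv_category_probs, dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise SpecValidationError(
                    f"{g.symbol}: cnv_category_probs must be a simplex (sum 1 +- 1e-9)"
                )
            if not g.variant_class_weights or min(g.variant_class_weights.values()) < 0:
                raise SpecValidationError(f"{g.symbol}: invalid variant_class_weights")
            if g.expr_log_sd <= 0:
                raise SpecValidationError(f"{g.symbol}: expr_log_sd must be > 0")
            if g.meth_concentration <= 0:
                raise SpecValidationError(f"{g.symbol}: meth_concentration must be > 0")
            for region in METHYLATION_REGIONS:
                if not 0.0 <= g.baseline_for(region) <= 1.0:
                    raise SpecValidationError(f"{g.symbol}: baseline beta outside [0, 1]")
            n_tumor = self.n_participants
            for idx, _off in g.expr_outliers:
                if not 0 <= idx < n_tumor:
                    raise SpecValidationError(
                        f"{g.symbol}: outlier sample index {idx} outside cohort"
                    )


@dataclass
class CohortData:
    """An in-memory cohort: the analysis-ready tables plus the truth."""

    spec: CohortSpec
    tumor_barcodes: list[str]
    normal_barcodes: list[str]
    maf_records: list[MutationRecord]
    maf_frame: pd.DataFrame
    cnv: CnvMatrix
    expression: ExpressionMatrix
    methylation: MethylationTable
    methylation_probes: pd.DataFrame
    truth: dict

    @property
    def roster(self) -> list[SampleBarcode]:
        return [parse_barcode(b) for b in self.tumor_barcodes + self.normal_barcodes]


def load_spec(path) -> CohortSpec:
    """Load a cohort spec from a YAML document mirroring :class:`CohortSpec`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    genes = []
    for g in doc.get("genes", []):
        g = dict(g)
        if "expr_outliers" in g:
            g["expr_outliers"] = tuple((int(i), float(o)) for i, o in g["expr_outliers"])
        if "cnv_category_probs" in g:
            g["cnv_category_probs"] = tuple(float(p) for p in g["cnv_category_probs"])
        genes.append(GeneSpec(**g))
    fields = {k: doc[k] for k in (
        "entity", "n_participants", "normal_fraction", "probes_per_region",
        "meth_missing_rate", "seed",
    ) if k in doc}
    spec = CohortSpec(genes=genes, **fields)
    spec.validate()
    return spec


def _barcode(participant: int, sample_type: int) -> str:
    return f"TCGA-SY-{participant:04d}-{sample_type:02d}A-11D-A001-01"


def _rng(spec: CohortSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Sample one cohort in memory; no files touched."""
    spec.validate()
    n = spec.n_participants
    n_normal = int(round(n * spec.normal_fraction))
    tumor_barcodes = [_barcode(i, 1) for i in range(n)]
    normal_barcodes = [_barcode(i, 11) for i in range(n_normal)]
    all_barcodes = tumor_barcodes + normal_barcodes
    parsed = [parse_barcode(b) for b in all_barcodes]
    tumor_keys = [parse_barcode(b).sample_key for b in tumor_barcodes]

    truth: dict = {
        "entity": spec.entity,
        "seed": spec.seed,
        "n_participants": n,
        "normal_fraction": spec.normal_fraction,
        "tumor_barcodes": tumor_barcodes,
        "normal_barcodes": normal_barcodes,
        "genes": {
            g.symbol: {
                "gene_id": g.gene_id,
                "mutation_rate": g.mutation_rate,
                "cnv_category_probs": list(g.cnv_category_probs),
                "expr_log_mean": g.expr_log_mean,
                "expr_log_sd": g.expr_log_sd,
                "expr_outliers": [list(o) for o in g.expr_outliers],
                "meth_baseline": g.meth_baseline,
                "meth_delta": g.meth_delta,
            }
            for g in spec.genes
        },
        "clipped": [],
    }

    # --- mutations ----------------------------------------------------
    rng = _rng(spec, 0)
    maf_rows: list[dict] = []
    mutation_truth: dict[str, dict[str, str]] = {}
    for g in spec.genes:
        classes = list(g.variant_class_weights)
        weights = np.asarray([g.variant_class_weights[c] for c in classes], dtype=float)
        weights = weights / weights.sum()
        hits = rng.random(n) < g.mutation_rate
        drawn = rng.choice(len(classes), size=n, p=weights)
        per_gene: dict[str, str] = {}
        for i in np.nonzero(hits)[0]:
            vclass = classes[drawn[i]]
            per_gene[tumor_keys[i]] = vclass
            maf_rows.append(
                {
                    "Hugo_Symbol": g.symbol,
                    "Entrez_Gene_Id": g.gene_id,
                    "Variant_Classification": vclass,
                    "Tumor_Sample_Barcode": tumor_barcodes[i],
                }
            )
        mutation_truth[g.symbol] = per_gene
    truth["mutations"] = mutation_truth
    maf_frame = pd.DataFrame(
        maf_rows,
        columns=["Hugo_Symbol", "Entrez_Gene_Id", "Variant_Classification", "Tumor_Sample_Barcode"],
    )
    maf_records = [
        MutationRecord(
            gene=r["Hugo_Symbol"],
            variant_class=r["Variant_Classification"],
            barcode=parse_barcode(r["Tumor_Sample_Barcode"]),
            entity=spec.entity,
        )
        for r in maf_rows
    ]

    # --- copy number --------------------------------------------------
    rng = _rng(spec, 1)
    cats = np.zeros((len(spec.genes), len(all_barcodes)), dtype=np.int8)
    cnv_truth: dict[str, list[int]] = {}
    cat_values = np.array(CATEGORIES_INT)
    for gi, g in enumerate(spec.genes):
        draw = rng.choice(5, size=n, p=np.asarray(g.cnv_category_probs, dtype=float))
        cats[gi, :n] = cat_values[draw]
        cnv_truth[g.symbol] = [int(v) for v in cats[gi]]
    truth["cnv"] = {"samples": all_barcodes, "categories": cnv_truth}
    cnv = CnvMatrix(
        entity=spec.entity,
        categories=pd.DataFrame(
            cats,
            index=pd.Index([g.symbol for g in spec.genes], name="gene"),
            columns=all_barcodes,
        ),
        annotation=pd.DataFrame(
            {
                "Gene Symbol": [g.symbol for g in spec.genes],
                "Locus ID": [g.gene_id for g in spec.genes],
                "Cytoband": ["1p36.33" for _ in spec.genes],
            }
        ).set_index(pd.Index([g.symbol for g in spec.genes], name="gene")),
        samples=parsed,
    )

    # --- expression ---------------------------------------------------
    rng = _rng(spec, 2)
    z = rng.standard_normal((len(spec.genes), len(all_barcodes)))
    for gi, g in enumerate(spec.genes):
        for idx, offset in g.expr_outliers:
            z[gi, idx] += offset
    mus = np.array([g.expr_log_mean for g in spec.genes])[:, None]
    sds = np.array([g.expr_log_sd for g in spec.genes])[:, None]
    values = np.exp(mus + sds * z)
    expr_frame = pd.DataFrame(
        values,
        index=pd.Index([g.symbol for g in spec.genes], name="gene"),
        columns=all_barcodes,
    )
    truth["expression"] = {
        g.symbol: [float(v) for v in values[gi]] for gi, g in enumerate(spec.genes)
    }
    expression = ExpressionMatrix(
        entity=spec.entity,
        values=expr_frame,
        gene_ids={g.symbol: g.gene_id for g in spec.genes},
        samples=parsed,
    )

    # --- methylation --------------------------------------------------
    rng = _rng(spec, 3)
    probe_rows: list[dict] = []
    agg_index: list[tuple[str, str]] = []
    agg_data: list[np.ndarray] = []
    probe_counter = 0
    n_all = len(all_barcodes)
    for g in spec.genes:
        for region in METHYLATION_REGIONS:
            base = g.baseline_for(region)
            delta = g.delta_for(region)
            tumor_mean = base + delta
            clipped_mean = min(max(tumor_mean, _MEAN_EPS), 1.0 - _MEAN_EPS)
            if clipped_mean != tumor_mean:
                truth["clipped"].append([g.symbol, region])
            normal_mean = min(max(base, _MEAN_EPS), 1.0 - _MEAN_EPS)
            means = np.where(
                np.arange(n_all) < n, clipped_mean, normal_mean
            )
            k = g.meth_concentration
            probes = rng.beta(means * k, (1.0 - means) * k,
                              size=(spec.probes_per_region, n_all))
            if spec.meth_missing_rate > 0:
                mask = rng.random(probes.shape) < spec.meth_missing_rate
                probes = np.where(mask, np.nan, probes)
            for p in range(spec.probes_per_region):
                probe_rows.append(
                    {
                        "Probe": f"cg{probe_counter:08d}",
                        "Gene_Symbol": g.symbol,
                        "Gene_Region": region,
                        **{bc: probes[p, j] for j, bc in enumerate(all_barcodes)},
                    }
                )
                probe_counter += 1
            observed = (~np.isnan(probes)).sum(axis=0)
            sums = np.nansum(probes, axis=0)
            agg = np.where(observed > 0, sums / np.maximum(observed, 1), np.nan)
            agg_index.append((g.symbol, region))
            agg_data.append(agg)
    meth_frame = pd.DataFrame(
        agg_data,
        index=pd.MultiIndex.from_tuples(agg_index, names=["gene", "region"]),
        columns=all_barcodes,
    ).sort_index()
    truth["methylation"] = {
        f"{gene}|{region}": [
            None if math.isnan(v) else float(v) for v in meth_frame.loc[(gene, region)]
        ]
        for gene, region in meth_frame.index
    }
    truth["methylation_samples"] = all_barcodes
    methylation = MethylationTable(entity=spec.entity, betas=meth_frame, samples=parsed)
    probes_frame = pd.DataFrame(
        probe_rows, columns=["Probe", "Gene_Symbol", "Gene_Region", *all_barcodes]
    )

    return CohortData(
        spec=spec,
        tumor_barcodes=tumor_barcodes,
        normal_barcodes=normal_barcodes,
        maf_records=maf_records,
        maf_frame=maf_frame,
        cnv=cnv,
        expression=expression,
        methylation=methylation,
        methylation_probes=probes_frame,
        truth=truth,
    )


CATEGORIES_INT = (-2, -1, 0, 1, 2)


def _fmt(v: float) -> str:
    # shortest decimal repr that round-trips the float exactly
    v = float(v)
    if math.isnan(v):
        return ""
    return repr(v)


def generate(spec: CohortSpec, outdir, write_truth: bool = True) -> CohortData:
    """Write the four flat files (plus roster and truth sidecar) to outdir.

    Identical spec and seed produce byte-identical files.
    """
    data = simulate_cohort(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    data.maf_frame.to_csv(outdir / FILE_NAMES["maf"], sep="\t", index=False)

    cnv_out = pd.concat(
        [data.cnv.annotation.reset_index(drop=True),
         data.cnv.categories.reset_index(drop=True)],
        axis=1,
    )
    cnv_out.to_csv(outdir / FILE_NAMES["cnv"], sep="\t", index=False)

    all_bc = data.tumor_barcodes + data.normal_barcodes
    with open(outdir / FILE_NAMES["rsem"], "w", encoding="utf-8") as fh:
        fh.write("Hybridization REF\t" + "\t".join(all_bc) + "\n")
        fh.write("gene_id\t" + "\t".join(["normalized_count"] * len(all_bc)) + "\n")
        for g in data.spec.genes:
            row = data.expression.values.loc[g.symbol]
            fh.write(
                f"{g.symbol}|{g.gene_id}\t"
                + "\t".join(_fmt(v) for v in row.to_numpy())
                + "\n"
            )

    with open(outdir / FILE_NAMES["meth"], "w", encoding="utf-8") as fh:
        fh.write("Probe\tGene_Symbol\tGene_Region\t" + "\t".join(all_bc) + "\n")
        for row in data.methylation_probes.itertuples(index=False):
            probe, gene, region, *betas = row
            fh.write(
                f"{probe}\t{gene}\t{region}\t" + "\t".join(_fmt(b) for b in betas) + "\n"
            )

    with open(outdir / FILE_NAMES["roster"], "w", encoding="utf-8") as fh:
        for bc in all_bc:
            fh.write(bc + "\n")

    if write_truth:
        with open(outdir / FILE_NAMES["truth"], "w", encoding="utf-8") as fh:
            json.dump(data.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return data


@dataclass
class TruthCheckReport:
    ok: bool
    failures: list[str] = field(default_factory=list)


def truth_check(outdir, atol: float = 1e-9) -> TruthCheckReport:
    """Re-read the generated files and verify them against the truth sidecar."""
    outdir = Path(outdir)
    failures: list[str] = []
    try:
        with open(outdir / FILE_NAMES["truth"], "r", encoding="utf-8") as fh:
            truth = json.load(fh)
    except FileNotFoundError:
        return TruthCheckReport(ok=False, failures=["truth sidecar missing"])

    entity = truth["entity"]
    all_bc = truth["tumor_barcodes"] + truth["normal_barcodes"]

    # mutations
    try:
        records, _ = formats.read_maf(outdir / FILE_NAMES["maf"], entity)
        seen: dict[str, dict[str, str]] = {g: {} for g in truth["mutations"]}
        for r in records:
            seen.setdefault(r.gene, {})[r.barcode.sample_key] = r.variant_class
        if seen != truth["mutations"]:
            for gene in set(seen) | set(truth["mutations"]):
                if seen.get(gene, {}) != truth["mutations"].get(gene, {}):
                    failures.append(f"maf: gene {gene} mutation set mismatch")
    except FileNotFoundError:
        failures.append("maf file missing")

    # cnv
    try:
        cnv = formats.read_gistic_thresholded(outdir / FILE_NAMES["cnv"], entity)
        t_samples = truth["cnv"]["samples"]
        for gene, cats in truth["cnv"]["categories"].items():
            got = cnv.categories.loc[gene, t_samples].to_numpy()
            diff = np.nonzero(got != np.asarray(cats))[0]
            if diff.size:
                failures.append(
                    f"cnv: gene {gene}, sample {t_samples[diff[0]]}: "
                    f"file {got[diff[0]]} != truth {cats[diff[0]]}"
                )
    except FileNotFoundError:
        failures.append("cnv file missing")

    # expression
    try:
        expr, _ = formats.read_rsem_matrix(outdir / FILE_NAMES["rsem"], entity)
        for gene, vals in truth["expression"].items():
            got = expr.values.loc[gene, all_bc].to_numpy(dtype=float)
            if not np.allclose(got, vals, rtol=0, atol=atol):
                failures.append(f"rsem: gene {gene} values differ beyond {atol}")
    except FileNotFoundError:
        failures.append("rsem file missing")

    # methylation
    try:
        meth, _ = formats.read_methylation(outdir / FILE_NAMES["meth"], entity)
        m_samples = truth["methylation_samples"]
        for key, vals in truth["methylation"].items():
            gene, region = key.split("|", 1)
            got = meth.betas.loc[(gene, region), m_samples].to_numpy(dtype=float)
            want = np.array([np.nan if v is None else v for v in vals], dtype=float)
            same_nan = np.isnan(got) == np.isnan(want)
            close = np.isnan(want) | (np.abs(got - np.nan_to_num(want)) <= atol)
            bad = ~(same_nan & (np.isnan(got) | np.isclose(got, want, rtol=0, atol=atol, equal_nan=True)))
            if bad.any():
                j = int(np.nonzero(bad)[0][0])
                failures.append(
                    f"methylation: ({gene}, {region}), sample {m_samples[j]} mismatch"
                )
    except FileNotFoundError:
        failures.append("methylation file missing")

    return TruthCheckReport(ok=not failures, failures=failures)
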