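"""Readers and writers for the four TCGA/Firehose flat-file dialects.

Everything downstream of this module consumes only the types defined here:
parsed sample barcodes, somatic mutation records (MAF), RSEM-normalized
expression matrices, GISTIC2.0 thresholded copy-number matrices, and
gene/region-aggregated 450k methylation beta tables.

Firehose files vary between snapshots; the dialects accepted here are pinned
(see the reader docstrings) so that round-trip tests against the bundled
cohort simulator are exact. Gene identity throughout is the HUGO symbol;
numeric ids are carried as metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeError",
    "FormatError",
    "SampleBarcode",
    "MutationRecord",
    "ExpressionMatrix",
    "MethylationTable",
    "CnvMatrix",
    "ReaderReport",
    "METHYLATION_REGIONS",
    "parse_barcode",
    "read_maf",
    "read_rsem_matrix",
    "read_gistic_thresholded",
    "read_methylation",
    "write_summary_table",
]


class BarcodeError(ValueError):
    """Raised for a TCGA sample barcode that does not follow the grammar."""


class FormatError(ValueError):
    """Raised for an input file violating its pinned dialect."""


#: The six Illumina 450k gene-group region tokens a methylation probe may
#: be annotated with. Composite annotations ("Body;3'UTR") are split and the
#: probe contributes to each region.
METHYLATION_REGIONS: tuple[str, ...] = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1stExon",
    "Body",
    "3'UTR",
)


@dataclass(frozen=True, slots=True)
class SampleBarcode:
    """A parsed TCGA sample barcode, e.g. ``TCGA-A1-A0SB-01A-11R-A144-07``.

    The first four dash-separated fields identify project, tissue source
    site, participant, and sample; the two leading digits of the sample
    field encode the sample type (01-09 tumor, 10-19 normal, 20-29 control).
    """

    project: str
    tss: str
    participant: str
    sample_type: int
    vial: str
    remainder: str | None
    raw: str

    @property
    def participant_id(self) -> str:
        return f"{self.project}-{self.tss}-{self.participant}"

    @property
    def sample_key(self) -> str:
        """Participant plus sample-type code; aliquot fields are dropped so
        replicate aliquots of one sample collapse onto one key."""
        return f"{self.participant_id}-{self.sample_type:02d}"

    def is_tumor(self) -> bool:
        return 1 <= self.sample_type <= 9

    def is_normal(self) -> bool:
        return 10 <= self.sample_type <= 19

    def serialize_prefix(self) -> str:
        return f"{self.participant_id}-{self.sample_type:02d}{self.vial}"


def parse_barcode(text: str) -> SampleBarcode:
    """Parse a TCGA sample barcode.

    Requires at least the four sample-level fields; anything beyond the
    sample field (portion/analyte, plate, center) is kept verbatim in
    ``remainder``.
    """
    raw = text.strip()
    fields = raw.split("-")
    if len(fields) < 4:
        raise BarcodeError(
            f"barcode {raw!r}: expected >=4 dash-separated fields "
            f"(missing sample-type field)"
        )
    project, tss, participant, sample_field = fields[:4]
    for name, value in (("project", project), ("tss", tss), ("participant", participant)):
        if not value:
            raise BarcodeError(f"barcode {raw!r}: empty {name} field")
    if len(sample_field) < 2 or not sample_field[:2].isdigit():
        raise BarcodeError(
            f"barcode {raw!r}: sample field {sample_field!r} must start with two digits"
        )
    sample_type = int(sample_field[:2])
    if not 1 <= sample_type <= 29:
        raise BarcodeError(
            f"barcode {raw!r}: sample type {sample_type:02d} outside 01..29"
        )
    remainder = "-".join(fields[4:]) if len(fields) > 4 else None
    return SampleBarcode(
        project=project,
        tss=tss,
        participant=participant,
        sample_type=sample_type,
        vial=sample_field[2:],
        remainder=remainder,
        raw=raw,
    )


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic mutation call: gene, Firehose variant classification,
    sample barcode, cohort label. The classification token is preserved
    verbatim from the input."""

    gene: str
    variant_class: str
    barcode: SampleBarcode
    entity: str


@dataclass(slots=True)
class ReaderReport:
    """Row accounting for a reader invocation."""

    n_rows: int = 0
    n_kept: int = 0
    dropped_gene: int = 0
    skipped_barcode: int = 0
    skipped_region: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass(slots=True)
class ExpressionMatrix:
    """RSEM-normalized expression, genes x samples, for one entity.

    ``values`` is indexed by gene label (the HUGO symbol, or ``SYMBOL|ID``
    where symbols collide) with one column per original barcode string.
    """

    entity: str
    values: pd.DataFrame
    gene_ids: dict[str, int]
    samples: list[SampleBarcode]

    @property
    def gene_labels(self) -> list[str]:
        return list(self.values.index)


@dataclass(slots=True)
class MethylationTable:
    """Gene/region-aggregated 450k beta values for one entity.

    ``betas`` carries a (gene, region) MultiIndex and one column per
    original barcode string; missing cells are NaN (masked probes are
    legitimate in level-3 methylation data and are never imputed).
    """

    entity: str
    betas: pd.DataFrame
    samples: list[SampleBarcode]


@dataclass(slots=True)
class CnvMatrix:
    """GISTIC2.0 thresholded categories, genes x samples, for one entity.

    Every entry is one of -2 (homozygous deletion), -1 (heterozygous
    deletion), 0 (normal copy number), +1 (low-level gain), +2 (high-level
    amplification).
    """

    entity: str
    categories: pd.DataFrame
    annotation: pd.DataFrame
    samples: list[SampleBarcode]


_MAF_REQUIRED = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


def read_maf(path, entity: str) -> tuple[list[MutationRecord], ReaderReport]:
    """Read a MAF-style somatic mutation table (level 2).

    Tab-separated with a header containing at least Hugo_Symbol,
    Variant_Classification and Tumor_Sample_Barcode; ``#`` comment lines
    allowed. Rows whose symbol is ``Unknown`` or ``?`` are dropped and
    counted; rows with unparseable barcodes are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: MAF missing mandatory column(s) {missing}")
    report = ReaderReport(n_rows=len(df))
    records: list[MutationRecord] = []
    for gene, vclass, bc_text in zip(
        df["Hugo_Symbol"], df["Variant_Classification"], df["Tumor_Sample_Barcode"]
    ):
        if gene in ("Unknown", "?", ""):
            report.dropped_gene += 1
            continue
        try:
            barcode = parse_barcode(bc_text)
        except BarcodeError as exc:
            report.skipped_barcode += 1
            report.warnings.append(str(exc))
            continue
        records.append(
            MutationRecord(gene=gene, variant_class=vclass, barcode=barcode, entity=entity)
        )
    report.n_kept = len(records)
    return records, report


def read_rsem_matrix(path, entity: str) -> tuple[ExpressionMatrix, ReaderReport]:
    """Read a Firehose RSEM normalized-count matrix (RNA-SeqV2 level 3).

    First column holds gene ids as ``SYMBOL|NUMID``; remaining columns are
    sample barcodes. An optional second header line of per-column measure
    names (e.g. ``normalized_count``) is detected and skipped. Rows with
    symbol ``?`` are dropped and counted. Missing or non-numeric cells are
    a format error (expression matrices do not legitimately contain holes).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: RSEM matrix needs a gene-id column and >=1 sample")
    report = ReaderReport(n_rows=len(df))
    if len(df) > 0:
        first = df.iloc[0, 1:]
        if all(not _is_number(v) for v in first):
            # second header line of measure names
            df = df.iloc[1:].reset_index(drop=True)
            report.n_rows = len(df)

    barcodes = [parse_barcode(c) for c in df.columns[1:]]
    symbols: list[str] = []
    gene_ids: list[int] = []
    keep_mask: list[bool] = []
    for gid_text in df.iloc[:, 0]:
        sym, _, num = gid_text.partition("|")
        if sym == "?":
            report.dropped_gene += 1
            keep_mask.append(False)
            continue
        keep_mask.append(True)
        symbols.append(sym)
        try:
            gene_ids.append(int(num) if num else -1)
        except ValueError as exc:
            raise FormatError(f"{path}: bad gene id {gid_text!r}") from exc

    data = df.loc[keep_mask, df.columns[1:]]
    values = data.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        row, col = next(
            (r, c) for r, c in zip(*np.nonzero(values.isna().to_numpy()))
        )
        raise FormatError(
            f"{path}: non-numeric value at data row {row}, column {data.columns[col]!r}"
        )
    if (values.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression value")

    labels = _disambiguate(symbols, gene_ids)
    values.index = pd.Index(labels, name="gene")
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene row {dup!r}")
    report.n_kept = len(values)
    return (
        ExpressionMatrix(
            entity=entity,
            values=values,
            gene_ids=dict(zip(labels, gene_ids)),
            samples=barcodes,
        ),
        report,
    )


def _disambiguate(symbols: Sequence[str], gene_ids: Sequence[int]) -> list[str]:
    counts = pd.Series(symbols).value_counts()
    return [
        f"{s}|{g}" if counts[s] > 1 else s for s, g in zip(symbols, gene_ids)
    ]


def _is_number(text: str) -> bool:
    try:
        float(text)
    except (TypeError, ValueError):
        return False
    return True


_GISTIC_LEADING = ("Gene Symbol", "Locus ID", "Cytoband")


def read_gistic_thresholded(path, entity: str) -> CnvMatrix:
    """Read a GISTIC2.0 ``all_thresholded.by_genes`` table (level 4).

    Leading columns Gene Symbol / Locus ID / Cytoband, then one integer
    column per barcode with values in {-2,...,2}. Duplicate gene symbols
    and out-of-range cells are format errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _GISTIC_LEADING if c not in df.columns[:3]]
    if missing:
        raise FormatError(f"{path}: GISTIC table missing leading column(s) {missing}")
    sample_cols = list(df.columns[3:])
    barcodes = [parse_barcode(c) for c in sample_cols]
    symbols = df["Gene Symbol"]
    if symbols.duplicated().any():
        dup = symbols[symbols.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene symbol {dup!r}")
    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any() or (arr != np.round(arr)).any():
        raise FormatError(f"{path}: non-integer copy-number category cell")
    if ((arr < -2) | (arr > 2)).any():
        r, c = next(zip(*np.nonzero((arr < -2) | (arr > 2))))
        raise FormatError(
            f"{path}: category {arr[r, c]:g} outside -2..2 at gene "
            f"{symbols.iloc[r]!r}, sample {sample_cols[c]!r}"
        )
    categories = pd.DataFrame(
        arr.astype(np.int8), index=pd.Index(symbols, name="gene"), columns=sample_cols
    )
    annotation = df[list(_GISTIC_LEADING)].set_index(symbols.rename("gene"))
    return CnvMatrix(
        entity=entity, categories=categories, annotation=annotation, samples=barcodes
    )


def read_methylation(path, entity: str) -> tuple[MethylationTable, ReaderReport]:
    """Read a level-3 450k-style methylation beta table.

    Two dialects, detected by the presence of a ``Probe`` column:

    * long/probe dialect — columns ``Probe``, ``Gene_Symbol``,
      ``Gene_Region``, then one beta column per barcode; probe betas are
      aggregated to (gene, region, sample) by the mean over probes,
      ignoring missing values;
    * wide dialect — columns ``Gene_Symbol``, ``Gene_Region``, then one
      column per barcode, already at gene/region resolution.

    Region annotations may be composite (``Body;3'UTR``); the probe then
    contributes to each named region. Unknown region tokens skip the row
    with a warning; betas outside [0,1] are format errors. Missing betas
    are allowed and stay missing — a cell with no observed probe is NaN,
    never 0.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    report = ReaderReport(n_rows=len(df))
    probe_dialect = "Probe" in df.columns
    needed = ["Gene_Symbol", "Gene_Region"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: methylation table missing column(s) {missing}")
    meta_cols = (["Probe"] if probe_dialect else []) + needed
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError(f"{path}: methylation table has no sample columns")
    barcodes = [parse_barcode(c) for c in sample_cols]

    raw_text = df[sample_cols]
    betas = raw_text.apply(pd.to_numeric, errors="coerce")
    if (betas.isna() & ~raw_text.isin(["", "NA"])).any().any():
        raise FormatError(f"{path}: non-numeric beta value")
    arr = betas.to_numpy(dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise FormatError(f"{path}: beta value outside [0,1]")

    rows: list[tuple[str, str]] = []
    row_data: list[np.ndarray] = []
    valid = set(METHYLATION_REGIONS)
    for i, (gene, region_text) in enumerate(zip(df["Gene_Symbol"], df["Gene_Region"])):
        regions = [r.strip() for r in region_text.split(";") if r.strip()]
        unknown = [r for r in regions if r not in valid]
        if unknown or not regions:
            report.skipped_region += 1
            report.warnings.append(
                f"row {i}: unknown region token(s) {unknown or [region_text]}"
            )
            continue
        for region in regions:
            rows.append((gene, region))
            row_data.append(arr[i])
    if rows:
        long = pd.DataFrame(
            row_data,
            index=pd.MultiIndex.from_tuples(rows, names=["gene", "region"]),
            columns=sample_cols,
        )
        # mean over probes per (gene, region), NaN-ignoring; all-NaN stays NaN
        agg = long.groupby(level=["gene", "region"], sort=True).mean()
    else:
        agg = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["gene", "region"]),
            columns=sample_cols,
            dtype=float,
        )
    report.n_kept = len(agg)
    return MethylationTable(entity=entity, betas=agg, samples=barcodes), report


def write_summary_table(rows, path) -> None:
    """Write records as a UTF-8 tab-separated table.

    ``rows`` is a DataFrame or an iterable of mappings sharing a schema.
    Floats are rendered with 6 significant digits; missing values become
    empty cells. Column order follows the DataFrame / first record.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows, columns=list(rows[0].keys()) if rows else None)
    df.to_csv(
        path,
        sep="\t",
        index=False,
        float_format="%.6g",
        na_rep="",
        encoding="utf-8",
    )
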