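"""Per-entity, per-gene somatic mutation frequencies and variant-class
breakdowns.

The mutation frequency of a gene in a cohort is the fraction of assayed
tumor samples carrying at least one qualifying record for that gene. The
denominator is the full assayed cohort, not only mutated samples: MAFs only
list mutated samples, so by default the cohort is every distinct tumor
barcode appearing anywhere in the entity's MAF, overridable with an
explicit roster (the realistic choice when a sample manifest exists).

Samples are keyed by participant plus sample-type code, so replicate
aliquots of one tumor count once. All Firehose variant classes — including
Silent — qualify by default; a class filter can restrict them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import MutationRecord, SampleBarcode

__all__ = [
    "VARIANT_CLASSIFICATIONS",
    "CohortIndex",
    "MutationProfile",
    "mutation_frequency",
    "global_mutation_profile",
    "class_breakdown",
]

#: Firehose variant-classification vocabulary (non-exhaustive in the wild;
#: classes actually present in the input always qualify).
VARIANT_CLASSIFICATIONS: frozenset[str] = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Silent",
        "Translation_Start_Site",
        "RNA",
        "Intron",
        "5'UTR",
        "3'UTR",
        "5'Flank",
        "3'Flank",
        "IGR",
    }
)


@dataclass(frozen=True)
class CohortIndex:
    """The assayed tumor samples of one entity — the frequency denominator."""

    entity: str
    tumor_samples: frozenset[str]

    @property
    def n_samples(self) -> int:
        return len(self.tumor_samples)

    @classmethod
    def from_records(cls, entity: str, records: Iterable[MutationRecord]) -> "CohortIndex":
        """Cohort = distinct tumor sample keys appearing in the MAF."""
        keys = frozenset(
            r.barcode.sample_key
            for r in records
            if r.entity == entity and r.barcode.is_tumor()
        )
        return cls(entity=entity, tumor_samples=keys)

    @classmethod
    def from_roster(cls, entity: str, barcodes: Iterable[SampleBarcode]) -> "CohortIndex":
        keys = frozenset(b.sample_key for b in barcodes if b.is_tumor())
        return cls(entity=entity, tumor_samples=keys)


@dataclass
class MutationProfile:
    """Mutation summary for one (entity, gene).

    ``class_counts`` tallies qualifying records per variant class;
    ``class_sample_counts`` tallies distinct mutated samples per class.
    """

    entity: str
    gene: str
    n_samples: int
    n_mutated: int
    class_counts: dict[str, int] = field(default_factory=dict)
    class_sample_counts: dict[str, int] = field(default_factory=dict)
    n_outside_cohort: int = 0

    @property
    def frequency(self) -> float:
        return self.n_mutated / self.n_samples


def mutation_frequency(
    records: Iterable[MutationRecord],
    cohort: CohortIndex,
    gene: str,
    class_filter: Sequence[str] | None = None,
) -> MutationProfile:
    """Mutation frequency and class breakdown of one gene in one cohort.

    A sample counts toward ``n_mutated`` at most once however many records
    it has for the gene. Records from samples outside the cohort are
    ignored and counted in ``n_outside_cohort``.
    """
    if cohort.n_samples == 0:
        raise ValueError(f"empty cohort for entity {cohort.entity!r}")
    present = {r.variant_class for r in records if r.entity == cohort.entity}
    if class_filter is not None:
        unknown = [
            c for c in class_filter if c not in VARIANT_CLASSIFICATIONS and c not in present
        ]
        if unknown:
            raise ValueError(f"unknown variant class(es) in filter: {unknown}")
        allowed = set(class_filter)
    else:
        allowed = None

    class_counts: dict[str, int] = {}
    class_samples: dict[str, set[str]] = {}
    mutated: set[str] = set()
    outside = 0
    for r in records:
        if r.entity != cohort.entity or r.gene != gene:
            continue
        if allowed is not None and r.variant_class not in allowed:
            continue
        key = r.barcode.sample_key
        if key not in cohort.tumor_samples:
            outside += 1
            continue
        mutated.add(key)
        class_counts[r.variant_class] = class_counts.get(r.variant_class, 0) + 1
        class_samples.setdefault(r.variant_class, set()).add(key)
    return MutationProfile(
        entity=cohort.entity,
        gene=gene,
        n_samples=cohort.n_samples,
        n_mutated=len(mutated),
        class_counts=class_counts,
        class_sample_counts={c: len(s) for c, s in class_samples.items()},
        n_outside_cohort=outside,
    )


def global_mutation_profile(
    records: Iterable[MutationRecord],
    cohorts: Mapping[str, CohortIndex],
    genes: Sequence[str],
    class_filter: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene x entity matrix of mutation frequencies (the global profile).

    Genes absent from an entity's records get frequency 0, not missing.
    """
    if not genes:
        raise ValueError("at least one gene required")
    records = list(records)
    entities = list(cohorts)
    if not entities:
        raise ValueError("at least one entity required")
    by_entity: dict[str, list[MutationRecord]] = {e: [] for e in entities}
    for r in records:
        if r.entity in by_entity:
            by_entity[r.entity].append(r)
    data = {
        entity: [
            mutation_frequency(by_entity[entity], cohorts[entity], g, class_filter).frequency
            for g in genes
        ]
        for entity in entities
    }
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def class_breakdown(profile: MutationProfile) -> list[tuple[str, float, float]]:
    """Per-class (slice proportion, per-sample percentage) for circle charts.

    The slice proportion relates a class's record count to all qualifying
    records of the gene; the sample percentage relates its distinct mutated
    samples to all tumor samples of the entity. Classes without any record
    are omitted.
    """
    total = sum(profile.class_counts.values())
    if total == 0:
        return []
    out = [
        (
            vclass,
            count / total,
            profile.class_sample_counts.get(vclass, 0) / profile.n_samples,
        )
        for vclass, count in profile.class_counts.items()
        if count > 0
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
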