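"""Call-quality filtering of raw variant records.

SNPs pass when the caller quality exceeds 20, supporting depth exceeds 2,
estimated copy number does not exceed 1.5, and no other called SNP lies
within 5 bp.  Both members of a close SNP pair are moved out of the SNP set
(reason "proximity"); the copy-number cut removes likely artifacts of
repeated sequence.  InDels pass when supported by strictly more than one
third of the mapped reads; SVs pass at read depth 3 or more.

All thresholds are exposed on :class:`FilterThresholds` with the strict /
inclusive readings noted per field.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import INDEL, SNP, SV, VariantRecord


@dataclass
class FilterThresholds:
    min_quality: float = 20.0  # exclusive: pass requires quality > 20
    min_depth: int = 2  # exclusive: pass requires depth > 2
    proximity_bp: int = 5  # SNPs <= 5 bp apart are both excluded
    max_copy_number: float = 1.5  # inclusive upper bound: pass at <= 1.5
    indel_min_support: float = 1.0 / 3.0  # exclusive: pass requires > 1/3
    sv_min_depth: int = 3  # inclusive: pass at depth >= 3


@dataclass
class Rejection:
    record: VariantRecord
    reason: str


def filter_snps(
    records: list[VariantRecord], thresholds: FilterThresholds | None = None
) -> tuple[list[VariantRecord], list[Rejection]]:
    """Split SNP records into (passed, rejected-with-reason).

    ``records`` must be sorted by (chrom, pos) and all of class SNP.
    Proximity is evaluated against *all* input SNPs, pass or fail, so the
    outcome does not depend on the order criteria are applied in.  Each
    rejection carries the first failing criterion in the order quality,
    depth, proximity, copy_number.
    """
    t = thresholds or FilterThresholds()
    keys = [(v.chrom, v.pos) for v in records]
    if keys != sorted(keys):
        raise ValueError("SNP records must be sorted by (chrom, pos)")
    for v in records:
        if v.vclass != SNP:
            raise ValueError(f"{v.chrom}:{v.pos} is not a SNP")

    crowded = [False] * len(records)
    for i, v in enumerate(records):
        for j in (i - 1, i + 1):
            if 0 <= j < len(records):
                w = records[j]
                if w.chrom == v.chrom and abs(w.pos - v.pos) <= t.proximity_bp:
                    crowded[i] = True

    passed, rejected = [], []
    for v, near in zip(records, crowded):
        if not v.quality > t.min_quality:
            rejected.append(Rejection(v, "quality"))
        elif not v.depth > t.min_depth:
            rejected.append(Rejection(v, "depth"))
        elif near:
            rejected.append(Rejection(v, "proximity"))
        elif not v.copy_number <= t.max_copy_number:
            rejected.append(Rejection(v, "copy_number"))
        else:
            passed.append(v)
    return passed, rejected


def filter_indels(
    records: list[VariantRecord], thresholds: FilterThresholds | None = None
) -> tuple[list[VariantRecord], list[Rejection]]:
    """Retain InDels supported by more than one third of mapped reads."""
    t = thresholds or FilterThresholds()
    passed, rejected = [], []
    for v in records:
        if v.vclass != INDEL:
            raise ValueError(f"{v.chrom}:{v.pos} is not an InDel")
        if v.support_fraction is None:
            raise ValueError(
                f"{v.chrom}:{v.pos}: InDel record lacks a support fraction"
            )
        if v.support_fraction > t.indel_min_support:
            passed.append(v)
        else:
            rejected.append(Rejection(v, "support_fraction"))
    return passed, rejected


def filter_svs(
    records: list[VariantRecord], thresholds: FilterThresholds | None = None
) -> tuple[list[VariantRecord], list[Rejection]]:
    """Retain SVs with read depth at or above the minimum (3)."""
    t = thresholds or FilterThresholds()
    passed, rejected = [], []
    for v in records:
        if v.vclass != SV:
            raise ValueError(f"{v.chrom}:{v.pos} is not an SV")
        if v.depth >= t.sv_min_depth:
            passed.append(v)
        else:
            rejected.append(Rejection(v, "depth"))
    return passed, rejected
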