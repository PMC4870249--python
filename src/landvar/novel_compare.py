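"""Novel-SNP identification against a known-variant database.

A SNP whose key is present in the database is *known*; of the remainder,
SNPs inside annotated repeat elements (where short-read SNP detection is
unreliable) are set aside as *repeat-excluded*, and the rest are *novel*.
The three sets partition the input.

Matching is allele-aware by default (chrom, pos, alt): a site shared with
the database but carrying a different alternate allele counts as novel.
Position-only matching is available for databases that do not record
alleles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .effect_annotator import EffectAnnotation
from .genome_io import IntervalTrack, VariantRecord, read_vcf


@dataclass
class KnownVariantDB:
    """Set of known SNP keys: (chrom, pos, alt) or (chrom, pos)."""

    keys: set[tuple] = field(default_factory=set)
    source: str = ""
    allele_aware: bool = True

    def __contains__(self, variant: VariantRecord) -> bool:
        if self.allele_aware:
            return (variant.chrom, variant.pos, variant.alt_allele) in self.keys
        return (variant.chrom, variant.pos) in self.keys

    @classmethod
    def from_keys(
        cls,
        keys: set[tuple[str, int, str]],
        source: str = "",
        allele_aware: bool = True,
    ) -> "KnownVariantDB":
        if allele_aware:
            return cls(keys=set(keys), source=source, allele_aware=True)
        return cls(
            keys={(c, p) for c, p, *_ in keys}, source=source, allele_aware=False
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, allele_aware: bool = True
    ) -> "KnownVariantDB":
        """Load a (chrom, pos[, ref], alt) table; a header row is skipped."""
        keys: set[tuple[str, int, str]] = set()
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#"):
                    continue
                try:
                    pos = int(row[1])
                except ValueError:  # header
                    continue
                alt = row[-1]
                keys.add((row[0], pos, alt))
        return cls.from_keys(keys, source=str(path), allele_aware=allele_aware)

    @classmethod
    def from_vcf(cls, path: str | Path, allele_aware: bool = True) -> "KnownVariantDB":
        keys = {
            (v.chrom, v.pos, v.alt_allele) for v in read_vcf(path)
        }
        return cls.from_keys(keys, source=str(path), allele_aware=allele_aware)


@dataclass
class NoveltyPartition:
    novel: list[VariantRecord]
    known: list[VariantRecord]
    repeat_excluded: list[VariantRecord]

    @property
    def n_input(self) -> int:
        return len(self.novel) + len(self.known) + len(self.repeat_excluded)


def find_novel(
    snps: list[VariantRecord],
    db: KnownVariantDB,
    repeats: IntervalTrack | None = None,
) -> NoveltyPartition:
    """Partition filtered SNPs into known / repeat-excluded / novel."""
    novel, known, excluded = [], [], []
    for v in snps:
        if v in db:
            known.append(v)
        elif repeats is not None and repeats.overlaps(v.chrom, v.pos, v.pos):
            excluded.append(v)
        else:
            novel.append(v)
    return NoveltyPartition(novel=novel, known=known, repeat_excluded=excluded)


def rank_genes_by_novel(
    novel: list[VariantRecord],
    annotations: list[EffectAnnotation],
    top_n: int = 10,
) -> list[dict]:
    """Genes ranked by novel-SNP count (descending, ties by gene id), with
    a per-region breakdown (CDS / intron / UTR)."""
    novel_keys = {v.key for v in novel}
    per_gene: dict[str, dict[str, int]] = {}
    for ann in annotations:
        if ann.affected_transcript is None or ann.variant.key not in novel_keys:
            continue
        counts = per_gene.setdefault(
            ann.affected_transcript,
            {"n_novel": 0, "cds": 0, "intron": 0, "utr5": 0, "utr3": 0},
        )
        counts["n_novel"] += 1
        if ann.region in counts:
            counts[ann.region] += 1
    ranked = sorted(per_gene.items(), key=lambda kv: (-kv[1]["n_novel"], kv[0]))
    return [
        {"transcript": tid, **counts} for tid, counts in ranked[:top_n]
    ]
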