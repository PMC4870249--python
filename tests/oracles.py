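"""Brute-force reference implementations used to cross-check the package.

Each oracle recomputes a quantity by the most direct route available —
rebuilding and translating the whole mutated coding sequence, per-base
interval scans, pairwise loops — independently of the code paths under
test.
"""

from __future__ import annotations

from Bio.Seq import Seq

from landvar.effect_annotator import DEFAULT_PROPERTY_TABLE, STOP_CODONS
from landvar.genome_io import GeneModel, GenomeSequence, VariantRecord


def mutate_genome(genome: GenomeSequence, variant: VariantRecord) -> GenomeSequence:
    """Apply one substitution to a copy of the genome (SNPs only)."""
    seq = genome.sequences[variant.chrom]
    pos = variant.pos
    assert seq[pos - 1] == variant.ref_allele
    mutated = seq[: pos - 1] + variant.alt_allele + seq[pos:]
    out = dict(genome.sequences)
    out[variant.chrom] = mutated
    return GenomeSequence(out)


def brute_force_snp_consequence(
    variant: VariantRecord, gene: GeneModel, genome: GenomeSequence
) -> tuple[str, set[str]]:
    """Classify a coding SNP by rebuilding and translating the entire
    mutated spliced CDS."""
    ref_cds = gene.spliced_cds(genome)
    alt_cds = gene.spliced_cds(mutate_genome(genome, variant))
    assert len(ref_cds) == len(alt_cds)
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())

    flags: set[str] = set()
    if alt_cds[:3] != "ATG" and ref_cds[:3] == "ATG":
        flags.add("start_lost")
    if "*" in alt_prot[:-1] and "*" not in ref_prot[:-1]:
        flags.add("premature_stop")
    if ref_cds[-3:] in STOP_CODONS and alt_cds[-3:] not in STOP_CODONS:
        flags.add("stop_lost")
    for ra, aa in zip(ref_prot, alt_prot):
        if ra != aa and ra in DEFAULT_PROPERTY_TABLE and aa in DEFAULT_PROPERTY_TABLE:
            if DEFAULT_PROPERTY_TABLE[ra] != DEFAULT_PROPERTY_TABLE[aa]:
                flags.add("property_change")
    consequence = "synonymous" if ref_prot == alt_prot else "non_synonymous"
    return consequence, flags


def brute_force_region(
    variant: VariantRecord, genes: list[GeneModel]
) -> str:
    """Per-base region classification with CDS > UTR > intron precedence."""
    start, end = variant.affected_interval()
    classes: set[str] = set()
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        for pos in range(start, end + 1):
            if not (gene.span[0] <= pos <= gene.span[1]):
                continue
            if any(s <= pos <= e for s, e in gene.cds_segments):
                classes.add("cds")
            elif any(s <= pos <= e for s, e in gene.utr5):
                classes.add("utr5")
            elif any(s <= pos <= e for s, e in gene.utr3):
                classes.add("utr3")
            elif any(s <= pos <= e for s, e in gene.exons):
                classes.add("utr")  # unannotated exonic
            else:
                classes.add("intron")
    for region in ("cds", "utr5", "utr3", "intron"):
        if region in classes:
            return region
    return "intergenic"


def brute_force_internal_stop(gene: GeneModel, genome: GenomeSequence) -> bool:
    cds = gene.spliced_cds(genome)
    codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    return any(c in STOP_CODONS for c in codons[:-1])


def brute_force_overlap_pairs(genes: list[GeneModel]) -> set[tuple[str, str]]:
    """All unordered pairs of genes with overlapping spans (same chrom)."""
    pairs = set()
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if a.chrom != b.chrom:
                continue
            if a.span[0] <= b.span[1] and b.span[0] <= a.span[1]:
                pairs.add(tuple(sorted((a.transcript_id, b.transcript_id))))
    return pairs


def brute_force_proximity(records: list[VariantRecord], dist: int = 5) -> set:
    """Keys of SNPs with another SNP within ``dist`` bp (pairwise loop)."""
    out = set()
    for a in records:
        for b in records:
            if a is b or a.chrom != b.chrom:
                continue
            if abs(a.pos - b.pos) <= dist:
                out.add(a.key)
    return out


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval union via a per-base set (small inputs only)."""
    bases: set[int] = set()
    for s, e in ivs:
        bases.update(range(s, e))
    out = []
    for b in sorted(bases):
        if out and b == out[-1][1]:
            out[-1] = (out[-1][0], b + 1)
        else:
            out.append((b, b + 1))
    return out
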