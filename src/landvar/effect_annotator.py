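"""Functional-effect classification of filtered variants.

Each variant is placed in exactly one genomic region class (intergenic,
intron, 5'/3' UTR, CDS) against the filtered, non-overlapping gene set.
Coding SNPs are classified synonymous / non-synonymous by codon
substitution, with "large-effect" flags for substitutions that create a
premature stop codon, abolish the terminal stop codon, alter the
initiation ATG, hit a splice site, or swap the encoded amino acid into a
different physicochemical property class (hydrophobic, negative, positive,
polar uncharged).  Coding InDels are classified frameshift (length not a
multiple of 3) or in-frame.

Splice-site classes: the *essential* splice site is the first 2 or last
2 bp of an intron; the broader *splice region* covers 1-3 bp into an exon
end adjacent to an intron plus intron bases 1-2 (so every essential site
is also in the splice region, and splice-region counts subsume essential
ones).  Splice classification is positional and applies whether the base
is reported as intron, UTR or CDS.

Large-effect flags are only evaluated for SNPs; InDel consequences are
limited to frameshift/in-frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genome_io import GeneModel, GenomeSequence, INDEL, SNP, VariantRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REGION_INTERGENIC = "intergenic"
REGION_UNKNOWN = "unknown"  # variant chromosome absent from the genome
REGION_INTRON = "intron"
REGION_UTR5 = "utr5"
REGION_UTR3 = "utr3"
REGION_CDS = "cds"

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non_synonymous"
UNDETERMINED = "undetermined"

FRAMESHIFT = "frameshift"
INFRAME = "inframe"

PREMATURE_STOP = "premature_stop"
STOP_LOST = "stop_lost"
START_LOST = "start_lost"
SPLICE_REGION = "splice_region"
ESSENTIAL_SPLICE = "essential_splice"
PROPERTY_CHANGE = "property_change"

LARGE_EFFECT_FLAGS = (
    PREMATURE_STOP,
    STOP_LOST,
    START_LOST,
    SPLICE_REGION,
    ESSENTIAL_SPLICE,
    PROPERTY_CHANGE,
)

#: Standard partition of the 20 amino acids into the four property classes.
#: The stop symbol is deliberately unmapped: a codon gaining or losing a stop
#: is flagged through the stop-specific classes, never as a property change.
DEFAULT_PROPERTY_TABLE: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "AVLIMFWPGC"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "polar_uncharged" for aa in "STNQY"},
}


@dataclass
class EffectAnnotation:
    variant: VariantRecord
    region: str
    affected_transcript: str | None = None
    snp_consequence: str | None = None  # CDS SNPs only
    indel_consequence: str | None = None  # CDS InDels only
    large_effect: frozenset[str] = frozenset()
    ref_aa: str | None = None
    alt_aa: str | None = None


@dataclass
class LargeEffectSummary:
    """Per-flag SNP counts and affected-transcript sets.

    Flag counts are independent: one SNP in the splice region of a coding
    exon contributes to every flag it carries, so columns may sum past the
    number of flagged SNPs.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {f: 0 for f in LARGE_EFFECT_FLAGS}
    )
    transcripts: dict[str, set[str]] = field(
        default_factory=lambda: {f: set() for f in LARGE_EFFECT_FLAGS}
    )

    @property
    def transcripts_with_large_effect(self) -> set[str]:
        out: set[str] = set()
        for txs in self.transcripts.values():
            out |= txs
        return out


class TranscriptIndex:
    """Span lookup over a filtered (pairwise non-overlapping) gene set."""

    def __init__(self, genes: list[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for chrom in {g.chrom for g in genes}:
            models = sorted(
                (g for g in genes if g.chrom == chrom), key=lambda g: g.span
            )
            self._by_chrom[chrom] = ([g.span[0] for g in models], models)

    def at(self, chrom: str, pos: int) -> GeneModel | None:
        """The transcript whose span contains the 1-based position, if any."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, models = entry
        from bisect import bisect_right

        i = bisect_right(starts, pos) - 1
        if i >= 0 and models[i].span[1] >= pos:
            return models[i]
        return None


def _point_region(pos: int, gene: GeneModel) -> str:
    """Region class of a single genomic base within a gene span."""
    for s, e in gene.cds_segments:
        if s <= pos <= e:
            return REGION_CDS
    for s, e in gene.utr5:
        if s <= pos <= e:
            return REGION_UTR5
    for s, e in gene.utr3:
        if s <= pos <= e:
            return REGION_UTR3
    for s, e in gene.exons:
        if s <= pos <= e:
            # exonic but outside annotated CDS/UTR features: side of the CDS
            # decides (covers annotations without explicit UTR records)
            if not gene.cds_segments:
                return REGION_UTR5
            cds_start = gene.cds_segments[0][0]
            upstream = pos < cds_start
            if gene.strand == "-":
                upstream = pos > gene.cds_segments[-1][1]
            return REGION_UTR5 if upstream else REGION_UTR3
    return REGION_INTRON


_REGION_PRECEDENCE = [REGION_CDS, REGION_UTR5, REGION_UTR3, REGION_INTRON]


def assign_region(
    variant: VariantRecord, index: TranscriptIndex
) -> tuple[str, GeneModel | None]:
    """Region class and affected transcript for one variant.

    Deletions are classified per deleted base with precedence
    CDS > 5'UTR > 3'UTR > intron over the deleted interval.
    """
    start, end = variant.affected_interval()
    gene = None
    for pos in (start, end):
        gene = index.at(variant.chrom, pos)
        if gene is not None:
            break
    if gene is None:
        return REGION_INTERGENIC, None
    classes = {_point_region(p, gene) for p in range(max(start, gene.span[0]),
                                                     min(end, gene.span[1]) + 1)}
    for region in _REGION_PRECEDENCE:
        if region in classes:
            return region, gene
    return REGION_INTERGENIC, None


def splice_site_sets(transcript: GeneModel) -> tuple[set[int], set[int]]:
    """Genomic positions of (essential splice sites, full splice region).

    The essential set holds the first 2 and last 2 bases of every intron;
    the region set adds 1-3 bp into each intron-adjacent exon end.  Both
    sets are symmetric in strand, so they are computed genomically.
    """
    introns = transcript.introns()
    essential: set[int] = set()
    region: set[int] = set()
    for s, e in introns:
        essential |= {s, s + 1, e - 1, e}
    region |= essential  # intron bases 1-2 at either end
    for es, ee in transcript.exons:
        if any(e + 1 == es for _, e in introns):  # intron abuts exon start
            region |= set(range(es, min(es + 3, ee + 1)))
        if any(s - 1 == ee for s, _ in introns):  # intron abuts exon end
            region |= set(range(max(ee - 2, es), ee + 1))
    return essential, region


def classify_splice(variant: VariantRecord, transcript: GeneModel) -> str | None:
    """None, ``splice_region`` or ``essential_splice`` for a SNP position."""
    if len(transcript.exons) < 2:
        return None
    essential, region = splice_site_sets(transcript)
    if variant.pos in essential:
        return ESSENTIAL_SPLICE
    if variant.pos in region:
        return SPLICE_REGION
    return None


def classify_snp_coding(
    variant: VariantRecord,
    transcript: GeneModel,
    genome: GenomeSequence,
    property_table: dict[str, str] | None = None,
) -> tuple[str, set[str], str | None, str | None]:
    """Codon-level consequence of a CDS SNP.

    Returns (snp_consequence, large_effect flags, ref_aa, alt_aa).  Codons
    containing N are ``undetermined`` and excluded from the synonymous /
    non-synonymous partition.
    """
    table = property_table or DEFAULT_PROPERTY_TABLE
    if transcript.cds_length % 3 != 0:
        raise ValueError(
            f"{transcript.transcript_id}: CDS length {transcript.cds_length} "
            "is not a multiple of 3; run gene filtration first"
        )
    cds = transcript.spliced_cds(genome)
    off = transcript.cds_offset(variant.pos)
    if off is None:
        raise ValueError(f"{variant.chrom}:{variant.pos} is not in the CDS")
    ref_base, alt_base = variant.ref_allele, variant.alt_allele
    if transcript.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    codon_idx, within = divmod(off, 3)
    ref_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    if ref_codon[within] != ref_base:
        raise ValueError(
            f"{variant.chrom}:{variant.pos}: reference allele "
            f"{variant.ref_allele!r} does not match the genome"
        )
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]

    if "N" in ref_codon or "N" in alt_codon:
        return UNDETERMINED, set(), None, None

    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    n_codons = transcript.cds_length // 3

    flags: set[str] = set()
    if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        flags.add(START_LOST)
    if alt_codon in STOP_CODONS and ref_codon not in STOP_CODONS:
        if codon_idx < n_codons - 1:
            flags.add(PREMATURE_STOP)
    if (
        codon_idx == n_codons - 1
        and ref_codon in STOP_CODONS
        and alt_codon not in STOP_CODONS
    ):
        flags.add(STOP_LOST)
    if (
        ref_aa in table
        and alt_aa in table
        and table[ref_aa] != table[alt_aa]
    ):
        flags.add(PROPERTY_CHANGE)

    consequence = SYNONYMOUS if ref_aa == alt_aa else NON_SYNONYMOUS
    return consequence, flags, ref_aa, alt_aa


def classify_indel_coding(variant: VariantRecord) -> str:
    """Frameshift unless the inserted/deleted length is a multiple of 3."""
    return INFRAME if variant.length % 3 == 0 else FRAMESHIFT


def annotate_variant(
    variant: VariantRecord,
    index: TranscriptIndex,
    genome: GenomeSequence,
    property_table: dict[str, str] | None = None,
) -> EffectAnnotation:
    if variant.chrom not in genome:
        return EffectAnnotation(variant=variant, region=REGION_UNKNOWN)
    region, gene = assign_region(variant, index)
    ann = EffectAnnotation(
        variant=variant,
        region=region,
        affected_transcript=gene.transcript_id if gene else None,
    )
    if gene is None:
        return ann
    flags: set[str] = set()
    if variant.vclass == SNP:
        splice = classify_splice(variant, gene)
        if splice == ESSENTIAL_SPLICE:
            flags |= {ESSENTIAL_SPLICE, SPLICE_REGION}
        elif splice == SPLICE_REGION:
            flags.add(SPLICE_REGION)
        if region == REGION_CDS:
            consequence, coding_flags, ref_aa, alt_aa = classify_snp_coding(
                variant, gene, genome, property_table
            )
            ann.snp_consequence = consequence
            ann.ref_aa, ann.alt_aa = ref_aa, alt_aa
            flags |= coding_flags
    elif variant.vclass == INDEL and region == REGION_CDS:
        ann.indel_consequence = classify_indel_coding(variant)
    ann.large_effect = frozenset(flags)
    return ann


def annotate_all(
    variants: list[VariantRecord],
    genes: list[GeneModel],
    genome: GenomeSequence,
    property_table: dict[str, str] | None = None,
) -> tuple[list[EffectAnnotation], LargeEffectSummary]:
    """Annotate every variant exactly once and tally large-effect flags."""
    index = TranscriptIndex(genes)
    annotations = [
        annotate_variant(v, index, genome, property_table) for v in variants
    ]
    summary = LargeEffectSummary()
    for ann in annotations:
        for flag in ann.large_effect:
            summary.counts[flag] += 1
            if ann.affected_transcript:
                summary.transcripts[flag].add(ann.affected_transcript)
    return annotations, summary


#: Truth-label precedence used to reduce a multi-flag annotation to a single
#: descriptive label (splice classes outrank coding classes, matching how
#: splice-site substitutions are tallied separately from codon effects).
_LABEL_PRECEDENCE = (
    ESSENTIAL_SPLICE,
    SPLICE_REGION,
    START_LOST,
    STOP_LOST,
    PREMATURE_STOP,
)


def primary_label(ann: EffectAnnotation) -> str:
    """Collapse an annotation to one of the 14 ground-truth effect labels."""
    for flag in _LABEL_PRECEDENCE:
        if flag in ann.large_effect:
            return flag
    if ann.indel_consequence == FRAMESHIFT:
        return "frameshift"
    if ann.indel_consequence == INFRAME:
        return "inframe_indel"
    if ann.snp_consequence == NON_SYNONYMOUS:
        if PROPERTY_CHANGE in ann.large_effect:
            return "nonsynonymous_property_change"
        return "nonsynonymous_conservative"
    if ann.snp_consequence == SYNONYMOUS:
        return SYNONYMOUS
    return ann.region
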