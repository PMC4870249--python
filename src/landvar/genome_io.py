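"""Readers/writers and the shared coordinate model.

Conventions
-----------
Positions (``VariantRecord.pos``, gene feature intervals) are 1-based
inclusive, matching GFF3/VCF.  Interval tracks and genome windows are
0-based half-open, matching BED/BEDGraph.  Conversion between the two
conventions is confined to this module.

Variant classes follow the short-read resequencing convention used
throughout the pipeline: single-base substitutions are SNPs, insertions
or deletions of 1-5 bp are InDels, and anything longer than 5 bp is a
structural variation (SV).
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = set("ACGTN")

SNP = "SNP"
INDEL = "INDEL"
SV = "SV"

#: inserted/deleted length (bp) above which a variant is an SV, not an InDel
SV_LENGTH_THRESHOLD = 5


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally invalid record (e.g. CDS outside its exons)."""


# ---------------------------------------------------------------------------
# Genome


@dataclass
class GenomeSequence:
    """An in-memory reference genome: ordered chromosomes of uppercase DNA."""

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end]."""
        return self.sequences[chrom][start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file; sequences are uppercased, record order preserved."""
    genome = GenomeSequence()
    for i, record in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(
                f"{path}: record {record.id!r} (entry {i + 1}) contains "
                f"non-DNA characters {sorted(bad)}"
            )
        if record.id in genome.sequences:
            raise ParseError(f"{path}: duplicate chromosome name {record.id!r}")
        genome.sequences[record.id] = seq
    return genome


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneModel:
    """A stranded transcript with exon/CDS/UTR sub-features.

    All intervals are 1-based inclusive ``(start, end)`` tuples in genomic
    order (ascending start regardless of strand).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        for name in ("exons", "cds_segments", "utr5", "utr3"):
            ivs = sorted(getattr(self, name))
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValidationError(
                        f"{self.transcript_id}: overlapping {name} intervals"
                    )
            for s, e in ivs:
                if s > e or s < 1:
                    raise ValidationError(
                        f"{self.transcript_id}: bad interval ({s}, {e}) in {name}"
                    )
            setattr(self, name, ivs)
        for s, e in self.cds_segments:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValidationError(
                    f"{self.transcript_id}: CDS segment ({s}, {e}) not contained "
                    "in any exon"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        """(min exon start, max exon end), 1-based inclusive."""
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive, genomic order."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def spliced_cds(self, genome: GenomeSequence) -> str:
        """The coding sequence in transcript orientation (starts with the
        start codon for a canonical gene)."""
        parts = [genome.fetch(self.chrom, s, e) for s, e in self.cds_segments]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic position ``pos`` within the spliced CDS
        (transcript orientation), or None if ``pos`` is not in the CDS."""
        off = 0
        for s, e in self.cds_segments:
            if s <= pos <= e:
                off += pos - s
                break
            off += e - s + 1
        else:
            return None
        if self.strand == "-":
            return self.cds_length - 1 - off
        return off

    def cds_genomic_pos(self, off: int) -> int:
        """Inverse of :meth:`cds_offset`: genomic 1-based position of the
        0-based spliced-CDS offset (transcript orientation)."""
        if not 0 <= off < self.cds_length:
            raise IndexError(f"CDS offset {off} out of range")
        if self.strand == "-":
            off = self.cds_length - 1 - off
        for s, e in self.cds_segments:
            seg = e - s + 1
            if off < seg:
                return s + off
            off -= seg
        raise AssertionError("unreachable")


def read_gff3(path: str | Path, genome: GenomeSequence) -> list[GeneModel]:
    """Parse gene models from GFF3, one :class:`GeneModel` per transcript.

    Transcripts on chromosomes absent from ``genome``, or with features
    beyond chromosome bounds, are rejected with an error.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.attributes.get("Parent", [mrna.id])[0]
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(mrna, order_by="start"):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        if mrna.seqid not in genome:
            raise ValidationError(
                f"{path}: transcript {mrna.id} on unknown chromosome {mrna.seqid!r}"
            )
        clen = len(genome.sequences[mrna.seqid])
        for s, e in exons + cds:
            if e > clen:
                raise ValidationError(
                    f"{path}: transcript {mrna.id} feature ({s}, {e}) overruns "
                    f"chromosome {mrna.seqid} (length {clen})"
                )
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_segments=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR hierarchy)."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        chrom, strand = txs[0].chrom, txs[0].strand
        gs = min(t.span[0] for t in txs)
        ge = max(t.span[1] for t in txs)
        lines.append(
            f"{chrom}\tlandvar\tgene\t{gs}\t{ge}\t.\t{strand}\t.\tID={gene_id}"
        )
        for t in sorted(txs, key=lambda t: t.transcript_id):
            s, e = t.span
            lines.append(
                f"{chrom}\tlandvar\tmRNA\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={t.transcript_id};Parent={gene_id}"
            )
            for ftype, ivs in (
                ("exon", t.exons),
                ("five_prime_UTR", t.utr5),
                ("CDS", t.cds_segments),
                ("three_prime_UTR", t.utr3),
            ):
                for fs, fe in ivs:
                    lines.append(
                        f"{chrom}\tlandvar\t{ftype}\t{fs}\t{fe}\t.\t{strand}\t.\t"
                        f"Parent={t.transcript_id}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Variants


@dataclass
class VariantRecord:
    """One variant call with its caller statistics.

    ``pos`` is the 1-based reference position; for InDels/SVs it is the
    VCF-style anchor base, so a deletion removes the interval
    ``(pos, pos + length]``.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    quality: float = 0.0
    depth: int = 0
    copy_number: float = 1.0
    support_fraction: float | None = None
    svtype: str | None = None

    @property
    def length(self) -> int:
        """bp of inserted/deleted sequence; 0 for a SNP."""
        return abs(len(self.alt_allele) - len(self.ref_allele))

    @property
    def vclass(self) -> str:
        if self.length == 0:
            if len(self.ref_allele) != 1:
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: length-preserving multi-base "
                    "alleles are not supported"
                )
            return SNP
        return INDEL if self.length <= SV_LENGTH_THRESHOLD else SV

    @property
    def is_deletion(self) -> bool:
        return len(self.alt_allele) < len(self.ref_allele)

    @property
    def is_insertion(self) -> bool:
        return len(self.alt_allele) > len(self.ref_allele)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def affected_interval(self) -> tuple[int, int]:
        """1-based inclusive genomic interval the variant touches.

        For a SNP this is (pos, pos); for a deletion the deleted bases
        (pos+1, pos+length); for an insertion the anchor base.
        """
        if self.is_deletion:
            return (self.pos + 1, self.pos + self.length)
        return (self.pos, self.pos)


def left_align(variant: VariantRecord, genome: GenomeSequence) -> VariantRecord:
    """Shift an anchored InDel to its leftmost equivalent representation.

    SNPs and variants that are not simple anchored indels are returned
    unchanged.
    """
    ref, alt, pos = variant.ref_allele, variant.alt_allele, variant.pos
    if variant.length == 0 or not (len(ref) == 1 or len(alt) == 1):
        return variant
    if ref[0] != alt[0]:
        return variant
    seq = genome.sequences[variant.chrom]
    indel = ref[1:] if len(ref) > 1 else alt[1:]
    # shifting left by one is valid while the last indel base equals the
    # current anchor base
    while pos > 1 and indel[-1] == seq[pos - 1]:
        indel = seq[pos - 1] + indel[:-1]
        pos -= 1
    if pos == variant.pos:
        return variant
    anchor = seq[pos - 1]
    if variant.is_deletion:
        ref2, alt2 = anchor + indel, anchor
    else:
        ref2, alt2 = anchor, anchor + indel
    return VariantRecord(
        chrom=variant.chrom,
        pos=pos,
        ref_allele=ref2,
        alt_allele=alt2,
        quality=variant.quality,
        depth=variant.depth,
        copy_number=variant.copy_number,
        support_fraction=variant.support_fraction,
        svtype=variant.svtype,
    )


_VCF_HEADER_INFO = [
    ('##INFO=<ID=DP,Number=1,Type=Integer,Description="Supporting read depth">'),
    ('##INFO=<ID=CN,Number=1,Type=Float,Description="Estimated copy number">'),
    (
        '##INFO=<ID=SF,Number=1,Type=Float,Description="Fraction of mapped reads '
        'supporting the gap">'
    ),
    ('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">'),
]


def read_vcf(
    path: str | Path, genome: GenomeSequence | None = None
) -> list[VariantRecord]:
    """Read a VCF 4.x file into :class:`VariantRecord` objects.

    Multi-allelic records are split into one record per alt allele.  When a
    genome is supplied, variants on chromosomes absent from it are dropped
    with a warning (the "unknown chromosome" bucket) and InDels are
    left-aligned.
    """
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if set(alt) - set("ACGTN"):
                    raise ParseError(
                        f"{path}: symbolic/breakend allele {alt!r} at "
                        f"{rec.chrom}:{rec.pos} has no defined length"
                    )
                info = rec.info
                v = VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref.upper(),
                    alt_allele=alt.upper(),
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                    depth=int(info["DP"]) if "DP" in info else 0,
                    copy_number=float(info["CN"]) if "CN" in info else 1.0,
                    support_fraction=float(info["SF"]) if "SF" in info else None,
                    svtype=str(info["SVTYPE"]) if "SVTYPE" in info else None,
                )
                if genome is not None:
                    if v.chrom not in genome:
                        warnings.warn(
                            f"variant at {v.chrom}:{v.pos} is on a chromosome "
                            "absent from the genome; it is reported in the "
                            "'unknown' bucket but not effect-annotated"
                        )
                    else:
                        v = left_align(v, genome)
                records.append(v)
    return records


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    genome: GenomeSequence | None = None,
) -> None:
    """Write records as sorted, deterministic, uncompressed VCF."""
    records = sorted(records, key=lambda v: (v.chrom, v.pos, v.ref_allele, v.alt_allele))
    contigs: dict[str, int | None]
    if genome is not None:
        contigs = dict(genome.lengths)
    else:
        contigs = {}
        for v in records:
            contigs.setdefault(v.chrom, None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            if length is None:
                fh.write(f"##contig=<ID={name}>\n")
            else:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_HEADER_INFO:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in records:
            info = [f"DP={v.depth}", f"CN={v.copy_number:g}"]
            if v.support_fraction is not None:
                info.append(f"SF={v.support_fraction:g}")
            if v.svtype is not None:
                info.append(f"SVTYPE={v.svtype}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t"
                f"{v.quality:g}\t.\t{';'.join(info)}\n"
            )


# ---------------------------------------------------------------------------
# Interval tracks (repeats, coverage, QTL regions)


@dataclass
class IntervalTrack:
    """Per-chromosome sorted, non-overlapping 0-based half-open intervals
    with an optional value (coverage) or label (region name)."""

    name: str = ""
    intervals: dict[str, list[tuple[int, int, object]]] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, value: object = None) -> None:
        if start >= end:
            raise ParseError(f"{self.name}: empty interval {chrom}:{start}-{end}")
        self.intervals.setdefault(chrom, []).append((start, end, value))

    def sort(self) -> None:
        for ivs in self.intervals.values():
            ivs.sort(key=lambda t: (t[0], t[1]))

    def merge(self) -> None:
        """Union overlapping/adjacent-overlapping intervals (values dropped)."""
        self.sort()
        for chrom, ivs in self.intervals.items():
            merged: list[tuple[int, int, object]] = []
            for s, e, _ in ivs:
                if merged and s <= merged[-1][1]:
                    ps, pe, _ = merged[-1]
                    merged[-1] = (ps, max(pe, e), None)
                else:
                    merged.append((s, e, None))
            self.intervals[chrom] = merged

    def iter_overlapping(
        self, chrom: str, start1: int, end1: int
    ) -> Iterator[tuple[int, int, object]]:
        """Yield track intervals overlapping the 1-based inclusive interval
        [start1, end1].  Requires a sorted, non-overlapping track (BEDGraph
        tracks and merged BED tracks satisfy this)."""
        ivs = self.intervals.get(chrom, [])
        s0, e0 = start1 - 1, end1  # to half-open
        i = bisect_right([iv[1] for iv in ivs], s0)  # first iv with end > s0
        for s, e, v in ivs[i:]:
            if s >= e0:
                break
            yield (s, e, v)

    def overlaps(self, chrom: str, start1: int, end1: int) -> bool:
        """True if the 1-based inclusive interval [start1, end1] overlaps
        any track interval (track must be sorted and non-overlapping)."""
        return next(iter(self.iter_overlapping(chrom, start1, end1)), None) is not None


def read_bed(path: str | Path, name: str = "") -> IntervalTrack:
    """Read a BED file; overlapping intervals are merged."""
    track = IntervalTrack(name=name or Path(path).stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            label = fields[3] if len(fields) > 3 else None
            track.add(chrom, start, end, label)
    track.sort()
    # unlabelled BED (repeat masks etc.) is treated as a set of regions and
    # merged; labelled BED (QTL names) keeps one interval per record
    if all(v is None for ivs in track.intervals.values() for _, _, v in ivs):
        track.merge()
    return track


def read_bedgraph(path: str | Path, name: str = "coverage") -> IntervalTrack:
    """Read a BEDGraph file; values preserved, intervals left unmerged."""
    track = IntervalTrack(name=name)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 BEDGraph columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            track.add(chrom, start, end, value)
    track.sort()
    return track


def write_bed(track: IntervalTrack, path: str | Path) -> None:
    track.sort()
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            for s, e, v in track.intervals[chrom]:
                if v is None:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
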