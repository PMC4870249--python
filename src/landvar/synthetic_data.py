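"""Synthetic genomes with planted, ground-truth-labelled variants.

The generator emulates the statistical structure of a deep-resequenced
maize-like genome at desk scale: a small multi-chromosome genome carrying
stranded multi-exon genes (canonical ATG start, single terminal stop,
GT..AG introns, UTRs), repeat annotation, a coverage track with uncovered
gaps, a known-SNP database covering a configurable share of the planted
SNPs, and variants planted in every functional-effect class and density
regime.

Every planted variant carries a ground-truth effect label constructed
directly from the gene structure (e.g. a premature-stop SNP is built by
choosing a sense codon one substitution away from a stop codon), so the
effect annotator can be held to 100% recovery.  All output is
deterministic for a given configuration and seed.

Default rates follow the genome-wide averages of a deeply resequenced
maize landrace: ~1,600 SNPs/Mb with windows above 3,500/Mb and below
500/Mb, ~103 InDels/Mb, ~19 SVs/Mb, and 62.8% of SNPs present in the
known-variant database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from . import effect_annotator as ea
from .genome_io import (
    GeneModel,
    GenomeSequence,
    IntervalTrack,
    VariantRecord,
    left_align,
    write_bed,
    write_fasta,
    write_gff3,
    write_vcf,
)

TRUTH_LABELS = (
    "intergenic",
    "intron",
    "utr5",
    "utr3",
    "synonymous",
    "nonsynonymous_property_change",
    "nonsynonymous_conservative",
    "premature_stop",
    "stop_lost",
    "start_lost",
    "splice_region",
    "essential_splice",
    "frameshift",
    "inframe_indel",
)

#: labels that require a host gene
GENIC_LABELS = tuple(l for l in TRUTH_LABELS if l != "intergenic")

_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in ea.STOP_CODONS
]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SimulationError(ValueError):
    """Infeasible configuration or unplantable label."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 5)
    #: per-window SNP rates (/Mb) cycled over successive density windows;
    #: includes a high (>3500/Mb) and a low (<500/Mb) regime
    snp_density_profile: tuple[float, ...] = (
        4000.0, 1500.0, 300.0, 1500.0, 1500.0,
        4000.0, 1500.0, 300.0, 1500.0, 1500.0,
    )
    density_window_bp: int = 100_000
    indel_rate: float = 103.0  # per Mb, intergenic background
    sv_rate: float = 19.0  # per Mb, intergenic background
    fraction_known: float = 0.628  # share of SNPs placed in the known-SNP DB
    repeat_fraction: float = 0.2
    uncovered_fraction: float = 0.02
    min_per_class: int = 20  # planted effect variants per genic label
    #: share of genes kept variant-free inside an SNP-free buffer, emulating
    #: conserved regions; yields inter-SNP gaps > 10 kb containing genes
    fraction_variant_free_genes: float = 0.25
    snp_free_buffer_bp: int = 6_000
    n_violators: int = 0  # genes deliberately failing the gene filter
    n_db_decoys: int = 50  # known-DB entries at positions with no variant
    insertion_fraction: float = 0.46  # insertions among background InDels
    indel_length_weights: tuple[float, ...] = (0.55, 0.20, 0.12, 0.08, 0.05)
    sv_length_range: tuple[int, int] = (6, 3000)
    sv_geom_p: float = 0.01  # geometric decay of SV lengths
    mean_coverage: float = 21.0
    verify_labels: bool = True  # re-annotate planted variants as a self-check

    def __post_init__(self) -> None:
        if min(self.indel_rate, self.sv_rate) < 0 or min(self.snp_density_profile) < 0:
            raise SimulationError("rates must be >= 0")
        for frac in (
            self.fraction_known,
            self.repeat_fraction,
            self.uncovered_fraction,
            self.insertion_fraction,
            self.fraction_variant_free_genes,
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError("fractions must be in [0, 1]")
        if self.chrom_length < 10 * self.density_window_bp:
            raise SimulationError(
                "chrom_length must be at least 10 density windows"
            )
        if self.exons_per_gene[0] < 2:
            raise SimulationError(
                "genes need >= 2 exons so splice labels are constructible"
            )


@dataclass
class PlantedVariant:
    record: VariantRecord
    truth_label: str
    truth_is_novel: bool = True


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    repeats: IntervalTrack
    coverage: IntervalTrack
    qtl: IntervalTrack
    known_db: set[tuple[str, int, str]]  # (chrom, pos, alt)
    planted: list[PlantedVariant]

    def records(self) -> list[VariantRecord]:
        return [p.record for p in self.planted]

    def truth_by_key(self) -> dict[tuple, PlantedVariant]:
        return {p.record.key: p for p in self.planted}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fasta")
        write_gff3(self.genes, outdir / "genes.gff3")
        write_vcf(self.records(), outdir / "variants.vcf", self.genome)
        write_bed(self.repeats, outdir / "repeats.bed")
        write_bed(self.qtl, outdir / "qtl.bed")
        with open(outdir / "coverage.bedgraph", "w") as fh:
            for chrom in sorted(self.coverage.intervals):
                for s, e, v in self.coverage.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
        with open(outdir / "known_snps.tsv", "w") as fh:
            fh.write("chrom\tpos\talt\n")
            for chrom, pos, alt in sorted(self.known_db):
                fh.write(f"{chrom}\t{pos}\t{alt}\n")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\ttruth_label\ttruth_is_novel\n")
            for p in sorted(self.planted, key=lambda p: p.record.key):
                v = p.record
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t"
                    f"{p.truth_label}\t{int(p.truth_is_novel)}\n"
                )


# ---------------------------------------------------------------------------
# gene construction


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


@dataclass
class _GeneDraft:
    """A gene in assembled (gene-local, 0-based) coordinates before
    placement on a chromosome."""

    seq: str  # transcript-orientation genomic sequence of the gene body
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]


def _build_gene_draft(
    rng: np.random.Generator, cfg: SimulationConfig, violation: str | None = None
) -> _GeneDraft:
    u5 = int(rng.integers(60, 201))
    u3 = int(rng.integers(60, 201))
    if violation == "short_cds":
        n_codons = int(rng.integers(10, 49))  # CDS < 150 bp
    else:
        n_codons = int(rng.integers(60, 201))
    body = [str(c) for c in rng.choice(_SENSE_CODONS, size=n_codons - 2)]
    if violation == "internal_stop":
        body[len(body) // 2] = "TAA"
    stop = str(rng.choice(sorted(ea.STOP_CODONS)))
    cds_seq = "ATG" + "".join(body) + stop
    transcript = _rand_dna(rng, u5) + cds_seq + _rand_dna(rng, u3)
    T = len(transcript)

    k = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    # splice junctions fall inside the CDS so UTRs stay contiguous and every
    # splice label is constructible
    lo, hi = u5 + 6, u5 + 3 * n_codons - 6
    cuts = sorted(int(c) for c in rng.choice(np.arange(lo, hi), size=k - 1, replace=False))
    intron_lens = [int(rng.integers(80, 301)) for _ in range(k - 1)]
    intron_seqs = ["GT" + _rand_dna(rng, L - 4) + "AG" for L in intron_lens]

    bounds = [0] + cuts + [T]  # exon j covers transcript (bounds[j], bounds[j+1]]
    pieces: list[str] = []
    exons, cds, utr5, utr3 = [], [], [], []
    off = 0

    def _ttype(p: int) -> str:  # transcript base type, 1-based
        if p <= u5:
            return "utr5"
        if p <= u5 + 3 * n_codons:
            return "cds"
        return "utr3"

    for j in range(k):
        a, b = bounds[j] + 1, bounds[j + 1]
        exons.append((off, off + (b - a)))
        p = a
        while p <= b:
            t = _ttype(p)
            q = p
            while q < b and _ttype(q + 1) == t:
                q += 1
            iv = (off + (p - a), off + (q - a))
            {"utr5": utr5, "cds": cds, "utr3": utr3}[t].append(iv)
            p = q + 1
        pieces.append(transcript[a - 1 : b])
        off += b - a + 1
        if j < k - 1:
            pieces.append(intron_seqs[j])
            off += intron_lens[j]
    return _GeneDraft("".join(pieces), exons, cds, utr5, utr3)


def _place_gene(
    draft: _GeneDraft, gene_idx: int, chrom: str, strand: str, start1: int
) -> tuple[GeneModel, str]:
    """Place a draft at 1-based genomic start; returns (model, genomic seq)."""
    glen = len(draft.seq)

    def conv(iv: tuple[int, int]) -> tuple[int, int]:
        i1, i2 = iv
        if strand == "+":
            return (start1 + i1, start1 + i2)
        return (start1 + glen - 1 - i2, start1 + glen - 1 - i1)

    seq = draft.seq
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    gid = f"gene{gene_idx:04d}"
    model = GeneModel(
        gene_id=gid,
        transcript_id=f"{gid}.t1",
        chrom=chrom,
        strand=strand,
        exons=sorted(conv(iv) for iv in draft.exons),
        cds_segments=sorted(conv(iv) for iv in draft.cds),
        utr5=sorted(conv(iv) for iv in draft.utr5),
        utr3=sorted(conv(iv) for iv in draft.utr3),
    )
    return model, seq


# ---------------------------------------------------------------------------
# variant planting


class _Occupancy:
    """Tracks bases blocked by already-planted variants (interval +/- 5 bp),
    guaranteeing >= 6 bp spacing between any two planted variants so the
    SNP proximity filter never removes planted calls."""

    MARGIN = 5

    def __init__(self) -> None:
        self._blocked: dict[str, set[int]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        blocked = self._blocked.get(chrom, set())
        return all(p not in blocked for p in range(start, end + 1))

    def claim(self, chrom: str, start: int, end: int) -> None:
        blocked = self._blocked.setdefault(chrom, set())
        blocked.update(range(start - self.MARGIN, end + self.MARGIN + 1))


def _snp_record(
    rng: np.random.Generator, chrom: str, pos: int, ref: str, alt: str
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        quality=round(float(rng.uniform(25, 60)), 1),
        depth=int(rng.integers(5, 31)),
        copy_number=round(float(rng.uniform(0.8, 1.4)), 2),
    )


def _coding_snp_candidates(label: str, cds: str) -> list[tuple[int, int, str]]:
    """All (codon_idx, within-codon offset, alt transcript base) producing
    the requested coding label on the given spliced CDS."""
    table = ea.DEFAULT_PROPERTY_TABLE
    n = len(cds) // 3
    out = []
    codons = [cds[i * 3 : i * 3 + 3] for i in range(n)]
    if label == "start_lost":
        rng_codons = [0]
    elif label == "stop_lost":
        rng_codons = [n - 1]
    else:
        rng_codons = list(range(1, n - 1))
    for ci in rng_codons:
        ref_codon = codons[ci]
        for w in range(3):
            for alt_base in _BASES:
                if alt_base == ref_codon[w]:
                    continue
                alt_codon = ref_codon[:w] + alt_base + ref_codon[w + 1 :]
                ref_aa = str(Seq(ref_codon).translate())
                alt_aa = str(Seq(alt_codon).translate())
                ok = False
                if label == "start_lost":
                    ok = ref_codon == "ATG"
                elif label == "stop_lost":
                    ok = ref_codon in ea.STOP_CODONS and alt_codon not in ea.STOP_CODONS
                elif label == "premature_stop":
                    ok = alt_codon in ea.STOP_CODONS
                elif alt_codon in ea.STOP_CODONS:
                    ok = False
                elif label == "synonymous":
                    ok = ref_aa == alt_aa
                elif label == "nonsynonymous_property_change":
                    ok = ref_aa != alt_aa and table[ref_aa] != table[alt_aa]
                elif label == "nonsynonymous_conservative":
                    ok = ref_aa != alt_aa and table[ref_aa] == table[alt_aa]
                if ok:
                    out.append((ci, w, alt_base))
    return out


def plant_effect_variant(
    gene: GeneModel,
    label: str,
    genome: GenomeSequence,
    rng: np.random.Generator,
    occupancy: _Occupancy | None = None,
) -> PlantedVariant:
    """Construct a variant in ``gene`` whose annotation is ``label``.

    Raises :class:`SimulationError` when the gene cannot host the label
    (e.g. no free position, or a splice label on a single-exon gene).
    """
    occ = occupancy or _Occupancy()
    chrom = gene.chrom
    _, splice_region = ea.splice_site_sets(gene)

    def try_snp(pos: int, alt_genomic: str) -> PlantedVariant | None:
        if not occ.free(chrom, pos, pos):
            return None
        rec = _snp_record(rng, chrom, pos, genome.base(chrom, pos), alt_genomic)
        occ.claim(chrom, pos, pos)
        return PlantedVariant(rec, label)

    if label in ("splice_region", "essential_splice"):
        introns = gene.introns()
        if not introns:
            raise SimulationError(f"{label} needs a multi-exon gene")
        candidates: list[int] = []
        if label == "essential_splice":
            for s, e in introns:
                candidates += [s, s + 1, e - 1, e]
        else:
            # 3 bp into an intron-adjacent exon end: exonic, never essential
            for es, ee in gene.exons:
                if any(e + 1 == es for _, e in introns):
                    candidates.append(es + 2)
                if any(s - 1 == ee for s, _ in introns):
                    candidates.append(ee - 2)
        for pos in rng.permutation(candidates).tolist():
            ref = genome.base(chrom, pos)
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            planted = try_snp(int(pos), alt)
            if planted:
                return planted
        raise SimulationError(f"no free {label} position in {gene.gene_id}")

    if label == "intron":
        introns = gene.introns()
        if not introns:
            raise SimulationError("intron label needs a multi-exon gene")
        for s, e in [introns[i] for i in rng.permutation(len(introns))]:
            pos = (s + e) // 2
            if pos in splice_region:
                continue
            ref = genome.base(chrom, pos)
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            planted = try_snp(pos, alt)
            if planted:
                return planted
        raise SimulationError(f"no free intron position in {gene.gene_id}")

    if label in ("utr5", "utr3"):
        ivs = gene.utr5 if label == "utr5" else gene.utr3
        if not ivs:
            raise SimulationError(f"{gene.gene_id} has no {label}")
        for s, e in [ivs[i] for i in rng.permutation(len(ivs))]:
            for pos in rng.permutation(np.arange(s, e + 1)).tolist():
                if pos in splice_region:
                    continue
                ref = genome.base(chrom, int(pos))
                alt = str(rng.choice([b for b in _BASES if b != ref]))
                planted = try_snp(int(pos), alt)
                if planted:
                    return planted
        raise SimulationError(f"no free {label} position in {gene.gene_id}")

    if label in ("frameshift", "inframe_indel"):
        length = 3 if label == "inframe_indel" else int(rng.choice([1, 2, 4, 5]))
        segs = [iv for iv in gene.cds_segments if iv[1] - iv[0] + 1 >= length + 8]
        if not segs:
            raise SimulationError(f"no CDS segment can host a {length}-bp InDel")
        for s, e in [segs[i] for i in rng.permutation(len(segs))]:
            positions = np.arange(s + 2, e - length - 1)
            for pos in rng.permutation(positions).tolist()[:40]:
                pos = int(pos)
                if rng.random() < 0.5:  # deletion
                    ref = genome.fetch(chrom, pos, pos + length)
                    alt = ref[0]
                else:
                    ins = _rand_dna(rng, length)
                    anchor = genome.base(chrom, pos)
                    if ins[-1] == anchor:  # keep the record left-aligned
                        ins = ins[:-1] + str(
                            rng.choice([b for b in _BASES if b != anchor])
                        )
                    ref, alt = anchor, anchor + ins
                rec = VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    quality=round(float(rng.uniform(25, 60)), 1),
                    depth=int(rng.integers(5, 31)),
                    support_fraction=round(float(rng.uniform(0.4, 0.95)), 3),
                )
                if left_align(rec, genome).pos != rec.pos:
                    continue
                a, b = rec.affected_interval()
                lo2, hi2 = min(a, rec.pos), max(b, rec.pos)
                if not occ.free(chrom, lo2, hi2):
                    continue
                occ.claim(chrom, lo2, hi2)
                return PlantedVariant(rec, label)
        raise SimulationError(f"no free CDS InDel site in {gene.gene_id}")

    # coding SNP labels
    cds = gene.spliced_cds(genome)
    cands = _coding_snp_candidates(label, cds)
    if not cands:
        raise SimulationError(f"{gene.gene_id} admits no {label} substitution")
    for idx in rng.permutation(len(cands)).tolist():
        ci, w, alt_t = cands[idx]
        pos = gene.cds_genomic_pos(ci * 3 + w)
        if pos in splice_region:
            continue
        alt_g = alt_t if gene.strand == "+" else alt_t.translate(_COMPLEMENT)
        planted = try_snp(pos, alt_g)
        if planted:
            return planted
    raise SimulationError(f"no free {label} site in {gene.gene_id}")


# ---------------------------------------------------------------------------
# whole-dataset simulation


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic dataset; deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    L = cfg.chrom_length

    # background sequence
    arrays = {
        c: rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L) for c in chrom_names
    }

    # build and place genes
    drafts: list[tuple[_GeneDraft, str | None]] = []
    for i in range(cfg.n_genes + cfg.n_violators):
        violation = None
        if i >= cfg.n_genes:
            violation = "short_cds" if (i - cfg.n_genes) % 2 == 0 else "internal_stop"
        drafts.append((_build_gene_draft(rng, cfg, violation), violation))

    per_chrom: dict[str, list[int]] = {c: [] for c in chrom_names}
    for i in range(len(drafts)):
        per_chrom[chrom_names[i % cfg.n_chroms]].append(i)

    genes: list[GeneModel] = []
    genic_mask = {c: np.zeros(L + 2, dtype=bool) for c in chrom_names}
    for chrom in chrom_names:
        idxs = per_chrom[chrom]
        total = sum(len(drafts[i][0].seq) for i in idxs)
        margin, min_gap = 2000, 500
        free = L - 2 * margin - total - min_gap * (len(idxs) + 1)
        if free < 0:
            raise SimulationError(
                f"{chrom}: {len(idxs)} genes ({total} bp) do not fit in {L} bp"
            )
        extra = rng.multinomial(free, [1 / (len(idxs) + 1)] * (len(idxs) + 1))
        cur = margin + 1
        for j, i in enumerate(idxs):
            cur += min_gap + int(extra[j])
            draft, _ = drafts[i]
            strand = "+" if i % 2 == 0 else "-"
            model, seq = _place_gene(draft, i, chrom, strand, cur)
            genes.append(model)
            arrays[chrom][cur - 1 : cur - 1 + len(seq)] = np.frombuffer(
                seq.encode(), dtype="S1"
            )
            s, e = model.span
            genic_mask[chrom][s : e + 1] = True
            cur += len(seq)

    genome = GenomeSequence(
        {c: arrays[c].tobytes().decode() for c in chrom_names}
    )

    occ = _Occupancy()
    planted: list[PlantedVariant] = []

    # reserve a share of genes as variant-free "conserved" loci: no variants
    # are planted in them and background SNPs keep a buffer distance, so the
    # surrounding inter-SNP gap exceeds the SNP-free region threshold
    clean_genes = [g for g in genes if int(g.gene_id[4:]) < cfg.n_genes]
    n_reserved = int(round(cfg.fraction_variant_free_genes * len(clean_genes)))
    reserved_idx = rng.choice(len(clean_genes), size=n_reserved, replace=False)
    reserved = {clean_genes[int(i)].gene_id for i in reserved_idx}
    for g in clean_genes:
        if g.gene_id in reserved:
            s, e = g.span
            lo = max(1, s - cfg.snp_free_buffer_bp)
            hi = min(L, e + cfg.snp_free_buffer_bp)
            genic_mask[g.chrom][lo : hi + 1] = True

    # planted effect variants, per label, alternating host strand
    hosts = [g for g in clean_genes if g.gene_id not in reserved]
    plus = [g for g in hosts if g.strand == "+"]
    minus = [g for g in hosts if g.strand == "-"]
    for label in GENIC_LABELS:
        n_planted = 0
        attempts = 0
        pools = {"+": plus[:], "-": minus[:]}
        while n_planted < cfg.min_per_class:
            strand = "+" if n_planted % 2 == 0 else "-"
            pool = pools[strand]
            if not pool or attempts > 20 * cfg.min_per_class:
                raise SimulationError(
                    f"could not plant {cfg.min_per_class} {label} variants"
                )
            gene = pool[int(rng.integers(len(pool)))]
            attempts += 1
            try:
                planted.append(
                    plant_effect_variant(gene, label, genome, rng, occ)
                )
                n_planted += 1
            except SimulationError:
                pool.remove(gene)

    # background intergenic SNPs per density window
    window_idx = 0
    for chrom in chrom_names:
        mask = genic_mask[chrom]
        for ws in range(0, L, cfg.density_window_bp):
            we = min(ws + cfg.density_window_bp, L)
            rate = cfg.snp_density_profile[
                window_idx % len(cfg.snp_density_profile)
            ]
            window_idx += 1
            target = int(round(rate * (we - ws) / 1e6))
            placed, tries = 0, 0
            while placed < target and tries < 60 * target:
                tries += 1
                pos = int(rng.integers(ws + 1, we + 1))  # 1-based
                if mask[pos] or not occ.free(chrom, pos, pos):
                    continue
                ref = genome.base(chrom, pos)
                alt = str(rng.choice([b for b in _BASES if b != ref]))
                rec = _snp_record(rng, chrom, pos, ref, alt)
                occ.claim(chrom, pos, pos)
                planted.append(PlantedVariant(rec, "intergenic"))
                placed += 1
            if placed < target:
                raise SimulationError(
                    f"{chrom}:{ws}-{we}: only {placed}/{target} SNPs placed"
                )

    # background intergenic InDels and SVs
    lengths_1to5 = np.arange(1, 6)
    n_indels = int(round(cfg.indel_rate * cfg.n_chroms * L / 1e6))
    n_svs = int(round(cfg.sv_rate * cfg.n_chroms * L / 1e6))
    for kind, n in (("indel", n_indels), ("sv", n_svs)):
        placed, tries = 0, 0
        while placed < n and tries < 200 * max(n, 1):
            tries += 1
            chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
            if kind == "indel":
                length = int(
                    rng.choice(lengths_1to5, p=np.array(cfg.indel_length_weights))
                )
            else:
                lo, hi = cfg.sv_length_range
                length = min(lo - 1 + int(rng.geometric(cfg.sv_geom_p)), hi)
            pos = int(rng.integers(1000, L - length - 1000))
            is_ins = rng.random() < cfg.insertion_fraction
            span_end = pos if is_ins else pos + length
            if genic_mask[chrom][pos : span_end + 1].any():
                continue
            if not occ.free(chrom, pos, span_end):
                continue
            if is_ins:
                ins = _rand_dna(rng, length)
                anchor = genome.base(chrom, pos)
                if ins[-1] == anchor:
                    ins = ins[:-1] + str(
                        rng.choice([b for b in _BASES if b != anchor])
                    )
                ref, alt = anchor, anchor + ins
                svtype = "insertion"
            else:
                ref = genome.fetch(chrom, pos, pos + length)
                alt = ref[0]
                svtype = "deletion"
            rec = VariantRecord(
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                quality=round(float(rng.uniform(25, 60)), 1),
                depth=int(rng.integers(5, 31)),
                support_fraction=(
                    round(float(rng.uniform(0.4, 0.95)), 3)
                    if kind == "indel"
                    else None
                ),
                svtype=svtype if kind == "sv" else None,
            )
            if kind == "sv" and svtype == "deletion" and rng.random() < 0.06:
                rec.svtype = "tandem_duplication"
            if left_align(rec, genome).pos != rec.pos:
                continue
            occ.claim(chrom, pos, span_end)
            planted.append(PlantedVariant(rec, "intergenic"))
            placed += 1
        if placed < n:
            raise SimulationError(f"only {placed}/{n} background {kind}s placed")

    # novelty: a fixed share of SNPs goes into the known-SNP DB
    snp_idx = [i for i, p in enumerate(planted) if p.record.vclass == "SNP"]
    n_known = int(round(cfg.fraction_known * len(snp_idx)))
    known_sel = rng.choice(len(snp_idx), size=n_known, replace=False)
    known_db: set[tuple[str, int, str]] = set()
    for k in known_sel:
        p = planted[snp_idx[int(k)]]
        p.truth_is_novel = False
        known_db.add((p.record.chrom, p.record.pos, p.record.alt_allele))
    for _ in range(cfg.n_db_decoys):  # DB sites where this genotype has no call
        chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
        pos = int(rng.integers(1, L + 1))
        if not occ.free(chrom, pos, pos):
            continue
        known_db.add((chrom, pos, str(rng.choice(list(_BASES)))))

    # repeat annotation: random intervals, may overlap genes
    repeats = IntervalTrack(name="repeats")
    for chrom in chrom_names:
        covered = 0
        while covered < cfg.repeat_fraction * L:
            length = int(rng.integers(500, 5001))
            start = int(rng.integers(0, L - length))
            repeats.add(chrom, start, start + length)
            covered += length
    repeats.merge()

    # coverage: uniform mean depth with uncovered gaps
    coverage = IntervalTrack(name="coverage")
    for chrom in chrom_names:
        n_gaps = max(1, int(cfg.uncovered_fraction * L // 5000))
        gap_starts = sorted(
            int(s) for s in rng.choice(L - 6000, size=n_gaps, replace=False)
        )
        gaps: list[tuple[int, int]] = []
        for gs in gap_starts:
            glen = int(rng.integers(2000, 8001))
            ge = min(gs + glen, L)
            if gaps and gs <= gaps[-1][1]:
                gaps[-1] = (gaps[-1][0], max(gaps[-1][1], ge))
            else:
                gaps.append((gs, ge))
        cur = 0
        for gs, ge in gaps:
            if gs > cur:
                coverage.add(chrom, cur, gs, cfg.mean_coverage)
            coverage.add(chrom, gs, ge, 0.0)
            cur = ge
        if cur < L:
            coverage.add(chrom, cur, L, cfg.mean_coverage)
    coverage.sort()

    # one named QTL interval per chromosome (middle third)
    qtl = IntervalTrack(name="qtl")
    for i, chrom in enumerate(chrom_names):
        qtl.add(chrom, L // 3, 2 * L // 3, f"qtl{i + 1}")
    qtl.sort()

    dataset = SimulatedDataset(
        config=cfg,
        genome=genome,
        genes=sorted(genes, key=lambda g: (g.chrom, g.span)),
        repeats=repeats,
        coverage=coverage,
        qtl=qtl,
        known_db=known_db,
        planted=sorted(planted, key=lambda p: p.record.key),
    )

    if cfg.verify_labels:
        _verify_planted_labels(dataset)
    return dataset


def _verify_planted_labels(dataset: SimulatedDataset) -> None:
    """Generation-time self-check: the annotator must recover every label."""
    clean = [
        g
        for g in dataset.genes
        if int(g.gene_id[4:]) < dataset.config.n_genes
    ]
    annotations, _ = ea.annotate_all(
        dataset.records(), clean, dataset.genome
    )
    truth = dataset.truth_by_key()
    for ann in annotations:
        expect = truth[ann.variant.key].truth_label
        got = ea.primary_label(ann)
        if got != expect:
            raise SimulationError(
                f"planted {expect} at {ann.variant.chrom}:{ann.variant.pos} "
                f"annotates as {got}; generator bug"
            )


def subsample_genotype(
    records: list[VariantRecord], fraction: float, seed: int
) -> list[VariantRecord]:
    """A derived genotype sharing a random subset of the focal calls; used
    to emulate multi-genotype comparisons in QTL windows."""
    rng = np.random.default_rng(seed)
    keep = rng.random(len(records)) < fraction
    return [v for v, k in zip(records, keep) if k]
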