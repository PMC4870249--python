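"""Summary tables, the end-to-end pipeline driver, and the command line.

The summary report mirrors the layout a resequencing study prints: a
per-chromosome count/density table for SNPs, InDels (split into
insertions and deletions) and SVs; an annotation partition
(intergenic / genic = intron + UTR + CDS, with synonymous vs
non-synonymous SNPs and frameshift vs in-frame InDels); the large-effect
SNP taxonomy with percentages of the non-synonymous total; InDel and SV
length distributions; and the novelty partition.

Percentages are computed from the counts in the same report, rounded
half-up at the displayed precision.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import click
import pandas as pd
import yaml

from . import effect_annotator as ea
from . import synthetic_data as sd
from .gene_filter import GeneFilterReport, filter_genes
from .genome_io import (
    GenomeSequence,
    IntervalTrack,
    VariantRecord,
    read_bed,
    read_bedgraph,
    read_fasta,
    read_gff3,
    read_vcf,
    write_bed,
    write_gff3,
    write_vcf,
)
from .novel_compare import KnownVariantDB, NoveltyPartition, find_novel, rank_genes_by_novel
from .region_scan import (
    DensityThresholds,
    DistanceReport,
    adjacent_distances,
    density_scan,
    qtl_window_compare,
    snp_free_regions,
)
from .variant_filter import FilterThresholds, filter_indels, filter_snps, filter_svs


def percentage(numerator: int, denominator: int, decimals: int = 2) -> float | None:
    """100 * numerator / denominator, rounded half-up; None when undefined."""
    if denominator == 0:
        return None
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# summary report


@dataclass
class SummaryReport:
    per_chromosome: pd.DataFrame
    annotation: pd.DataFrame  # one row per variant type
    large_effect: pd.DataFrame  # rows: all SNPs / novel SNPs
    indel_length_hist: pd.DataFrame  # length 1-5 x insertion/deletion
    sv_summary: pd.DataFrame  # per svtype count and length stats
    novelty: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_chromosome": self.per_chromosome.to_dict(orient="records"),
            "annotation": self.annotation.to_dict(orient="records"),
            "large_effect": self.large_effect.to_dict(orient="records"),
            "indel_length_hist": self.indel_length_hist.to_dict(orient="records"),
            "sv_summary": self.sv_summary.to_dict(orient="records"),
            "novelty": self.novelty,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def write_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in (
            ("per_chromosome", self.per_chromosome),
            ("annotation", self.annotation),
            ("large_effect", self.large_effect),
            ("indel_length_hist", self.indel_length_hist),
            ("sv_summary", self.sv_summary),
        ):
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


def _chrom_of(v: VariantRecord, genome: GenomeSequence) -> str:
    return v.chrom if v.chrom in genome else "unknown"


def _per_chromosome_table(
    genome: GenomeSequence,
    snps: list[VariantRecord],
    indels: list[VariantRecord],
    svs: list[VariantRecord],
) -> pd.DataFrame:
    chroms = list(genome.chrom_names)
    has_unknown = any(
        v.chrom not in genome for v in [*snps, *indels, *svs]
    )
    rows = []
    order = chroms + (["unknown"] if has_unknown else [])
    for chrom in order + ["total"]:
        if chrom == "total":
            sel = lambda vs: vs  # noqa: E731
            mb = sum(genome.lengths.values()) / 1e6
        else:
            sel = lambda vs, c=chrom: [v for v in vs if _chrom_of(v, genome) == c]  # noqa: E731
            mb = genome.lengths.get(chrom, 0) / 1e6
        s, i, v_ = sel(snps), sel(indels), sel(svs)
        ins = [x for x in i if x.is_insertion]
        dels = [x for x in i if x.is_deletion]
        d = lambda n: round(n / mb) if mb > 0 else None  # noqa: E731
        rows.append(
            {
                "chrom": chrom,
                "snps": len(s),
                "snps_per_mb": d(len(s)),
                "indels": len(i),
                "indels_per_mb": d(len(i)),
                "insertions": len(ins),
                "insertions_per_mb": d(len(ins)),
                "deletions": len(dels),
                "deletions_per_mb": d(len(dels)),
                "svs": len(v_),
                "svs_per_mb": d(len(v_)),
            }
        )
    return pd.DataFrame(rows)


def _annotation_row(vtype: str, anns: list[ea.EffectAnnotation]) -> dict:
    regions = [a.region for a in anns]
    n = len(anns)
    intron = regions.count(ea.REGION_INTRON)
    utr = regions.count(ea.REGION_UTR5) + regions.count(ea.REGION_UTR3)
    cds = regions.count(ea.REGION_CDS)
    genic = intron + utr + cds
    if vtype == "SNPs":
        disruptive = sum(a.snp_consequence == ea.NON_SYNONYMOUS for a in anns)
        neutral = sum(a.snp_consequence == ea.SYNONYMOUS for a in anns)
        undet = sum(a.snp_consequence == ea.UNDETERMINED for a in anns)
    else:
        disruptive = sum(a.indel_consequence == ea.FRAMESHIFT for a in anns)
        neutral = sum(a.indel_consequence == ea.INFRAME for a in anns)
        undet = 0
    return {
        "variant_type": vtype,
        "total": n,
        "intergenic": regions.count(ea.REGION_INTERGENIC),
        "unknown_chrom": regions.count(ea.REGION_UNKNOWN),
        "genic": genic,
        "intron": intron,
        "utr": utr,
        "cds": cds,
        "nonsynonymous_or_frameshift": disruptive,
        "synonymous_or_inframe": neutral,
        "undetermined": undet,
        "pct_genic": percentage(genic, n),
        "pct_cds_of_genic": percentage(cds, genic) if genic else None,
        "pct_disruptive_of_cds": percentage(disruptive, cds) if cds else None,
    }


_LE_COLUMNS = {
    "premature_stop": ea.PREMATURE_STOP,
    "stop_lost": ea.STOP_LOST,
    "start_lost": ea.START_LOST,
    "splice_site": ea.SPLICE_REGION,
    "essential_splice": ea.ESSENTIAL_SPLICE,
    "property_change": ea.PROPERTY_CHANGE,
}


def _large_effect_row(name: str, anns: list[ea.EffectAnnotation]) -> dict:
    nonsyn = sum(a.snp_consequence == ea.NON_SYNONYMOUS for a in anns)
    row: dict = {"snp_set": name, "nonsynonymous": nonsyn}
    for col, flag in _LE_COLUMNS.items():
        count = sum(flag in a.large_effect for a in anns)
        row[col] = count
        row[f"{col}_pct"] = percentage(count, nonsyn)
    return row


def build_report(
    genome: GenomeSequence,
    snps: list[VariantRecord],
    indels: list[VariantRecord],
    svs: list[VariantRecord],
    annotations: list[ea.EffectAnnotation],
    novelty: NoveltyPartition | None = None,
) -> SummaryReport:
    """Assemble the per-chromosome, annotation, large-effect, length and
    novelty summaries from upstream outputs.  Deterministic."""
    by_key = {a.variant.key: a for a in annotations}
    snp_anns = [by_key[v.key] for v in snps if v.key in by_key]
    indel_anns = [by_key[v.key] for v in indels if v.key in by_key]

    annotation = pd.DataFrame(
        [
            _annotation_row("SNPs", snp_anns),
            _annotation_row("InDels", indel_anns),
        ]
    )

    le_rows = [_large_effect_row("all", snp_anns)]
    novelty_summary: dict = {}
    if novelty is not None:
        novel_keys = {v.key for v in novelty.novel}
        novel_anns = [a for a in snp_anns if a.variant.key in novel_keys]
        le_rows.append(_large_effect_row("novel", novel_anns))
        n_in = novelty.n_input
        novelty_summary = {
            "n_input": n_in,
            "n_known": len(novelty.known),
            "n_repeat_excluded": len(novelty.repeat_excluded),
            "n_novel": len(novelty.novel),
            "pct_known": percentage(len(novelty.known), n_in),
            "pct_repeat_excluded": percentage(len(novelty.repeat_excluded), n_in),
            "pct_novel": percentage(len(novelty.novel), n_in),
        }
    large_effect = pd.DataFrame(le_rows)

    hist_rows = []
    for length in range(1, 6):
        hist_rows.append(
            {
                "length": length,
                "insertions": sum(
                    1 for v in indels if v.is_insertion and v.length == length
                ),
                "deletions": sum(
                    1 for v in indels if v.is_deletion and v.length == length
                ),
            }
        )
    indel_hist = pd.DataFrame(hist_rows)

    sv_rows = []
    svtypes = sorted({v.svtype or "other" for v in svs}) if svs else []
    for t in svtypes:
        lengths = [v.length for v in svs if (v.svtype or "other") == t]
        sv_rows.append(
            {
                "svtype": t,
                "count": len(lengths),
                "min_length": min(lengths),
                "median_length": int(pd.Series(lengths).median()),
                "max_length": max(lengths),
            }
        )
    sv_summary = pd.DataFrame(
        sv_rows, columns=["svtype", "count", "min_length", "median_length", "max_length"]
    )

    return SummaryReport(
        per_chromosome=_per_chromosome_table(genome, snps, indels, svs),
        annotation=annotation,
        large_effect=large_effect,
        indel_length_hist=indel_hist,
        sv_summary=sv_summary,
        novelty=novelty_summary,
    )


def annotations_to_dataframe(annotations: list[ea.EffectAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        v = a.variant
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "vclass": v.vclass,
                "region": a.region,
                "transcript": a.affected_transcript or "",
                "snp_consequence": a.snp_consequence or "",
                "indel_consequence": a.indel_consequence or "",
                "large_effect": ",".join(sorted(a.large_effect)),
                "ref_aa": a.ref_aa or "",
                "alt_aa": a.alt_aa or "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end synthetic pipeline


@dataclass
class PipelineResult:
    dataset: sd.SimulatedDataset
    genes: list  # retained gene models
    gene_report: GeneFilterReport
    snps: list[VariantRecord]
    indels: list[VariantRecord]
    svs: list[VariantRecord]
    n_rejected: dict[str, int]
    annotations: list[ea.EffectAnnotation]
    large_effect: ea.LargeEffectSummary
    novelty: NoveltyPartition
    distances: DistanceReport
    snp_free: list
    snp_free_genes: list
    scans: dict
    qtl_compare: object
    report: SummaryReport


def run_synthetic_pipeline(
    config: sd.SimulationConfig,
    scan_window_bp: int = 100_000,
    n_extra_genotypes: int = 2,
) -> PipelineResult:
    """Simulate a dataset and push it through every pipeline stage."""
    dataset = sd.simulate(config)
    genes, gene_report = filter_genes(dataset.genes, dataset.genome)

    records = dataset.records()
    raw_snps = sorted(
        (v for v in records if v.vclass == "SNP"), key=lambda v: (v.chrom, v.pos)
    )
    raw_indels = [v for v in records if v.vclass == "INDEL"]
    raw_svs = [v for v in records if v.vclass == "SV"]
    snps, rej_s = filter_snps(raw_snps)
    indels, rej_i = filter_indels(raw_indels)
    svs, rej_v = filter_svs(raw_svs)

    annotations, le_summary = ea.annotate_all(
        snps + indels + svs, genes, dataset.genome
    )

    db = KnownVariantDB.from_keys(dataset.known_db, source="synthetic")
    novelty = find_novel(snps, db, dataset.repeats)

    distances = adjacent_distances(snps)
    regions, region_genes = snp_free_regions(
        snps, genes, dataset.repeats, dataset.coverage
    )

    thresholds = DensityThresholds(window_bp=scan_window_bp)
    scans = {
        "snp": density_scan(snps, dataset.genome, thresholds, "snp"),
        "novel": density_scan(novelty.novel, dataset.genome, thresholds, "novel"),
        "indel": density_scan(indels, dataset.genome, thresholds, "indel"),
        "sv": density_scan(svs, dataset.genome, thresholds, "sv"),
    }

    variant_sets = {"focal": snps}
    for g in range(n_extra_genotypes):
        variant_sets[f"inbred{g + 1}"] = sd.subsample_genotype(
            snps, 0.5, seed=config.seed + 1000 + g
        )
    qtl_cmp = qtl_window_compare(
        variant_sets, dataset.qtl, dataset.genome, focal="focal", genes=genes
    )

    report = build_report(dataset.genome, snps, indels, svs, annotations, novelty)
    return PipelineResult(
        dataset=dataset,
        genes=genes,
        gene_report=gene_report,
        snps=snps,
        indels=indels,
        svs=svs,
        n_rejected={
            "snp": len(rej_s),
            "indel": len(rej_i),
            "sv": len(rej_v),
        },
        annotations=annotations,
        large_effect=le_summary,
        novelty=novelty,
        distances=distances,
        snp_free=regions,
        snp_free_genes=region_genes,
        scans=scans,
        qtl_compare=qtl_cmp,
        report=report,
    )


# ---------------------------------------------------------------------------
# command line


def _fail(message: str) -> None:
    click.echo(f"error: {message}", err=True)
    sys.exit(1)


def _load_inputs(fasta: str, gff: str | None = None):
    try:
        genome = read_fasta(fasta)
    except FileNotFoundError:
        _fail(f"genome FASTA not found: {fasta}")
    genes = None
    if gff is not None:
        try:
            raw = read_gff3(gff, genome)
        except FileNotFoundError:
            _fail(f"gene annotation not found: {gff}")
        genes, _ = filter_genes(raw, genome)
    return genome, genes


@click.group()
def cli() -> None:
    """Genome-wide variation characterization pipeline."""


@cli.command()
@click.option("--config", "config_path", required=False, type=str)
@click.option("--seed", type=int, default=None)
@click.option("--out", "outdir", required=True, type=str)
def simulate(config_path: str | None, seed: int | None, outdir: str) -> None:
    """Generate a synthetic genome + variant dataset."""
    params = {}
    if config_path:
        try:
            params = yaml.safe_load(Path(config_path).read_text()) or {}
        except FileNotFoundError:
            _fail(f"config not found: {config_path}")
    if seed is not None:
        params["seed"] = seed
    cfg = sd.SimulationConfig(**params)
    dataset = sd.simulate(cfg)
    dataset.write(outdir)
    click.echo(
        f"simulated {cfg.n_chroms} chromosomes, {len(dataset.genes)} genes, "
        f"{len(dataset.planted)} variants -> {outdir}"
    )


@cli.command("filter-genes")
@click.option("--fasta", required=True)
@click.option("--gff", required=True)
@click.option("--out-gff", required=True)
@click.option("--report", "report_path", default=None)
def filter_genes_cmd(fasta: str, gff: str, out_gff: str, report_path: str | None):
    genome, _ = _load_inputs(fasta)
    try:
        models = read_gff3(gff, genome)
    except FileNotFoundError:
        _fail(f"gene annotation not found: {gff}")
    retained, rep = filter_genes(models, genome)
    write_gff3(retained, out_gff)
    if report_path:
        Path(report_path).write_text(json.dumps(rep.as_dict(), indent=2))
    click.echo(f"retained {rep.n_retained}/{rep.n_input} genes")


@cli.command("filter-variants")
@click.option("--fasta", required=True)
@click.option("--vcf", required=True)
@click.option("--out-prefix", required=True)
def filter_variants_cmd(fasta: str, vcf: str, out_prefix: str):
    genome, _ = _load_inputs(fasta)
    try:
        records = read_vcf(vcf, genome)
    except FileNotFoundError:
        _fail(f"VCF not found: {vcf}")
    snps = sorted(
        (v for v in records if v.vclass == "SNP"), key=lambda v: (v.chrom, v.pos)
    )
    indels = [v for v in records if v.vclass == "INDEL"]
    svs = [v for v in records if v.vclass == "SV"]
    ps, rs = filter_snps(snps)
    pi, ri = filter_indels(indels)
    pv, rv = filter_svs(svs)
    for name, passed in (("snps", ps), ("indels", pi), ("svs", pv)):
        write_vcf(passed, f"{out_prefix}.{name}.pass.vcf", genome)
    with open(f"{out_prefix}.rejected.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\treason\n")
        for rej in [*rs, *ri, *rv]:
            v = rej.record
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t{rej.reason}\n"
            )
    click.echo(
        f"SNPs {len(ps)} pass/{len(rs)} fail; InDels {len(pi)}/{len(ri)}; "
        f"SVs {len(pv)}/{len(rv)}"
    )


@cli.command()
@click.option("--fasta", required=True)
@click.option("--gff", required=True)
@click.option("--vcf", required=True)
@click.option("--out-tsv", required=True)
@click.option("--summary-json", default=None)
def annotate(fasta: str, gff: str, vcf: str, out_tsv: str, summary_json: str | None):
    genome, genes = _load_inputs(fasta, gff)
    try:
        records = read_vcf(vcf, genome)
    except FileNotFoundError:
        _fail(f"VCF not found: {vcf}")
    annotations, summary = ea.annotate_all(records, genes, genome)
    annotations_to_dataframe(annotations).to_csv(out_tsv, sep="\t", index=False)
    if summary_json:
        Path(summary_json).write_text(
            json.dumps(
                {
                    "counts": summary.counts,
                    "n_transcripts_with_large_effect": len(
                        summary.transcripts_with_large_effect
                    ),
                },
                indent=2,
                sort_keys=True,
            )
        )
    click.echo(f"annotated {len(annotations)} variants -> {out_tsv}")


@cli.command()
@click.option("--fasta", required=True)
@click.option("--gff", required=True)
@click.option("--vcf", required=True)
@click.option("--repeats", default=None)
@click.option("--coverage", default=None)
@click.option("--min-len", default=10_000, show_default=True)
@click.option("--out-bed", required=True)
def regions(fasta, gff, vcf, repeats, coverage, min_len, out_bed):
    """Detect SNP-free regions and their candidate genes."""
    genome, genes = _load_inputs(fasta, gff)
    try:
        records = read_vcf(vcf, genome)
    except FileNotFoundError:
        _fail(f"VCF not found: {vcf}")
    snps = [v for v in records if v.vclass == "SNP"]
    rep = read_bed(repeats) if repeats else None
    cov = read_bedgraph(coverage) if coverage else None
    calls, cand = snp_free_regions(snps, genes, rep, cov, min_len)
    track = IntervalTrack(name="snp_free")
    for r in calls:
        track.add(r.chrom, r.start - 1, r.end, ";".join(r.genes) or "snp_free")
    write_bed(track, out_bed)
    click.echo(f"{len(calls)} SNP-free regions, {len(cand)} candidate genes")


@cli.command()
@click.option("--fasta", required=True)
@click.option("--vcf", required=True)
@click.option("--type", "vtype", default="snp", show_default=True)
@click.option("--window", default=1_000_000, show_default=True)
@click.option("--out-tsv", required=True)
@click.option("--calls-bed", default=None)
def density(fasta, vcf, vtype, window, out_tsv, calls_bed):
    """Per-window density scan with high/low-density region calls."""
    genome, _ = _load_inputs(fasta)
    try:
        records = read_vcf(vcf, genome)
    except FileNotFoundError:
        _fail(f"VCF not found: {vcf}")
    result = density_scan(
        records, genome, DensityThresholds(window_bp=window), vtype
    )
    result.windows.to_csv(out_tsv, sep="\t", index=False)
    if calls_bed:
        track = IntervalTrack(name="calls")
        for r in result.calls:
            track.add(r.chrom, r.start - 1, r.end, f"{r.kind}:{r.density_per_mb:.0f}")
        write_bed(track, calls_bed)
    click.echo(f"{len(result.calls)} density region calls")


@cli.command()
@click.option("--vcf", required=True)
@click.option("--fasta", required=True)
@click.option("--db", "db_path", required=True)
@click.option("--repeats", default=None)
@click.option("--out-prefix", required=True)
@click.option("--position-only", is_flag=True, default=False)
def novel(vcf, fasta, db_path, repeats, out_prefix, position_only):
    """Partition SNPs into known / repeat-excluded / novel."""
    genome, _ = _load_inputs(fasta)
    try:
        records = read_vcf(vcf, genome)
    except FileNotFoundError:
        _fail(f"VCF not found: {vcf}")
    try:
        db = KnownVariantDB.from_tsv(db_path, allele_aware=not position_only)
    except FileNotFoundError:
        _fail(f"known-variant DB not found: {db_path}")
    snps = [v for v in records if v.vclass == "SNP"]
    rep = read_bed(repeats) if repeats else None
    part = find_novel(snps, db, rep)
    write_vcf(part.novel, f"{out_prefix}.novel.vcf", genome)
    summary = {
        "n_input": part.n_input,
        "n_known": len(part.known),
        "n_repeat_excluded": len(part.repeat_excluded),
        "n_novel": len(part.novel),
        "pct_novel": percentage(len(part.novel), part.n_input),
    }
    Path(f"{out_prefix}.novelty.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    click.echo(
        f"{len(part.novel)} novel / {len(part.known)} known / "
        f"{len(part.repeat_excluded)} repeat-excluded"
    )


@cli.command("qtl-compare")
@click.option("--fasta", required=True)
@click.option("--qtl", "qtl_path", required=True)
@click.option("--vcf", "vcfs", multiple=True, required=True,
              help="NAME=path.vcf, repeatable; first is the focal genotype")
@click.option("--window", default=10_000, show_default=True)
@click.option("--out-tsv", required=True)
def qtl_compare(fasta, qtl_path, vcfs, window, out_tsv):
    genome, _ = _load_inputs(fasta)
    try:
        qtl_track = read_bed(qtl_path)
    except FileNotFoundError:
        _fail(f"QTL BED not found: {qtl_path}")
    sets = {}
    for spec_ in vcfs:
        name, _, path = spec_.partition("=")
        if not path:
            _fail(f"--vcf expects NAME=path, got {spec_!r}")
        try:
            sets[name] = [
                v for v in read_vcf(path, genome) if v.vclass == "SNP"
            ]
        except FileNotFoundError:
            _fail(f"VCF not found: {path}")
    result = qtl_window_compare(sets, qtl_track, genome, window_bp=window)
    result.matrix.to_csv(out_tsv, sep="\t", index=False)
    for t in result.top_windows:
        click.echo(
            f"{t.qtl}: top window {t.chrom}:{t.start}-{t.end} "
            f"({t.density_per_mb:.0f}/Mb)"
        )


@cli.command("run-all")
@click.option("--config", "config_path", required=True)
@click.option("--out", "outdir", required=True)
def run_all(config_path: str, outdir: str) -> None:
    """Simulate and run the full pipeline, writing all reports."""
    try:
        params = yaml.safe_load(Path(config_path).read_text()) or {}
    except FileNotFoundError:
        _fail(f"config not found: {config_path}")
    scan_window = int(params.pop("scan_window_bp", 100_000))
    cfg = sd.SimulationConfig(**params)
    result = run_synthetic_pipeline(cfg, scan_window_bp=scan_window)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.dataset.write(out / "data")
    result.report.to_json(out / "summary.json")
    result.report.write_tsv(out / "tables")
    annotations_to_dataframe(result.annotations).to_csv(
        out / "annotations.tsv", sep="\t", index=False
    )
    ranked = rank_genes_by_novel(result.novelty.novel, result.annotations)
    pd.DataFrame(ranked).to_csv(out / "novel_gene_ranking.tsv", sep="\t", index=False)
    for stage, n in (
        ("genes retained", result.gene_report.n_retained),
        ("SNPs passing filters", len(result.snps)),
        ("InDels passing filters", len(result.indels)),
        ("SVs passing filters", len(result.svs)),
        ("novel SNPs", len(result.novelty.novel)),
        ("SNP-free regions", len(result.snp_free)),
    ):
        click.echo(f"{stage}: {n}")
    click.echo(f"reports written to {out}")


if __name__ == "__main__":
    cli()
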