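"""Assemble the final summary tables.

Builds the per-chromosome count/density table, the annotation partition,
the large-effect taxonomy (for all and for novel SNPs), the InDel length
histogram, the SV type summary and the novelty partition, and writes
them as TSV + JSON under results/.
"""

from pathlib import Path

from landvar.gene_filter import filter_genes
from landvar.genome_io import read_bed, read_fasta, read_gff3, read_vcf
from landvar.novel_compare import KnownVariantDB, find_novel
from landvar.report import build_report
import landvar.effect_annotator as ea

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"


def main() -> None:
    genome = read_fasta(DATA / "genome.fasta")
    genes, _ = filter_genes(read_gff3(DATA / "genes.gff3", genome), genome)
    snps = read_vcf(DATA / "snps.pass.vcf", genome)
    indels = read_vcf(DATA / "indels.pass.vcf", genome)
    svs = read_vcf(DATA / "svs.pass.vcf", genome)
    annotations, _ = ea.annotate_all(snps + indels + svs, genes, genome)
    db = KnownVariantDB.from_tsv(DATA / "known_snps.tsv")
    novelty = find_novel(snps, db, read_bed(DATA / "repeats.bed"))

    report = build_report(genome, snps, indels, svs, annotations, novelty)
    outdir = ROOT / "results" / "07_summary"
    report.write_tsv(outdir)
    report.to_json(outdir / "summary.json")
    print(report.per_chromosome.to_string(index=False))
    print()
    print(report.annotation.to_string(index=False))
    print()
    print("novelty:", report.novelty)


if __name__ == "__main__":
    main()
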