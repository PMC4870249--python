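"""Partition passed SNPs into known / repeat-excluded / novel and rank
genes by novel-SNP load.

Matching against the known-SNP database is allele-aware
(chromosome, position, alternate allele); SNPs absent from the database
but inside annotated repeats are set aside rather than called novel.
"""

import json
from pathlib import Path

import pandas as pd

import landvar.effect_annotator as ea
from landvar.gene_filter import filter_genes
from landvar.genome_io import read_bed, read_fasta, read_gff3, read_vcf
from landvar.novel_compare import KnownVariantDB, find_novel, rank_genes_by_novel
from landvar.report import percentage

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"


def main() -> None:
    genome = read_fasta(DATA / "genome.fasta")
    genes, _ = filter_genes(read_gff3(DATA / "genes.gff3", genome), genome)
    snps = read_vcf(DATA / "snps.pass.vcf", genome)
    repeats = read_bed(DATA / "repeats.bed")
    db = KnownVariantDB.from_tsv(DATA / "known_snps.tsv")

    part = find_novel(snps, db, repeats)
    annotations, _ = ea.annotate_all(snps, genes, genome)
    ranked = rank_genes_by_novel(part.novel, annotations, top_n=10)
    pd.DataFrame(ranked).to_csv(
        ROOT / "results" / "05_novel_gene_ranking.tsv", sep="\t", index=False
    )
    out = {
        "n_input": part.n_input,
        "n_known": len(part.known),
        "n_repeat_excluded": len(part.repeat_excluded),
        "n_novel": len(part.novel),
        "pct_known": percentage(len(part.known), part.n_input),
        "pct_novel": percentage(len(part.novel), part.n_input),
    }
    (ROOT / "results" / "05_novelty_summary.json").write_text(
        json.dumps(out, indent=2)
    )
    print(json.dumps(out, indent=2))
    if ranked:
        print("top gene by novel SNPs:", ranked[0])


if __name__ == "__main__":
    main()
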