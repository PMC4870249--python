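"""Filter the gene set and the raw variant calls.

Applies the four gene-filtration rules (CDS >= 150 bp, no internal stop,
longest transcript per locus, no overlapping loci) and the call-quality
criteria (SNPs: quality > 20, depth > 2, no neighbour within 5 bp, copy
number <= 1.5; InDels: support > 1/3; SVs: depth >= 3), reading the
simulated dataset from scratch/data/ through the standard file formats.
"""

import json
from pathlib import Path

from landvar.gene_filter import filter_genes
from landvar.genome_io import read_fasta, read_gff3, read_vcf, write_gff3, write_vcf
from landvar.variant_filter import filter_indels, filter_snps, filter_svs

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"


def main() -> None:
    genome = read_fasta(DATA / "genome.fasta")
    models = read_gff3(DATA / "genes.gff3", genome)
    genes, gene_report = filter_genes(models, genome)
    write_gff3(genes, DATA / "genes.filtered.gff3")

    records = read_vcf(DATA / "variants.vcf", genome)
    snps = sorted((v for v in records if v.vclass == "SNP"),
                  key=lambda v: (v.chrom, v.pos))
    indels = [v for v in records if v.vclass == "INDEL"]
    svs = [v for v in records if v.vclass == "SV"]
    ps, rs = filter_snps(snps)
    pi, ri = filter_indels(indels)
    pv, rv = filter_svs(svs)
    for name, passed in (("snps", ps), ("indels", pi), ("svs", pv)):
        write_vcf(passed, DATA / f"{name}.pass.vcf", genome)

    summary = {
        "genes": gene_report.as_dict(),
        "snps": {"pass": len(ps), "fail": len(rs)},
        "indels": {"pass": len(pi), "fail": len(ri)},
        "svs": {"pass": len(pv), "fail": len(rv)},
    }
    (ROOT / "results" / "02_filter_summary.json").write_text(
        json.dumps(summary, indent=2)
    )
    print(f"genes: {gene_report.n_retained}/{gene_report.n_input} retained")
    print(f"SNPs {len(ps)} pass ({len(rs)} fail); InDels {len(pi)} "
          f"({len(ri)} fail); SVs {len(pv)} ({len(rv)} fail)")


if __name__ == "__main__":
    main()
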