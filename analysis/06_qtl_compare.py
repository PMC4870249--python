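"""Compare SNP density across genotypes in 10-kb windows inside QTL
intervals.

The focal genotype is the simulated landrace; two derived genotypes are
formed by subsampling half of its calls, emulating inbred lines that
share part of the variation.  For each QTL the window with the highest
focal SNP density is reported with its overlapping genes.
"""

import json
from pathlib import Path

from landvar.gene_filter import filter_genes
from landvar.genome_io import read_bed, read_fasta, read_gff3, read_vcf
from landvar.region_scan import qtl_window_compare
from landvar.synthetic_data import subsample_genotype

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"


def main() -> None:
    genome = read_fasta(DATA / "genome.fasta")
    genes, _ = filter_genes(read_gff3(DATA / "genes.gff3", genome), genome)
    snps = read_vcf(DATA / "snps.pass.vcf", genome)
    qtl = read_bed(DATA / "qtl.bed")
    sets = {
        "focal": snps,
        "inbred1": subsample_genotype(snps, 0.5, seed=1001),
        "inbred2": subsample_genotype(snps, 0.5, seed=1002),
    }
    result = qtl_window_compare(sets, qtl, genome, focal="focal", genes=genes)
    result.matrix.to_csv(
        ROOT / "results" / "06_qtl_window_densities.tsv", sep="\t", index=False
    )
    top = [
        {
            "qtl": t.qtl,
            "window": f"{t.chrom}:{t.start}-{t.end}",
            "focal_density_per_mb": t.density_per_mb,
            "genes": t.genes,
        }
        for t in result.top_windows
    ]
    (ROOT / "results" / "06_qtl_top_windows.json").write_text(
        json.dumps(top, indent=2)
    )
    print(json.dumps(top, indent=2))


if __name__ == "__main__":
    main()
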