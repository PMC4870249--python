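"""Positional structure of the SNP landscape.

Computes adjacent-SNP distance bins, SNP-free regions (>10 kb inter-SNP
gaps) with candidate genes cleaned of repeats and unsequenced spans, and
100-kb window density scans with merged high/low-density region calls
for SNPs, InDels and SVs.  Writes window tables and region calls.
"""

import json
from pathlib import Path

from landvar.gene_filter import filter_genes
from landvar.genome_io import read_bed, read_bedgraph, read_fasta, read_gff3, read_vcf
from landvar.region_scan import (
    DensityThresholds,
    adjacent_distances,
    density_scan,
    snp_free_regions,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"


def main() -> None:
    genome = read_fasta(DATA / "genome.fasta")
    genes, _ = filter_genes(read_gff3(DATA / "genes.gff3", genome), genome)
    snps = read_vcf(DATA / "snps.pass.vcf", genome)
    indels = read_vcf(DATA / "indels.pass.vcf", genome)
    svs = read_vcf(DATA / "svs.pass.vcf", genome)
    repeats = read_bed(DATA / "repeats.bed")
    coverage = read_bedgraph(DATA / "coverage.bedgraph")

    dist = adjacent_distances(snps)
    regions, candidates = snp_free_regions(snps, genes, repeats, coverage)
    thresholds = DensityThresholds(window_bp=100_000)
    out = {
        "adjacent_distance_bins": {
            "lt_100bp": dist.bin_lt_100,
            "100bp_to_1kb": dist.bin_100_to_1kb,
            "ge_1kb": dist.bin_ge_1kb,
        },
        "n_snp_free_regions": len(regions),
        "n_candidate_genes_without_snps": len(candidates),
        "density_calls": {},
    }
    for vtype, variants in (("snp", snps), ("indel", indels), ("sv", svs)):
        scan = density_scan(variants, genome, thresholds, vtype)
        scan.windows.to_csv(
            ROOT / "results" / f"04_density_windows_{vtype}.tsv",
            sep="\t", index=False,
        )
        out["density_calls"][vtype] = {
            "high": sum(c.kind == "high_density" for c in scan.calls),
            "low": sum(c.kind == "low_density" for c in scan.calls),
        }
    (ROOT / "results" / "04_region_summary.json").write_text(
        json.dumps(out, indent=2)
    )
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
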