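import dataclasses

import numpy as np
import pytest

from landvar.genome_io import GenomeSequence, IntervalTrack, VariantRecord
from landvar.region_scan import (
    DensityThresholds,
    adjacent_distances,
    density_scan,
    qtl_window_compare,
    snp_free_regions,
)


def snp(pos, chrom="chr1"):
    return VariantRecord(chrom, pos, "A", "T")


class TestAdjacentDistances:
    def test_binned_example(self):
        rep = adjacent_distances([snp(100), snp(150), snp(900)])
        assert rep.distances["chr1"] == [50, 750]
        assert (rep.bin_lt_100, rep.bin_100_to_1kb, rep.bin_ge_1kb) == (1, 1, 0)

    def test_single_snp_no_distances(self):
        rep = adjacent_distances([snp(500)])
        assert rep.distances["chr1"] == []

    def test_chromosomes_do_not_mix(self):
        rep = adjacent_distances([snp(100), snp(200, "chr2")])
        assert all(d == [] for d in rep.distances.values())

    def test_uniform_snps_have_geometric_spacing(self):
        # at per-base rate lam, inter-SNP distances are ~geometric with
        # mean 1/lam; compare the sample mean against the closed form
        rng = np.random.default_rng(12)
        lam = 1 / 200
        positions = np.cumsum(rng.geometric(lam, size=4000))
        rep = adjacent_distances([snp(int(p)) for p in positions])
        d = np.array(rep.distances["chr1"], dtype=float)
        assert abs(d.mean() - 1 / lam) < 4 * d.std() / np.sqrt(len(d))


class TestSnpFreeRegions:
    def test_gap_longer_than_10kb_called(self):
        regions, _ = snp_free_regions([snp(1000), snp(12001)], [])
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.length) == (1001, 12000, 11000)

    def test_gap_of_exactly_10kb_not_called(self):
        regions, _ = snp_free_regions([snp(1000), snp(11001)], [])
        assert regions == []

    def test_chromosome_ends_not_regions(self):
        regions, _ = snp_free_regions([snp(50_000)], [])
        assert regions == []

    def _gene(self, start, end, tid="g1"):
        from landvar.genome_io import GeneModel

        return GeneModel(
            gene_id=tid, transcript_id=f"{tid}.t", chrom="chr1", strand="+",
            exons=[(start, end)], cds_segments=[(start, end)],
        )

    def test_contained_gene_reported(self):
        gene = self._gene(3000, 4000)
        regions, cand = snp_free_regions([snp(1000), snp(12001)], [gene])
        assert [g.transcript_id for g in cand] == ["g1.t"]
        assert regions[0].genes == ["g1.t"]

    def test_gene_overlapping_repeat_excluded(self):
        gene = self._gene(3000, 4000)
        repeats = IntervalTrack("rep")
        repeats.add("chr1", 3500, 3600)
        repeats.sort()
        _, cand = snp_free_regions([snp(1000), snp(12001)], [gene], repeats)
        assert cand == []

    def test_gene_with_zero_coverage_excluded(self):
        gene = self._gene(3000, 4000)
        cov = IntervalTrack("cov")
        cov.add("chr1", 0, 3499, 21.0)
        cov.add("chr1", 3499, 3600, 0.0)  # unsequenced stretch inside gene
        cov.add("chr1", 3600, 20000, 21.0)
        cov.sort()
        _, cand = snp_free_regions([snp(1000), snp(12001)], [gene], None, cov)
        assert cand == []

    def test_fully_covered_gene_retained(self):
        gene = self._gene(3000, 4000)
        cov = IntervalTrack("cov")
        cov.add("chr1", 0, 20000, 21.0)
        cov.sort()
        _, cand = snp_free_regions([snp(1000), snp(12001)], [gene], None, cov)
        assert len(cand) == 1

    def test_regions_disjoint_from_snps(self, pipeline):
        result, _ = pipeline
        positions = {(v.chrom, v.pos) for v in result.snps}
        for r in result.snp_free:
            assert all(
                (r.chrom, p) not in positions for p in (r.start, r.end)
            )
            # flanking positions are SNPs by construction
            assert (r.chrom, r.start - 1) in positions
            assert (r.chrom, r.end + 1) in positions


class TestDensityScan:
    def _genome(self, n=2, L=1_000_000):
        return GenomeSequence({f"chr{i + 1}": "A" * L for i in range(n)})

    def test_high_call_above_3500(self):
        genome = self._genome(1)
        rng = np.random.default_rng(0)
        snps = [snp(int(p) + 1) for p in rng.choice(1_000_000, 4000, replace=False)]
        res = density_scan(snps, genome, DensityThresholds(), "snp")
        assert [c.kind for c in res.calls] == ["high_density"]

    def test_low_call_below_500(self):
        genome = self._genome(1)
        snps = [snp(p) for p in range(1, 1_000_000, 5525)]  # 181/Mb
        res = density_scan(snps, genome, DensityThresholds(), "snp")
        assert [c.kind for c in res.calls] == ["low_density"]
        assert res.calls[0].density_per_mb == pytest.approx(181, abs=1)

    def test_empty_chromosome_all_low(self):
        genome = self._genome(1)
        res = density_scan([], genome, DensityThresholds(window_bp=100_000), "snp")
        assert (res.windows["count"] == 0).all()
        # adjacent qualifying windows merge into one whole-chromosome call
        assert len(res.calls) == 1
        assert (res.calls[0].start, res.calls[0].end) == (1, 1_000_000)

    def test_window_counts_conserve_totals(self, pipeline):
        result, _ = pipeline
        scan = result.scans["snp"]
        per_chrom_from_windows = scan.windows.groupby("chrom")["count"].sum()
        for chrom, n in per_chrom_from_windows.items():
            assert n == sum(v.chrom == chrom for v in result.snps)

    def test_terminal_short_window_density_normalized(self):
        genome = GenomeSequence({"chr1": "A" * 1_250_000})
        snps = [snp(1_200_001 + i * 100) for i in range(200)]  # in last 250 kb
        res = density_scan(snps, genome, DensityThresholds(), "snp")
        last = res.windows.iloc[-1]
        assert last["end"] - last["start"] == 250_000
        assert last["density_per_mb"] == pytest.approx(200 / 0.25)

    def test_plot_density_writes_figure(self, tmp_path):
        from landvar.region_scan import plot_density

        genome = self._genome(1)
        res = density_scan(
            [snp(p) for p in range(1, 1_000_000, 2000)],
            genome,
            DensityThresholds(window_bp=100_000),
            "snp",
        )
        out = tmp_path / "density.png"
        plot_density(res, str(out))
        assert out.stat().st_size > 0

    def test_translation_equivariance(self):
        genome = self._genome(1, L=2_000_000)
        rng = np.random.default_rng(3)
        base = sorted(int(p) for p in rng.choice(500_000, 900, replace=False))
        shift = 1_000_000  # a whole number of windows
        t = DensityThresholds(window_bp=100_000)
        res_a = density_scan([snp(p + 1) for p in base], genome, t, "snp")
        res_b = density_scan([snp(p + 1 + shift) for p in base], genome, t, "snp")
        nw = shift // t.window_bp
        dens_a = res_a.windows["density_per_mb"].to_numpy()
        dens_b = res_b.windows["density_per_mb"].to_numpy()
        assert (dens_a[:nw] == dens_b[nw:]).all()


class TestQtlCompare:
    def _setup(self, qtl_span=(100_000, 200_000)):
        genome = GenomeSequence({"chr1": "A" * 300_000})
        qtl = IntervalTrack("qtl")
        qtl.add("chr1", *qtl_span, "krn1")
        qtl.sort()
        return genome, qtl

    def test_planted_spike_recovered(self):
        genome, qtl = self._setup()
        rng = np.random.default_rng(1)
        background = [
            snp(int(p)) for p in rng.integers(100_001, 200_000, size=100)
        ]
        spike = [snp(140_001 + i * 90) for i in range(100)]  # 10x density
        res = qtl_window_compare(
            {"focal": background + spike, "other": background},
            qtl,
            genome,
        )
        top = res.top_windows[0]
        assert (top.start, top.end) == (140_000, 150_000)

    def test_identical_genotypes_identical_rows(self):
        genome, qtl = self._setup()
        variants = [snp(p) for p in range(100_500, 199_000, 777)]
        res = qtl_window_compare(
            {"a": variants, "b": variants}, qtl, genome, focal="a"
        )
        assert (res.matrix["a"] == res.matrix["b"]).all()

    def test_short_qtl_single_window(self):
        genome, qtl = self._setup(qtl_span=(100_000, 104_000))
        res = qtl_window_compare({"a": [snp(101_000)]}, qtl, genome)
        assert len(res.matrix) == 1
        row = res.matrix.iloc[0]
        assert (row["start"], row["end"]) == (100_000, 104_000)

    def test_off_chromosome_qtl_rejected(self):
        genome, _ = self._setup()
        qtl = IntervalTrack("qtl")
        qtl.add("chr1", 250_000, 400_000, "beyond")
        qtl.sort()
        with pytest.raises(ValueError):
            qtl_window_compare({"a": []}, qtl, genome)
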