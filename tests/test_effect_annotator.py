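import dataclasses

import numpy as np
import pytest
from Bio.Seq import Seq

import landvar.effect_annotator as ea
from landvar.genome_io import GenomeSequence, VariantRecord

from .oracles import brute_force_region, brute_force_snp_consequence


def snp(pos, ref, alt, chrom="chrT"):
    return VariantRecord(chrom, pos, ref, alt)


# Fixture gene layout (forward strand, see conftest.build_gene):
# utr5 21-30, CDS 31-45 + 126-143, intron 46-125, utr3 144-153.
# Coding sequence: ATG GCT TGG GAA AAA CCC GGG TTT CAT TGC TAA.


class TestAssignRegion:
    @pytest.mark.parametrize(
        "pos,region",
        [
            (31, "cds"),
            (140, "cds"),
            (25, "utr5"),
            (148, "utr3"),
            (60, "intron"),
            (10, "intergenic"),
            (170, "intergenic"),
        ],
    )
    def test_point_regions(self, fwd_gene, pos, region):
        genome, gene = fwd_gene
        index = ea.TranscriptIndex([gene])
        v = snp(pos, genome.base("chrT", pos), "A" if genome.base("chrT", pos) != "A" else "T")
        got, _ = ea.assign_region(v, index)
        assert got == region

    def test_deletion_spanning_exon_intron_boundary_is_cds(self, fwd_gene):
        genome, gene = fwd_gene
        index = ea.TranscriptIndex([gene])
        # delete bases 45 (CDS) and 46 (intron): CDS wins by precedence
        ref = genome.fetch("chrT", 44, 46)
        v = VariantRecord("chrT", 44, ref, ref[0])
        region, _ = ea.assign_region(v, index)
        assert region == "cds"
        assert brute_force_region(v, [gene]) == "cds"

    def test_deletion_region_matches_bruteforce(self, fwd_gene):
        genome, gene = fwd_gene
        index = ea.TranscriptIndex([gene])
        rng = np.random.default_rng(5)
        for _ in range(200):
            pos = int(rng.integers(1, 150))
            length = int(rng.integers(1, 6))
            ref = genome.fetch("chrT", pos, pos + length)
            v = VariantRecord("chrT", pos, ref, ref[0])
            region, _ = ea.assign_region(v, index)
            oracle = brute_force_region(v, [gene])
            assert region == oracle, (pos, length)


class TestCodingSnp:
    def classify(self, fixture, pos, alt):
        genome, gene = fixture
        v = snp(pos, genome.base("chrT", pos), alt)
        return ea.classify_snp_coding(v, gene, genome)

    def test_synonymous(self, fwd_gene):
        # GCT -> GCC, Ala -> Ala
        consequence, flags, ref_aa, alt_aa = self.classify(fwd_gene, 36, "C")
        assert consequence == "synonymous" and flags == set()
        assert (ref_aa, alt_aa) == ("A", "A")

    def test_premature_stop(self, fwd_gene):
        # TGG -> TGA mid-CDS
        consequence, flags, _, alt_aa = self.classify(fwd_gene, 39, "A")
        assert consequence == "non_synonymous"
        assert flags == {"premature_stop"}
        assert alt_aa == "*"

    def test_stop_lost(self, fwd_gene):
        # terminal TAA -> CAA
        consequence, flags, *_ = self.classify(fwd_gene, 141, "C")
        assert consequence == "non_synonymous"
        assert "stop_lost" in flags

    def test_property_change(self, fwd_gene):
        # GCT -> GAT: Ala (hydrophobic) -> Asp (negative)
        consequence, flags, ref_aa, alt_aa = self.classify(fwd_gene, 35, "A")
        assert consequence == "non_synonymous"
        assert flags == {"property_change"}
        assert (ref_aa, alt_aa) == ("A", "D")

    def test_start_lost(self, fwd_gene):
        consequence, flags, *_ = self.classify(fwd_gene, 31, "G")
        assert consequence == "non_synonymous"
        assert "start_lost" in flags

    def test_minus_strand_start_lost_verified_by_oracle(self, rev_gene):
        genome, gene = rev_gene
        pos = gene.cds_genomic_pos(0)  # codon-1 A of ATG, transcript sense
        assert genome.base("chrT", pos) == "T"  # complement on the genome
        v = snp(pos, "T", "C")  # transcript-sense A -> G
        consequence, flags, *_ = ea.classify_snp_coding(v, gene, genome)
        assert "start_lost" in flags
        o_consequence, o_flags = brute_force_snp_consequence(v, gene, genome)
        assert (consequence, flags) == (o_consequence, o_flags)

    def test_undetermined_with_N(self, fwd_gene):
        genome, gene = fwd_gene
        seq = genome.sequences["chrT"]
        genome_n = GenomeSequence({"chrT": seq[:33] + "N" + seq[34:]})
        v = snp(36, "T", "C")
        consequence, flags, ref_aa, alt_aa = ea.classify_snp_coding(
            v, gene, genome_n
        )
        assert consequence == "undetermined"
        assert flags == set() and ref_aa is None

    def test_reference_mismatch_rejected(self, fwd_gene):
        genome, gene = fwd_gene
        with pytest.raises(ValueError):
            ea.classify_snp_coding(snp(36, "G", "C"), gene, genome)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_oracle_equivalence_random_coding_snps(self, strand, sim_dataset):
        """Single-codon classification must agree with rebuilding and
        translating the entire mutated CDS, across random substitutions on
        genes of either strand."""
        genome = sim_dataset.genome
        genes = [g for g in sim_dataset.genes if g.strand == strand][:6]
        rng = np.random.default_rng(17 if strand == "+" else 18)
        checked = 0
        for gene in genes:
            for _ in range(100):
                off = int(rng.integers(0, gene.cds_length))
                pos = gene.cds_genomic_pos(off)
                ref = genome.base(gene.chrom, pos)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                v = snp(pos, ref, alt, chrom=gene.chrom)
                consequence, flags, *_ = ea.classify_snp_coding(v, gene, genome)
                o_consequence, o_flags = brute_force_snp_consequence(
                    v, gene, genome
                )
                assert (consequence, flags) == (o_consequence, o_flags), v
                checked += 1
        assert checked >= 500


class TestSplice:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (46, "essential_splice"),  # intron base 1 (GT donor G)
            (47, "essential_splice"),  # intron base 2
            (124, "essential_splice"),  # intron last-but-one (AG acceptor A)
            (125, "essential_splice"),  # intron last base
            (43, "splice_region"),  # 3 bp into the exon 3' end
            (45, "splice_region"),  # 1 bp into the exon
            (126, "splice_region"),  # 1 bp into the downstream exon
            (50, None),  # intron base 5
            (35, None),  # deep in the exon
        ],
    )
    def test_positions(self, fwd_gene, pos, expected):
        genome, gene = fwd_gene
        v = snp(pos, genome.base("chrT", pos), "A" if genome.base("chrT", pos) != "A" else "C")
        assert ea.classify_splice(v, gene) == expected

    def test_minus_strand_essential_sites_are_intron_ends(self, rev_gene):
        # on the minus strand the donor GT is at the genomic *end* of the
        # intron; both intron ends must still be essential
        genome, gene = rev_gene
        (s, e), = gene.introns()
        essential, _ = ea.splice_site_sets(gene)
        assert essential == {s, s + 1, e - 1, e}
        # transcript-sense donor dinucleotide reads GT after revcomp
        donor = str(Seq(genome.fetch("chrT", e - 1, e)).reverse_complement())
        assert donor == "GT"


class TestIndelConsequence:
    @pytest.mark.parametrize(
        "length,expected",
        [(1, "frameshift"), (2, "frameshift"), (3, "inframe"),
         (4, "frameshift"), (5, "frameshift")],
    )
    def test_length_mod_three(self, length, expected):
        v = VariantRecord("c", 10, "A" * (length + 1), "A")
        assert ea.classify_indel_coding(v) == expected

    def test_inframe_codon_deletion_in_gene(self, fwd_gene):
        genome, gene = fwd_gene
        index = ea.TranscriptIndex([gene])
        ref = genome.fetch("chrT", 128, 131)  # delete GGG codon
        v = VariantRecord("chrT", 128, ref, ref[0], support_fraction=0.5)
        ann = ea.annotate_variant(v, index, genome)
        assert ann.region == "cds"
        assert ann.indel_consequence == "inframe"


class TestAnnotateAll:
    def test_empty_inputs(self, fwd_gene):
        genome, gene = fwd_gene
        anns, summary = ea.annotate_all([], [gene], genome)
        assert anns == []
        assert all(v == 0 for v in summary.counts.values())

    def test_intergenic_only(self, fwd_gene):
        genome, gene = fwd_gene
        variants = [snp(5, genome.base("chrT", 5), "A"),
                    snp(165, genome.base("chrT", 165), "A")]
        anns, summary = ea.annotate_all(variants, [gene], genome)
        assert {a.region for a in anns} == {"intergenic"}
        assert all(not a.large_effect for a in anns)

    def test_planted_truth_labels_recovered(self, sim_dataset):
        """The central integration check: annotating the planted variants
        recovers every ground-truth label exactly."""
        anns, _ = ea.annotate_all(
            sim_dataset.records(), sim_dataset.genes, sim_dataset.genome
        )
        truth = sim_dataset.truth_by_key()
        mismatches = [
            (a.variant.key, truth[a.variant.key].truth_label, ea.primary_label(a))
            for a in anns
            if ea.primary_label(a) != truth[a.variant.key].truth_label
        ]
        assert mismatches == []

    def test_strand_symmetry(self, sim_dataset):
        """Reverse-complementing the genome and flipping all coordinates
        and strands leaves every consequence label unchanged."""
        genome, genes = sim_dataset.genome, sim_dataset.genes
        lengths = genome.lengths
        snps = [p.record for p in sim_dataset.planted
                if p.record.vclass == "SNP"][:400]

        def flip_iv(chrom, iv):
            s, e = iv
            L = lengths[chrom]
            return (L - e + 1, L - s + 1)

        flipped_genome = GenomeSequence(
            {c: str(Seq(s).reverse_complement()) for c, s in genome.sequences.items()}
        )
        flipped_genes = [
            dataclasses.replace(
                g,
                strand="-" if g.strand == "+" else "+",
                exons=sorted(flip_iv(g.chrom, iv) for iv in g.exons),
                cds_segments=sorted(flip_iv(g.chrom, iv) for iv in g.cds_segments),
                utr5=sorted(flip_iv(g.chrom, iv) for iv in g.utr5),
                utr3=sorted(flip_iv(g.chrom, iv) for iv in g.utr3),
            )
            for g in genes
        ]
        comp = str.maketrans("ACGTN", "TGCAN")
        flipped_snps = [
            VariantRecord(
                v.chrom,
                lengths[v.chrom] - v.pos + 1,
                v.ref_allele.translate(comp),
                v.alt_allele.translate(comp),
            )
            for v in snps
        ]
        anns, _ = ea.annotate_all(snps, genes, genome)
        flipped_anns, _ = ea.annotate_all(
            flipped_snps, flipped_genes, flipped_genome
        )
        labels = [ea.primary_label(a) for a in anns]
        flipped_labels = [ea.primary_label(a) for a in flipped_anns]
        assert labels == flipped_labels

    def test_region_partition(self, sim_dataset):
        anns, _ = ea.annotate_all(
            sim_dataset.records(), sim_dataset.genes, sim_dataset.genome
        )
        regions = {a.region for a in anns}
        assert regions <= {"intergenic", "intron", "utr5", "utr3", "cds"}
        cds_snps = [a for a in anns
                    if a.region == "cds" and a.variant.vclass == "SNP"]
        assert all(a.snp_consequence is not None for a in cds_snps)
        n = sum(a.snp_consequence == c for a in cds_snps
                for c in ("synonymous", "non_synonymous", "undetermined"))
        assert n == len(cds_snps)
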