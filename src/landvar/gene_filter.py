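"""Reference gene-set filtration.

Four rules are applied, in order, to the raw gene annotation before any
variant is annotated:

1. transcripts with a CDS shorter than 150 bp are removed;
2. transcripts whose coding region contains an internal stop codon are
   removed;
3. of the transcripts at one gene locus, only the longest (by CDS length)
   is retained;
4. of overlapping gene loci, only the longest is retained.

"Longest" always means CDS length; ties break on the lexicographically
smallest transcript id so the output is deterministic.  Rule 4 compares
gene spans (min exon start to max exon end) on the same chromosome,
regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .genome_io import GeneModel, GenomeSequence

MIN_CDS_LENGTH = 150


@dataclass
class GeneFilterReport:
    n_input: int = 0
    n_removed_short_cds: int = 0
    n_removed_internal_stop: int = 0
    n_collapsed_transcripts: int = 0
    n_removed_overlap: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def has_internal_stop(model: GeneModel, genome: GenomeSequence) -> bool:
    """True if the spliced CDS contains a stop codon before its final codon.

    The final codon, if a stop, is not internal.  Codons containing N
    translate to X and never count as stops.
    """
    cds = model.spliced_cds(genome)
    n_codons = len(cds) // 3
    protein = str(Seq(cds[: n_codons * 3]).translate())
    return "*" in protein[: n_codons - 1]


def _longest(models: list[GeneModel]) -> GeneModel:
    return max(models, key=lambda m: (m.cds_length, _neg_id(m.transcript_id)))


def _neg_id(tid: str) -> tuple[int, ...]:
    # invert lexicographic order so max() prefers the smallest id on ties
    return tuple(-ord(c) for c in tid)


def filter_genes(
    models: list[GeneModel], genome: GenomeSequence
) -> tuple[list[GeneModel], GeneFilterReport]:
    """Apply the four filtration rules; returns (retained, report).

    The retained set has one transcript per locus, every CDS >= 150 bp with
    no internal stop, and pairwise non-overlapping gene spans.
    """
    report = GeneFilterReport(n_input=len(models))

    stage = [m for m in models if m.cds_length >= MIN_CDS_LENGTH]
    report.n_removed_short_cds = report.n_input - len(stage)

    kept = [m for m in stage if not has_internal_stop(m, genome)]
    report.n_removed_internal_stop = len(stage) - len(kept)
    stage = kept

    by_locus: dict[str, list[GeneModel]] = {}
    for m in stage:
        by_locus.setdefault(m.gene_id, []).append(m)
    stage = [_longest(txs) for txs in by_locus.values()]
    report.n_collapsed_transcripts = sum(len(t) - 1 for t in by_locus.values())

    retained = _drop_overlapping(stage)
    report.n_removed_overlap = len(stage) - len(retained)
    report.n_retained = len(retained)

    retained.sort(key=lambda m: (m.chrom, m.span, m.transcript_id))
    return retained, report


def _drop_overlapping(models: list[GeneModel]) -> list[GeneModel]:
    """Among overlapping gene spans keep the longest CDS.

    Removal is iterative: within each connected cluster of mutually
    overlapping spans the longest gene is kept and every gene overlapping
    *it* is removed; survivors are re-examined, so the output is pairwise
    non-overlapping.
    """
    out: list[GeneModel] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom_models in by_chrom.values():
        pool = sorted(
            chrom_models, key=lambda m: (-m.cds_length, m.transcript_id)
        )
        kept: list[GeneModel] = []
        for m in pool:
            s, e = m.span
            if any(s <= k.span[1] and k.span[0] <= e for k in kept):
                continue
            kept.append(m)
        out.extend(kept)
    return out
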