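"""Genome-scale positional summaries of the filtered variant calls.

Covers: distances between adjacent SNPs; SNP-free regions (inter-SNP gaps
longer than 10 kb) with the genes they contain, cleaned of repeats and of
unsequenced genes; sliding-window density scans with high/low-density
region calls; and 10-kb window comparisons of SNP density across
genotypes inside QTL intervals.

Windows are 0-based half-open and tile each chromosome from zero; the
terminal window may be short and its density is normalized by its true
length so per-Mb thresholds stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import (
    GeneModel,
    GenomeSequence,
    IntervalTrack,
    VariantRecord,
)

#: default per-Mb density thresholds by variant type (high, low); a low bound
#: of None disables low-density calls for that type
DEFAULT_LIMITS: dict[str, tuple[float, float | None]] = {
    "snp": (3500.0, 500.0),
    "novel": (500.0, 20.0),
    "indel": (250.0, 10.0),
    "sv": (80.0, None),
}


@dataclass
class DensityThresholds:
    window_bp: int = 1_000_000
    qtl_window_bp: int = 10_000
    limits: dict[str, tuple[float, float | None]] = field(
        default_factory=lambda: dict(DEFAULT_LIMITS)
    )

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.qtl_window_bp <= 0:
            raise ValueError("window sizes must be positive")
        for vtype, (high, low) in self.limits.items():
            if low is not None and not high > low:
                raise ValueError(f"{vtype}: high threshold must exceed low")


@dataclass
class RegionCall:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    kind: str  # snp_free | high_density | low_density
    variant_type: str | None = None
    density_per_mb: float | None = None
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# adjacent-SNP distances


@dataclass
class DistanceReport:
    n_snps: int
    distances: dict[str, list[int]]
    bin_lt_100: int = 0
    bin_100_to_1kb: int = 0
    bin_ge_1kb: int = 0

    def fractions_of_snps(self) -> dict[str, float]:
        """Bin counts as fractions of the total SNP count (the convention
        used when a study reports 'x% of adjacent SNPs')."""
        if self.n_snps == 0:
            return {}
        return {
            "lt_100": self.bin_lt_100 / self.n_snps,
            "100_to_1kb": self.bin_100_to_1kb / self.n_snps,
            "ge_1kb": self.bin_ge_1kb / self.n_snps,
        }


def adjacent_distances(snps: list[VariantRecord]) -> DistanceReport:
    """Distances between consecutive SNPs on the same chromosome, binned
    into <100 bp, 100 bp to <1 kb, and >=1 kb."""
    by_chrom: dict[str, list[int]] = {}
    for v in snps:
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    report = DistanceReport(n_snps=len(snps), distances={})
    for chrom, positions in by_chrom.items():
        positions.sort()
        dists = [b - a for a, b in zip(positions, positions[1:])]
        report.distances[chrom] = dists
        for d in dists:
            if d < 100:
                report.bin_lt_100 += 1
            elif d < 1000:
                report.bin_100_to_1kb += 1
            else:
                report.bin_ge_1kb += 1
    return report


# ---------------------------------------------------------------------------
# SNP-free regions


def _gene_is_sequenced(gene: GeneModel, coverage: IntervalTrack | None) -> bool:
    """False when any base of the gene span has zero (or missing) coverage."""
    if coverage is None:
        return True
    s, e = gene.span
    covered_to = s - 1  # last 1-based position known covered
    for cs, ce, value in coverage.iter_overlapping(gene.chrom, s, e):
        if float(value) <= 0:
            return False
        if cs > covered_to:  # gap in the track = unsequenced bases
            return False
        covered_to = max(covered_to, ce)
    return covered_to >= e


def snp_free_regions(
    snps: list[VariantRecord],
    genes: list[GeneModel],
    repeats: IntervalTrack | None = None,
    coverage: IntervalTrack | None = None,
    min_len: int = 10_000,
) -> tuple[list[RegionCall], list[GeneModel]]:
    """Inter-SNP gaps strictly longer than ``min_len`` and the candidate
    genes fully contained in them.

    A region spans the bases strictly between two adjacent SNPs; chromosome
    ends before the first / after the last SNP do not qualify.  Candidate
    genes overlapping a repeat element, or with any unsequenced base in
    their span, are excluded.
    """
    by_chrom: dict[str, list[int]] = {}
    for v in snps:
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    regions: list[RegionCall] = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        for p1, p2 in zip(positions, positions[1:]):
            if p2 - p1 - 1 > min_len:
                regions.append(
                    RegionCall(chrom=chrom, start=p1 + 1, end=p2 - 1, kind="snp_free")
                )

    candidates: list[GeneModel] = []
    region_by_chrom: dict[str, list[RegionCall]] = {}
    for r in regions:
        region_by_chrom.setdefault(r.chrom, []).append(r)
    for gene in genes:
        s, e = gene.span
        host = next(
            (
                r
                for r in region_by_chrom.get(gene.chrom, [])
                if r.start <= s and e <= r.end
            ),
            None,
        )
        if host is None:
            continue
        if repeats is not None and repeats.overlaps(gene.chrom, s, e):
            continue
        if not _gene_is_sequenced(gene, coverage):
            continue
        host.genes.append(gene.transcript_id)
        candidates.append(gene)
    return regions, candidates


# ---------------------------------------------------------------------------
# density scanning


@dataclass
class DensityScanResult:
    variant_type: str
    windows: pd.DataFrame  # chrom, start, end, count, density_per_mb
    calls: list[RegionCall]
    per_chromosome: pd.DataFrame  # chrom, count, length_bp, density_per_mb


def density_scan(
    variants: list[VariantRecord],
    genome: GenomeSequence,
    thresholds: DensityThresholds | None = None,
    variant_type: str = "snp",
) -> DensityScanResult:
    """Tile each chromosome with fixed windows, compute per-window variant
    density (/Mb), and call merged high/low-density regions."""
    t = thresholds or DensityThresholds()
    high, low = t.limits[variant_type]
    counts: dict[str, dict[int, int]] = {c: {} for c in genome.chrom_names}
    for v in variants:
        if v.chrom in counts:
            w = (v.pos - 1) // t.window_bp
            counts[v.chrom][w] = counts[v.chrom].get(w, 0) + 1

    rows = []
    flagged: list[tuple[str, int, int, str, int]] = []  # chrom,s,e,kind,count
    for chrom, length in genome.lengths.items():
        for ws in range(0, length, t.window_bp):
            we = min(ws + t.window_bp, length)
            n = counts[chrom].get(ws // t.window_bp, 0)
            density = n / ((we - ws) / 1e6)
            rows.append((chrom, ws, we, n, density))
            if density > high:
                flagged.append((chrom, ws, we, "high_density", n))
            elif low is not None and density < low:
                flagged.append((chrom, ws, we, "low_density", n))

    calls: list[RegionCall] = []
    for chrom, ws, we, kind, n in flagged:
        prev = calls[-1] if calls else None
        if (
            prev is not None
            and prev.chrom == chrom
            and prev.kind == kind
            and prev.end == ws  # prev.end is 1-based inclusive == ws half-open
        ):
            new_count = prev.density_per_mb * (prev.length / 1e6) + n
            prev.end = we
            prev.density_per_mb = new_count / ((we - (prev.start - 1)) / 1e6)
        else:
            calls.append(
                RegionCall(
                    chrom=chrom,
                    start=ws + 1,
                    end=we,
                    kind=kind,
                    variant_type=variant_type,
                    density_per_mb=n / ((we - ws) / 1e6),
                )
            )

    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "count", "density_per_mb"]
    )
    per_chrom = (
        windows.groupby("chrom", sort=True)
        .agg(count=("count", "sum"))
        .reset_index()
    )
    per_chrom["length_bp"] = per_chrom["chrom"].map(genome.lengths)
    per_chrom["density_per_mb"] = per_chrom["count"] / (
        per_chrom["length_bp"] / 1e6
    )
    return DensityScanResult(
        variant_type=variant_type,
        windows=windows,
        calls=calls,
        per_chromosome=per_chrom,
    )


def plot_density(scan: DensityScanResult, path: str) -> None:
    """Minimal per-chromosome density line plot, for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = scan.windows["chrom"].unique()
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 2 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = scan.windows[scan.windows["chrom"] == chrom]
        ax.plot(sub["start"] / 1e6, sub["density_per_mb"], drawstyle="steps-post")
        ax.set_ylabel(f"{chrom}\n{scan.variant_type}/Mb")
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# QTL 10-kb window comparison across genotypes


@dataclass
class QTLTopWindow:
    qtl: str
    chrom: str
    start: int  # 0-based half-open window
    end: int
    density_per_mb: float
    genes: list[str] = field(default_factory=list)


@dataclass
class QTLCompareResult:
    matrix: pd.DataFrame  # qtl, chrom, start, end + one density column/genotype
    top_windows: list[QTLTopWindow]


def qtl_window_compare(
    variant_sets: dict[str, list[VariantRecord]],
    qtl_regions: IntervalTrack,
    genome: GenomeSequence,
    focal: str | None = None,
    window_bp: int = 10_000,
    genes: list[GeneModel] | None = None,
) -> QTLCompareResult:
    """Per-genotype variant density in fixed windows tiled across each QTL.

    The focal genotype (first set by default) determines, per QTL, the
    top window reported with its contained/overlapping genes.  A QTL
    shorter than one window yields a single window spanning the QTL.
    """
    if not variant_sets:
        raise ValueError("at least one genotype variant set is required")
    focal = focal or next(iter(variant_sets))
    positions: dict[str, dict[str, list[int]]] = {}
    for name, records in variant_sets.items():
        d: dict[str, list[int]] = {}
        for v in records:
            d.setdefault(v.chrom, []).append(v.pos)
        for ps in d.values():
            ps.sort()
        positions[name] = d

    from bisect import bisect_left, bisect_right

    rows = []
    top: list[QTLTopWindow] = []
    for chrom in sorted(qtl_regions.intervals):
        if chrom not in genome:
            raise ValueError(f"QTL interval on unknown chromosome {chrom!r}")
        clen = len(genome.sequences[chrom])
        for qs, qe, label in qtl_regions.intervals[chrom]:
            if qe > clen:
                raise ValueError(
                    f"QTL {label} ({chrom}:{qs}-{qe}) overruns the chromosome"
                )
            name = str(label) if label is not None else f"{chrom}:{qs}-{qe}"
            best: QTLTopWindow | None = None
            for ws in range(qs, qe, window_bp):
                we = min(ws + window_bp, qe)
                row: dict[str, object] = {
                    "qtl": name,
                    "chrom": chrom,
                    "start": ws,
                    "end": we,
                }
                for gname, by_chrom in positions.items():
                    ps = by_chrom.get(chrom, [])
                    n = bisect_right(ps, we) - bisect_left(ps, ws + 1)
                    row[gname] = n / ((we - ws) / 1e6)
                rows.append(row)
                if best is None or row[focal] > best.density_per_mb:
                    best = QTLTopWindow(
                        qtl=name,
                        chrom=chrom,
                        start=ws,
                        end=we,
                        density_per_mb=float(row[focal]),
                    )
            assert best is not None
            if genes:
                best.genes = [
                    g.transcript_id
                    for g in genes
                    if g.chrom == chrom
                    and g.span[0] <= best.end
                    and g.span[1] >= best.start + 1
                ]
            top.append(best)
    return QTLCompareResult(matrix=pd.DataFrame(rows), top_windows=top)
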