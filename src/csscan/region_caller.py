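"""Cluster-region calling, merging, ranking and gene annotation.

A cluster region is a run of top-1% SNPs (consecutive members no more
than a gap apart) containing at least one top-0.1% SNP and at least
five top-1% SNPs. Regions closer than 1 Mb are merged, extended with
+-0.5 Mb flanks, ranked by peak smoothed CSS and intersected with a
protein-coding gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .css_core import CSSTrack
from .errors import FormatError, NamespaceError
from .genotype_io import MarkerMap

MERGE_BP = 1_000_000
FLANK_BP = 500_000
MIN_TOP1_SUPPORT = 5


@dataclass
class GeneRecord:
    chrom: str
    start_bp: int
    stop_bp: int
    name: str
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.stop_bp:
            raise FormatError(f"gene {self.name}: start > stop")


@dataclass
class ClusterRegion:
    """Called selection-signature interval (1-based, closed bounds)."""

    chrom: str
    start_bp: int
    stop_bp: int
    n_top01: int
    n_top1: int
    peak_css: float
    rank: int | None = None
    flank_start: int | None = None
    flank_stop: int | None = None
    genes_in_peak: list = field(default_factory=list)
    genes_in_flank: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_bp > self.stop_bp:
            raise FormatError("region start > stop")

    @property
    def span_bp(self) -> int:
        return self.stop_bp - self.start_bp + 1

    def overlaps_position(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start_bp <= pos <= self.stop_bp


def call_clusters(
    track: CSSTrack,
    mm: MarkerMap,
    gap_bp: int | None = None,
    min_top1: int = MIN_TOP1_SUPPORT,
    support_includes_significant: bool = True,
    sig_frac: float = 0.001,
    support_frac: float = 0.01,
) -> list[ClusterRegion]:
    """Group top-1% SNPs into qualifying cluster regions.

    Consecutive top-1% SNPs at most ``gap_bp`` apart (default: the
    smoothing window span) form a run; a run becomes a region when it
    holds >= 1 top-0.1% SNP and >= ``min_top1`` top-1% SNPs. With
    ``support_includes_significant`` the top-0.1% members count toward
    the five (they are a subset of the top 1%); the stricter reading
    requires five others.
    """
    if gap_bp is None:
        gap_bp = track.window_bp
    sig = track.flags[sig_frac]
    top1 = track.flags[support_frac]
    regions: list[ClusterRegion] = []
    for chrom, sl in mm.chrom_slices().items():
        idx = np.flatnonzero(top1[sl]) + sl.start
        if len(idx) == 0:
            continue
        pos = mm.pos[idx]
        breaks = np.flatnonzero(np.diff(pos) > gap_bp)
        for run in np.split(idx, breaks + 1):
            n1 = len(run)
            n01 = int(sig[run].sum())
            support = n1 if support_includes_significant else n1 - n01
            if n01 >= 1 and support >= min_top1:
                lo, hi = int(mm.pos[run[0]]), int(mm.pos[run[-1]])
                members = np.arange(sl.start, sl.stop)
                inside = members[(mm.pos[members] >= lo) & (mm.pos[members] <= hi)]
                regions.append(
                    ClusterRegion(
                        chrom=chrom,
                        start_bp=lo,
                        stop_bp=hi,
                        n_top01=int(sig[inside].sum()),
                        n_top1=int(top1[inside].sum()),
                        peak_css=float(track.smoothed_css[inside].max()),
                    )
                )
    return regions


def merge_clusters(
    regions: list[ClusterRegion], merge_bp: int = MERGE_BP
) -> list[ClusterRegion]:
    """Merge same-chromosome regions spaced < ``merge_bp`` apart.

    The gap is ``next.start - prev.stop``; merging is transitive. SNP
    counts are summed and the peak is the maximum.
    """
    ordered = sorted(regions, key=lambda r: (str(r.chrom), r.start_bp))
    out: list[ClusterRegion] = []
    for r in ordered:
        if (
            out
            and out[-1].chrom == r.chrom
            and r.start_bp - out[-1].stop_bp < merge_bp
        ):
            prev = out[-1]
            out[-1] = ClusterRegion(
                chrom=prev.chrom,
                start_bp=prev.start_bp,
                stop_bp=max(prev.stop_bp, r.stop_bp),
                n_top01=prev.n_top01 + r.n_top01,
                n_top1=prev.n_top1 + r.n_top1,
                peak_css=max(prev.peak_css, r.peak_css),
            )
        else:
            out.append(r)
    return out


def attach_flanks(
    regions: list[ClusterRegion], flank_bp: int = FLANK_BP
) -> list[ClusterRegion]:
    """Set flank bounds to +-``flank_bp`` around each region, floored at 1."""
    for r in regions:
        r.flank_start = max(1, r.start_bp - flank_bp)
        r.flank_stop = r.stop_bp + flank_bp
    return regions


def rank_regions(regions: list[ClusterRegion]) -> list[ClusterRegion]:
    """Rank 1 = highest peak CSS; ties broken by (chrom, start)."""
    ordered = sorted(
        regions, key=lambda r: (-r.peak_css, str(r.chrom), r.start_bp)
    )
    for i, r in enumerate(ordered, 1):
        r.rank = i
    return ordered


def _overlap(a_start, a_stop, b_start, b_stop) -> bool:
    return a_start <= b_stop and b_start <= a_stop


def map_genes(
    regions: list[ClusterRegion],
    genes: list[GeneRecord],
    flank_bp: int = FLANK_BP,
) -> list[ClusterRegion]:
    """Attach in-peak and in-flank gene names to each region.

    A gene is in-peak if its interval shares any bp with the region
    (closed intervals), in-flank if it overlaps the flank extension but
    not the peak. Raises when the annotation and the map use disjoint
    chromosome namespaces.
    """
    if regions and genes:
        rc = {str(r.chrom) for r in regions}
        gc = {str(g.chrom) for g in genes}
        if not rc & gc:
            raise NamespaceError(
                f"no shared chromosome labels between regions {sorted(rc)} "
                f"and annotation {sorted(gc)}"
            )
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(str(g.chrom), []).append(g)
    for r in regions:
        if r.flank_start is None:
            r.flank_start = max(1, r.start_bp - flank_bp)
            r.flank_stop = r.stop_bp + flank_bp
        in_peak, in_flank = [], []
        for g in by_chrom.get(str(r.chrom), []):
            if _overlap(g.start_bp, g.stop_bp, r.start_bp, r.stop_bp):
                in_peak.append(g.name)
            elif _overlap(g.start_bp, g.stop_bp, r.flank_start, r.flank_stop):
                in_flank.append(g.name)
        r.genes_in_peak = sorted(in_peak)
        r.genes_in_flank = sorted(in_flank)
    return regions


# ---------------------------------------------------------------------------
# annotation readers and report writer
# ---------------------------------------------------------------------------

def read_genes_bed(path) -> list[GeneRecord]:
    """BED (0-based half-open) gene list -> 1-based closed records."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 else f"gene{ln}"
            genes.append(
                GeneRecord(parts[0], int(parts[1]) + 1, int(parts[2]), name)
            )
    return genes


def read_genes_gff3(
    path, feature: str = "gene", protein_coding_only: bool = True
) -> list[GeneRecord]:
    """Extract gene features from a GFF3 file (1-based closed, as GFF)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: malformed GFF3 line: {line[:60]}")
            if parts[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            biotype = attrs.get("biotype", attrs.get("gene_biotype", ""))
            if protein_coding_only and biotype and biotype != "protein_coding":
                continue
            name = attrs.get("Name", attrs.get("gene_name", attrs.get("ID", "?")))
            genes.append(
                GeneRecord(parts[0], int(parts[3]), int(parts[4]), name, biotype)
            )
    return genes


def write_report(regions: list[ClusterRegion], out_prefix) -> tuple[Path, Path]:
    """Write the region table (TSV) and a BED of peak + flank intervals.

    Internal 1-based closed intervals become 0-based half-open in BED.
    Returns (tsv_path, bed_path).
    """
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    bed_path = out_prefix.with_suffix(".bed")
    rows = []
    for r in regions:
        rows.append(
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "stop_bp": r.stop_bp,
                "n_top01": r.n_top01,
                "n_top1": r.n_top1,
                "peak_css": round(r.peak_css, 6),
                "rank": r.rank if r.rank is not None else "",
                "flank_start": r.flank_start if r.flank_start is not None else "",
                "flank_stop": r.flank_stop if r.flank_stop is not None else "",
                "genes_in_peak": ",".join(r.genes_in_peak),
                "genes_in_flank": ",".join(r.genes_in_flank),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "stop_bp", "n_top01", "n_top1", "peak_css",
            "rank", "flank_start", "flank_stop", "genes_in_peak",
            "genes_in_flank",
        ],
    ).to_csv(tsv_path, sep="\t", index=False)
    with open(bed_path, "w") as fh:
        for r in regions:
            tag = f"region{r.rank}" if r.rank is not None else "region"
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.stop_bp}\t{tag}_peak\n")
            if r.flank_start is not None:
                fh.write(
                    f"{r.chrom}\t{r.flank_start - 1}\t{r.flank_stop}\t{tag}_flank\n"
                )
    return tsv_path, bed_path
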