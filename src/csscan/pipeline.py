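"""End-to-end scan orchestration: ingest -> QC -> components -> CSS ->
smoothing -> thresholds -> regions -> genes, with deterministic file
outputs and a stage-tagged error model."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .component_stats import ComponentScores, compute_components
from .css_core import CSSTrack, build_track, TOP_FRACS
from .errors import CsscanError, MarkerLookupError, SampleLookupError, StageError
from .genotype_io import (
    CohortContrast,
    HaplotypeSet,
    MarkerMap,
    QCReport,
    allele_frequencies,
    qc_filter,
    read_contrast,
    read_plink,
    read_vcf,
    split_cohorts,
)
from .region_caller import (
    ClusterRegion,
    attach_flanks,
    call_clusters,
    map_genes,
    merge_clusters,
    rank_regions,
    read_genes_bed,
    read_genes_gff3,
    write_report,
)


@dataclass
class ScanConfig:
    """Flat configuration for one contrast scan."""

    genotypes: str
    contrast: str
    out_dir: str
    genes: str | None = None
    autosomes: list | None = None
    window_bp: int = 100_000
    top_fracs: tuple = TOP_FRACS
    merge_bp: int = 1_000_000
    flank_bp: int = 500_000
    cluster_gap_bp: int | None = None
    min_top1_support: int = 5
    max_missing: float = 0.05
    min_maf: float = 0.01
    ehh_truncation: float = 0.05
    ehh_max_gap: int = 200_000
    make_plot: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        from .errors import ConfigError

        if self.window_bp <= 0 or self.merge_bp <= 0 or self.flank_bp <= 0:
            raise ConfigError("distances must be positive")
        for f in self.top_fracs:
            if not (0.0 < f < 1.0):
                raise ConfigError("top fractions must lie in (0, 1)")


@dataclass
class ScanResult:
    hs: HaplotypeSet
    mm: MarkerMap
    qc: QCReport
    scores: ComponentScores
    track: CSSTrack
    regions: list
    paths: dict = field(default_factory=dict)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except CsscanError as e:
            raise StageError(name, e) from e
        except (OSError, ValueError, IndexError) as e:
            raise StageError(name, e) from e

    return wrap


def scan_in_memory(
    hs: HaplotypeSet,
    mm: MarkerMap,
    contrast: CohortContrast,
    config: ScanConfig | None = None,
    **kwargs,
) -> tuple[CSSTrack, list, ComponentScores]:
    """Run components -> CSS -> regions on an in-memory panel.

    Convenience entry point for simulations and tests; file-free.
    """
    if config is None:
        config = ScanConfig(genotypes="", contrast="", out_dir="", **kwargs)
    sel, ref = split_cohorts(hs, contrast)
    scores = compute_components(
        sel, ref, mm, config.ehh_truncation, config.ehh_max_gap
    )
    track = build_track(scores, mm, config.window_bp, config.top_fracs)
    regions = call_clusters(
        track,
        mm,
        gap_bp=config.cluster_gap_bp,
        min_top1=config.min_top1_support,
    )
    regions = merge_clusters(regions, config.merge_bp)
    regions = attach_flanks(regions, config.flank_bp)
    regions = rank_regions(regions)
    for r in regions:
        assert r.start_bp <= r.stop_bp and r.n_top01 >= 1
    return track, regions, scores


def run_scan(config: ScanConfig) -> ScanResult:
    """Full file-to-file pipeline for one contrast.

    Writes, under ``config.out_dir``: qc_report.tsv, components.tsv,
    scan.tsv, regions.tsv, regions.bed, scan.log and (optionally) a
    Manhattan-style plot. Deterministic for fixed inputs and seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"csscan {__version__}",
        f"config: {config}",
    ]

    geno = Path(config.genotypes)
    if geno.suffix in (".vcf", ".gz") or geno.name.endswith(".vcf.gz"):
        hs, mm = _stage("ingest")(read_vcf, geno, config.autosomes)
    else:
        hs, mm = _stage("ingest")(read_plink, geno)
    log_lines.append(f"ingest: {hs.n_samples} samples, {len(mm)} markers")

    hs, mm, qc = _stage("qc")(
        qc_filter, hs, mm, config.max_missing, config.min_maf
    )
    log_lines.append(
        f"qc: retained {qc.n_retained}/{qc.n_input} markers "
        f"(missing>{config.max_missing}: {qc.n_removed_missing}, "
        f"maf<{config.min_maf}: {qc.n_removed_maf})"
    )
    qc.to_tsv(out_dir / "qc_report.tsv")

    contrast = _stage("contrast")(read_contrast, config.contrast)
    sel, ref = _stage("contrast")(split_cohorts, hs, contrast)
    log_lines.append(
        f"contrast '{contrast.label}': {sel.n_samples} selected vs "
        f"{ref.n_samples} reference"
    )

    scores = _stage("components")(
        compute_components, sel, ref, mm, config.ehh_truncation, config.ehh_max_gap
    )
    scores.to_tsv(mm, out_dir / "components.tsv")

    track = _stage("css")(build_track, scores, mm, config.window_bp, config.top_fracs)
    for frac in sorted(config.top_fracs):
        log_lines.append(
            f"threshold top-{frac * 100:g}%: {track.thresholds[frac]:.6f} "
            f"({int(track.flags[frac].sum())} SNPs)"
        )
    track.to_tsv(mm, out_dir / "scan.tsv")
    assert len(track.raw_css) == len(mm)

    regions = _stage("regions")(
        call_clusters, track, mm, config.cluster_gap_bp, config.min_top1_support
    )
    regions = merge_clusters(regions, config.merge_bp)
    regions = attach_flanks(regions, config.flank_bp)
    regions = rank_regions(regions)
    log_lines.append(f"regions: {len(regions)} called")

    if config.genes is not None:
        gp = Path(config.genes)
        if not gp.exists():
            raise StageError("genes", FileNotFoundError(str(gp)))
        reader = read_genes_gff3 if gp.suffix in (".gff", ".gff3") else read_genes_bed
        genes = _stage("genes")(reader, gp)
        regions = _stage("genes")(map_genes, regions, genes, config.flank_bp)
        log_lines.append(f"genes: {len(genes)} annotation records")

    tsv_path, bed_path = write_report(regions, out_dir / "regions")
    paths = {
        "qc": out_dir / "qc_report.tsv",
        "components": out_dir / "components.tsv",
        "scan": out_dir / "scan.tsv",
        "regions": tsv_path,
        "bed": bed_path,
        "log": out_dir / "scan.log",
    }
    if config.make_plot:
        paths["plot"] = out_dir / "manhattan.png"
        _stage("plot")(plot_track, track, mm, paths["plot"])
    (out_dir / "scan.log").write_text("\n".join(log_lines) + "\n")
    return ScanResult(hs, mm, qc, scores, track, regions, paths)


def summarize_genotype_frequencies(
    hs: HaplotypeSet,
    mm: MarkerMap,
    snp_id: str,
    grouping: dict,
) -> pd.DataFrame:
    """Per-group genotype-class frequencies at one SNP.

    ``grouping`` maps sample id -> group label. Classes are labelled
    with allele letters (ref-ref, ref-alt, alt-alt); frequencies sum to
    1 per group over called genotypes.
    """
    j = mm.index_of(snp_id)
    ref, alt = str(mm.ref_allele[j]), str(mm.alt_allele[j])
    labels = [ref + ref, ref + alt, alt + alt]
    geno = hs.genotypes()[:, j]
    sample_index = {s: i for i, s in enumerate(hs.sample_ids)}
    rows = []
    groups: dict = {}
    for s, g in grouping.items():
        if s not in sample_index:
            raise SampleLookupError(f"unknown sample id {s!r}")
        groups.setdefault(g, []).append(sample_index[s])
    for g in sorted(groups, key=str):
        gvals = geno[groups[g]]
        called = gvals[gvals >= 0]
        n = len(called)
        counts = [(called == k).sum() for k in (0, 1, 2)]
        row = {"group": g, "n": n}
        for lab, c in zip(labels, counts):
            row[lab] = c / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def plot_track(track: CSSTrack, mm: MarkerMap, path) -> None:
    """Two-panel Manhattan-style plot (raw + smoothed) with the top-0.1%
    threshold drawn as a dashed line on the smoothed panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    offset = 0
    ticks, labels = [], []
    for chrom, sl in mm.chrom_slices().items():
        x = mm.pos[sl] + offset
        axes[0].scatter(x, track.raw_css[sl], s=2)
        axes[1].scatter(x, track.smoothed_css[sl], s=2)
        ticks.append(offset + (mm.pos[sl][0] + mm.pos[sl][-1]) / 2)
        labels.append(str(chrom))
        offset += int(mm.pos[sl][-1]) + 1
    frac = min(track.thresholds) if track.thresholds else None
    if frac is not None:
        axes[1].axhline(track.thresholds[frac], ls="--", color="red", lw=1)
    axes[0].set_ylabel("CSS (raw)")
    axes[1].set_ylabel("CSS (smoothed)")
    axes[1].set_xticks(ticks, labels)
    axes[1].set_xlabel("chromosome")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
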