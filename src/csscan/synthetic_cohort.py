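"""Two-cohort haplotype simulator with an implantable selective sweep.

Neutral background: ancestral allele frequencies are drawn uniformly
and per-cohort frequencies follow the Balding–Nichols Beta model with a
configurable differentiation parameter; haplotype alleles are sampled
independently per site. The sweep implant overwrites a configured
fraction of haplotypes in each cohort with a shared founder haplotype
over a window around the sweep site, truncated per haplotype by an
exponential "escape" distance, giving joint frequency-shift,
differentiation and haplotype-length signals.

Everything is driven by one seeded generator, so panels regenerate
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .genotype_io import CohortContrast, HaplotypeSet, MarkerMap, write_vcf


@dataclass(frozen=True)
class SimConfig:
    n_sel: int = 20
    n_ref: int = 80
    n_snps: int = 2500          # per chromosome
    n_chrom: int = 2
    mean_spacing_bp: int = 10_000
    background_fst: float = 0.05
    sweep: bool = True
    sweep_chrom: str = "1"
    sweep_pos: int | None = None  # None = middle of the sweep chromosome
    carrier_frac_sel: float = 0.8
    carrier_frac_ref: float = 0.1
    sweep_halfwidth_bp: int = 150_000
    escape_rate: float = 5e-6   # per-bp hazard of recombining off the founder
    mut_noise: float = 0.01     # per-site flip probability on copied segments
    core_start_freq: float | None = 0.02  # pre-sweep frequency of the swept allele
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sel, self.n_ref, self.n_snps, self.n_chrom) < 1:
            raise ConfigError("cohort/panel sizes must be positive")
        if not (0.0 <= self.background_fst < 1.0):
            raise ConfigError("background_fst must lie in [0, 1)")
        for f in (self.carrier_frac_sel, self.carrier_frac_ref, self.mut_noise):
            if not (0.0 <= f <= 1.0):
                raise ConfigError("fractions must lie in [0, 1]")
        # equal fractions are allowed (null implant); an inverted contrast
        # would put the signal in the wrong cohort
        if self.sweep and self.carrier_frac_sel < self.carrier_frac_ref:
            raise ConfigError(
                "carrier_frac_sel must be >= carrier_frac_ref"
            )
        if self.escape_rate < 0 or self.mean_spacing_bp <= 0:
            raise ConfigError("rates and spacings must be non-negative")


@dataclass
class SweepTruth:
    """Where the sweep was implanted (realized core marker)."""

    sweep_chrom: str
    sweep_pos: int          # position of the core marker actually used
    core_index: int
    carrier_frac_sel: float
    carrier_frac_ref: float
    config: SimConfig

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"sweep_chrom\t{self.sweep_chrom}\n")
            fh.write(f"sweep_pos\t{self.sweep_pos}\n")
            fh.write(f"core_index\t{self.core_index}\n")
            fh.write(f"carrier_frac_sel\t{self.carrier_frac_sel}\n")
            fh.write(f"carrier_frac_ref\t{self.carrier_frac_ref}\n")
            for k, v in asdict(self.config).items():
                fh.write(f"config.{k}\t{v}\n")


def sample_neutral_freqs(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (ancestral, selected, reference) per-SNP ALT frequencies.

    Ancestral p ~ Uniform(0.05, 0.95); each cohort frequency ~
    Beta(p(1-F)/F, (1-p)(1-F)/F) independently with F the background
    differentiation; F = 0 degenerates to both cohorts sharing p.
    """
    n = config.n_chrom * config.n_snps
    anc = rng.uniform(0.05, 0.95, size=n)
    F = config.background_fst
    if F == 0.0:
        return anc, anc.copy(), anc.copy()
    scale = (1.0 - F) / F
    p_sel = rng.beta(anc * scale, (1.0 - anc) * scale)
    p_ref = rng.beta(anc * scale, (1.0 - anc) * scale)
    return anc, p_sel, p_ref


def simulate_neutral_haplotypes(
    p_sel: np.ndarray,
    p_ref: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[HaplotypeSet, MarkerMap]:
    """Independent-site haplotypes at the given cohort frequencies.

    Marker positions are cumulative exponential spacings (>= 1 bp each)
    with the configured mean; sample order is selected then reference.
    """
    n = config.n_chrom * config.n_snps
    if len(p_sel) != n or len(p_ref) != n:
        raise ConfigError("frequency vectors must have n_chrom * n_snps entries")
    chroms, poss, ids = [], [], []
    for c in range(1, config.n_chrom + 1):
        gaps = np.maximum(
            1, np.round(rng.exponential(config.mean_spacing_bp, config.n_snps))
        ).astype(np.int64)
        pos = np.cumsum(gaps)
        chroms.extend([str(c)] * config.n_snps)
        poss.extend(pos.tolist())
        ids.extend(f"chr{c}.{p}" for p in pos)
    mm = MarkerMap(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(ids, dtype=object),
        np.array(["A"] * n, dtype=object),
        np.array(["G"] * n, dtype=object),
    )
    hap_sel = (rng.random((2 * config.n_sel, n)) < p_sel).astype(np.int8)
    hap_ref = (rng.random((2 * config.n_ref, n)) < p_ref).astype(np.int8)
    alleles = np.concatenate([hap_sel, hap_ref], axis=0)
    ids_s = [f"SEL{i + 1:03d}" for i in range(config.n_sel)]
    ids_r = [f"REF{i + 1:03d}" for i in range(config.n_ref)]
    return HaplotypeSet(alleles, ids_s + ids_r, phased=True), mm


def _sweep_window(mm: MarkerMap, config: SimConfig) -> tuple[np.ndarray, int]:
    """Marker indices within the sweep window and the core marker index."""
    on_chrom = np.flatnonzero(mm.chrom == config.sweep_chrom)
    if len(on_chrom) == 0:
        raise ConfigError(f"no markers on chromosome {config.sweep_chrom!r}")
    sweep_pos = config.sweep_pos
    if sweep_pos is None:
        sweep_pos = int(mm.pos[on_chrom[len(on_chrom) // 2]])
    window = on_chrom[
        np.abs(mm.pos[on_chrom] - sweep_pos) <= config.sweep_halfwidth_bp
    ]
    if len(window) == 0:
        raise ConfigError(
            f"no markers within {config.sweep_halfwidth_bp} bp of "
            f"{config.sweep_chrom}:{sweep_pos}"
        )
    return window, int(window[np.argmin(np.abs(mm.pos[window] - sweep_pos))])


def implant_sweep(
    hs: HaplotypeSet,
    mm: MarkerMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[HaplotypeSet, SweepTruth]:
    """Overwrite carrier haplotypes with a founder around the sweep site.

    Within +-sweep_halfwidth_bp of the configured position a founder
    haplotype is drawn (ALT at the core). In each cohort a
    carrier-fraction of haplotypes copies the founder outward from the
    core until an exponential escape distance (mean 1/escape_rate bp)
    truncates the copy; per-site flips at ``mut_noise`` then perturb the
    copied segment, except the core, which all carriers keep.
    """
    window, core = _sweep_window(mm, config)
    core_pos = int(mm.pos[core])

    alleles = hs.alleles.copy()
    # founder: copy of one random existing haplotype over the window, ALT core
    founder = alleles[rng.integers(0, hs.n_haplotypes), window].copy()
    founder[window == core] = 1

    n_sel_hap = 2 * config.n_sel
    offsets = (mm.pos[window] - core_pos).astype(float)
    cohorts = (
        (np.arange(0, n_sel_hap), config.carrier_frac_sel),
        (np.arange(n_sel_hap, hs.n_haplotypes), config.carrier_frac_ref),
    )
    for rows, frac in cohorts:
        carriers = rows[rng.random(len(rows)) < frac]
        for h in carriers:
            if config.escape_rate > 0:
                reach_l = rng.exponential(1.0 / config.escape_rate)
                reach_r = rng.exponential(1.0 / config.escape_rate)
            else:
                reach_l = reach_r = np.inf
            copied = (offsets >= -reach_l) & (offsets <= reach_r)
            seg = founder[copied].copy()
            if config.mut_noise > 0:
                flips = rng.random(len(seg)) < config.mut_noise
                seg[flips] = 1 - seg[flips]
            alleles[h, window[copied]] = seg
            alleles[h, core] = 1
    truth = SweepTruth(
        sweep_chrom=config.sweep_chrom,
        sweep_pos=core_pos,
        core_index=int(core),
        carrier_frac_sel=config.carrier_frac_sel,
        carrier_frac_ref=config.carrier_frac_ref,
        config=config,
    )
    return HaplotypeSet(alleles, hs.sample_ids, hs.phased), truth


def simulate_cohort(
    config: SimConfig,
) -> tuple[HaplotypeSet, MarkerMap, CohortContrast, SweepTruth | None]:
    """End-to-end panel generation from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    _, p_sel, p_ref = sample_neutral_freqs(config, rng)
    hs, mm = simulate_neutral_haplotypes(p_sel, p_ref, config, rng)
    truth = None
    if config.sweep:
        if config.core_start_freq is not None:
            # swept alleles start rare: resample the core column at a low
            # shared frequency before the implant raises it in carriers
            _, core = _sweep_window(mm, config)
            hs.alleles[:, core] = (
                rng.random(hs.n_haplotypes) < config.core_start_freq
            ).astype(np.int8)
        hs, truth = implant_sweep(hs, mm, config, rng)
    contrast = CohortContrast(
        [s for s in hs.sample_ids if s.startswith("SEL")],
        [s for s in hs.sample_ids if s.startswith("REF")],
        label="simulated",
    )
    return hs, mm, contrast, truth


def write_fixture(config: SimConfig, out_dir) -> dict:
    """Simulate and write VCF + contrast + truth files; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hs, mm, contrast, truth = simulate_cohort(config)
    vcf = out_dir / "panel.vcf"
    write_vcf(hs, mm, vcf)
    contrast_path = out_dir / "contrast.tsv"
    with open(contrast_path, "w") as fh:
        for s in contrast.selected_ids:
            fh.write(f"{s}\tselected\n")
        for s in contrast.reference_ids:
            fh.write(f"{s}\treference\n")
    paths = {"vcf": vcf, "contrast": contrast_path}
    if truth is not None:
        truth_path = out_dir / "truth.tsv"
        truth.to_tsv(truth_path)
        paths["truth"] = truth_path
    return paths
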