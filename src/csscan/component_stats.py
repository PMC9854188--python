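"""Per-SNP constituent selection statistics: FST, deltaSAF, XP-EHH.

All three are computed for a selected-vs-reference contrast on complete,
phased haplotype matrices. Undefined values (monomorphic FST, zero iHH)
are encoded as NaN — "unavailable" — rather than raised; the composite
combiner downstream copes with a reduced test count per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateDistributionError
from .genotype_io import HaplotypeSet, MarkerMap

_RELABEL_EVERY = 60  # int64 labels hold ~62 doubling steps before overflow


@dataclass
class EHHProfile:
    """Extended haplotype homozygosity decay around a core marker.

    ``distances`` are signed bp offsets from the core (negative =
    upstream), sorted ascending and always containing 0 with EHH 1
    (pooled-core convention: the zero-length extension puts every
    haplotype in one class). Only values >= the truncation floor are
    recorded; extension stops at the first value below it, which is
    discarded.
    """

    core_index: int
    distances: np.ndarray
    ehh_values: np.ndarray
    truncation: float = 0.05

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.int64)
        self.ehh_values = np.asarray(self.ehh_values, dtype=float)
        if len(self.distances) != len(self.ehh_values):
            raise ContractError("distances/ehh_values length mismatch")

    @property
    def ihh(self) -> float:
        return ihh(self)


@dataclass
class ComponentScores:
    """Per-SNP component statistics; NaN marks an unavailable test."""

    fst: np.ndarray
    dsaf: np.ndarray
    xpehh: np.ndarray

    def __post_init__(self) -> None:
        self.fst = np.asarray(self.fst, dtype=float)
        self.dsaf = np.asarray(self.dsaf, dtype=float)
        self.xpehh = np.asarray(self.xpehh, dtype=float)
        n = len(self.fst)
        if len(self.dsaf) != n or len(self.xpehh) != n:
            raise ContractError("component vectors have unequal lengths")

    @property
    def available(self) -> np.ndarray:
        """Boolean (n_snps, 3) availability flags, columns (fst, dsaf, xpehh)."""
        return ~np.isnan(np.stack([self.fst, self.dsaf, self.xpehh], axis=1))

    def to_dataframe(self, mm: MarkerMap) -> pd.DataFrame:
        av = self.available
        return pd.DataFrame(
            {
                "chrom": mm.chrom,
                "pos": mm.pos,
                "snp_id": mm.snp_id,
                "fst": self.fst,
                "dsaf": self.dsaf,
                "xpehh": self.xpehh,
                "fst_available": av[:, 0].astype(int),
                "dsaf_available": av[:, 1].astype(int),
                "xpehh_available": av[:, 2].astype(int),
            }
        )

    def to_tsv(self, mm: MarkerMap, path) -> None:
        self.to_dataframe(mm).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _require_comparable(sel: HaplotypeSet, ref: HaplotypeSet) -> None:
    if sel.n_markers != ref.n_markers:
        raise ContractError(
            f"marker dimension mismatch: {sel.n_markers} vs {ref.n_markers}"
        )


def _require_complete(hs: HaplotypeSet, what: str) -> None:
    if hs.has_missing:
        raise ContractError(f"{what} requires complete data (no missing calls)")


def fst_per_snp(sel: HaplotypeSet, ref: HaplotypeSet) -> np.ndarray:
    """Weir–Cockerham two-population theta from haplotype allele counts.

    Haploid formulation: with haplotype counts n1, n2 and ALT
    frequencies p1, p2,

        MSP = n1 (p1 - pbar)^2 + n2 (p2 - pbar)^2
        MSG = [n1 p1 (1 - p1) + n2 p2 (1 - p2)] / (n1 + n2 - 2)
        nc  = (N - (n1^2 + n2^2) / N)                (N = n1 + n2)
        theta = (MSP - MSG) / (MSP + (nc - 1) MSG)

    Negative estimates are retained. SNPs monomorphic for the same
    allele in both cohorts are undefined (NaN).
    """
    _require_comparable(sel, ref)
    _require_complete(sel, "fst"), _require_complete(ref, "fst")
    n1, n2 = sel.n_haplotypes, ref.n_haplotypes
    if n1 < 4 or n2 < 4:
        raise ContractError("each cohort needs >= 2 diploid samples")
    p1 = sel.alleles.mean(axis=0)
    p2 = ref.alleles.mean(axis=0)
    N = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / N
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (N - 2)
    nc = N - (n1 * n1 + n2 * n2) / N
    denom = msp + (nc - 1) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, (msp - msg) / np.where(denom > 0, denom, 1), np.nan)
    return theta


def delta_saf(sel: HaplotypeSet, ref: HaplotypeSet) -> np.ndarray:
    """Signed ALT-frequency change, selected minus reference."""
    _require_comparable(sel, ref)
    _require_complete(sel, "dsaf"), _require_complete(ref, "dsaf")
    return sel.alleles.mean(axis=0) - ref.alleles.mean(axis=0)


def _pair_fraction(labels: np.ndarray, n: int) -> float:
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1)).sum()) / (n * (n - 1))


def _extend(
    alleles: np.ndarray,
    pos: np.ndarray,
    core: int,
    step: int,
    truncation: float,
    max_gap: int,
) -> tuple[list[int], list[float]]:
    """Walk outward from the core in one direction, recording EHH.

    The extended haplotype class includes the core allele. Stops at the
    chromosome end, at an inter-marker gap > ``max_gap``, or at the
    first EHH value below ``truncation`` (that value is dropped).
    """
    n = alleles.shape[0]
    labels = alleles[:, core].astype(np.int64)
    dists: list[int] = []
    ehhs: list[float] = []
    j = core
    depth = 0
    while True:
        nxt = j + step
        if nxt < 0 or nxt >= alleles.shape[1]:
            break
        if abs(int(pos[nxt]) - int(pos[j])) > max_gap:
            break
        labels = labels * 2 + alleles[:, nxt]
        depth += 1
        if depth % _RELABEL_EVERY == 0:
            labels = np.unique(labels, return_inverse=True)[1].astype(np.int64)
        e = _pair_fraction(labels, n)
        if e < truncation:
            break
        dists.append(int(pos[nxt]) - int(pos[core]))
        ehhs.append(e)
        j = nxt
    return dists, ehhs


def ehh(
    hs: HaplotypeSet,
    mm: MarkerMap,
    core_index: int,
    truncation: float = 0.05,
    max_gap: int = 200_000,
) -> EHHProfile:
    """EHH decay profile around ``core_index``, both directions.

    EHH(d) = sum_h C(n_h, 2) / C(n, 2) over distinct haplotypes spanning
    the core to offset d; EHH(0) = 1 by the pooled-core convention.
    Extension never crosses a chromosome boundary.
    """
    if core_index < 0 or core_index >= len(mm):
        raise IndexError(f"core_index {core_index} out of range")
    _require_complete(hs, "ehh")
    if hs.n_haplotypes < 2:
        raise ContractError("ehh needs >= 2 haplotypes")
    sl = None
    for s in mm.chrom_slices().values():
        if s.start <= core_index < s.stop:
            sl = s
            break
    alleles = hs.alleles[:, sl]
    pos = mm.pos[sl]
    core = core_index - sl.start
    ld, le = _extend(alleles, pos, core, -1, truncation, max_gap)
    rd, re_ = _extend(alleles, pos, core, +1, truncation, max_gap)
    dists = np.array(ld[::-1] + [0] + rd, dtype=np.int64)
    vals = np.array(le[::-1] + [1.0] + re_, dtype=float)
    return EHHProfile(core_index, dists, vals, truncation)


def ihh(profile: EHHProfile) -> float:
    """Trapezoidal integral of EHH over bp, both directions summed."""
    d, e = profile.distances, profile.ehh_values
    left = d <= 0
    right = d >= 0
    area = 0.0
    if left.sum() > 1:
        area += float(np.trapezoid(e[left][::-1], -d[left][::-1]))
    if right.sum() > 1:
        area += float(np.trapezoid(e[right], d[right]))
    return area


def xpehh_raw(
    sel: HaplotypeSet,
    ref: HaplotypeSet,
    mm: MarkerMap,
    core_index: int,
    truncation: float = 0.05,
    max_gap: int = 200_000,
) -> float:
    """ln(iHH_selected / iHH_reference) at one core; NaN if either is 0."""
    _require_comparable(sel, ref)
    ihh_s = ihh(ehh(sel, mm, core_index, truncation, max_gap))
    ihh_r = ihh(ehh(ref, mm, core_index, truncation, max_gap))
    if ihh_s <= 0.0 or ihh_r <= 0.0:
        return float("nan")
    # difference of logs keeps xpehh(sel, ref) == -xpehh(ref, sel) exact
    return float(np.log(ihh_s) - np.log(ihh_r))


def xpehh_scan(
    sel: HaplotypeSet,
    ref: HaplotypeSet,
    mm: MarkerMap,
    truncation: float = 0.05,
    max_gap: int = 200_000,
) -> np.ndarray:
    """Unstandardized XP-EHH at every marker."""
    _require_comparable(sel, ref)
    _require_complete(sel, "xpehh"), _require_complete(ref, "xpehh")
    out = np.empty(len(mm))
    for sl in mm.chrom_slices().values():
        a_s = sel.alleles[:, sl]
        a_r = ref.alleles[:, sl]
        pos = mm.pos[sl]
        for core in range(sl.stop - sl.start):
            out[sl.start + core] = _xpehh_one(
                a_s, a_r, pos, core, truncation, max_gap
            )
    return out


def _ihh_one(alleles, pos, core, truncation, max_gap) -> float:
    area = 0.0
    for step in (-1, +1):
        d, e = _extend(alleles, pos, core, step, truncation, max_gap)
        if d:
            area += float(
                np.trapezoid([1.0] + e, [0] + [abs(x) for x in d])
            )
    return area


def _xpehh_one(a_s, a_r, pos, core, truncation, max_gap) -> float:
    ihh_s = _ihh_one(a_s, pos, core, truncation, max_gap)
    ihh_r = _ihh_one(a_r, pos, core, truncation, max_gap)
    if ihh_s <= 0.0 or ihh_r <= 0.0:
        return float("nan")
    return float(np.log(ihh_s) - np.log(ihh_r))


def xpehh_standardize(raw: np.ndarray) -> np.ndarray:
    """Genome-wide zero-mean unit-sd normalization over available entries."""
    raw = np.asarray(raw, dtype=float)
    avail = ~np.isnan(raw)
    if avail.sum() < 2:
        raise ContractError("need >= 2 available raw XP-EHH values")
    mu = raw[avail].mean()
    sd = raw[avail].std(ddof=0)
    if sd == 0.0:
        raise DegenerateDistributionError("raw XP-EHH has zero variance")
    out = np.full_like(raw, np.nan)
    out[avail] = (raw[avail] - mu) / sd
    return out


def compute_components(
    sel: HaplotypeSet,
    ref: HaplotypeSet,
    mm: MarkerMap,
    truncation: float = 0.05,
    max_gap: int = 200_000,
    with_xpehh: bool = True,
) -> ComponentScores:
    """All three component statistics for a contrast.

    XP-EHH is skipped (all-NaN) when either panel is not phased or
    ``with_xpehh`` is false.
    """
    fst = fst_per_snp(sel, ref)
    dsaf = delta_saf(sel, ref)
    if with_xpehh and sel.phased and ref.phased:
        raw = xpehh_scan(sel, ref, mm, truncation, max_gap)
        xpe = xpehh_standardize(raw)
    else:
        xpe = np.full(len(mm), np.nan)
    return ComponentScores(fst, dsaf, xpe)
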