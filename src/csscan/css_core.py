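"""Composite selection signal: rank combination, smoothing, thresholds.

The combiner turns each component statistic into fractional ranks
(larger value = more evidence of selection in the target cohort), maps
them through the inverse normal CDF, averages the scores per SNP and
converts the mean — distributed N(0, 1/m) under the null — into a
one-sided p-value reported as -log10 p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ThresholdError
from .component_stats import ComponentScores
from .genotype_io import MarkerMap, chrom_sort_key

TOP_FRACS = (0.001, 0.01)


def fractional_rank(values: np.ndarray) -> np.ndarray:
    """Fractional ranks r = rank / (n_available + 1) in (0, 1).

    Values are ranked ascending; ties get the mean of their tied integer
    ranks; NaN entries stay NaN and do not count toward n.
    """
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    avail = ~np.isnan(values)
    n = int(avail.sum())
    if n < 2:
        raise ContractError("fractional_rank needs >= 2 available values")
    out[avail] = stats.rankdata(values[avail], method="average") / (n + 1)
    return out


def css_from_ranks(ranks: np.ndarray) -> np.ndarray:
    """Combine a (n_snps, m) fractional-rank matrix into raw CSS.

    z_ij = Phi^-1(r_ij); zbar_i = mean over available j; under the null
    zbar_i ~ N(0, 1/m_i); p_i = 1 - Phi(zbar_i * sqrt(m_i));
    raw_css_i = -log10 p_i. Computed via the normal log-survival
    function so extreme scores do not underflow.
    """
    ranks = np.atleast_2d(np.asarray(ranks, dtype=float))
    avail = ~np.isnan(ranks)
    vals = ranks[avail]
    if ((vals <= 0) | (vals >= 1)).any():
        raise ContractError("fractional ranks must lie strictly in (0, 1)")
    m = avail.sum(axis=1)
    if (m < 1).any():
        raise ContractError("every SNP needs >= 1 available component")
    z = np.where(avail, stats.norm.ppf(np.where(avail, ranks, 0.5)), 0.0)
    zbar = z.sum(axis=1) / m
    return -stats.norm.logsf(zbar * np.sqrt(m)) / math.log(10)


def css_combine(scores: ComponentScores) -> np.ndarray:
    """Raw CSS per SNP from component statistics.

    Each component is converted to fractional ranks in the direction
    where larger means more evidence of selection in the target cohort
    (FST as-is; dsaf and XP-EHH already signed toward the target).
    """
    cols = []
    for vec in (scores.fst, scores.dsaf, scores.xpehh):
        if (~np.isnan(vec)).sum() >= 2:
            cols.append(fractional_rank(vec))
        else:
            cols.append(np.full(len(vec), np.nan))
    ranks = np.stack(cols, axis=1)
    if (~np.isnan(ranks)).sum(axis=1).min() < 1:
        raise ContractError("some SNP has no available component")
    return css_from_ranks(ranks)


def smooth_track(raw: np.ndarray, mm: MarkerMap, window_bp: int) -> np.ndarray:
    """Centered sliding-window mean of ``raw`` over physical position.

    Each SNP's smoothed value is the mean raw value of all SNPs on the
    same chromosome within +-window_bp/2 of its position (self
    inclusive); windows never cross chromosome boundaries.
    """
    if window_bp <= 0:
        raise ContractError("window_bp must be positive")
    raw = np.asarray(raw, dtype=float)
    if len(raw) != len(mm):
        raise ContractError("raw track length != marker count")
    half = window_bp / 2.0
    out = np.empty_like(raw)
    for sl in mm.chrom_slices().values():
        pos = mm.pos[sl].astype(float)
        vals = raw[sl]
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        out[sl] = (cum[hi] - cum[lo]) / (hi - lo)
    return out


@dataclass
class ThresholdResult:
    """Empirical genome-wide quantile thresholds and per-SNP flags."""

    thresholds: dict
    flags: dict

    def n_flagged(self, frac: float) -> int:
        return int(self.flags[frac].sum())


def empirical_thresholds(
    smoothed: np.ndarray,
    mm: MarkerMap,
    top_fracs: tuple = TOP_FRACS,
) -> ThresholdResult:
    """Flag the top ``frac`` of SNPs genome-wide for each fraction.

    Exactly ceil(frac * n) SNPs are flagged per fraction; ties at the
    boundary are broken deterministically by (value desc, chrom, pos).
    A constant track raises (no meaningful empirical quantile exists).
    """
    smoothed = np.asarray(smoothed, dtype=float)
    n = len(smoothed)
    if len(mm) != n:
        raise ContractError("track length != marker count")
    if n < 1 / min(top_fracs):
        raise ThresholdError(
            f"{n} SNPs too few for a top-{min(top_fracs)} threshold"
        )
    if np.all(smoothed == smoothed[0]):
        raise ThresholdError("constant track: empirical thresholds undefined")
    # map index order is already (chrom, pos) order, so it is the tie-break
    order = np.lexsort((np.arange(n), -smoothed))
    thresholds, flags = {}, {}
    for frac in sorted(top_fracs):
        k = math.ceil(frac * n)
        flag = np.zeros(n, dtype=bool)
        flag[order[:k]] = True
        thresholds[frac] = float(smoothed[order[k - 1]])
        flags[frac] = flag
    return ThresholdResult(thresholds, flags)


@dataclass
class CSSTrack:
    """Per-SNP raw and smoothed CSS with empirical significance flags."""

    raw_css: np.ndarray
    smoothed_css: np.ndarray
    window_bp: int
    thresholds: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw_css = np.asarray(self.raw_css, dtype=float)
        self.smoothed_css = np.asarray(self.smoothed_css, dtype=float)
        if len(self.raw_css) != len(self.smoothed_css):
            raise ContractError("raw/smoothed length mismatch")

    @property
    def n_snps(self) -> int:
        return len(self.raw_css)

    def top_flags(self, frac: float) -> np.ndarray:
        return self.flags[frac]

    def to_dataframe(self, mm: MarkerMap) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": mm.chrom,
                "pos": mm.pos,
                "snp_id": mm.snp_id,
                "raw_css": self.raw_css,
                "smoothed_css": self.smoothed_css,
            }
        )
        for frac in sorted(self.flags, reverse=True):
            pct = f"{frac * 100:g}"
            df[f"top{pct}pct"] = self.flags[frac].astype(int)
        return df

    def to_tsv(self, mm: MarkerMap, path) -> None:
        self.to_dataframe(mm).to_csv(path, sep="\t", index=False, float_format="%.10g")


def build_track(
    scores: ComponentScores,
    mm: MarkerMap,
    window_bp: int,
    top_fracs: tuple = TOP_FRACS,
) -> CSSTrack:
    """Combine, smooth and threshold in one step."""
    raw = css_combine(scores)
    smoothed = smooth_track(raw, mm, window_bp)
    th = empirical_thresholds(smoothed, mm, top_fracs)
    return CSSTrack(raw, smoothed, window_bp, th.thresholds, th.flags)
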