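"""Genotype ingestion, QC filtering and cohort handling.

Reads phased VCF and PLINK (text ``.ped``/``.map`` or binary
``.bed``/``.bim``/``.fam``) panels into an in-memory haplotype matrix,
applies marker-level QC (missingness, MAF) and splits samples into a
selected/reference contrast.

Conventions
-----------
* Coordinates are 1-based inclusive, as in VCF.
* Haplotype matrices are ``int8`` with ``0`` = REF, ``1`` = ALT and
  ``-1`` = missing; row ``2*i`` and ``2*i + 1`` belong to sample ``i``.
* Scanning statistics require complete, phased data; ingestion never
  imputes — callers must supply phased panels for haplotype statistics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ContrastError,
    EmptyPanelError,
    FormatError,
    PhasingError,
    SampleLookupError,
)

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)


def chrom_sort_key(label: str):
    """Sort key placing numeric chromosome labels in numeric order."""
    s = str(label)
    m = re.fullmatch(r"(?:chr)?(\d+)", s, flags=re.IGNORECASE)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, s)


@dataclass
class MarkerMap:
    """Ordered per-SNP coordinate records.

    Positions must be strictly increasing within each chromosome and
    chromosomes must occupy contiguous blocks.
    """

    chrom: np.ndarray
    pos: np.ndarray
    snp_id: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        n = len(self.pos)
        for arr in (self.chrom, self.snp_id, self.ref_allele, self.alt_allele):
            if len(arr) != n:
                raise FormatError("marker map fields have inconsistent lengths")
        self._validate_order()

    def _validate_order(self) -> None:
        seen: set = set()
        prev_chrom = None
        for i in range(len(self.pos)):
            c = self.chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise FormatError(
                        f"chromosome {c!r} occupies non-contiguous blocks"
                    )
                seen.add(c)
                prev_chrom = c
            elif self.pos[i] <= self.pos[i - 1]:
                raise FormatError(
                    f"positions not strictly increasing on {c!r} at index {i}"
                )

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list:
        out, seen = [], set()
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> contiguous index slice."""
        slices: dict = {}
        start = 0
        n = len(self.pos)
        for i in range(1, n + 1):
            if i == n or self.chrom[i] != self.chrom[start]:
                slices[self.chrom[start]] = slice(start, i)
                start = i
        return slices

    def subset(self, idx) -> "MarkerMap":
        return MarkerMap(
            self.chrom[idx],
            self.pos[idx],
            self.snp_id[idx],
            self.ref_allele[idx],
            self.alt_allele[idx],
        )

    def index_of(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_id == snp_id)
        if len(hits) == 0:
            from .errors import MarkerLookupError

            raise MarkerLookupError(f"unknown SNP id {snp_id!r}")
        return int(hits[0])

    def genome_order(self) -> np.ndarray:
        """Indices sorting markers by (chromosome, position)."""
        keys = [chrom_sort_key(c) for c in self.chrom]
        return np.array(
            sorted(range(len(self.pos)), key=lambda i: (keys[i], self.pos[i])),
            dtype=np.int64,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "snp_id": self.snp_id,
                "ref": self.ref_allele,
                "alt": self.alt_allele,
            }
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotype matrix with sample labels.

    ``alleles`` has one row per haplotype (two consecutive rows per
    diploid sample) and one column per marker. ``phased=False`` marks
    genotype-only ingestion (PLINK without phase information): such a
    set supports frequency-based statistics but not haplotype ones.
    """

    alleles: np.ndarray
    sample_ids: list
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        if self.alleles.ndim != 2:
            raise FormatError("allele matrix must be 2-D")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise FormatError(
                f"{self.alleles.shape[0]} haplotype rows for "
                f"{len(self.sample_ids)} samples (expected 2 per sample)"
            )
        bad = ~np.isin(self.alleles, (-1, 0, 1))
        if bad.any():
            raise FormatError("allele matrix entries must be in {-1, 0, 1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.alleles == MISSING).any())

    def sample_of_haplotype(self, row: int) -> str:
        return self.sample_ids[row // 2]

    def rows_for_samples(self, ids: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in ids:
            if s not in index:
                raise SampleLookupError(f"unknown sample id {s!r}")
            rows.extend((2 * index[s], 2 * index[s] + 1))
        return np.asarray(rows, dtype=np.int64)

    def subset_markers(self, idx) -> "HaplotypeSet":
        return HaplotypeSet(self.alleles[:, idx], self.sample_ids, self.phased)

    def subset_samples(self, ids: Sequence[str]) -> "HaplotypeSet":
        rows = self.rows_for_samples(ids)
        return HaplotypeSet(self.alleles[rows], list(ids), self.phased)

    def genotypes(self) -> np.ndarray:
        """Per-sample ALT dosage (0/1/2), -1 where either allele missing."""
        a = self.alleles.reshape(self.n_samples, 2, self.n_markers)
        g = a.sum(axis=1).astype(np.int8)
        g[(a == MISSING).any(axis=1)] = MISSING
        return g


@dataclass
class CohortContrast:
    """Named selected-vs-reference sample split."""

    selected_ids: list
    reference_ids: list
    label: str = "contrast"

    def __post_init__(self) -> None:
        self.selected_ids = list(self.selected_ids)
        self.reference_ids = list(self.reference_ids)
        if not self.selected_ids or not self.reference_ids:
            raise ContrastError("both cohorts must be non-empty")
        overlap = set(self.selected_ids) & set(self.reference_ids)
        if overlap:
            raise ContrastError(f"samples in both cohorts: {sorted(overlap)}")


@dataclass
class QCReport:
    """Counts of markers removed per criterion."""

    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int
    max_missing: float
    min_maf: float
    removed_ids: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"markers_input\t{self.n_input}\n")
            fh.write(f"removed_missing_gt_{self.max_missing}\t{self.n_removed_missing}\n")
            fh.write(f"removed_maf_lt_{self.min_maf}\t{self.n_removed_maf}\n")
            fh.write(f"markers_retained\t{self.n_retained}\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_vcf(
    path,
    autosomes: Iterable[str] | None = None,
    strict: bool = True,
) -> tuple[HaplotypeSet, MarkerMap]:
    """Read a phased VCF into a haplotype set and marker map.

    Parameters
    ----------
    path
        VCF file (plain text or bgzipped) with GT fields.
    autosomes
        If given, only records whose CHROM is in this set are kept.
    strict
        Under ``strict=True`` an unphased heterozygote or a multiallelic
        record raises; otherwise offending records are skipped.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    if "GT" not in {f for f in _format_fields(vcf)}:
        raise FormatError(f"{path}: no GT field declared in header")
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: no samples")
    autoset = set(map(str, autosomes)) if autosomes is not None else None

    cols: list[np.ndarray] = []
    chroms: list[str] = []
    poss: list[int] = []
    ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    for var in vcf:
        if autoset is not None and str(var.CHROM) not in autoset:
            continue
        if len(var.ALT) != 1:
            if strict:
                raise FormatError(
                    f"{path}: non-biallelic record at {var.CHROM}:{var.POS}"
                )
            continue
        gts = var.genotypes
        if gts is None or len(gts) != len(samples):
            raise FormatError(f"{path}: missing GT at {var.CHROM}:{var.POS}")
        col = np.empty(2 * len(samples), dtype=np.int8)
        ok = True
        for i, g in enumerate(gts):
            a0, a1, ph = g[0], g[1], g[-1]
            if a0 >= 0 and a1 >= 0 and not ph and a0 != a1:
                if strict:
                    raise PhasingError(
                        f"{path}: unphased genotype at {var.CHROM}:{var.POS} "
                        f"sample {samples[i]}"
                    )
                ok = False
                break
            col[2 * i] = a0 if a0 >= 0 else MISSING
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING
        if not ok:
            continue
        cols.append(col)
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if not cols:
        raise EmptyPanelError(f"{path}: no usable biallelic records")
    mm = _sorted_map(chroms, poss, ids, refs, alts)
    order = _resort_order(chroms, poss)
    alleles = np.stack([cols[i] for i in order], axis=1)
    return HaplotypeSet(alleles, samples, phased=True), mm


def _format_fields(vcf) -> Iterable[str]:
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                yield h["ID"]
        except KeyError:
            continue


def _resort_order(chroms, poss) -> list[int]:
    return sorted(
        range(len(poss)), key=lambda i: (chrom_sort_key(chroms[i]), poss[i])
    )


def _sorted_map(chroms, poss, ids, refs, alts) -> MarkerMap:
    order = _resort_order(chroms, poss)
    return MarkerMap(
        np.array([chroms[i] for i in order], dtype=object),
        np.array([poss[i] for i in order], dtype=np.int64),
        np.array([ids[i] for i in order], dtype=object),
        np.array([refs[i] for i in order], dtype=object),
        np.array([alts[i] for i in order], dtype=object),
    )


def write_vcf(hs: HaplotypeSet, mm: MarkerMap, path) -> None:
    """Write a phased (or genotype-only) panel as an uncompressed VCF."""
    if hs.n_markers != len(mm):
        raise FormatError("haplotype/marker dimension mismatch")
    sep = "|" if hs.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=csscan\n")
        for c in mm.chromosomes():
            sl = mm.chrom_slices()[c]
            fh.write(f"##contig=<ID={c},length={int(mm.pos[sl][-1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hs.sample_ids)
            + "\n"
        )
        a = hs.alleles
        for j in range(len(mm)):
            gts = []
            for i in range(hs.n_samples):
                x, y = a[2 * i, j], a[2 * i + 1, j]
                gts.append(
                    f"{'.' if x < 0 else int(x)}{sep}{'.' if y < 0 else int(y)}"
                )
            fh.write(
                f"{mm.chrom[j]}\t{mm.pos[j]}\t{mm.snp_id[j]}\t"
                f"{mm.ref_allele[j]}\t{mm.alt_allele[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_plink(prefix) -> tuple[HaplotypeSet, MarkerMap]:
    """Read a PLINK panel (``.ped``/``.map`` or ``.bed``/``.bim``/``.fam``).

    Binary/text PLINK stores unphased genotypes, so the returned set has
    ``phased=False``; haplotype statistics refuse such input until a
    phased panel is supplied.
    """
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return _read_bed(prefix)
    if prefix.with_suffix(".ped").exists():
        return _read_ped(prefix)
    raise FormatError(f"no .bed or .ped found for prefix {prefix}")


def _read_map(path) -> tuple[list, list, list]:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected 4 columns")
    return (
        df[0].tolist(),
        df[3].astype(np.int64).tolist(),
        df[1].tolist(),
    )


def _read_ped(prefix: Path) -> tuple[HaplotypeSet, MarkerMap]:
    chroms, poss, ids = _read_map(prefix.with_suffix(".map"))
    n_snp = len(ids)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    allele_pairs: list[list[str]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snp:
                raise FormatError(
                    f"{prefix}.ped: row for {parts[1] if len(parts) > 1 else '?'} "
                    f"has {len(parts) - 6} allele fields, expected {2 * n_snp}"
                )
            samples.append(parts[1])
            allele_pairs.append(parts[6:])
    if not samples:
        raise FormatError(f"{prefix}.ped: empty file")
    # establish per-marker REF (major) / ALT (minor) from observed alleles
    alleles = np.full((2 * len(samples), n_snp), MISSING, dtype=np.int8)
    refs, alts = [], []
    for j in range(n_snp):
        obs = [row[2 * j + k] for row in allele_pairs for k in (0, 1)]
        letters = sorted({a for a in obs if a != "0"})
        if len(letters) > 2:
            raise FormatError(f"{prefix}.ped: marker {ids[j]} not biallelic")
        if not letters:
            refs.append("N")
            alts.append("N")
            continue
        counts = {a: obs.count(a) for a in letters}
        if len(letters) == 1:
            ref, alt = letters[0], letters[0]
        else:
            # major allele is REF; lexicographic tie-break for determinism
            ref = max(letters, key=lambda a: (counts[a], a))
            alt = letters[0] if letters[1] == ref else letters[1]
        refs.append(ref)
        alts.append(alt)
        code = {"0": MISSING, ref: np.int8(0), alt: np.int8(1)}
        for i, row in enumerate(allele_pairs):
            alleles[2 * i, j] = code[row[2 * j]]
            alleles[2 * i + 1, j] = code[row[2 * j + 1]]
    mm, alleles = _reorder(chroms, poss, ids, refs, alts, alleles, str(prefix))
    return HaplotypeSet(alleles, samples, phased=False), mm


def _read_bed(prefix: Path) -> tuple[HaplotypeSet, MarkerMap]:
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None, dtype=str)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    n_snp, n_sam = len(bim), len(fam)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if len(raw) < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise FormatError(f"{prefix}.bed: bad magic number")
    if raw[2] != 0x01:
        raise FormatError(f"{prefix}.bed: only SNP-major layout supported")
    bpf = (n_sam + 3) // 4
    body = raw[3:]
    if len(body) != bpf * n_snp:
        raise FormatError(
            f"{prefix}.bed: size inconsistent with {n_snp} markers x {n_sam} samples"
        )
    codes = np.unpackbits(
        body.reshape(n_snp, bpf), axis=1, bitorder="little"
    ).reshape(n_snp, bpf * 4, 2)
    two_bit = codes[:, :n_sam, 0] + 2 * codes[:, :n_sam, 1]  # per PLINK1 coding
    # 0 = hom A1 (alt/alt), 1 = missing, 2 = het, 3 = hom A2 (ref/ref)
    alleles = np.empty((2 * n_sam, n_snp), dtype=np.int8)
    lut_a = np.array([1, MISSING, 0, 0], dtype=np.int8)
    lut_b = np.array([1, MISSING, 1, 0], dtype=np.int8)
    alleles[0::2, :] = lut_a[two_bit].T
    alleles[1::2, :] = lut_b[two_bit].T
    mm, alleles = _reorder(
        bim[0].tolist(),
        bim[3].astype(np.int64).tolist(),
        bim[1].tolist(),
        bim[5].tolist(),  # A2 = REF (major)
        bim[4].tolist(),  # A1 = ALT (minor)
        alleles,
        str(prefix),
    )
    return HaplotypeSet(alleles, fam[1].tolist(), phased=False), mm


def _reorder(chroms, poss, ids, refs, alts, alleles, origin: str):
    order = _resort_order(chroms, poss)
    if order != list(range(len(poss))):
        logger.warning("%s: markers out of (chrom, pos) order; re-sorting", origin)
        alleles = alleles[:, order]
    mm = _sorted_map(chroms, poss, ids, refs, alts)
    return mm, alleles


def write_ped(hs: HaplotypeSet, mm: MarkerMap, prefix) -> None:
    """Write ``.ped``/``.map`` (letters from the map's REF/ALT)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(len(mm)):
            fh.write(f"{mm.chrom[j]}\t{mm.snp_id[j]}\t0\t{mm.pos[j]}\n")
    letters = np.stack(
        [mm.ref_allele.astype(str), mm.alt_allele.astype(str)], axis=0
    )
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(hs.sample_ids):
            fields = [f"FAM{i + 1}", sid, "0", "0", "0", "-9"]
            for j in range(len(mm)):
                for k in (0, 1):
                    a = hs.alleles[2 * i + k, j]
                    fields.append("0" if a < 0 else letters[a, j])
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# QC and cohort operations
# ---------------------------------------------------------------------------

def qc_filter(
    hs: HaplotypeSet,
    mm: MarkerMap,
    max_missing: float = 0.05,
    min_maf: float = 0.01,
) -> tuple[HaplotypeSet, MarkerMap, QCReport]:
    """Remove markers with missing rate > ``max_missing`` or MAF < ``min_maf``.

    Both inequalities are strict, so markers exactly at a threshold
    survive. MAF is computed over all samples pooled.
    """
    a = hs.alleles
    miss = (a == MISSING).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(
            miss < 1.0,
            np.where(a == 1, 1.0, 0.0).sum(axis=0)
            / np.maximum((a != MISSING).sum(axis=0), 1),
            np.nan,
        )
    maf = np.minimum(freq, 1.0 - freq)
    fail_missing = miss > max_missing
    fail_maf = np.isnan(maf) | (maf < min_maf)
    keep = ~(fail_missing | fail_maf)
    if not keep.any():
        raise EmptyPanelError("QC removed every marker")
    report = QCReport(
        n_input=len(mm),
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
        max_missing=max_missing,
        min_maf=min_maf,
        removed_ids=list(mm.snp_id[~keep]),
    )
    return hs.subset_markers(keep), mm.subset(keep), report


def allele_frequencies(
    hs: HaplotypeSet, ids: Sequence[str] | None = None
) -> np.ndarray:
    """Per-SNP ALT frequency over the haplotypes of ``ids`` (default: all)."""
    if ids is None:
        rows = np.arange(hs.n_haplotypes)
    else:
        if len(ids) == 0:
            raise SampleLookupError("empty sample set")
        rows = hs.rows_for_samples(ids)
    a = hs.alleles[rows]
    called = a != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, (a == 1).sum(axis=0) / np.maximum(n, 1), np.nan)


def split_cohorts(
    hs: HaplotypeSet, contrast: CohortContrast
) -> tuple[HaplotypeSet, HaplotypeSet]:
    """Split a panel into (selected, reference) haplotype sets."""
    missing = [
        s
        for s in contrast.selected_ids + contrast.reference_ids
        if s not in set(hs.sample_ids)
    ]
    if missing:
        raise ContrastError(f"contrast samples absent from panel: {missing}")
    return (
        hs.subset_samples(contrast.selected_ids),
        hs.subset_samples(contrast.reference_ids),
    )


def read_contrast(path, label: str | None = None) -> CohortContrast:
    """Read a two-column TSV ``sample<TAB>role`` with roles
    ``selected``/``reference``."""
    sel, ref = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 'sample<TAB>role'")
            sample, role = parts
            if role == "selected":
                sel.append(sample)
            elif role == "reference":
                ref.append(sample)
            else:
                raise FormatError(f"{path}:{ln}: unknown role {role!r}")
    return CohortContrast(sel, ref, label or Path(path).stem)
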