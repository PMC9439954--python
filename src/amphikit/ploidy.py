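"""Ploidy estimation from allele depths in mixed-ploidy resequencing data.

Two per-window estimators are computed from filtered SNPs.  With k SNPs in
a window,

    n_freq  = sum(both-allele depth) / sum(alternative-allele depth)
    n_depth = mean(both-allele depth) / d1

where d1 is the single-haplotype depth — the leftmost mode of the pooled
depth distribution of reference, alternative and both alleles.  A triploid
chromosome shows n ~ 3 and minor-allele frequencies near 1/3; a diploid
shows n ~ 2 and frequencies near 1/2.  Chromosomes whose depth and allele
frequency jointly sit at the (p-1)/p or (p+1)/p signature are flagged as
whole-haplotype loss/gain dosage anomalies.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .records import SiteRecord

logger = logging.getLogger(__name__)

CALL_BASELINE = "baseline"
CALL_LOSS = "loss"
CALL_GAIN = "gain"
CALL_AMBIGUOUS = "ambiguous"


class PeakNotFoundError(RuntimeError):
    """No usable mode in the allele-depth distribution."""


@dataclass(frozen=True)
class FilterProfile:
    """The four SNP retention thresholds.

    ``max_ratio`` bounds the depth ratio of the two (deepest) alleles —
    between 1:9 and 9:1 for a triploid, 1:6 and 6:1 for a diploid, bounds
    inclusive; ``max_site_depth`` is a strict upper bound on total site
    depth; every allele of the retained pair needs ``min_allele_depth``
    reads; and adjacent SNPs closer than ``min_snp_spacing`` are both
    dropped.
    """

    max_ratio: float = 9.0
    max_site_depth: int = 200
    min_allele_depth: int = 5
    min_snp_spacing: int = 5

    def __post_init__(self):
        if self.max_ratio < 1 or self.max_site_depth <= 0:
            raise ValueError("max_ratio >= 1 and max_site_depth > 0 required")
        if self.min_allele_depth <= 0 or self.min_snp_spacing <= 0:
            raise ValueError("min_allele_depth and min_snp_spacing must be > 0")

    @classmethod
    def triploid(cls) -> "FilterProfile":
        return cls(max_ratio=9.0, max_site_depth=200)

    @classmethod
    def diploid(cls) -> "FilterProfile":
        return cls(max_ratio=6.0, max_site_depth=400)


@dataclass
class FilterResult:
    records: list[SiteRecord]
    rejections: Counter = field(default_factory=Counter)

    @property
    def n_retained(self) -> int:
        return len(self.records)


def filter_snps(records: Iterable[SiteRecord], profile: FilterProfile) -> FilterResult:
    """Apply the four SNP thresholds; returns survivors and rejection counts.

    Records must be position-sorted within each (sample, chromosome).  The
    depth-ratio, site-depth and allele-depth gates run per record; the
    spacing gate then removes *both* members of any surviving pair closer
    than ``min_snp_spacing``.
    """
    rejections: Counter = Counter()
    staged: list[SiteRecord] = []
    last_pos: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.sample_id, rec.chrom)
        if key in last_pos and rec.pos < last_pos[key]:
            raise ValueError(
                f"records unsorted at {rec.chrom}:{rec.pos} (sample {rec.sample_id})")
        last_pos[key] = rec.pos
        hi, lo = rec.two_deepest()
        if lo == 0 or hi > profile.max_ratio * lo:
            rejections["allele_ratio"] += 1
            continue
        if rec.total >= profile.max_site_depth:
            rejections["site_depth"] += 1
            continue
        if lo < profile.min_allele_depth:
            rejections["allele_depth"] += 1
            continue
        staged.append(rec)

    kept: list[SiteRecord] = []
    by_group: dict[tuple[str, str], list[SiteRecord]] = {}
    for rec in staged:
        by_group.setdefault((rec.sample_id, rec.chrom), []).append(rec)
    for group in by_group.values():
        pos = np.array([r.pos for r in group])
        too_close = np.zeros(pos.size, dtype=bool)
        if pos.size > 1:
            close = np.diff(pos) < profile.min_snp_spacing
            too_close[:-1] |= close
            too_close[1:] |= close
        rejections["snp_spacing"] += int(too_close.sum())
        kept.extend(r for r, bad in zip(group, too_close) if not bad)

    result = FilterResult(records=kept, rejections=rejections)
    logger.info("filter_snps retained %d records; rejections: %s",
                len(kept), dict(rejections))
    return result


@dataclass(frozen=True)
class HaploidDepth:
    """The single-haplotype depth d1 and how it was found."""

    d1: float
    peaks: tuple[float, ...]
    smooth_window: int

    def __float__(self) -> float:
        return self.d1


def estimate_single_haplotype_depth(
    records: Sequence[SiteRecord],
    min_records: int = 1000,
    smooth_window: int | None = None,
    prominence_frac: float = 0.05,
) -> HaploidDepth:
    """Locate d1 as the leftmost mode of the pooled allele-depth distribution.

    The depths of the reference allele, the alternative allele and both
    combined are pooled into one integer histogram, smoothed with a moving
    average, and scanned for local maxima with prominence at least
    ``prominence_frac`` of the highest; the peak at the smallest depth is
    the single-haplotype depth (the "both" mode sits at ploidy x d1).
    """
    records = list(records)
    if len(records) < min_records:
        raise ValueError(
            f"need >= {min_records} filtered records to locate the "
            f"single-haplotype depth, got {len(records)}")
    values = np.concatenate([
        np.array([r.ref_depth for r in records]),
        np.array([r.alt_depth for r in records]),
        np.array([r.both_depth for r in records]),
    ])
    counts = np.bincount(values).astype(float)
    if smooth_window is None:
        iqr = float(np.subtract(*np.percentile(values, [75, 25])))
        fd = 2.0 * iqr / len(values) ** (1 / 3)  # Freedman-Diaconis width
        smooth_window = max(3, int(round(fd)) | 1)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts, kernel, mode="same")
    peaks, _ = find_peaks(smoothed, prominence=prominence_frac * smoothed.max())
    if peaks.size == 0:
        raise PeakNotFoundError(
            "no depth mode found; try a different smooth_window or a lower "
            "prominence_frac")
    return HaploidDepth(d1=float(peaks[0]),
                        peaks=tuple(float(p) for p in peaks),
                        smooth_window=smooth_window)


@dataclass
class PloidyWindow:
    """Windowed allele-depth sums and the two ploidy estimates."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    k: int
    sum_alt_depth: int
    sum_both_depth: int
    n_freq: float | None
    n_depth: float
    flagged: bool = False


def estimate_window_ploidy(
    records: Iterable[SiteRecord],
    d1: HaploidDepth | float,
    window_bp: int = 1_000_000,
) -> list[PloidyWindow]:
    """Per-window ploidy from filtered SNPs via non-overlapping windows.

    Windows without SNPs are omitted; a window whose alternative-allele
    depth sums to zero reports ``n_freq=None`` with ``flagged=True`` but
    still carries ``n_depth``.
    """
    d1v = float(d1)
    if d1v <= 0:
        raise ValueError("d1 must be positive")
    acc: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    for rec in records:
        w = (rec.pos - 1) // window_bp
        key = (rec.chrom, w)
        if key not in acc:
            acc[key] = [0, 0, 0]
            order.append(key)
        slot = acc[key]
        slot[0] += 1
        slot[1] += rec.alt_depth
        slot[2] += rec.both_depth
    windows = []
    for chrom, w in order:
        k, s_alt, s_both = acc[(chrom, w)]
        n_freq = s_both / s_alt if s_alt > 0 else None
        if n_freq is None:
            logger.warning("window %s:%d-%d has zero alternative depth",
                           chrom, w * window_bp, (w + 1) * window_bp)
        windows.append(PloidyWindow(
            chrom=chrom, start=w * window_bp, end=(w + 1) * window_bp,
            k=k, sum_alt_depth=s_alt, sum_both_depth=s_both,
            n_freq=n_freq, n_depth=(s_both / k) / d1v,
            flagged=n_freq is None))
    return windows


def summarize_allele_frequency(records: Iterable[SiteRecord]) -> pd.DataFrame:
    """Per-chromosome mean allele frequencies over retained SNPs.

    Two views are reported per chromosome: ``mean_alt_freq`` is the mean
    frequency of the (deepest) alternative allele, alt/(ref+alt) — the
    unbiased dosage signature (1/3 for a triploid with one variant
    haplotype, 1/2 for a diploid, given a reference that carries the major
    allele); ``mean_minor_freq`` folds each site to min(ref, alt)/(ref+alt),
    which is bounded by 0.5 but biased slightly below it at finite depth.
    """
    rows: dict[str, list[float]] = {}
    minor_rows: dict[str, list[float]] = {}
    for rec in records:
        both = rec.both_depth
        if both == 0:
            continue
        rows.setdefault(rec.chrom, []).append(rec.alt_depth / both)
        minor_rows.setdefault(rec.chrom, []).append(
            min(rec.ref_depth, rec.alt_depth) / both)
    if not rows:
        logger.warning("no SNPs to summarize")
    data = [
        (chrom, len(v), float(np.mean(v)), float(np.mean(minor_rows[chrom])))
        for chrom, v in rows.items()
    ]
    return pd.DataFrame(
        data, columns=["chrom", "n_snps", "mean_alt_freq", "mean_minor_freq"]
    ).set_index("chrom")


@dataclass(frozen=True)
class ChromosomeDosage:
    """Per-chromosome dosage call from joint depth and frequency evidence."""

    chrom: str
    minor_allele_frequency: float
    relative_depth: float
    call: str
    copies: int


def _folded_freq_target(copies: int) -> float:
    """Expected folded minor-allele frequency for a chromosome with
    ``copies`` haplotypes under the single-odd-haplotype site model.

    For a loss to ``copies`` haplotypes the surviving variant sites show the
    odd allele at 1/copies; a gained chromosome is a mixture over which
    haplotype was duplicated whose mean equals the pre-gain baseline.
    """
    if copies < 2:
        return 0.0
    return min(0.5, 1.0 / copies)


def detect_dosage_anomaly(
    windows: Sequence[PloidyWindow],
    freqs: pd.DataFrame,
    depth_tol: float = 0.10,
    freq_tol: float = 0.06,
) -> list[ChromosomeDosage]:
    """Flag chromosomes that lost or gained one haplotype.

    The genome-wide baseline copy number p is the rounded median of
    ``n_depth`` over all windows; each chromosome's relative depth is its
    median ``n_depth`` / p.  A loss call requires relative depth within
    ``depth_tol`` of (p-1)/p *and* a folded minor-allele frequency within
    ``freq_tol`` of the (p-1)-copy expectation; gain analogously against
    (p+1)/p (the gain frequency expectation, averaged over which haplotype
    duplicated, coincides with the baseline 1/p).  Conflicting depth and
    frequency evidence yields "ambiguous", never a silent baseline.
    """
    chroms = sorted({w.chrom for w in windows},
                    key=[w.chrom for w in windows].index)
    if len(chroms) < 5:
        raise ValueError("need >= 5 chromosomes to establish a baseline")
    all_nd = np.array([w.n_depth for w in windows])
    baseline = max(1, int(round(float(np.median(all_nd)))))

    calls = []
    for chrom in chroms:
        nd = float(np.median([w.n_depth for w in windows if w.chrom == chrom]))
        rel = nd / baseline
        try:
            f = float(freqs.loc[chrom, "mean_minor_freq"])
        except KeyError:
            logger.warning("no allele-frequency summary for %s", chrom)
            f = math.nan
        d_base = abs(rel - 1.0) <= depth_tol
        d_loss = abs(rel - (baseline - 1) / baseline) <= depth_tol
        d_gain = abs(rel - (baseline + 1) / baseline) <= depth_tol
        f_base = abs(f - _folded_freq_target(baseline)) <= freq_tol
        f_loss = abs(f - _folded_freq_target(baseline - 1)) <= freq_tol
        f_gain = abs(f - _folded_freq_target(baseline)) <= freq_tol

        if d_base and f_base:
            call, copies = CALL_BASELINE, baseline
        elif d_loss and f_loss and baseline >= 2:
            call, copies = CALL_LOSS, baseline - 1
        elif d_gain and f_gain:
            call, copies = CALL_GAIN, baseline + 1
        else:
            call, copies = CALL_AMBIGUOUS, int(round(nd))
        calls.append(ChromosomeDosage(chrom, f, rel, call, copies))
    return calls


def heterozygosity_windows(
    records: Iterable[SiteRecord],
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Heterozygous-site counts in non-overlapping windows, per Mb.

    Every retained SNP record counts as one heterozygous site.  Windows with
    zero SNPs between occupied windows of the same chromosome are included
    with zero counts.
    """
    acc: dict[tuple[str, int], int] = {}
    max_w: dict[str, int] = {}
    order: list[str] = []
    for rec in records:
        w = (rec.pos - 1) // window_bp
        acc[(rec.chrom, w)] = acc.get((rec.chrom, w), 0) + 1
        if rec.chrom not in max_w:
            order.append(rec.chrom)
        max_w[rec.chrom] = max(max_w.get(rec.chrom, 0), w)
    rows = []
    for chrom in order:
        for w in range(max_w[chrom] + 1):
            n = acc.get((chrom, w), 0)
            rows.append((chrom, w * window_bp, (w + 1) * window_bp, n,
                         n / window_bp * 1e6))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_het",
                                       "het_per_mb"])
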