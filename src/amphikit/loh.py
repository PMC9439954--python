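"""Loss-of-heterozygosity, gene-conversion and mutation-rate analysis.

A clonal (gynogenetic) pedigree is genotyped site by site from allele
depths: a site is heterozygous when the minor allele has >= 6 reads,
homozygous when it has <= 2, ambiguous in between or outside the coverage
bounds.  An LOH site is founder-heterozygous and focal-homozygous; runs of
LOH sites are merged into tracts and classified as gene deletion (tract
depth consistent with one fewer haplotype) or gene conversion (copy number
preserved).  Rates are per founder-heterozygous assayed site per
generation; the base-substitution rate follows mu_bs = m / (ploidy * n * T)
over ancestrally homozygous sites.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import SiteRecord

logger = logging.getLogger(__name__)

STATE_HET = "heterozygous"
STATE_HOM = "homozygous"
STATE_AMBIGUOUS = "ambiguous"

KIND_CONVERSION = "gene_conversion"
KIND_DELETION = "gene_deletion"
KIND_UNCLASSIFIED = "unclassified"

HET_MIN_MINOR = 6
HOM_MAX_MINOR = 2
DEFAULT_COVERAGE_BOUNDS = (20, 80)


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    chrom: str
    pos: int  # 1-based
    state: str
    minor_depth: int
    both_depth: int
    major_allele: str


def call_genotype(
    record: SiteRecord,
    coverage_bounds: tuple[int, int] = DEFAULT_COVERAGE_BOUNDS,
) -> GenotypeCall:
    """Genotype one site from its two deepest allele depths.

    Sites outside the total-coverage bounds are ambiguous; otherwise the
    minor-depth rule applies (>= 6 reads heterozygous, <= 2 homozygous,
    in between ambiguous).
    """
    lo_cov, hi_cov = coverage_bounds
    hi, lo = record.two_deepest()
    if not lo_cov <= record.total <= hi_cov:
        state = STATE_AMBIGUOUS
    elif lo >= HET_MIN_MINOR:
        state = STATE_HET
    elif lo <= HOM_MAX_MINOR:
        state = STATE_HOM
    else:
        state = STATE_AMBIGUOUS
    return GenotypeCall(record.sample_id, record.chrom, record.pos, state,
                        lo, hi + lo, record.major_allele)


def genotype_sample(
    records: Iterable[SiteRecord],
    coverage_bounds: tuple[int, int] = DEFAULT_COVERAGE_BOUNDS,
) -> dict[tuple[str, int], GenotypeCall]:
    """Genotype a sample's records, keyed by (chrom, pos)."""
    return {(r.chrom, r.pos): call_genotype(r, coverage_bounds) for r in records}


@dataclass
class LohSite:
    """A founder-heterozygous site that is homozygous in the focal sample."""

    chrom: str
    pos: int  # 1-based
    retained_allele: str
    founder_minor_depth: int
    co_states: dict[str, str] = field(default_factory=dict)
    unique: bool = True
    kind: str | None = None


def call_loh_sites(
    calls: Mapping[str, Mapping[tuple[str, int], GenotypeCall]],
    founder: str,
    focal: str,
    mask: Sequence | None = None,
) -> list[LohSite]:
    """LOH sites of ``focal`` relative to ``founder``.

    ``calls`` maps sample id -> {(chrom, pos): GenotypeCall}.  A site is
    emitted when the founder call is heterozygous and the focal call
    homozygous, with neither ambiguous.  ``mask`` intervals (attributes
    chrom/start/end, 0-based half-open — e.g. indel-adjacent regions) are
    excluded.  Sites where any other (non-founder) sample is also homozygous
    are marked shared (``unique=False``): shared events are treated as
    inherited and kept out of rate numerators.
    """
    if focal == founder:
        raise ValueError("focal sample must differ from the founder")
    if founder not in calls or focal not in calls:
        raise KeyError("founder and focal must both be genotyped")
    masked: dict[str, list[tuple[int, int]]] = {}
    for iv in mask or ():
        masked.setdefault(iv.chrom, []).append((iv.start, iv.end))

    founder_calls = calls[founder]
    focal_calls = calls[focal]
    others = [s for s in calls if s not in (founder, focal)]
    out: list[LohSite] = []
    n_masked = 0
    for key in sorted(founder_calls.keys() & focal_calls.keys()):
        chrom, pos = key
        if any(s <= pos - 1 < e for s, e in masked.get(chrom, ())):
            n_masked += 1
            continue
        fo = founder_calls[key]
        fc = focal_calls[key]
        if fo.state != STATE_HET or fc.state != STATE_HOM:
            continue
        co = {s: calls[s][key].state for s in others if key in calls[s]}
        out.append(LohSite(
            chrom=chrom, pos=pos, retained_allele=fc.major_allele,
            founder_minor_depth=fo.minor_depth, co_states=co,
            unique=not any(st == STATE_HOM for st in co.values())))
    logger.info("call_loh_sites: %d LOH sites for %s (%d masked sites skipped)",
                len(out), focal, n_masked)
    return out


@dataclass
class LohTract:
    """A contiguous run of LOH sites (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    sites: list[LohSite]
    is_singleton: bool = False
    kind: str | None = None
    median_relative_depth: float | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_unique_sites(self) -> int:
        return sum(1 for s in self.sites if s.unique)


@dataclass
class TractAssembly:
    tracts: list[LohTract]
    singletons: list[LohTract]

    def all_tracts(self) -> list[LohTract]:
        return self.tracts + self.singletons


def assemble_tracts(
    sites: Sequence[LohSite],
    max_gap_bp: int = 50_000,
    min_sites: int = 3,
) -> TractAssembly:
    """Greedy single-pass merge of position-sorted LOH sites into tracts.

    Consecutive sites on the same chromosome at most ``max_gap_bp`` apart
    join one tract.  Runs with fewer than ``min_sites`` members are reported
    separately as singletons rather than silently discarded, so every site
    belongs to exactly one tract or singleton.
    """
    tracts: list[LohTract] = []
    singles: list[LohTract] = []
    run: list[LohSite] = []

    def flush():
        if not run:
            return
        t = LohTract(chrom=run[0].chrom, start=run[0].pos - 1, end=run[-1].pos,
                     sites=list(run), is_singleton=len(run) < min_sites)
        (singles if t.is_singleton else tracts).append(t)

    for site in sites:
        if run and (site.chrom != run[-1].chrom
                    or site.pos - run[-1].pos > max_gap_bp):
            flush()
            run = []
        elif run and site.pos < run[-1].pos:
            raise ValueError("LOH sites must be position-sorted")
        run.append(site)
    flush()
    return TractAssembly(tracts=tracts, singletons=singles)


def classify_tract(
    tract: LohTract,
    depth_track: pd.DataFrame,
    genome_median_depth: float,
    baseline_ploidy: int = 3,
    deletion_cut: float | None = None,
    max_missing: float = 0.5,
) -> LohTract:
    """Split gene-deletion from gene-conversion tracts by relative depth.

    ``depth_track`` holds windowed mean depths (chrom/start/end/mean_depth).
    The tract's median window depth relative to the genome median is
    compared with ``deletion_cut``, by default the midpoint between the
    one-fewer-haplotype ratio (p-1)/p and 1 — 5/6 for a triploid baseline,
    matching depth guides at 33x against a 50x genome.  Tracts with depth
    data over less than half their span are left unclassified.  Member sites
    inherit the tract class.
    """
    if genome_median_depth <= 0:
        raise ValueError("genome_median_depth must be positive")
    p = baseline_ploidy
    if deletion_cut is None:
        deletion_cut = ((p - 1) / p + 1.0) / 2.0
    win = depth_track[(depth_track["chrom"] == tract.chrom)
                      & (depth_track["end"] > tract.start)
                      & (depth_track["start"] < tract.end)]
    span = max(1, tract.end - tract.start)
    covered = int((np.minimum(win["end"], tract.end)
                   - np.maximum(win["start"], tract.start)).clip(lower=0).sum())
    if covered / span < (1.0 - max_missing):
        tract.kind = KIND_UNCLASSIFIED
        tract.median_relative_depth = None
    else:
        ratio = float(win["mean_depth"].median()) / genome_median_depth
        tract.median_relative_depth = ratio
        tract.kind = KIND_DELETION if ratio <= deletion_cut else KIND_CONVERSION
    for s in tract.sites:
        s.kind = tract.kind
    return tract


@dataclass(frozen=True)
class RateEstimate:
    """An event rate with its numerator, denominator and per-individual parts."""

    kind: str
    m: int
    denominator: float
    rate: float
    per_individual: tuple = ()


def estimate_loh_rates(
    tracts_by_individual: Mapping[str, Iterable[LohTract]],
    assayed_het_sites: Mapping[str, int],
    generations: Mapping[str, int],
) -> dict[str, RateEstimate]:
    """LOH / conversion / deletion rates per heterozygous site per generation.

    Only unique LOH sites (present in a single individual, i.e. newly
    arising) enter the numerators; the per-individual denominator is its
    founder-heterozygous assayed site count times its pedigree depth in
    generations.  The pooled rate is sum(m_i)/sum(n_i*T_i), so the weighted
    per-individual rates average to it; conversion and deletion site counts
    partition the classified LOH sites.
    """
    kinds = ("loh", KIND_CONVERSION, KIND_DELETION)
    per: dict[str, list[tuple[str, int, float, float]]] = {k: [] for k in kinds}
    totals = {k: 0 for k in kinds}
    denom_total = 0.0
    for ind, tracts in tracts_by_individual.items():
        n_sites = assayed_het_sites[ind]
        t_gen = generations[ind]
        denom = float(n_sites) * t_gen
        if denom <= 0:
            raise ValueError(f"zero rate denominator for individual {ind!r}")
        denom_total += denom
        counts = Counter()
        for tract in tracts:
            u = tract.n_unique_sites
            counts["loh"] += u
            if tract.kind in (KIND_CONVERSION, KIND_DELETION):
                counts[tract.kind] += u
            elif tract.kind is None or tract.kind == KIND_UNCLASSIFIED:
                logger.warning("unclassified tract %s:%d-%d excluded from "
                               "conversion/deletion split", tract.chrom,
                               tract.start, tract.end)
        for k in kinds:
            totals[k] += counts[k]
            per[k].append((ind, counts[k], denom, counts[k] / denom))
    return {
        k: RateEstimate(kind=k, m=totals[k], denominator=denom_total,
                        rate=totals[k] / denom_total,
                        per_individual=tuple(per[k]))
        for k in kinds
    }


def count_assayed_het_sites(
    founder_calls: Mapping[tuple[str, int], GenotypeCall],
    focal_calls: Mapping[tuple[str, int], GenotypeCall],
) -> int:
    """Founder-heterozygous sites with an unambiguous call in the focal sample."""
    return sum(
        1 for key, c in founder_calls.items()
        if c.state == STATE_HET
        and key in focal_calls and focal_calls[key].state != STATE_AMBIGUOUS)


@dataclass(frozen=True)
class MutationSite:
    chrom: str
    pos: int
    line: str
    founder_allele: str
    new_allele: str


def call_substitutions(
    calls: Mapping[str, Mapping[tuple[str, int], GenotypeCall]],
    founder: str,
    lines: Sequence[str],
    excluded_chroms: Mapping[str, set[str]] | None = None,
) -> list[MutationSite]:
    """New base substitutions: founder-homozygous sites heterozygous in
    exactly one line.

    A qualifying site is homozygous (unambiguous) in the founder, carries an
    unambiguous heterozygous genotype in exactly one line, and is homozygous
    in every other line assayed there.  Chromosomes with non-baseline ploidy
    are excluded per line via ``excluded_chroms``; a line is simply not
    assayed on its excluded chromosomes.
    """
    excluded = excluded_chroms or {}
    founder_calls = calls[founder]
    out: list[MutationSite] = []
    for key, fo in founder_calls.items():
        if fo.state != STATE_HOM:
            continue
        chrom, pos = key
        assayed = [
            ln for ln in lines
            if chrom not in excluded.get(ln, set()) and key in calls[ln]
        ]
        if not assayed:
            continue
        states = {ln: calls[ln][key].state for ln in assayed}
        if any(st == STATE_AMBIGUOUS for st in states.values()):
            continue
        het_lines = [ln for ln, st in states.items() if st == STATE_HET]
        if len(het_lines) != 1:
            continue
        ln = het_lines[0]
        out.append(MutationSite(chrom, pos, ln, fo.major_allele,
                                calls[ln][key].major_allele))
    return out


def estimate_mutation_rate(
    m: int,
    n_sites: int,
    generations: int,
    ploidy: int = 3,
) -> RateEstimate:
    """Base-substitution rate mu_bs = m / (ploidy * n_sites * T).

    ``n_sites`` is the number of analysed genomic positions; multiplying by
    the ploidy counts each haplotype copy as an independently mutable site.
    """
    if generations <= 0:
        raise ValueError("generations must be positive")
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    denom = float(ploidy) * n_sites * generations
    return RateEstimate(kind="base_substitution", m=m, denominator=denom,
                        rate=m / denom)
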