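"""Synthetic amphidiploid/amphitriploid genomes with gynogenetic pedigrees.

This module generates the ground-truth data the rest of the package is tested
against.  It emulates, with controllable parameters:

* an amphidiploid (AABB) or amphitriploid (AAABBB) genome — each chromosome
  carries two or three near-identical haplotypes, and chromosomes are split
  between the two anciently diverged subgenomes A and B;
* clonal gynogenetic propagation: offspring are copies of the mother modified
  only by gene-conversion tracts, base substitutions and whole-chromosome
  haplotype loss/gain;
* short-read sequencing evidence as per-site per-allele read depths
  (Poisson total depth, multinomial allocation across alleles);
* copy-number-proportional gene expression.

Every random draw flows from one root seed through named substreams, so the
genome, the pedigree, the read depths and the expression noise can each be
regenerated independently.  All injected events are appended to a
:class:`SimTruth` ledger; replaying the ledger on the founder reproduces any
descendant exactly, which is the basis of the recovery tests.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .convmodel import apply_conversion
from .records import SiteRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

# named substream keys hanging off the root seed
_STREAM_GENOME = 0
_STREAM_PEDIGREE = 1
_STREAM_DEPTHS = 2
_STREAM_EXPRESSION = 3

# fixed entropy for per-gene base expression levels (independent of genome
# and of the run seed, so the same gene gets the same base level everywhere)
_GENE_BASE_ENTROPY = 715517


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for a named substream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class SimConfig:
    """Parameters of the synthetic genome, pedigree and sequencing model.

    Rates are per-generation quantities of the clonal pedigree:
    ``conversion_rate`` is the expected number of gene-conversion tracts per
    chromosome per generation, ``substitution_rate`` the per-site
    per-haplotype base substitution probability, ``chromosome_loss_rate`` the
    per-chromosome probability of a whole-haplotype dosage event (loss or
    gain, equal odds).  ``pairwise_divergence`` is the probability that two
    haplotypes of the same chromosome differ at a site.
    """

    n_chromosomes: int = 5
    chrom_length: int = 1_000_000
    ploidy: int = 3
    pairwise_divergence: float = 0.005
    depth_per_haplotype: float = 33.0
    conversion_rate: float = 0.0284
    tract_length_mean: float = 15_000.0
    substitution_rate: float = 8.88e-9
    chromosome_loss_rate: float = 0.0
    generations: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ConfigError("n_chromosomes and chrom_length must be positive")
        if self.ploidy < 1:
            raise ConfigError("ploidy must be >= 1")
        if not 0.0 <= self.pairwise_divergence <= 1.0:
            raise ConfigError("pairwise_divergence must be in [0, 1]")
        if self.pairwise_divergence * self.ploidy / 2.0 > 1.0:
            raise ConfigError(
                "pairwise_divergence too high for this ploidy under the "
                "single-variant-haplotype site model"
            )
        if self.depth_per_haplotype <= 0:
            raise ConfigError("depth_per_haplotype must be > 0")
        if self.conversion_rate < 0 or self.tract_length_mean < 1:
            raise ConfigError("conversion_rate >= 0 and tract_length_mean >= 1 required")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ConfigError("substitution_rate must be in [0, 1]")
        if not 0.0 <= self.chromosome_loss_rate <= 1.0:
            raise ConfigError("chromosome_loss_rate must be in [0, 1]")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")


@dataclass
class Chromosome:
    """One chromosome: a mapping reference plus its haplotype copies.

    ``reference`` is the (haploid) assembly sequence reads are compared
    against; ``haplotypes`` are the near-identical copies actually present.
    Sequences are uint8 arrays over base codes 0..3 (ACGT).
    """

    name: str
    subgenome: str
    reference: np.ndarray
    haplotypes: list[np.ndarray]

    @property
    def length(self) -> int:
        return int(self.reference.size)

    @property
    def copies(self) -> int:
        return len(self.haplotypes)

    def validate(self) -> None:
        for h in self.haplotypes:
            if h.size != self.reference.size:
                raise ValueError(f"haplotype length mismatch on {self.name}")


@dataclass
class HaplotypeGenome:
    """A set of chromosomes, each with one or more haplotype copies."""

    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for c in self.chromosomes:
            c.validate()

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def contigs(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def copy(self) -> "HaplotypeGenome":
        return HaplotypeGenome(
            [
                Chromosome(c.name, c.subgenome, c.reference,
                           [h.copy() for h in c.haplotypes])
                for c in self.chromosomes
            ]
        )


# ---------------------------------------------------------------------------
# truth ledger


@dataclass(frozen=True)
class ConversionEvent:
    generation: int
    chrom: str
    donor: int
    recipient: int
    start: int  # 0-based half-open
    end: int


@dataclass(frozen=True)
class SubstitutionEvent:
    generation: int
    chrom: str
    haplotype: int
    position: int  # 0-based
    old: str
    new: str


@dataclass(frozen=True)
class DosageEvent:
    generation: int
    chrom: str
    kind: str  # "loss" or "gain"
    haplotype: int  # lost index, or duplicated source index for a gain


@dataclass
class SimTruth:
    """Append-only ledger of every event injected after the founder."""

    events: list = field(default_factory=list)
    generation: int = 0
    rejected: list = field(default_factory=list)

    def conversions(self) -> list[ConversionEvent]:
        return [e for e in self.events if isinstance(e, ConversionEvent)]

    def substitutions(self) -> list[SubstitutionEvent]:
        return [e for e in self.events if isinstance(e, SubstitutionEvent)]

    def dosage_events(self) -> list[DosageEvent]:
        return [e for e in self.events if isinstance(e, DosageEvent)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            if isinstance(e, ConversionEvent):
                rows.append(("conversion", e.generation, e.chrom, e.start, e.end,
                             e.donor, e.recipient, ""))
            elif isinstance(e, SubstitutionEvent):
                rows.append(("substitution", e.generation, e.chrom, e.position,
                             e.position + 1, e.haplotype, -1, f"{e.old}>{e.new}"))
            else:
                rows.append(("dosage", e.generation, e.chrom, -1, -1,
                             e.haplotype, -1, e.kind))
        return pd.DataFrame(
            rows,
            columns=["event", "generation", "chrom", "start", "end",
                     "donor", "recipient", "detail"],
        )


# ---------------------------------------------------------------------------
# founder


def simulate_founder(config: SimConfig) -> tuple[HaplotypeGenome, SimTruth]:
    """Generate the founder genome of the lineage.

    Each chromosome gets ``config.ploidy`` haplotypes derived from a random
    reference sequence.  Variant sites carry exactly one divergent haplotype
    ("at most one odd copy per site"), placed uniformly; the per-site
    segregating probability is chosen so that the expected pairwise haplotype
    divergence equals ``config.pairwise_divergence``.  Under this model the
    reference carries the majority allele at every triploid variant site,
    mirroring how a collapsed haploid assembly represents the genome.
    """
    rng = substream(config.seed, _STREAM_GENOME)
    p = config.ploidy
    # one odd haplotype makes (p-1) of the p(p-1)/2 pairs differ => a site
    # segregates with probability divergence * p / 2
    seg_prob = config.pairwise_divergence * p / 2.0 if p > 1 else 0.0

    n_a = (config.n_chromosomes + 1) // 2
    chroms: list[Chromosome] = []
    for i in range(config.n_chromosomes):
        sub = "A" if i < n_a else "B"
        name = f"chr{i + 1:02d}{sub}"
        ref = rng.integers(0, 4, config.chrom_length, dtype=np.uint8)
        haps = [ref.copy() for _ in range(p)]
        if seg_prob > 0:
            pos = np.flatnonzero(rng.random(config.chrom_length) < seg_prob)
            odd = rng.integers(0, p, pos.size)
            alt = (ref[pos] + rng.integers(1, 4, pos.size)) % 4
            for h in range(p):
                m = odd == h
                haps[h][pos[m]] = alt[m].astype(np.uint8)
        chroms.append(Chromosome(name, sub, ref, haps))
    return HaplotypeGenome(chroms), SimTruth()


# ---------------------------------------------------------------------------
# pedigree propagation


def propagate_generation(
    genome: HaplotypeGenome,
    config: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypeGenome, SimTruth]:
    """One generation of clonal gynogenetic propagation.

    The offspring is a copy of the parent modified by, per chromosome and in
    this order: Poisson(``conversion_rate``)-many gene-conversion tracts with
    uniformly chosen distinct donor/recipient haplotypes and geometric tract
    lengths; per-site per-haplotype base substitutions at
    ``substitution_rate``; and at most one whole-chromosome haplotype
    loss/gain event at ``chromosome_loss_rate``.  All events are appended to
    the truth ledger in application order.
    """
    gen = truth.generation + 1
    if rng is None:
        rng = substream(config.seed, _STREAM_PEDIGREE, gen)
    child = genome.copy()
    for chrom in child.chromosomes:
        _convert_chromosome(chrom, config, truth, rng, gen)
        _mutate_chromosome(chrom, config, truth, rng, gen)
        _dosage_chromosome(chrom, config, truth, rng, gen)
    truth.generation = gen
    return child, truth


def _convert_chromosome(chrom, config, truth, rng, gen) -> None:
    p = chrom.copies
    n_tracts = rng.poisson(config.conversion_rate)
    for _ in range(n_tracts):
        if p < 2:
            truth.rejected.append((gen, chrom.name, "conversion_single_haplotype"))
            logger.warning("conversion skipped on single-haplotype %s", chrom.name)
            continue
        donor = int(rng.integers(p))
        recipient = int((donor + 1 + rng.integers(p - 1)) % p)
        start = int(rng.integers(chrom.length))
        length = int(rng.geometric(1.0 / config.tract_length_mean))
        end = min(start + length, chrom.length)
        chrom.haplotypes = apply_conversion(chrom.haplotypes, donor, recipient,
                                            (start, end))
        truth.events.append(ConversionEvent(gen, chrom.name, donor, recipient,
                                            start, end))


def _mutate_chromosome(chrom, config, truth, rng, gen) -> None:
    if config.substitution_rate <= 0:
        return
    for h, hap in enumerate(chrom.haplotypes):
        n_mut = rng.binomial(chrom.length, config.substitution_rate)
        if n_mut == 0:
            continue
        pos = rng.choice(chrom.length, size=n_mut, replace=False)
        for pp in np.sort(pos):
            old = int(hap[pp])
            new = (old + int(rng.integers(1, 4))) % 4
            hap[pp] = new
            truth.events.append(SubstitutionEvent(gen, chrom.name, h, int(pp),
                                                  BASES[old], BASES[new]))


def _dosage_chromosome(chrom, config, truth, rng, gen) -> None:
    if config.chromosome_loss_rate <= 0:
        return
    if rng.random() >= config.chromosome_loss_rate:
        return
    kind = "loss" if rng.random() < 0.5 else "gain"
    if kind == "loss":
        if chrom.copies <= 1:
            truth.rejected.append((gen, chrom.name, "loss_single_haplotype"))
            logger.warning("haplotype loss rejected on single-copy %s", chrom.name)
            return
        idx = int(rng.integers(chrom.copies))
        del chrom.haplotypes[idx]
    else:
        idx = int(rng.integers(chrom.copies))
        chrom.haplotypes.append(chrom.haplotypes[idx].copy())
    truth.events.append(DosageEvent(gen, chrom.name, kind, idx))


# forced-event helpers -------------------------------------------------------


def inject_conversion(genome, truth, chrom_name, donor, recipient, start, end,
                      generation=None):
    """Apply one deterministic conversion tract and record it in the ledger."""
    chrom = genome.chromosome(chrom_name)
    if not 0 <= start < end <= chrom.length:
        raise ValueError(f"interval [{start}, {end}) outside {chrom_name}")
    chrom.haplotypes = apply_conversion(chrom.haplotypes, donor, recipient,
                                        (start, end))
    gen = truth.generation if generation is None else generation
    truth.events.append(ConversionEvent(gen, chrom_name, donor, recipient,
                                        start, end))
    return genome, truth


def lose_haplotype(genome, truth, chrom_name, index, generation=None):
    """Remove one haplotype of a chromosome (whole-chromosome loss)."""
    chrom = genome.chromosome(chrom_name)
    if chrom.copies <= 1:
        raise ValueError(f"cannot lose the only haplotype of {chrom_name}")
    del chrom.haplotypes[index]
    gen = truth.generation if generation is None else generation
    truth.events.append(DosageEvent(gen, chrom_name, "loss", index))
    return genome, truth


def gain_haplotype(genome, truth, chrom_name, source_index, generation=None):
    """Duplicate one haplotype of a chromosome (whole-chromosome gain)."""
    chrom = genome.chromosome(chrom_name)
    chrom.haplotypes.append(chrom.haplotypes[source_index].copy())
    gen = truth.generation if generation is None else generation
    truth.events.append(DosageEvent(gen, chrom_name, "gain", source_index))
    return genome, truth


def replay(founder: HaplotypeGenome, truth: SimTruth) -> HaplotypeGenome:
    """Re-apply the truth ledger to the founder.

    Returns a genome identical to the descendant the ledger was recorded
    from; used as the ground-truth consistency check.
    """
    genome = founder.copy()
    for e in truth.events:
        chrom = genome.chromosome(e.chrom)
        if isinstance(e, ConversionEvent):
            chrom.haplotypes = apply_conversion(chrom.haplotypes, e.donor,
                                                e.recipient, (e.start, e.end))
        elif isinstance(e, SubstitutionEvent):
            chrom.haplotypes[e.haplotype][e.position] = _BASE_TO_CODE[e.new]
        elif isinstance(e, DosageEvent):
            if e.kind == "loss":
                del chrom.haplotypes[e.haplotype]
            else:
                chrom.haplotypes.append(chrom.haplotypes[e.haplotype].copy())
    return genome


@dataclass
class Pedigree:
    """A gynogenetic clonal pedigree: founder plus per-line descendants."""

    founder: HaplotypeGenome
    samples: dict[str, HaplotypeGenome]
    truths: dict[str, SimTruth]
    generations: dict[str, int]


def simulate_pedigree(config: SimConfig, n_lines: int = 2,
                      founder_truth: SimTruth | None = None,
                      founder: HaplotypeGenome | None = None) -> Pedigree:
    """Simulate ``n_lines`` independent clonal lines from one founder.

    Each line is propagated for ``config.generations`` generations; the
    individual sampled is the final generation of its line.
    """
    if founder is None:
        founder, _ = simulate_founder(config)
    samples: dict[str, HaplotypeGenome] = {}
    truths: dict[str, SimTruth] = {}
    gens: dict[str, int] = {}
    for j in range(n_lines):
        genome = founder
        truth = SimTruth()
        for g in range(1, config.generations + 1):
            rng = substream(config.seed, _STREAM_PEDIGREE, j, g)
            genome, truth = propagate_generation(genome, config, truth, rng=rng)
        name = f"line{j + 1}_G{config.generations}"
        samples[name] = genome
        truths[name] = truth
        gens[name] = config.generations
    return Pedigree(founder, samples, truths, gens)


# ---------------------------------------------------------------------------
# sequencing-depth observations


def segregating_positions(chrom: Chromosome) -> np.ndarray:
    """0-based positions where any two haplotypes of the chromosome differ."""
    if chrom.copies < 2:
        return np.empty(0, dtype=np.int64)
    mask = np.zeros(chrom.length, dtype=bool)
    h0 = chrom.haplotypes[0]
    for h in chrom.haplotypes[1:]:
        mask |= h != h0
    return np.flatnonzero(mask)


def _allele_counts(chrom: Chromosome, pos: np.ndarray) -> np.ndarray:
    """(n_sites, 4) haplotype copy count per base code."""
    counts = np.zeros((pos.size, 4), dtype=np.int32)
    idx = np.arange(pos.size)
    for hap in chrom.haplotypes:
        counts[idx, hap[pos]] += 1
    return counts


def simulate_depths(
    genome: HaplotypeGenome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    positions: dict[str, np.ndarray] | None = None,
    sample_id: str = "sample1",
) -> list[SiteRecord]:
    """Sequencing evidence at variant sites as per-allele read depths.

    At each site the total depth is Poisson(copies x depth_per_haplotype) and
    reads are allocated to alleles multinomially in proportion to the
    haplotype copies carrying each allele.  By default only sites segregating
    in this genome are emitted; pass ``positions`` (per chromosome, 0-based)
    to force records at a shared site list, e.g. the union of variant sites
    across a pedigree — sites monomorphic in this sample are then reported
    with all reads on the carried allele.
    """
    if rng is None:
        rng = substream(config.seed, _STREAM_DEPTHS)
    d1 = config.depth_per_haplotype
    out: list[SiteRecord] = []
    for chrom in genome.chromosomes:
        pos = (positions.get(chrom.name, np.empty(0, dtype=np.int64))
               if positions is not None else segregating_positions(chrom))
        pos = np.asarray(pos, dtype=np.int64)
        if pos.size == 0:
            continue
        counts = _allele_counts(chrom, pos)
        p = chrom.copies
        totals = rng.poisson(p * d1, pos.size)
        allele_depths = rng.multinomial(totals, counts / p)
        ref_codes = chrom.reference[pos]
        for i in range(pos.size):
            rc = int(ref_codes[i])
            present = np.flatnonzero(counts[i])
            # alts ordered by descending copy count, base code breaking ties
            alt_codes = sorted((c for c in present if c != rc),
                               key=lambda c: (-counts[i, c], c))
            depths = (int(allele_depths[i, rc]),
                      *(int(allele_depths[i, c]) for c in alt_codes))
            out.append(SiteRecord(
                sample_id=sample_id,
                chrom=chrom.name,
                pos=int(pos[i]) + 1,
                ref=BASES[rc],
                alts=tuple(BASES[c] for c in alt_codes),
                depths=depths,
            ))
    return out


def pedigree_depths(pedigree: Pedigree, config: SimConfig,
                    include_founder: bool = True) -> dict[str, list[SiteRecord]]:
    """Depth records for every pedigree sample over the union of variant sites."""
    genomes: dict[str, HaplotypeGenome] = {}
    if include_founder:
        genomes["founder"] = pedigree.founder
    genomes.update(pedigree.samples)
    union: dict[str, np.ndarray] = {}
    for name in pedigree.founder.contigs():
        site_sets = [segregating_positions(g.chromosome(name))
                     for g in genomes.values()]
        union[name] = np.unique(np.concatenate(site_sets))
    records: dict[str, list[SiteRecord]] = {}
    for k, (sid, g) in enumerate(genomes.items()):
        rng = substream(config.seed, _STREAM_DEPTHS, k)
        records[sid] = simulate_depths(g, config, rng=rng, positions=union,
                                       sample_id=sid)
    return records


def depth_track(
    genome: HaplotypeGenome,
    config: SimConfig,
    window_bp: int = 200_000,
    probes_per_window: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Windowed mean total depth, from Poisson draws at evenly spaced probes.

    This is the whole-genome (mostly monomorphic) depth summary used by tract
    classification and the depth-calibration checks; columns are
    (chrom, start, end, n_probes, mean_depth) with 0-based half-open windows.
    """
    if rng is None:
        rng = substream(config.seed, _STREAM_DEPTHS, 999)
    rows = []
    for chrom in genome.chromosomes:
        lam = chrom.copies * config.depth_per_haplotype
        for start in range(0, chrom.length, window_bp):
            end = min(start + window_bp, chrom.length)
            n = max(1, int(probes_per_window * (end - start) / window_bp))
            mean = float(rng.poisson(lam, n).mean())
            rows.append((chrom.name, start, end, n, mean))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes",
                                       "mean_depth"])


# ---------------------------------------------------------------------------
# expression


def _gene_base_level(gene_name: str) -> float:
    """Per-gene base expression level, from a fixed-seed distribution.

    Keyed by the gene name only, so the same gene has the same base level in
    every genome — dosage ratios between genomes are then exact when noise
    is zero.
    """
    key = zlib.crc32(gene_name.encode())
    g = np.random.default_rng(
        np.random.SeedSequence(entropy=_GENE_BASE_ENTROPY, spawn_key=(key,)))
    return float(g.lognormal(mean=np.log(10.0), sigma=1.0))


def simulate_expression(
    genome: HaplotypeGenome,
    genes,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Copy-number-proportional expression values per gene.

    ``genes`` is an iterable of intervals with ``chrom``, ``start``, ``end``,
    ``name`` attributes (0-based half-open).  Expression is
    copies x base_level x lognormal(0, noise_sd) noise.
    """
    rng = substream(seed, _STREAM_EXPRESSION)
    rows = []
    for g in genes:
        try:
            chrom = genome.chromosome(g.chrom)
        except KeyError:
            raise ValueError(f"gene {g.name!r} on unknown chromosome {g.chrom!r}")
        if not 0 <= g.start < g.end <= chrom.length:
            raise ValueError(
                f"gene {g.name!r} interval [{g.start}, {g.end}) outside "
                f"{g.chrom} (length {chrom.length})")
        base = _gene_base_level(g.name)
        noise = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
        rows.append((g.name, g.chrom, chrom.copies, chrom.copies * base * noise))
    return pd.DataFrame(rows, columns=["gene", "chrom", "copies", "expression"])
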