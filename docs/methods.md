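# Methods

This note documents the models behind `amphikit`, the defaults and why,
the numerical choices, and what the synthetic data does and does not
emulate.

## The genome and sequencing model

A chromosome is a haploid **reference** sequence plus `p` near-identical
**haplotype** copies (p = 3 for an amphitriploid set, 2 for an
amphidiploid). The two subgenomes A and B are anciently diverged; reads
map to their own subgenome's reference, so each chromosome can be
simulated independently and subgenome identity is just a label.

Founder variant sites carry exactly **one divergent haplotype** per site.
This matches the empirical picture of three highly similar alleles per
homeologue and makes the site model analytically transparent: with one odd
copy among p, a fraction 2/p of haplotype pairs differ at a segregating
site, so sites are made segregating with probability
`pairwise_divergence × p/2` to hit the configured pairwise divergence
exactly in expectation. The reference carries the majority allele, as a
collapsed haploid assembly does. Multi-allelic sites arise only through
later substitutions.

Sequencing evidence at a site is `total ~ Poisson(p × d₁)` reads allocated
to alleles `multinomial(total, copy fractions)`, where `d₁` (default 33
reads) is the depth contributed by one haplotype copy. There are no
mapping errors, no reference bias, no GC or mappability waves, and no
base-calling noise — so recovery results on simulations bound what the
estimators can do under ideal mapping, not what they achieve on real
alignments.

## Clonal pedigree

Offspring are clonal copies of the mother modified, per chromosome and
generation, by three event classes (all appended to a replayable truth
ledger):

* **Gene conversion** — `Poisson(conversion_rate)` tracts; ordered
  (donor, recipient) drawn uniformly from the p(p−1) possibilities;
  start uniform; length geometric with mean `tract_length_mean` (minimum
  1 bp, clipped at the chromosome end). The geometric law is a stand-in —
  no tract-length distribution is established for this system — and is
  deliberately exposed as configuration.
* **Base substitution** — per site per haplotype at `substitution_rate`
  (default 8.88 × 10⁻⁹ per site per haplotype per generation, the measured
  clonal-lineage rate scale); single-nucleotide only, no indels.
* **Whole-chromosome dosage** — with probability `chromosome_loss_rate`
  one haplotype is lost or (equal odds) duplicated; loss of the last copy
  is rejected and logged.

The default `conversion_rate` of 0.0284 tracts/chromosome/generation is
derived from the target per-heterozygous-site conversion rate of
~1.42 × 10⁻⁴ per generation: with 1 Mb chromosomes, 15 kb mean tracts and
the ~1/3 homozygous-conversion fraction,
rate ≈ γ × tract_len / (3 L). The replay property (ledger applied to the
founder reproduces any descendant bit-for-bit) is enforced by test.

Randomness flows from a single root seed through named substreams
(genome, pedigree, depths, expression), so each stage can be regenerated
independently and identical configs give identical outputs.

## Ploidy estimation

SNPs pass four gates (tracked per-gate in an audit counter): allele depth
ratio within [1:R, R:1] **inclusive** (R = 9 triploid, 6 diploid; the
boundary inclusion is a documented choice, the published thresholds leave
it open), total site depth strictly below 200×/400×, both retained
alleles ≥ 5 reads, and ≥ 5 bp to the nearest SNP (both members of a close
pair are removed, after the three per-site gates). Tri-allelic sites are
reduced to their two deepest alleles.

`d₁` is found from the pooled integer histogram of reference,
alternative and both-allele depths, smoothed by a moving average whose
width defaults to the Freedman–Diaconis bin width of the pooled sample;
the **leftmost** local maximum above 5% prominence is taken ("smallest
peak" = smallest depth value, not smallest height). Both window
estimators, `n_freq` and `n_depth`, are plain ratios of windowed sums —
windows are 0-based half-open and non-overlapping (1 Mb ploidy, 500 kb
heterozygosity).

Allele-frequency summaries report two views. `mean_alt_freq` — the mean
frequency of the deepest non-reference allele — is the unbiased dosage
signature (1/3 triploid, 1/2 diploid) because the simulator's reference
carries the major allele. `mean_minor_freq` folds each site to
min(ref, alt)/(ref+alt); it is bounded by 0.5 as a minor-allele frequency
must be, but at finite depth its mean sits below 0.5 by E|f − 0.5|
(≈ 0.049 at 66×). Dosage calls use the folded view with tolerance 0.06,
which absorbs that bias at d₁ ≥ 30.

**Dosage anomalies.** The baseline copy number p is the rounded
genome-wide median of `n_depth`. A loss call needs relative depth within
±0.10 of (p−1)/p *and* folded frequency within ±0.06 of 1/(p−1); a gain
needs depth at (p+1)/p and frequency consistent with 1/p. The gain
frequency target is deliberately the baseline value: averaging over which
haplotype was duplicated, the expected minor-allele frequency of a gained
chromosome is a mixture of 1/(p+1) and 2/(p+1) whose mean equals 1/p, so
depth — not frequency — is the discriminating evidence for gains.
Conflicting evidence yields an explicit "ambiguous" call.

## LOH, conversion and mutation rates

Genotypes: total coverage within [20, 80] (tuned to ~50× genomes; scale
the bounds with depth), then minor-allele depth ≥ 6 → heterozygous,
≤ 2 → homozygous, else ambiguous. The LOH pipeline is: coverage gate →
genotype rule → founder-het/focal-hom requirement → optional
indel-adjacency mask → shared-vs-unique partition. Only **unique** LOH
sites (homozygous in exactly one individual) enter rate numerators;
shared ones are treated as inherited.

Tracts are a greedy single-pass merge of sorted LOH sites with gaps
≤ 50 kb (configurable); runs below 3 sites are kept as singletons, so
sites always partition into tracts. Classification compares the tract's
median windowed depth against the genome median: ratio ≤ (2p−1)/(2p) —
the midpoint between (p−1)/p and 1, i.e. 5/6 ≈ 0.833 for a triploid,
splitting the 33× and 50× depth guides of a 50× genome — calls gene
deletion, above it gene conversion; tracts with depth data over less than
half their span stay unclassified and are excluded from the
conversion/deletion split (with a warning).

Rates: per individual, rate = unique LOH sites / (founder-heterozygous
assayed sites × generations since the sequenced founder); the pooled rate
is Σm / Σ(nᵢTᵢ), so weighted per-individual rates average to it exactly.
The base-substitution rate is μ_bs = m / (ploidy × n × T) over
founder-homozygous sites that are unambiguously heterozygous in exactly
one line, with non-baseline-ploidy chromosomes excluded per line.

## Conversion fate model

A scenario is an **ordered** (donor, recipient) pair — p(p−1) of them,
six in a triploid; the unordered convention would give three and disagree
with the event's directionality. Outcomes for a variant on c of p copies:
"eliminated" (reaches 0 copies), "reduced" (down but nonzero, only
possible for c > 1), "unchanged", "expanded" (up; reaching p copies is
fixation). Tract-site classes (homozygous-LOH / converted-heterozygous /
unchanged-heterozygous / invariant) partition every tract and are
verified against re-application of the conversion. Under the
one-odd-haplotype site model the expected homozygous fraction is exactly
1/p for p ≥ 3 (1/3 in a triploid — the 12-of-35 regime) and 1 for a
diploid, computed by enumeration with an optional Monte-Carlo check.

## Gene-family expansion

Depths are normalized per sample so the genome-wide median maps to 1.0
per baseline genome, making all calls scale-invariant. A site qualifies
iff min(focal) > 2 × max(outgroup) — both cut-offs **strict**, as are the
60% gene fraction and the half-up copy-number rounding. Consequence worth
knowing: a region at exactly 2.0× relative copy number sits on the
boundary and essentially never qualifies under Poisson noise; the rule
detects expansions with margin (≳ 2.5×), which is the regime the recovery
tests exercise (3× duplications: sensitivity ≥ 0.95, zero false calls).
The qualifying-site stage is the automatic front end of what is, in
practice, a pipeline ending in manual curation of assemblies — final
family counts are out of its scope.

## Problem sizes and determinism

Tests and the acceptance script run at reduced scale — chromosomes of
0.2–1 Mb, 5–25 chromosomes, pedigrees of 1–5 lines over 2–4 generations —
chosen so the whole suite completes in well under a minute of simulation
time while every stochastic assertion retains ≥ 3σ margins (binomial or
Poisson standard errors are computed in the tests themselves). All
stochastic tests use fixed seeds; hypothesis property tests are bounded
and seeded by example generation only.

## Known limitations

* No read-level simulation (FASTQ/mapping), no indels, no crossover
  recombination, no selection, no k-mer analyses.
* The LOH multi-step filter is a defined, auditable approximation of a
  published pipeline whose full details are not public; absolute site
  counts from real data are therefore not comparable, only rates and
  classifications.
* Depth tracks summarize Poisson sampling at probe positions; segmental
  (sub-chromosomal) deletions are not generated by the simulator, so
  deletion-classification is tested on constructed depth tracks.
* The conversion tract-length law (geometric) is conventional, not
  measured; change `tract_length_mean` or swap the distribution if better
  data exists.
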