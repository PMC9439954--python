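# amphikit

Analysis toolkit for **mixed-ploidy resequencing data** from clonal
(gynogenetic) vertebrate lineages — the setting exemplified by the
amphitriploid gibel carp, whose genome carries two anciently diverged
subgenomes (A and B) at three near-identical haplotype copies each
(AAABBB), next to its amphidiploid (AABB) sexual relative.

It is written for population/genome researchers who have per-site
per-allele read depths (a VCF with `AD` fields) from such genomes and want
to answer, with auditable code:

* **What is the ploidy of each chromosome?** From filtered SNPs in 1 Mb
  windows, with *k* SNPs per window and *d₁* the single-haplotype depth
  (the leftmost mode of the pooled allele-depth distribution):

  n_freq = Σᵏ(depth of both alleles) / Σᵏ(depth of alternative alleles)

  n_depth = (1/k · Σᵏ depth of both alleles) / d₁

  A triploid chromosome shows n ≈ 3 and minor-allele frequencies near 1/3;
  a diploid shows n ≈ 2 and frequencies near 1/2. Chromosomes that jointly
  shift to ~2/3 (or 4/3) relative depth and diploid-like frequencies are
  flagged as whole-haplotype **loss/gain dosage anomalies**.
* **Where did heterozygosity disappear?** In a clonal pedigree, sites that
  are founder-heterozygous but offspring-homozygous (minor-allele depth
  ≥ 6× for het, ≤ 2× for hom, coverage-bounded) are LOH sites; runs of them
  are merged into tracts and classified as **gene deletion** (tract depth
  consistent with one fewer haplotype) or **gene conversion** (copy number
  preserved). Rates are per heterozygous site per generation, and the
  base-substitution rate follows μ_bs = m / (3nT) for a triploid.
* **What does one conversion do to a mutation?** The fate model enumerates
  all p(p−1) ordered donor→recipient scenarios: in a triploid a single-copy
  variant is eliminated, unchanged or expanded in 2/2/2 of the six
  scenarios (50/50 cleared/spread in a diploid), and ~1/3 of heterozygous
  sites inside a converted tract become homozygous.
* **Which gene families expanded in the focal lineage?** Sites where the
  minimum normalized depth over focal samples exceeds twice the maximum
  over outgroup samples; genes with > 60% qualifying CDS sites are called
  expanded, with a depth-based copy-number estimate.

Because raw sequencing data of this kind is bulky and access-controlled,
the package ships a first-class **simulator** (`amphikit.simdata`) that
generates AABB/AAABBB genomes, clonal pedigrees with injected conversion
tracts, substitutions and whole-chromosome dosage events (all recorded in a
replayable truth ledger), Poisson/multinomial read-depth observations, and
copy-number-proportional expression — the ground truth every estimator is
tested against.

## Worked example

```python
import numpy as np
from amphikit import simdata, ploidy

config = simdata.SimConfig(n_chromosomes=5, chrom_length=1_000_000,
                           ploidy=3, pairwise_divergence=0.005,
                           depth_per_haplotype=33.0, seed=1)
genome, _ = simdata.simulate_founder(config)
records = simdata.simulate_depths(genome, config)

kept = ploidy.filter_snps(records, ploidy.FilterProfile.triploid())
d1 = ploidy.estimate_single_haplotype_depth(kept.records)
windows = ploidy.estimate_window_ploidy(kept.records, d1)
freqs = ploidy.summarize_allele_frequency(kept.records)

print(f"retained SNPs: {kept.n_retained}")
print(f"single-haplotype depth d1: {d1.d1:.0f}")
print(f"median depth-based ploidy: {np.median([w.n_depth for w in windows]):.2f}")
print(f"mean minor-allele frequency: {freqs['mean_alt_freq'].mean():.3f}")
```

prints

```
retained SNPs: 35501
single-haplotype depth d1: 33
median depth-based ploidy: 3.00
mean minor-allele frequency: 0.333
```

i.e. the filtered SNPs of the simulated amphitriploid show the expected
triploid signature: total depth three times the single-haplotype depth
(3 × 33 ≈ 99×) and a minor allele carried by one of three haplotypes
(frequency ≈ 1/3). A diploid control run with
`FilterProfile.diploid()` prints ≈ 2.00 and ≈ 0.500.

The same pipeline is scriptable from the shell:

```bash
akit simulate --out-dir sim --seed 1
akit ploidy --vcf sim/variants.vcf --sample founder --out-dir out
akit convfates --ploidy 3 --copies 1
akit loh call --vcf sim/variants.vcf --founder founder \
     --focal line1_G4 --out loh_sites.bed
```

## Layout

| module | purpose |
| --- | --- |
| `amphikit.simdata` | synthetic genomes, pedigrees, depths, expression, truth ledger |
| `amphikit.ploidy` | SNP filters, d₁ estimation, windowed ploidy, dosage anomalies, heterozygosity windows |
| `amphikit.loh` | genotype calls, LOH sites/tracts, deletion vs conversion, LOH/conversion/mutation rates |
| `amphikit.convmodel` | conversion fate enumeration, tract application, per-site tract classes |
| `amphikit.expansion` | normalized depth matrices, qualifying sites, expanded-gene calls |
| `amphikit.io` / `amphikit.cli` | VCF/BED/GFF3 readers and writers, manifests, the `akit` command |

See `docs/methods.md` for the models, parameter choices and limitations.
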