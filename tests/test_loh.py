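"""Genotype calls, LOH sites/tracts, classification and rate estimates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amphikit import loh, simdata
from amphikit.records import SiteRecord


def rec(ref_d, alt_d, pos=100, chrom="chr1", sample="s"):
    return SiteRecord(sample_id=sample, chrom=chrom, pos=pos, ref="A",
                      alts=("T",), depths=(ref_d, alt_d))


class TestGenotypeRule:
    @pytest.mark.parametrize("depths,expected", [
        ((30, 12), loh.STATE_HET),        # minor 12 >= 6
        ((40, 1), loh.STATE_HOM),         # minor 1 <= 2
        ((30, 4), loh.STATE_AMBIGUOUS),   # 2 < minor < 6
        ((90, 10), loh.STATE_AMBIGUOUS),  # total 100 > 80 coverage bound
        ((15, 2), loh.STATE_AMBIGUOUS),   # total 17 < 20 coverage bound
    ])
    def test_minor_depth_and_coverage_rules(self, depths, expected):
        assert loh.call_genotype(rec(*depths)).state == expected

    @given(st.integers(0, 120), st.integers(0, 120))
    @settings(max_examples=100, deadline=None)
    def test_idempotent_on_reconstructed_records(self, a, b):
        call = loh.call_genotype(rec(max(a, b), min(a, b)))
        again = loh.call_genotype(rec(call.both_depth - call.minor_depth,
                                      call.minor_depth))
        assert again.state == call.state
        assert again.minor_depth == call.minor_depth


def _calls(states_by_sample, chrom="chr1", pos=100):
    """Build genotype-call maps from {sample: (ref_d, alt_d)}."""
    out = {}
    for sample, depth_list in states_by_sample.items():
        out[sample] = {}
        for i, depths in enumerate(depth_list):
            p = pos + 10 * i
            out[sample][(chrom, p)] = loh.call_genotype(
                rec(*depths, pos=p, sample=sample))
    return out


class TestLohSites:
    def test_definition_and_sharing(self):
        calls = _calls({
            "founder": [(20, 10), (20, 10), (20, 10)],
            "kid1": [(33, 0), (30, 4), (20, 10)],   # LOH, ambiguous, het
            "kid2": [(33, 0), (33, 0), (20, 10)],   # shares site 1
        })
        sites = loh.call_loh_sites(calls, "founder", "kid1")
        assert [s.pos for s in sites] == [100]
        assert not sites[0].unique  # kid2 is homozygous there too
        sites2 = loh.call_loh_sites(calls, "founder", "kid2")
        assert [(s.pos, s.unique) for s in sites2] == [(100, False),
                                                       (110, True)]

    def test_focal_must_differ_from_founder(self):
        calls = _calls({"founder": [(20, 10)]})
        with pytest.raises(ValueError):
            loh.call_loh_sites(calls, "founder", "founder")

    def test_mask_excludes_indel_adjacent_sites(self):
        from amphikit.io import Interval
        calls = _calls({"founder": [(20, 10)], "kid": [(33, 0)]})
        sites = loh.call_loh_sites(calls, "founder", "kid",
                                   mask=[Interval("chr1", 95, 105)])
        assert sites == []

    def test_unique_sites_lie_in_injected_tracts(self):
        cfg = simdata.SimConfig(
            n_chromosomes=2, chrom_length=300_000, ploidy=3,
            pairwise_divergence=0.005, depth_per_haplotype=50 / 3,
            conversion_rate=1.0, tract_length_mean=20_000,
            substitution_rate=0.0, generations=2, seed=71)
        ped = simdata.simulate_pedigree(cfg, n_lines=2)
        records = simdata.pedigree_depths(ped, cfg)
        calls = {s: loh.genotype_sample(r) for s, r in records.items()}
        focal = list(ped.samples)[0]
        convs = ped.truths[focal].conversions()
        assert convs, "expected conversions at this rate"
        sites = [s for s in loh.call_loh_sites(calls, "founder", focal)
                 if s.unique]
        assert len(sites) > 20
        in_tract = [any(c.chrom == s.chrom and c.start <= s.pos - 1 < c.end
                        for c in convs) for s in sites]
        assert np.mean(in_tract) >= 0.95  # truth-ledger precision


class TestTracts:
    def _sites(self, positions, chrom="chr1"):
        return [loh.LohSite(chrom=chrom, pos=p, retained_allele="A",
                            founder_minor_depth=10) for p in positions]

    def test_close_sites_form_one_tract(self):
        asm = loh.assemble_tracts(self._sites([1000, 2000, 3000, 4000, 5000]),
                                  max_gap_bp=10_000)
        assert len(asm.tracts) == 1 and asm.tracts[0].n_sites == 5
        assert asm.tracts[0].start == 999 and asm.tracts[0].end == 5000

    def test_distant_clusters_split(self):
        asm = loh.assemble_tracts(
            self._sites([1000, 2000, 3000, 1_001_000, 1_002_000, 1_003_000]),
            max_gap_bp=10_000)
        assert len(asm.tracts) == 2

    def test_small_runs_become_singletons_not_dropped(self):
        asm = loh.assemble_tracts(self._sites([1000, 500_000]),
                                  max_gap_bp=10_000, min_sites=3)
        assert len(asm.tracts) == 0 and len(asm.singletons) == 2
        total = sum(t.n_sites for t in asm.all_tracts())
        assert total == 2  # partition: every site in exactly one tract

    def test_injected_tract_recovered_with_reciprocal_overlap(self):
        cfg = simdata.SimConfig(
            n_chromosomes=1, chrom_length=300_000, ploidy=3,
            pairwise_divergence=0.001, depth_per_haplotype=50 / 3,
            conversion_rate=0.0, substitution_rate=0.0, seed=73)
        genome, _ = simdata.simulate_founder(cfg)
        child = genome.copy()
        truth = simdata.SimTruth()
        start, end = 100_000, 150_000
        simdata.inject_conversion(child, truth, "chr01A", 0, 1, start, end)
        ped = simdata.Pedigree(genome, {"kid": child}, {"kid": truth},
                               {"kid": 1})
        records = simdata.pedigree_depths(ped, cfg)
        calls = {s: loh.genotype_sample(r) for s, r in records.items()}
        sites = loh.call_loh_sites(calls, "founder", "kid")
        asm = loh.assemble_tracts(sorted(sites, key=lambda s: s.pos),
                                  max_gap_bp=20_000)
        assert len(asm.tracts) == 1
        t = asm.tracts[0]
        overlap = min(t.end, end) - max(t.start, start)
        assert overlap / (end - start) >= 0.8
        assert overlap / (t.end - t.start) >= 0.8

    def test_unsorted_sites_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            loh.assemble_tracts(self._sites([2000, 1000]), max_gap_bp=10_000)


class TestTractClassification:
    def _tract(self, start=10_000, end=30_000):
        sites = [loh.LohSite(chrom="chr1", pos=p, retained_allele="A",
                             founder_minor_depth=10)
                 for p in range(start + 1, end, 5_000)]
        return loh.LohTract(chrom="chr1", start=start, end=end, sites=sites)

    def _track(self, depth, chrom="chr1", length=100_000, window=5_000):
        import pandas as pd
        rows = [(chrom, s, s + window, 10, depth)
                for s in range(0, length, window)]
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "n_probes", "mean_depth"])

    def test_deletion_at_two_thirds_depth(self):
        t = loh.classify_tract(self._tract(), self._track(33.0), 50.0)
        assert t.kind == loh.KIND_DELETION
        assert all(s.kind == loh.KIND_DELETION for s in t.sites)

    def test_conversion_preserves_depth(self):
        t = loh.classify_tract(self._tract(), self._track(50.0), 50.0)
        assert t.kind == loh.KIND_CONVERSION

    def test_boundary_case_above_cut_is_conversion(self):
        # ratio 0.84 just above the 5/6 midpoint cut
        t = loh.classify_tract(self._tract(), self._track(42.0), 50.0)
        assert t.kind == loh.KIND_CONVERSION

    def test_missing_depth_unclassified(self):
        track = self._track(50.0).iloc[:1]  # covers only 5 kb of 20 kb
        t = loh.classify_tract(self._tract(), track, 50.0)
        assert t.kind == loh.KIND_UNCLASSIFIED


class TestRates:
    def _tracts(self, n_unique, kind):
        sites = [loh.LohSite(chrom="chr1", pos=1000 + 10 * i,
                             retained_allele="A", founder_minor_depth=10,
                             unique=i < n_unique, kind=kind)
                 for i in range(n_unique + 2)]
        for s in sites[n_unique:]:
            s.unique = False
        t = loh.LohTract(chrom="chr1", start=999, end=sites[-1].pos,
                         sites=sites, kind=kind)
        return [t]

    def test_rate_arithmetic(self):
        rates = loh.estimate_loh_rates(
            {"kid": self._tracts(30, loh.KIND_CONVERSION)},
            assayed_het_sites={"kid": 100_000},
            generations={"kid": 2})
        assert rates["loh"].rate == pytest.approx(1.5e-4)
        assert rates["gene_conversion"].rate == pytest.approx(1.5e-4)
        assert rates["gene_deletion"].rate == 0.0

    def test_pooled_equals_sum_over_individuals(self):
        tracts = {"a": self._tracts(10, loh.KIND_CONVERSION),
                  "b": self._tracts(5, loh.KIND_DELETION)}
        rates = loh.estimate_loh_rates(
            tracts, assayed_het_sites={"a": 50_000, "b": 25_000},
            generations={"a": 2, "b": 4})
        r = rates["loh"]
        assert r.m == 15
        assert r.denominator == 50_000 * 2 + 25_000 * 4
        assert r.rate == pytest.approx(r.m / r.denominator)
        assert sum(m for _, m, _, _ in r.per_individual) == r.m
        # conversion + deletion partition the LOH sites
        assert rates["gene_conversion"].m + rates["gene_deletion"].m == r.m

    def test_zero_events_zero_rate(self):
        rates = loh.estimate_loh_rates(
            {"kid": []}, assayed_het_sites={"kid": 1000},
            generations={"kid": 1})
        assert rates["loh"].rate == 0.0

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            loh.estimate_loh_rates({"kid": []},
                                   assayed_het_sites={"kid": 0},
                                   generations={"kid": 1})

    def test_conversion_rate_recovered_within_factor_two(self):
        # gamma tuned so the per-het-site LOH rate is ~1.5e-4 per generation:
        # rate = gamma * (tract_len / L) * (1/3)  =>  gamma = 3 L rate / len.
        # Short tracts pooled over multi-line pedigrees keep the compound-
        # Poisson dispersion of the site count small enough for a factor-2
        # check.
        target = 1.5e-4
        length, tract_len = 500_000, 1_000
        cfg_proto = dict(
            n_chromosomes=2, chrom_length=length, ploidy=3,
            pairwise_divergence=0.005, depth_per_haplotype=50 / 3,
            conversion_rate=target * 3 * length / tract_len,
            tract_length_mean=tract_len, substitution_rate=0.0, generations=2)
        m_total, denom_total = 0, 0.0
        for rep in range(10):
            cfg = simdata.SimConfig(**cfg_proto, seed=100 + rep)
            ped = simdata.simulate_pedigree(cfg, n_lines=5)
            records = simdata.pedigree_depths(ped, cfg)
            calls = {s: loh.genotype_sample(r) for s, r in records.items()}
            for focal in ped.samples:
                sites = [s for s in
                         loh.call_loh_sites(calls, "founder", focal)
                         if s.unique]
                het = loh.count_assayed_het_sites(calls["founder"],
                                                  calls[focal])
                m_total += len(sites)
                denom_total += het * cfg.generations
        rate = m_total / denom_total
        assert target / 2 <= rate <= target * 2


class TestSubstitutions:
    def test_rate_arithmetic(self):
        est = loh.estimate_mutation_rate(m=9, n_sites=10**6, generations=3)
        assert est.rate == pytest.approx(1e-6)
        assert loh.estimate_mutation_rate(0, 10**6, 3).rate == 0.0
        with pytest.raises(ValueError):
            loh.estimate_mutation_rate(1, 10**6, 0)

    def test_single_line_het_required(self):
        calls = _calls({
            "founder": [(33, 0), (33, 0), (33, 0)],
            "l1": [(20, 10), (20, 10), (30, 4)],
            "l2": [(33, 0), (20, 10), (33, 0)],
        })
        out = loh.call_substitutions(calls, "founder", ["l1", "l2"])
        # site 0: only l1 het -> mutation; site 1: two het lines -> no;
        # site 2: l1 ambiguous -> no
        assert [(m.pos, m.line) for m in out] == [(100, "l1")]

    def test_non_baseline_chromosome_excluded_per_line(self):
        calls = _calls({"founder": [(33, 0)], "l1": [(20, 10)],
                        "l2": [(33, 0)]})
        out = loh.call_substitutions(calls, "founder", ["l1", "l2"],
                                     excluded_chroms={"l1": {"chr1"}})
        assert out == []

    def test_poisson_recovery_of_mutation_rate(self):
        mu, length, gens = 1e-6, 1_000_000, 4
        cfg_proto = dict(n_chromosomes=1, chrom_length=length, ploidy=3,
                         pairwise_divergence=0.0, depth_per_haplotype=50 / 3,
                         conversion_rate=0.0, substitution_rate=mu,
                         generations=gens)
        estimates = []
        for rep in range(50):
            cfg = simdata.SimConfig(**cfg_proto, seed=300 + rep)
            ped = simdata.simulate_pedigree(cfg, n_lines=1)
            focal = list(ped.samples)[0]
            records = simdata.pedigree_depths(ped, cfg)
            calls = {s: loh.genotype_sample(r) for s, r in records.items()}
            m = len(loh.call_substitutions(calls, "founder", [focal]))
            estimates.append(
                loh.estimate_mutation_rate(m, length, gens).rate)
        # per replicate, expected mutations = 3 * L * mu * T = 12
        se = math.sqrt(12 / 50) / (3 * length * gens)
        assert abs(np.mean(estimates) - mu) < 3 * se

    def test_loh_rate_much_higher_than_substitution_rate(self):
        cfg = simdata.SimConfig(
            n_chromosomes=2, chrom_length=200_000, ploidy=3,
            pairwise_divergence=0.005, depth_per_haplotype=50 / 3,
            conversion_rate=1.0, tract_length_mean=10_000,
            substitution_rate=8.88e-9, generations=2, seed=91)
        ped = simdata.simulate_pedigree(cfg, n_lines=1)
        focal = list(ped.samples)[0]
        records = simdata.pedigree_depths(ped, cfg)
        calls = {s: loh.genotype_sample(r) for s, r in records.items()}
        sites = [s for s in loh.call_loh_sites(calls, "founder", focal)
                 if s.unique]
        het = loh.count_assayed_het_sites(calls["founder"], calls[focal])
        loh_rate = len(sites) / (het * cfg.generations)
        m = len(loh.call_substitutions(calls, "founder", [focal]))
        sub_rate = loh.estimate_mutation_rate(
            m, cfg.chrom_length * cfg.n_chromosomes, cfg.generations).rate
        assert loh_rate > 100 * sub_rate
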