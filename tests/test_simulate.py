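"""Simulator contracts: determinism, Hardy-Weinberg structure, scenario
planting, depth model, and file round trips."""

import numpy as np
import pytest

from mendelscope.filters import (
    FilterScenario,
    filter_compound_het,
    filter_dominant_private,
    filter_recessive_hom,
)
from mendelscope.io import read_coverage, read_ped, read_vcf, write_coverage, write_ped, write_vcf
from mendelscope.origin import test_mosaicism as _test_mosaicism
from mendelscope.simulate import (
    DEFAULT_GENOME,
    SimulationConfig,
    simulate_allele_depths,
    simulate_cohort,
    simulate_coverage,
    simulate_family,
    simulate_tissue_depths,
)


def scenario_for(ds, moi):
    case_ids = tuple(s.id for s in ds.pedigree if s.role == "case")
    by_id = {s.id for s in ds.pedigree}
    design = ds.config.design
    parent_map = {
        cid: (
            "sire" if "sire" in by_id and design != "single_case" else None,
            "dam" if "dam" in by_id and design == "trio" else None,
        )
        for cid in case_ids
    }
    return FilterScenario(
        moi_hypothesis=moi,
        design=design,
        case_ids=case_ids,
        control_ids=tuple(s.id for s in ds.pedigree if s.role == "control"),
        parent_map=parent_map,
    )


class TestCohort:
    def test_seeded_runs_are_identical(self):
        cfg = SimulationConfig(seed=42, n_controls=50, n_background_variants=100)
        f1, g1 = simulate_cohort(cfg)
        f2, g2 = simulate_cohort(cfg)
        assert np.array_equal(f1, f2) and np.array_equal(g1, g2)

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(seed=1))[1]
        b = simulate_cohort(SimulationConfig(seed=2))[1]
        assert not np.array_equal(a, b)

    def test_hardy_weinberg_het_fraction(self):
        """1000 controls at frequency ~0.5 show ~50% heterozygotes."""
        cfg = SimulationConfig(seed=3, n_controls=1000, n_background_variants=400,
                               beta_a=50, beta_b=50, freq_min=0.45, freq_max=0.55)
        freqs, geno = simulate_cohort(cfg)
        het = (geno == 1).mean()
        expected = np.mean(2 * freqs * (1 - freqs))
        assert abs(het - expected) < 0.04

    def test_frequencies_respect_truncation(self):
        freqs, _ = simulate_cohort(SimulationConfig(seed=4, n_background_variants=2000))
        assert freqs.min() >= 0.01 and freqs.max() <= 0.99


class TestScenarios:
    def test_recessive_planted_variant_is_recovered(self):
        cfg = SimulationConfig(seed=11, scenario="recessive_hom", n_controls=500)
        ds = simulate_family(cfg)
        res = filter_recessive_hom(ds.variants, scenario_for(ds, "recessive_hom"))
        assert [v.key for v in res.retained] == ds.truth.planted_keys

    def test_compound_het_planted_pair_is_the_only_hit(self):
        cfg = SimulationConfig(seed=12, scenario="compound_het", n_controls=500)
        ds = simulate_family(cfg)
        res = filter_compound_het(ds.variants, scenario_for(ds, "recessive_compound_het"))
        pairs = [pair for pairs in res.gene_pairs.values() for pair in pairs]
        assert len(pairs) == 1
        assert sorted([pairs[0][0].key, pairs[0][1].key]) == sorted(ds.truth.planted_keys)

    def test_de_novo_dominant_recovered(self):
        cfg = SimulationConfig(seed=13, scenario="de_novo_dominant", n_controls=500)
        ds = simulate_family(cfg)
        res = filter_dominant_private(ds.variants, scenario_for(ds, "dominant_private"))
        assert ds.truth.planted_keys[0] in [v.key for v in res.retained]

    def test_mosaic_sire_semen_detection_power(self):
        """Fraction-0.1 mosaicism at ~40x semen depth detected in >= 80%
        of seeds (exact binomial power)."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, scenario="mosaic_sire", design="half_sibs",
                                   n_cases=2, n_controls=20, n_background_variants=20)
            ds = simulate_family(cfg)
            tissues = simulate_tissue_depths(ds)
            alt, depth = tissues["semen"]
            if _test_mosaicism(alt, depth) == "low_level_mosaic":
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_incompatible_scenario_design_errors(self):
        with pytest.raises(ValueError, match="trio"):
            SimulationConfig(scenario="de_novo_dominant", design="half_sibs")
        with pytest.raises(ValueError, match="half-sib"):
            SimulationConfig(scenario="mosaic_sire", design="trio")

    def test_no_scenario_leakage(self):
        """Under scenario=none the MOI filters come back (nearly) empty."""
        clean = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, scenario="none", n_controls=500)
            ds = simulate_family(cfg)
            n_hits = len(
                filter_recessive_hom(ds.variants, scenario_for(ds, "recessive_hom")).retained
            ) + len(
                filter_dominant_private(ds.variants, scenario_for(ds, "dominant_private")).retained
            )
            clean += n_hits == 0
        assert clean >= 0.95 * n_seeds


class TestDepths:
    def test_hom_ref_with_zero_error_has_no_alt_reads(self):
        cfg = SimulationConfig(seed=5, error_rate=0.0, n_controls=30,
                               n_background_variants=50)
        ds = simulate_allele_depths(simulate_family(cfg))
        for v in ds.variants:
            for c in v.calls.values():
                if c.dosage == 0:
                    assert c.alt_depth == 0

    def test_het_fraction_near_half(self):
        cfg = SimulationConfig(seed=6, n_controls=100, n_background_variants=100)
        ds = simulate_allele_depths(simulate_family(cfg))
        alt = total = 0
        for v in ds.variants:
            for c in v.calls.values():
                if c.dosage == 1 and c.total_depth:
                    alt += c.alt_depth
                    total += c.total_depth
        assert total > 10_000
        assert abs(alt / total - 0.5) < 0.02

    def test_trisomic_sites_pool_to_two_thirds(self):
        cfg = SimulationConfig(seed=7, scenario="trisomy", n_controls=5,
                               n_background_variants=10, n_informative_sites=400)
        ds = simulate_allele_depths(simulate_family(cfg))
        alt = total = 0
        for v in ds.variants:
            if ds.truth.alt_copies_of_three.get(v.key) == 2:
                c = v.calls["case"]
                alt += c.alt_depth
                total += c.total_depth
        assert total > 3000
        assert abs(alt / total - 2 / 3) < 0.02


class TestCoverage:
    def test_male_x_half_of_autosomal_mean(self):
        cfg = SimulationConfig(seed=8)
        windows = simulate_coverage(cfg, sex="male")
        auto = np.mean([w.count for w in windows
                        if w.interval.chrom.startswith("Chr") and
                        w.interval.chrom not in ("ChrX", "ChrY") and not w.partial])
        x = np.mean([w.count for w in windows if w.interval.chrom == "ChrX" and not w.partial])
        assert abs(x / auto - 0.5) < 0.02

    def test_planted_events_shift_means(self):
        tri = simulate_coverage(SimulationConfig(seed=9, scenario="trisomy",
                                                 event_chrom="Chr2"), "male")
        auto = np.mean([w.count for w in tri if w.interval.chrom == "Chr1" and not w.partial])
        event = np.mean([w.count for w in tri if w.interval.chrom == "Chr2" and not w.partial])
        assert abs(event / auto - 1.5) < 0.03
        mono_cfg = SimulationConfig(seed=9, scenario="terminal_monosomy", event_chrom="Chr2")
        mono = simulate_coverage(mono_cfg, "male")
        seg = mono_cfg.genome[1].length - mono_cfg.terminal_loss_length
        tail = np.mean([w.count for w in mono
                        if w.interval.chrom == "Chr2" and w.interval.start > seg and not w.partial])
        assert abs(tail / auto - 0.5) < 0.03

    def test_window_larger_than_chromosome_yields_single_partial(self):
        from mendelscope.simulate import Chromosome
        cfg = SimulationConfig(seed=10, genome=(Chromosome("Chr1", 4000, "autosome"),),
                               window_size=10_000)
        windows = simulate_coverage(cfg, "male")
        assert len(windows) == 1 and windows[0].partial and windows[0].width == 4000


class TestRoundTrip:
    def test_emitted_files_reproduce_in_memory_truth(self, tmp_path):
        cfg = SimulationConfig(seed=21, scenario="recessive_hom", n_controls=20,
                               n_background_variants=30)
        ds = simulate_allele_depths(simulate_family(cfg))
        vcf, ped, cov = (str(tmp_path / n) for n in ("c.vcf", "c.ped", "c.tsv"))
        write_vcf(ds.variants, vcf, ds.sample_ids,
                  {c.name: c.length for c in cfg.genome})
        write_ped(ds.pedigree, ped)
        write_coverage(simulate_coverage(cfg, "male"), cov)

        back_ped = read_ped(ped)
        assert [s.id for s in back_ped] == ds.sample_ids
        back = read_vcf(vcf, sex_by_sample={s.id: s.sex for s in back_ped})
        assert [v.key for v in back] == [v.key for v in ds.variants]
        for orig, rt in zip(ds.variants, back):
            for sid in ds.sample_ids:
                assert rt.calls[sid].dosage == orig.calls[sid].dosage
                assert rt.calls[sid].alt_depth == orig.calls[sid].alt_depth
        back_cov = read_coverage(cov, cfg.window_size)
        assert len(back_cov) == sum(-(-c.length // cfg.window_size) for c in cfg.genome)
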