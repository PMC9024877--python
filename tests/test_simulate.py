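"""Synthetic genomes: exact planted recovery, determinism, GC control."""

import numpy as np
import pytest

from ssrsurvey import (
    CSSRPlan,
    DensityModel,
    PlantConfig,
    build_cssrs,
    classify_regions,
    generate_cohort,
    generate_genome,
    scan_ssrs,
)
from ssrsurvey.errors import ConfigError
from ssrsurvey.scan import ScanParams
from scipy import stats as sps


def test_planted_recovery_exact(small_planted):
    """Scan + compound assembly + region calls reproduce the truth exactly."""
    cfg, (rec, ann, truth) = small_planted
    ssrs = scan_ssrs(rec)
    assert [s.key() for s in ssrs] == [t.key() for t in truth.ssrs]
    cssrs, in_cssr = build_cssrs(ssrs, cfg.dmax)
    assert [c.key() for c in cssrs] == [t.key() for t in truth.cssrs]
    assert sum(in_cssr) == sum(t.complexity for t in truth.cssrs)
    assert classify_regions(ssrs, ann) == truth.ssr_regions
    assert classify_regions(cssrs, ann) == truth.cssr_regions


def test_truth_loci_satisfy_invariants(small_planted):
    cfg, (rec, ann, truth) = small_planted
    seqs = dict(rec.contigs)
    for s in truth.ssrs:
        assert s.length == s.period * s.repeats
        assert seqs[s.contig_id][s.start - 1 : s.end] == s.motif * s.repeats
    for c in truth.cssrs:
        assert c.complexity >= 2
        for a, b in zip(c.members, c.members[1:]):
            gap = b.start - a.end - 1
            assert 0 <= gap <= cfg.dmax
        assert c.span_length >= sum(m.length for m in c.members)


def test_same_seed_same_genome():
    cfg = PlantConfig(genome_size=20_000, gc_content=0.55, seed=77,
                      ssr_plan=(("A", 6, 5),), cds_fraction=0.7)
    a = generate_genome(cfg)
    b = generate_genome(cfg)
    assert a[0].contigs == b[0].contigs
    assert a[1].cds_intervals == b[1].cds_intervals
    assert [s.key() for s in a[2].ssrs] == [s.key() for s in b[2].ssrs]


def test_background_gc_near_target():
    # binomial concentration: at 200 kb, 6 sd is about 0.0067
    cfg = PlantConfig(genome_size=200_000, gc_content=0.60, seed=5)
    rec, ann, truth = generate_genome(cfg)
    assert truth.background_gc == pytest.approx(0.60, abs=0.01)
    assert ann is None
    assert truth.cleaning_passes >= 1  # cleaning ran and terminated


def test_clean_background_scans_empty():
    cfg = PlantConfig(genome_size=30_000, gc_content=0.45, seed=9)
    rec, _, truth = generate_genome(cfg)
    assert truth.ssrs == [] and scan_ssrs(rec) == []


def test_features_that_do_not_fit_rejected_before_sampling():
    with pytest.raises(ConfigError, match="clearance"):
        generate_genome(
            PlantConfig(genome_size=150, gc_content=0.5, seed=1,
                        ssr_plan=(("A", 6, 20),))
        )


def test_below_threshold_plant_rejected():
    with pytest.raises(ConfigError, match="threshold"):
        generate_genome(
            PlantConfig(genome_size=10_000, gc_content=0.5, seed=1,
                        ssr_plan=(("A", 5, 1),))
        )


def test_impossible_compound_plan_rejected():
    # abutting mono-A then AC: the junction A always extends the first run
    with pytest.raises(ConfigError, match="scanner-consistent"):
        generate_genome(
            PlantConfig(genome_size=10_000, gc_content=0.5, seed=1,
                        cssr_plan=(CSSRPlan(("A", "AC"), (6, 3), (0,)),))
        )


def test_gap_above_dmax_rejected():
    with pytest.raises(ConfigError, match="gap"):
        PlantConfig(genome_size=10_000, gc_content=0.5, seed=1, dmax=10,
                    cssr_plan=(CSSRPlan(("A", "AC"), (6, 3), (11,)),))


def test_multi_contig_sizes_and_ids():
    cfg = PlantConfig(genome_size=10_001, gc_content=0.5, seed=3, n_contigs=3)
    rec, _, _ = generate_genome(cfg)
    assert rec.total_length == 10_001
    assert [c for c, _ in rec.contigs] == ["contig_1", "contig_2", "contig_3"]


def test_cohort_proportional_without_noise_gives_rho_one():
    dm = DensityModel(ssr_per_kb=2.0, cssr_per_kb=0.0, relative_noise=0.0)
    cohort = generate_cohort(n=6, size_range=(20_000, 60_000),
                             gc_range=(0.5, 0.6), density_model=dm, seed=11,
                             cds_fraction=None)
    sizes = np.array([rec.total_length for rec, _, _ in cohort], float)
    planted = np.array([len(t.ssrs) for _, _, t in cohort], float)
    rho, _ = sps.pearsonr(sizes, planted)
    assert rho == pytest.approx(1.0, abs=0.005)


def test_cohort_preconditions_and_determinism():
    with pytest.raises(ConfigError):
        generate_cohort(n=1, seed=1)
    with pytest.raises(ConfigError):
        generate_cohort(n=3, size_range=(50_000, 10_000), seed=1)
    dm = DensityModel(ssr_per_kb=1.0, cssr_per_kb=0.05)
    a = generate_cohort(n=3, size_range=(15_000, 25_000), gc_range=(0.5, 0.6),
                        density_model=dm, seed=42, cds_fraction=None)
    b = generate_cohort(n=3, size_range=(15_000, 25_000), gc_range=(0.5, 0.6),
                        density_model=dm, seed=42, cds_fraction=None)
    assert [r.contigs for r, _, _ in a] == [r.contigs for r, _, _ in b]


def test_cohort_recovery_and_complexity():
    dm = DensityModel(ssr_per_kb=2.0, cssr_per_kb=0.3)
    cohort = generate_cohort(n=3, size_range=(30_000, 50_000),
                             gc_range=(0.52, 0.64), density_model=dm, seed=8)
    for rec, ann, truth in cohort:
        ssrs = scan_ssrs(rec)
        assert [s.key() for s in ssrs] == [t.key() for t in truth.ssrs]
        cssrs, _ = build_cssrs(ssrs, 10)
        assert [c.key() for c in cssrs] == [t.key() for t in truth.cssrs]
        assert all(c.complexity >= 2 for c in cssrs)
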