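"""Compound assembly: the dmax gap rule, maximality, spectrum, unique motifs."""

import numpy as np
import pytest

from ssrsurvey import build_cssrs, complexity_spectrum, unique_compound_motifs
from ssrsurvey.scan import SSRLocus, standardize_motif

from _oracles import chain_components


def mk(start, motif, repeats, contig="c1", genome="g1"):
    period = len(motif)
    return SSRLocus(
        genome_id=genome, contig_id=contig, start=start,
        end=start + period * repeats - 1, period=period, motif=motif,
        standard_motif=standardize_motif(motif), repeats=repeats,
    )


def test_two_ssrs_within_dmax_chain():
    loci = [mk(1, "A", 6), mk(12, "AC", 3)]  # gap = 12 - 6 - 1 = 5
    cssrs, in_cssr = build_cssrs(loci, dmax=10)
    assert len(cssrs) == 1
    c = cssrs[0]
    assert (c.start, c.end, c.complexity, c.span_length) == (1, 17, 2, 17)
    assert c.compound_motif == "A-AC"
    assert in_cssr == [True, True]


def test_gap_above_dmax_keeps_ssrs_individual():
    loci = [mk(1, "A", 6), mk(18, "AC", 3)]  # gap = 11
    cssrs, in_cssr = build_cssrs(loci, dmax=10)
    assert cssrs == []
    assert in_cssr == [False, False]


def test_maximality_three_members():
    loci = [mk(1, "A", 6), mk(10, "AC", 3), mk(20, "AGC", 3)]
    cssrs, _ = build_cssrs(loci, dmax=10)
    assert len(cssrs) == 1
    assert cssrs[0].complexity == 3
    assert cssrs[0].compound_motif == "A-AC-AGC"


def test_abutting_is_gap_zero():
    loci = [mk(1, "A", 6), mk(7, "AC", 3)]
    cssrs, _ = build_cssrs(loci, dmax=0)
    assert len(cssrs) == 1


def test_chains_do_not_cross_contigs():
    loci = [mk(1, "A", 6, contig="c1"), mk(9, "AC", 3, contig="c2")]
    cssrs, _ = build_cssrs(loci, dmax=50)
    assert cssrs == []


def test_unsorted_or_overlapping_input_rejected():
    with pytest.raises(ValueError):
        build_cssrs([mk(10, "A", 6), mk(1, "AC", 3)])
    with pytest.raises(ValueError):
        build_cssrs([mk(1, "A", 6), mk(3, "AC", 3)])


@pytest.mark.parametrize("dmax", [0, 1, 10, 50])
def test_chain_assembly_matches_transitive_closure(dmax):
    """Maximal chains equal the connected components of the proximity relation."""
    rng = np.random.default_rng(dmax + 7)
    for _ in range(25):
        loci = []
        pos = 1
        for _ in range(int(rng.integers(2, 50))):
            motif = ["A", "AC", "AGC"][int(rng.integers(0, 3))]
            reps = 6 if motif == "A" else 3
            loci.append(mk(pos, motif, reps))
            pos = loci[-1].end + 1 + int(rng.integers(0, 60))
        cssrs, in_cssr = build_cssrs(loci, dmax)
        spans = [(l.start, l.end) for l in loci]
        expected = chain_components(spans, dmax)
        got = [
            [loci.index(m) for m in c.members] for c in cssrs
        ]
        assert got == expected
        member_idx = {i for comp in expected for i in comp}
        assert [i in member_idx for i in range(len(loci))] == in_cssr


def test_dmax_monotonicity():
    """Larger dmax never reduces member count, never adds singletons."""
    rng = np.random.default_rng(3)
    loci = []
    pos = 1
    for _ in range(60):
        loci.append(mk(pos, "AC", 3))
        pos = loci[-1].end + 1 + int(rng.integers(0, 30))
    prev_members, prev_singles = -1, len(loci) + 1
    for dmax in (0, 2, 5, 10, 25, 50):
        cssrs, in_cssr = build_cssrs(loci, dmax)
        members = sum(c.complexity for c in cssrs)
        singles = in_cssr.count(False)
        assert members >= prev_members
        assert singles <= prev_singles
        assert members >= 2 * len(cssrs)  # equality iff all complexity 2
        prev_members, prev_singles = members, singles


def test_complexity_spectrum_counts_and_proportions():
    loci = [mk(1, "A", 6), mk(10, "AC", 3), mk(40, "A", 6), mk(50, "AC", 3), mk(60, "AGC", 3)]
    cssrs, _ = build_cssrs(loci, dmax=10)
    counts, props = complexity_spectrum(cssrs)
    assert counts == {2: 1, 3: 1}
    assert props == {2: 0.5, 3: 0.5}
    assert complexity_spectrum([]) == ({}, {})
    assert min(counts) >= 2


def test_unique_compound_motifs():
    a = build_cssrs([mk(1, "A", 6), mk(10, "AC", 3)], 10)[0]          # A-AC
    b = build_cssrs([mk(1, "A", 6), mk(10, "AGC", 3)], 10)[0]         # A-AGC
    per_genome, total = unique_compound_motifs({"g1": a + b, "g2": a})
    assert per_genome == {"g1": 1, "g2": 0}
    assert total == 1
    # single-genome cohort: everything unique; within-genome duplicates count once
    per_genome, total = unique_compound_motifs({"solo": a + a + b})
    assert per_genome == {"solo": 2}
    assert total == 2
    with pytest.raises(ValueError):
        unique_compound_motifs({})
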