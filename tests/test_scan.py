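"""SSR scanner: worked examples, oracle equivalence, motif canonicalization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrsurvey import ScanParams, enumerate_standard_motifs, scan_sequence, standardize_motif
from ssrsurvey.errors import ConfigError
from ssrsurvey.scan import DEFAULT_MIN_REPEATS, has_minimal_period, reverse_complement

from _oracles import brute_force_scan
from conftest import random_sequence


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("AAAAAA", [(1, 6, "A", 6)]),               # threshold boundary
        ("AAAAA", []),                              # one copy short
        ("ATATATATA", [(1, 8, "AT", 4)]),           # trailing partial copy truncated
        ("ACACAC", [(1, 6, "AC", 3)]),              # reported once, at minimal period
        ("AAAAAANAAAAAA", [(1, 6, "A", 6), (8, 13, "A", 6)]),  # N breaks runs
        ("", []),
        ("GGGGGGGG", [(1, 8, "G", 8)]),
        ("ACGACGACGAC", [(1, 9, "ACG", 3)]),
    ],
)
def test_scan_examples(seq, expected):
    got = [(l.start, l.end, l.motif, l.repeats) for l in scan_sequence(seq)]
    assert got == expected


def test_scan_locus_fields():
    (locus,) = scan_sequence("ATATATATA", genome_id="g", contig_id="c1")
    assert locus.period == 2
    assert locus.length == 8 == locus.period * locus.repeats
    assert locus.standard_motif == "AT"
    assert (locus.genome_id, locus.contig_id) == ("g", "c1")


def test_minimal_period_never_reported_as_longer():
    # a pure AC run must not additionally appear as period 4 or 6
    loci = scan_sequence("AC" * 12)
    assert [(l.period, l.repeats) for l in loci] == [(2, 12)]


def test_custom_thresholds():
    params = ScanParams(min_repeats={1: 6, 2: 5, 3: 3, 4: 3, 5: 3, 6: 3})
    assert scan_sequence("ATATATAT", params) == []
    assert len(scan_sequence("ATATATATAT", params)) == 1


@pytest.mark.parametrize("bad", [{1: 1}, {}, {1: 6, 2: 3}])
def test_invalid_params_rejected(bad):
    with pytest.raises(ConfigError):
        ScanParams(min_repeats=bad)


@pytest.mark.parametrize("gc", [0.3, 0.5, 0.65])
def test_scanner_matches_brute_force(gc):
    """Greedy scanner equals the naive enumerator on random sequences."""
    rng = np.random.default_rng(int(gc * 100))
    for _ in range(30):
        seq = random_sequence(rng, 2000, gc)
        fast = [(l.start, l.end, l.motif, l.repeats) for l in scan_sequence(seq)]
        slow = brute_force_scan(seq, DEFAULT_MIN_REPEATS)
        assert fast == slow


def test_scanner_matches_brute_force_with_ambiguity():
    rng = np.random.default_rng(99)
    for _ in range(20):
        seq = list(random_sequence(rng, 1500, 0.4))
        for pos in rng.integers(0, 1500, size=30):
            seq[pos] = "N"
        seq = "".join(seq)
        fast = [(l.start, l.end, l.motif, l.repeats) for l in scan_sequence(seq)]
        assert fast == brute_force_scan(seq, DEFAULT_MIN_REPEATS)


def test_scan_determinism():
    rng = np.random.default_rng(5)
    seq = random_sequence(rng, 5000, 0.55)
    assert scan_sequence(seq) == scan_sequence(seq)


# --- motif standardization ----------------------------------------------------


@pytest.mark.parametrize(
    "motif,expected",
    [
        ("GT", "AC"),
        ("TC", "AG"),
        ("GCC", "CCG"),
        ("A", "A"),
        ("T", "A"),
        ("G", "C"),
        ("C", "C"),
        ("AT", "AT"),
        ("CG", "CG"),
    ],
)
def test_standardize_examples(motif, expected):
    assert standardize_motif(motif) == expected


def test_standardize_rejects_invalid():
    for bad in ("", "AN", "AU", "ax"):
        with pytest.raises(ValueError):
            standardize_motif(bad)


def _all_minimal_motifs(period):
    for tup in itertools.product("ACGT", repeat=period):
        m = "".join(tup)
        if has_minimal_period(m):
            yield m


@given(st.integers(1, 6), st.data())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_standardize_class_invariance(period, data):
    """Same value on every rotation and on the reverse complement."""
    motifs = list(_all_minimal_motifs(period))
    m = data.draw(st.sampled_from(motifs))
    std = standardize_motif(m)
    assert standardize_motif(std) == std  # idempotent
    assert standardize_motif(reverse_complement(m)) == std
    for i in range(len(m)):
        assert standardize_motif(m[i:] + m[:i]) == std


@pytest.mark.parametrize("period,size", [(1, 2), (2, 4), (3, 10), (4, 33), (5, 102), (6, 350)])
def test_standard_motif_class_sizes(period, size):
    """Canonical classes partition the minimal-period motifs of each length."""
    classes = enumerate_standard_motifs(period)
    assert len(classes) == size
    # brute-force partition: group all minimal motifs by canonical form
    groups = {}
    for m in _all_minimal_motifs(period):
        groups.setdefault(standardize_motif(m), set()).add(m)
    assert set(groups) == set(classes)
    assert sum(len(g) for g in groups.values()) == sum(1 for _ in _all_minimal_motifs(period))


def test_enumerate_rejects_bad_period():
    with pytest.raises(ValueError):
        enumerate_standard_motifs(7)
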