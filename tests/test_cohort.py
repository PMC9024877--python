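"""Cohort statistics: mean complexity, the Z index, Pearson correlations."""

import math

import numpy as np
import pytest

from ssrsurvey import mean_complexity, pearson_table, z_scores
from ssrsurvey.stats import GenomeSummary


def summary(gid, ncssr, ncssr_members, size=2_000_000, gc=0.55, nssr=5000):
    return GenomeSummary(
        genome_id=gid, genome_size=size, gc_content=gc, nSSR=nssr,
        nCSSR=ncssr, ncSSR=ncssr_members, cSSR_pct=0.0, RA_ssr=0.0,
        RD_ssr=0.0, RA_cssr=0.0, RD_cssr=0.0, type_counts={}, pattern="",
        pattern_tie=False, coding_fraction_ssr=None, coding_fraction_cssr=None,
    )


def test_mean_complexity_worked_example():
    s = [summary("a", 200, 400), summary("b", 150, 450)]
    assert mean_complexity(s) == pytest.approx((2.0 + 3.0) / 2)


def test_mean_complexity_degenerate_cases():
    assert mean_complexity([summary("a", 10, 20)]) == 2.0  # single genome
    with pytest.warns(UserWarning, match="excluded"):
        assert mean_complexity([summary("a", 10, 20), summary("b", 0, 0)]) == 2.0
    with pytest.raises(ValueError):
        with pytest.warns(UserWarning):
            mean_complexity([summary("a", 0, 0)])


def test_z_worked_example():
    s = [summary("a", 200, 400)]
    table = z_scores(s, c_bar=2.5)
    assert table.loc[0, "nCSSR_exp"] == pytest.approx(160.0)
    assert table.loc[0, "Z"] == pytest.approx(40 / math.sqrt(160), abs=1e-9)
    assert s[0].Z == table.loc[0, "Z"]  # summaries are filled in place


def test_z_zero_when_observed_equals_expected():
    s = [summary("a", 200, 500)]
    table = z_scores(s, c_bar=2.5)
    assert table.loc[0, "Z"] == 0.0


def test_z_sign_and_linear_switch():
    under = z_scores([summary("a", 100, 500)], 2.5).loc[0, "Z"]   # exp 200 > obs
    over = z_scores([summary("a", 300, 500)], 2.5).loc[0, "Z"]
    assert under < 0 < over
    lin = z_scores([summary("a", 300, 500)], 2.5, denominator="linear").loc[0, "Z"]
    assert lin == pytest.approx((300 - 200) / 200)
    with pytest.raises(ValueError):
        z_scores([summary("a", 1, 2)], 2.5, denominator="cubic")


def test_z_sums_to_zero_when_all_ratios_equal_cbar():
    s = [summary(f"g{i}", 100 * (i + 1), 250 * (i + 1)) for i in range(6)]
    c_bar = mean_complexity(s)  # every ratio is 2.5
    table = z_scores(s, c_bar)
    assert table["Z"].sum() == pytest.approx(0.0, abs=1e-12)
    # order invariance
    again = z_scores(list(reversed(s)), c_bar)
    assert sorted(table["Z"]) == pytest.approx(sorted(again["Z"]))


def test_pearson_exact_lines():
    s = [
        summary(f"g{i}", 10, 20, size=1_000_000 + 100_000 * i,
                nssr=2 * (1_000_000 + 100_000 * i) // 1000, gc=0.5 + 0.01 * i)
        for i in range(10)
    ]
    t = pearson_table(s, pairs=[("nSSR", "genome_size")])
    assert t.loc[0, "rho"] == pytest.approx(1.0)
    # anti-correlation
    for i, x in enumerate(s):
        x.nSSR = 10_000 - i * 100
    t = pearson_table(s, pairs=[("nSSR", "genome_size")])
    assert t.loc[0, "rho"] == pytest.approx(-1.0)


def test_pearson_self_and_zero_variance():
    s = [summary(f"g{i}", 10, 20, size=1_000_000 + i, nssr=100 + 7 * i) for i in range(5)]
    t = pearson_table(s, pairs=[("nSSR", "nSSR")])
    assert t.loc[0, "rho"] == pytest.approx(1.0)
    for x in s:
        x.nSSR = 42
    with pytest.warns(UserWarning, match="zero variance"):
        t = pearson_table(s, pairs=[("nSSR", "genome_size")])
    assert np.isnan(t.loc[0, "rho"])


def test_pearson_needs_three_genomes_and_known_variables():
    s = [summary("a", 1, 2), summary("b", 1, 2)]
    with pytest.raises(ValueError):
        pearson_table(s)
    s.append(summary("c", 1, 2))
    with pytest.raises(ValueError):
        pearson_table(s, pairs=[("nSSR", "bogus")])


def test_default_pairs_cover_both_counts():
    s = [
        summary(f"g{i}", 100 + i, 210 + 2 * i, size=2_000_000 + 50_000 * i,
                gc=0.55 + 0.002 * i, nssr=5_000 + 40 * i)
        for i in range(8)
    ]
    t = pearson_table(s)
    assert set(t["pair"]) == {
        "nSSR~genome_size", "nSSR~gc_content", "nSSR~ncSSR",
        "nCSSR~genome_size", "nCSSR~gc_content", "nCSSR~nSSR", "nCSSR~ncSSR",
    }
    assert ((t["rho"] <= 1) & (t["rho"] >= -1)).all()
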