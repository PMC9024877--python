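"""Cross-genome statistics: mean compound complexity, Z index, correlations.

The Z index asks whether a genome compounds its repeats more or less than
the cohort average.  With C_bar the cohort mean of per-genome ncSSR/nCSSR
(average members per compound locus), the expected compound-locus count for
genome i is

    nCSSR_exp_i = ncSSR_i / C_bar

and the index standardizes the observed deviation:

    Z_i = (nCSSR_obs_i - nCSSR_exp_i) / sqrt(nCSSR_exp_i)

a Poisson-like standardization; positive Z means more compound loci (less
aggregation per locus) than the cohort average implies.  A plain-ratio
denominator is available behind ``z_denominator="linear"`` and the choice
is recorded in the run manifest.

Pearson correlations among genome size, GC content, nSSR, nCSSR and ncSSR
use the product-moment coefficient with a two-sided p-value from the
t transform with n-2 degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GenomeSummary

__all__ = [
    "DEFAULT_PEARSON_PAIRS",
    "mean_complexity",
    "z_scores",
    "pearson_table",
    "CohortResult",
]

#: Variables available for correlation analysis.
_VARIABLES = ("genome_size", "gc_content", "nSSR", "nCSSR", "ncSSR")

#: Default pairs: nSSR and nCSSR each against size, GC and the other counts.
DEFAULT_PEARSON_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("nSSR", "genome_size"),
    ("nSSR", "gc_content"),
    ("nSSR", "ncSSR"),
    ("nCSSR", "genome_size"),
    ("nCSSR", "gc_content"),
    ("nCSSR", "nSSR"),
    ("nCSSR", "ncSSR"),
)


def mean_complexity(summaries: Sequence[GenomeSummary]) -> float:
    """Cohort mean of per-genome ncSSR_i / nCSSR_i.

    Genomes with no compound loci have an undefined ratio and are excluded
    with a warning; if every genome lacks them, raises ValueError.
    """
    ratios = []
    excluded = []
    for s in summaries:
        if s.nCSSR >= 1:
            ratios.append(s.ncSSR / s.nCSSR)
        else:
            excluded.append(s.genome_id)
    if excluded:
        warnings.warn(
            f"{len(excluded)} genome(s) without compound loci excluded from "
            f"mean complexity: {', '.join(excluded[:5])}"
        )
    if not ratios:
        raise ValueError("no genome has any compound locus; mean complexity undefined")
    return float(np.mean(ratios))


def z_scores(
    summaries: Sequence[GenomeSummary],
    c_bar: float,
    denominator: str = "sqrt",
) -> pd.DataFrame:
    """Expected compound-locus counts and Z index per genome.

    Fills nCSSR_exp and Z on each summary and returns them as a table.
    Genomes with nCSSR_exp == 0 get Z = NA.
    """
    if c_bar <= 0:
        raise ValueError(f"c_bar must be positive, got {c_bar}")
    if denominator not in ("sqrt", "linear"):
        raise ValueError(f"unknown z denominator {denominator!r}")
    rows = []
    for s in summaries:
        exp = s.ncSSR / c_bar
        if exp > 0:
            scale = math.sqrt(exp) if denominator == "sqrt" else exp
            z = (s.nCSSR - exp) / scale
        else:
            z = None
        s.nCSSR_exp = exp
        s.Z = z
        rows.append(
            {
                "genome_id": s.genome_id,
                "ncSSR": s.ncSSR,
                "nCSSR_obs": s.nCSSR,
                "nCSSR_exp": exp,
                "Z": np.nan if z is None else z,
            }
        )
    return pd.DataFrame(rows, columns=["genome_id", "ncSSR", "nCSSR_obs", "nCSSR_exp", "Z"])


def pearson_table(
    summaries: Sequence[GenomeSummary],
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Pearson rho and two-sided p-value for each requested variable pair.

    Requires at least 3 genomes.  A pair involving a zero-variance variable
    gets rho = NA with a warning.
    """
    if len(summaries) < 3:
        raise ValueError("pearson_table requires at least 3 genomes")
    pairs = tuple(pairs) if pairs is not None else DEFAULT_PEARSON_PAIRS
    values = {
        v: np.array([getattr(s, v) for s in summaries], dtype=float)
        for v in _VARIABLES
    }
    rows = []
    for a, b in pairs:
        if a not in values or b not in values:
            raise ValueError(f"unknown correlation variable in pair ({a}, {b})")
        x, y = values[a], values[b]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"zero variance in pair ({a}, {b}); rho undefined")
            rho, p = np.nan, np.nan
        else:
            rho, p = sps.pearsonr(x, y)
        rows.append({"pair": f"{a}~{b}", "rho": rho, "p_value": p, "n": len(summaries)})
    return pd.DataFrame(rows, columns=["pair", "rho", "p_value", "n"])


@dataclass
class CohortResult:
    """Cross-genome aggregates computed from per-genome summaries."""

    n: int
    c_bar: float
    z_table: pd.DataFrame
    correlations: pd.DataFrame
    complexity_counts: Dict[int, int]
    complexity_proportions: Dict[int, float]
    unique_motif_counts: Dict[str, int]
    unique_motif_total: int
    total_ssr: int
    total_cssr_loci: int
    total_cssr_members: int
    pattern_tally: Dict[str, int]
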