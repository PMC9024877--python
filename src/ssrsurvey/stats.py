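"""Per-genome repeat statistics.

Counts are normalized per kilobase of the assembly studied (kb = 1000 bp
exactly; ambiguity bases stay in the denominator):

* relative abundance (RA) — loci per kb;
* relative density (RD) — repeat base pairs per kb; for compound loci the
  full span including interruptions is counted, since the compound locus is
  a single genomic feature.

cSSR% is the percentage of all SSRs that are members of a compound locus,
100 * ncSSR / nSSR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .annotate import coding_fraction
from .compound import CSSRLocus
from .io import GenomeRecord
from .scan import SSRLocus

__all__ = [
    "GenomeSummary",
    "summarize_genome",
    "classify_pattern",
    "motif_ra_matrix",
]

_TYPE_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass
class GenomeSummary:
    """Per-genome repeat statistics (Z and nCSSR_exp filled at cohort level)."""

    genome_id: str
    genome_size: int
    gc_content: float
    nSSR: int
    nCSSR: int
    ncSSR: int
    cSSR_pct: float
    RA_ssr: float
    RD_ssr: float
    RA_cssr: float
    RD_cssr: float
    type_counts: Dict[int, int]
    pattern: str
    pattern_tie: bool
    coding_fraction_ssr: Optional[float]
    coding_fraction_cssr: Optional[float]
    subclade_label: Optional[str] = None
    nCSSR_exp: Optional[float] = None
    Z: Optional[float] = None


def classify_pattern(type_counts: Dict[int, int]) -> Tuple[str, bool]:
    """Descending-order label of mono/di/tri counts, e.g. "di>tri>mono".

    Ties are joined with "=" and flagged (second element True).
    """
    triples = [(_TYPE_NAMES[p], type_counts.get(p, 0)) for p in (1, 2, 3)]
    triples.sort(key=lambda t: (-t[1], t[0]))
    parts = [triples[0][0]]
    tie = False
    for prev, cur in zip(triples, triples[1:]):
        if cur[1] == prev[1]:
            parts.append("=" + cur[0])
            tie = True
        else:
            parts.append(">" + cur[0])
    return "".join(parts), tie


def summarize_genome(
    genome: GenomeRecord,
    ssrs: Sequence[SSRLocus],
    cssrs: Sequence[CSSRLocus],
    ssr_regions: Optional[Sequence[str]] = None,
    cssr_regions: Optional[Sequence[str]] = None,
) -> GenomeSummary:
    """Compute all per-genome statistics except the cohort-level Z index."""
    if genome.total_length <= 0:
        raise ValueError(f"genome {genome.genome_id!r} has size 0")
    kb = genome.total_length / 1000.0
    nssr = len(ssrs)
    ncssr_loci = len(cssrs)
    ncssr_members = sum(c.complexity for c in cssrs)
    type_counts = {p: 0 for p in range(1, 7)}
    for s in ssrs:
        type_counts[s.period] = type_counts.get(s.period, 0) + 1
    pattern, tie = classify_pattern(type_counts)
    return GenomeSummary(
        genome_id=genome.genome_id,
        genome_size=genome.total_length,
        gc_content=genome.gc_content,
        nSSR=nssr,
        nCSSR=ncssr_loci,
        ncSSR=ncssr_members,
        cSSR_pct=(100.0 * ncssr_members / nssr) if nssr else 0.0,
        RA_ssr=nssr / kb,
        RD_ssr=sum(s.length for s in ssrs) / kb,
        RA_cssr=ncssr_loci / kb,
        RD_cssr=sum(c.span_length for c in cssrs) / kb,
        type_counts=type_counts,
        pattern=pattern,
        pattern_tie=tie,
        coding_fraction_ssr=coding_fraction(ssr_regions) if ssr_regions is not None else None,
        coding_fraction_cssr=coding_fraction(cssr_regions) if cssr_regions is not None else None,
        subclade_label=genome.subclade_label,
    )


def motif_ra_matrix(
    genomes: Sequence[GenomeRecord],
    loci_by_genome: Dict[str, Sequence[SSRLocus]],
) -> pd.DataFrame:
    """Relative abundance (loci/kb) of each observed standard motif per genome.

    Rows are standard motifs ordered by (period, motif); a row is present
    iff the motif is observed in at least one genome, and absent motifs get
    0 in the other genomes' columns.
    """
    sizes = {g.genome_id: g.total_length for g in genomes}
    counts: Dict[str, Dict[str, int]] = {}
    for gid, loci in loci_by_genome.items():
        for s in loci:
            counts.setdefault(s.standard_motif, {}).setdefault(gid, 0)
            counts[s.standard_motif][gid] += 1
    motifs = sorted(counts, key=lambda m: (len(m), m))
    columns = [g.genome_id for g in genomes]
    data = {
        gid: [counts[m].get(gid, 0) / (sizes[gid] / 1000.0) for m in motifs]
        for gid in columns
    }
    df = pd.DataFrame(data, index=pd.Index(motifs, name="standard_motif"))
    return df
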