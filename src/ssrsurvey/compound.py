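"""Compound microsatellite (CSSR) assembly under the dmax gap rule.

A CSSR is a maximal chain of >= 2 SSRs on one contig in which every adjacent
pair is separated by at most ``dmax`` bases (the gap is the number of bases
strictly between the two loci; gap 0 means abutting).  Member SSRs keep
their identity: they still count toward nSSR, and the per-genome count of
members is ncSSR, so cSSR% = 100 * ncSSR / nSSR is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .scan import SSRLocus

__all__ = [
    "CSSRLocus",
    "build_cssrs",
    "complexity_spectrum",
    "unique_compound_motifs",
]

DEFAULT_DMAX = 10


@dataclass(frozen=True)
class CSSRLocus:
    """A maximal chain of SSRs with inter-repeat gaps <= dmax."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    members: Tuple[SSRLocus, ...]
    compound_motif: str

    @property
    def complexity(self) -> int:
        """Number of member SSRs (the chain's C)."""
        return len(self.members)

    @property
    def span_length(self) -> int:
        """Full genomic span including interruption bases."""
        return self.end - self.start + 1

    def key(self) -> tuple:
        return (self.contig_id, self.start, self.end, self.compound_motif)


def _validate_sorted(loci: Sequence[SSRLocus]) -> None:
    prev_by_contig: Dict[Tuple[str, str], SSRLocus] = {}
    for loc in loci:
        k = (loc.genome_id, loc.contig_id)
        prev = prev_by_contig.get(k)
        if prev is not None:
            if loc.start <= prev.start:
                raise ValueError(
                    f"loci not sorted by start on {loc.contig_id}: "
                    f"{prev.start} then {loc.start}"
                )
            if loc.start <= prev.end:
                raise ValueError(
                    f"overlapping loci on {loc.contig_id}: "
                    f"[{prev.start},{prev.end}] and [{loc.start},{loc.end}]"
                )
        prev_by_contig[k] = loc


def build_cssrs(
    loci: Sequence[SSRLocus], dmax: int = DEFAULT_DMAX
) -> Tuple[List[CSSRLocus], List[bool]]:
    """Assemble maximal SSR chains with adjacent gaps <= dmax.

    Parameters
    ----------
    loci
        SSR loci sorted by (contig, start) and non-overlapping per contig
        (the scanner's output satisfies this).
    dmax
        Maximum number of bases strictly between two adjacent member SSRs.

    Returns
    -------
    (cssrs, in_cssr)
        All maximal chains with complexity >= 2 and, parallel to the input,
        a boolean flag marking each SSR that is a member of some chain.
    """
    if dmax < 0:
        raise ValueError("dmax must be >= 0")
    _validate_sorted(loci)
    cssrs: List[CSSRLocus] = []
    in_cssr = [False] * len(loci)

    chain: List[int] = []

    def flush() -> None:
        if len(chain) >= 2:
            members = tuple(loci[j] for j in chain)
            cssrs.append(
                CSSRLocus(
                    genome_id=members[0].genome_id,
                    contig_id=members[0].contig_id,
                    start=members[0].start,
                    end=members[-1].end,
                    members=members,
                    compound_motif="-".join(m.standard_motif for m in members),
                )
            )
            for j in chain:
                in_cssr[j] = True
        chain.clear()

    for idx, loc in enumerate(loci):
        if chain:
            prev = loci[chain[-1]]
            same = (prev.genome_id, prev.contig_id) == (loc.genome_id, loc.contig_id)
            if same and loc.start - prev.end - 1 <= dmax:
                chain.append(idx)
                continue
            flush()
        chain.append(idx)
    flush()
    return cssrs, in_cssr


def complexity_spectrum(
    cssrs: Iterable[CSSRLocus],
) -> Tuple[Dict[int, int], Dict[int, float]]:
    """Counts and proportions of CSSRs by complexity (number of members)."""
    counts: Dict[int, int] = {}
    for c in cssrs:
        counts[c.complexity] = counts.get(c.complexity, 0) + 1
    total = sum(counts.values())
    props = {k: v / total for k, v in counts.items()} if total else {}
    return dict(sorted(counts.items())), dict(sorted(props.items()))


def unique_compound_motifs(
    cohort: Mapping[str, Sequence[CSSRLocus]],
) -> Tuple[Dict[str, int], int]:
    """Per-genome counts of compound-motif patterns seen in exactly one genome.

    A pattern is *unique* when it occurs in exactly one genome of the cohort
    (any number of times there); duplicates within a genome count once.
    Returns the per-genome counts and their total.
    """
    if not cohort:
        raise ValueError("cohort must contain at least one genome")
    pattern_sets = {gid: {c.compound_motif for c in cs} for gid, cs in cohort.items()}
    occurrence: Dict[str, int] = {}
    for patterns in pattern_sets.values():
        for pat in patterns:
            occurrence[pat] = occurrence.get(pat, 0) + 1
    per_genome = {
        gid: sum(1 for pat in patterns if occurrence[pat] == 1)
        for gid, patterns in pattern_sets.items()
    }
    return per_genome, sum(per_genome.values())
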