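"""Coding / noncoding placement of SSR and CSSR loci.

A locus is *coding* when its span overlaps any CDS interval by at least one
base; compound loci are classified by their full span.  Genomes without an
annotation get region "NA" rather than zero counts.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .io import AnnotationIndex

__all__ = ["classify_regions", "coding_fraction"]

CODING = "coding"
NONCODING = "noncoding"
NA = "NA"


def _build_trees(index: AnnotationIndex) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for contig, intervals in index.cds_intervals.items():
        # intervaltree is half-open; convert 1-based inclusive (s, e) -> [s, e+1)
        trees[contig] = IntervalTree.from_tuples((s, e + 1) for s, e in intervals)
    return trees


def classify_regions(loci: Sequence, index: Optional[AnnotationIndex]) -> List[str]:
    """Region call (coding / noncoding / NA) for each locus, in input order.

    ``loci`` may mix SSR and CSSR objects: anything with contig_id, start
    and end.  With no annotation index every call is NA.  A locus on a
    contig absent from the index's genome namespace is called noncoding
    with a warning.
    """
    if index is None:
        return [NA] * len(loci)
    trees = _build_trees(index)
    known = set(index.cds_intervals)
    calls: List[str] = []
    warned: set = set()
    for loc in loci:
        tree = trees.get(loc.contig_id)
        if tree is None:
            if loc.contig_id not in known and loc.contig_id not in warned:
                warned.add(loc.contig_id)
                warnings.warn(
                    f"locus contig {loc.contig_id!r} absent from annotation "
                    f"for genome {index.genome_id!r}; called noncoding"
                )
            calls.append(NONCODING)
            continue
        calls.append(CODING if tree.overlaps(loc.start, loc.end + 1) else NONCODING)
    return calls


def coding_fraction(calls: Sequence[str]) -> Optional[float]:
    """Percent of classified loci that are coding; None when all calls are NA."""
    coding = sum(1 for c in calls if c == CODING)
    noncoding = sum(1 for c in calls if c == NONCODING)
    if coding + noncoding == 0:
        return None
    return 100.0 * coding / (coding + noncoding)
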