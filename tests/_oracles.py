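"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the scanner oracle walks
the sequence character by character, and the chain oracle takes a
transitive closure of the pairwise proximity relation.
"""

from typing import Dict, List, Sequence, Tuple

ACGT = set("ACGT")


def brute_force_scan(
    seq: str, min_repeats: Dict[int, int], max_period: int = 6
) -> List[Tuple[int, int, str, int]]:
    """Naive O(L^2) greedy SSR enumeration.

    At each position, periods are tried in increasing order; the maximal
    perfect run is extended character by character, minimal-period and
    copy-number filters applied, and the first qualifying run emitted
    (truncated to whole copies); scanning resumes after it.  Returns
    (start, end, motif, repeats) with 1-based inclusive coordinates.
    """
    out = []
    L = len(seq)
    i = 0
    while i < L:
        emitted = False
        for p in range(1, max_period + 1):
            if i + p > L:
                break
            motif = seq[i : i + p]
            if not set(motif) <= ACGT:
                continue
            # minimal period: motif must not be a repetition of a shorter unit
            if any(
                p % d == 0 and motif == motif[:d] * (p // d) for d in range(1, p)
            ):
                continue
            e = i + p
            while e < L and seq[e] in ACGT and seq[e] == seq[e - p]:
                e += 1
            repeats = (e - i) // p
            if repeats >= min_repeats[p]:
                end = i + repeats * p
                out.append((i + 1, end, motif, repeats))
                i = end
                emitted = True
                break
        if not emitted:
            i += 1
    return out


def chain_components(
    spans: Sequence[Tuple[int, int]], dmax: int
) -> List[List[int]]:
    """Connected components of the "gap <= dmax" relation, brute force.

    ``spans`` are (start, end) on one contig, any order.  Returns index
    lists (into the input) of every component with >= 2 members, each
    sorted by start; components are ordered by their first start.
    """
    n = len(spans)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = spans[i], spans[j]
            if s1 > s2:
                (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
            gap = s2 - e1 - 1
            if gap <= dmax:
                parent[find(i)] = find(j)

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    comps = [
        sorted(g, key=lambda k: spans[k][0]) for g in groups.values() if len(g) >= 2
    ]
    comps.sort(key=lambda g: spans[g[0]][0])
    return comps


def interval_overlaps(
    intervals: Sequence[Tuple[int, int]], start: int, end: int
) -> bool:
    """All-pairs overlap check: 1-based inclusive, >= 1 shared base."""
    return any(s <= end and e >= start for s, e in intervals)
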