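"""Perfect microsatellite (SSR) detection and motif canonicalization.

An SSR is a perfect tandem repetition of a 1-6 bp motif.  Qualifying runs
must reach a per-period minimum copy number (default 6 copies for
mononucleotide repeats and 3 copies for periods 2-6, the thresholds
customary for small prokaryotic genomes).  Motifs are reported together
with their *standard motif*: the canonical representative of the motif's
equivalence class under cyclic rotation and reverse complementation, so
that strand and phase do not fragment counts (e.g. GT, TG, CA and AC all
standardize to AC).

Scanning is greedy left-to-right: at each position, periods are tried in
increasing order and the first qualifying maximal run is emitted, truncated
to whole motif copies; scanning resumes immediately after it.  This yields
one canonical, non-overlapping decomposition per contig, the convention of
MISA/Krait-style repeat finders.  Runs never cross an ambiguity code (N or
any other non-ACGT character) or a contig boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import numpy as np

from .errors import ConfigError

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "SSRLocus",
    "ScanParams",
    "scan_ssrs",
    "scan_sequence",
    "standardize_motif",
    "enumerate_standard_motifs",
    "reverse_complement",
    "has_minimal_period",
]

#: Minimum complete motif copies per period (mono..hexa).
DEFAULT_MIN_REPEATS: Dict[int, int] = {1: 6, 2: 3, 3: 3, 4: 3, 5: 3, 6: 3}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def has_minimal_period(motif: str) -> bool:
    """True when ``motif`` is not a whole-number repetition of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class SSRLocus:
    """One perfect microsatellite locus (1-based inclusive coordinates)."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    period: int
    motif: str
    standard_motif: str
    repeats: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def key(self) -> tuple:
        """Identity tuple used for exact locus comparison."""
        return (self.contig_id, self.start, self.end, self.motif)


@dataclass(frozen=True)
class ScanParams:
    """Detection thresholds for the SSR scanner."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_period: int = 6

    def __post_init__(self):
        if not 1 <= self.max_period <= 6:
            raise ConfigError(f"max_period must be in 1..6, got {self.max_period}")
        for p in range(1, self.max_period + 1):
            if p not in self.min_repeats:
                raise ConfigError(f"min_repeats missing period {p}")
            if self.min_repeats[p] < 2:
                raise ConfigError(
                    f"min_repeats[{p}] = {self.min_repeats[p]}; at least 2 copies required"
                )

    def as_dict(self) -> dict:
        return {
            "min_repeats": {str(k): int(v) for k, v in sorted(self.min_repeats.items())},
            "max_period": self.max_period,
        }


def standardize_motif(motif: str) -> str:
    """Canonical representative of a motif's rotation/reverse-complement class.

    Returns the lexicographically smallest string (A<C<G<T) among all cyclic
    rotations of the motif and of its reverse complement.  Idempotent and
    constant on each equivalence class.
    """
    if not motif or not set(motif) <= _ACGT:
        raise ValueError(f"motif must be a nonempty string over ACGT, got {motif!r}")
    return _standardize_cached(motif)


@lru_cache(maxsize=None)
def _standardize_cached(motif: str) -> str:
    rc = reverse_complement(motif)
    n = len(motif)
    candidates = {motif[i:] + motif[:i] for i in range(n)}
    candidates.update(rc[i:] + rc[:i] for i in range(n))
    return min(candidates)


@lru_cache(maxsize=None)
def enumerate_standard_motifs(period: int) -> frozenset:
    """All standard (canonical) motifs of a given period.

    Brute force over the 4**period strings, keeping only minimal-period
    motifs and collapsing each to its standard representative.
    """
    if not 1 <= period <= 6:
        raise ValueError(f"period must be in 1..6, got {period}")
    out: Set[str] = set()
    for tup in itertools.product("ACGT", repeat=period):
        m = "".join(tup)
        if has_minimal_period(m):
            out.add(_standardize_cached(m))
    return frozenset(out)


# --- scanning ---------------------------------------------------------------

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _match_false_index(seq_codes: np.ndarray, valid: np.ndarray, p: int):
    """Positions j where a[j] != a[j+p] (or either base ambiguous), with sentinel.

    Also returns the start positions of True-runs long enough to seed a
    qualifying repeat of period p (thresh matched positions from the start).
    """
    eq = (seq_codes[p:] == seq_codes[:-p]) & valid[p:] & valid[:-p]
    false_idx = np.flatnonzero(~eq)
    false_idx = np.append(false_idx, eq.size)  # sentinel
    return eq, false_idx


def _candidate_starts(eq: np.ndarray, thresh: int) -> np.ndarray:
    """Start positions i such that eq[i : i+thresh] is all True."""
    if eq.size < thresh or thresh <= 0:
        return np.empty(0, dtype=np.int64)
    x = eq.view(np.int8)
    bounds = np.concatenate((np.flatnonzero(np.diff(x) != 0) + 1, [x.size]))
    prev = 0
    out = []
    for b in bounds:
        if x[prev] and b - prev >= thresh:
            out.append(np.arange(prev, b - thresh + 1, dtype=np.int64))
        prev = int(b)
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(out)


def scan_sequence(
    seq: str,
    params: ScanParams | None = None,
    *,
    genome_id: str = "",
    contig_id: str = "",
) -> List[SSRLocus]:
    """Detect all perfect SSRs in one contig sequence.

    Returns loci sorted by start, mutually non-overlapping, each truncated
    to whole motif copies, with minimal-period motifs only.
    """
    params = params or ScanParams()
    L = len(seq)
    if L == 0:
        return []
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (
        (codes == _BASE_CODES[0])
        | (codes == _BASE_CODES[1])
        | (codes == _BASE_CODES[2])
        | (codes == _BASE_CODES[3])
    )
    periods = list(range(1, params.max_period + 1))
    false_idx: Dict[int, np.ndarray] = {}
    thresh: Dict[int, int] = {}
    cand_parts = []
    for p in periods:
        if L <= p:
            continue
        eq, fidx = _match_false_index(codes, valid, p)
        false_idx[p] = fidx
        # matched positions needed from a start for >= min_repeats copies
        thresh[p] = p * (params.min_repeats[p] - 1)
        cand_parts.append(_candidate_starts(eq, thresh[p]))
    if not cand_parts:
        return []
    cand = np.unique(np.concatenate(cand_parts))
    if cand.size == 0:
        return []

    loci: List[SSRLocus] = []
    cursor = 0
    ci = 0
    n_cand = cand.size
    while ci < n_cand:
        i = int(cand[ci])
        if i < cursor:
            ci += 1
            continue
        emitted = False
        for p in periods:
            fidx = false_idx.get(p)
            if fidx is None or i >= fidx[-1]:
                continue
            cnt = int(fidx[np.searchsorted(fidx, i)]) - i
            if cnt < thresh[p]:
                continue
            motif = seq[i : i + p]
            if not has_minimal_period(motif):
                continue
            run_len = p + cnt
            repeats = run_len // p
            end = i + repeats * p  # exclusive, 0-based
            loci.append(
                SSRLocus(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=i + 1,
                    end=end,
                    period=p,
                    motif=motif,
                    standard_motif=_standardize_cached(motif),
                    repeats=repeats,
                )
            )
            cursor = end
            emitted = True
            break
        if not emitted:
            cursor = i + 1
            ci += 1
    return loci


def scan_ssrs(genome, params: ScanParams | None = None) -> List[SSRLocus]:
    """Detect all perfect SSRs across every contig of a genome record."""
    params = params or ScanParams()
    loci: List[SSRLocus] = []
    for contig_id, seq in genome.contigs:
        loci.extend(
            scan_sequence(
                seq, params, genome_id=genome.genome_id, contig_id=contig_id
            )
        )
    return loci
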