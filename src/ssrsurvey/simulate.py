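"""Synthetic genomes with planted microsatellites and exact ground truth.

The generator emulates the genomic setting of small marine picocyanobacteria:
multi-contig assemblies of 1.68-3.31 Mb with GC between 52 and 65%, perfect
SSRs of periods 1-6 planted at controlled counts per standard motif, and
clusters of adjacent SSRs within a configurable gap forming compound loci.

The construction guarantees that the scanner's output on the synthetic
genome equals the planted truth *exactly*:

1. the background is sampled base-by-base at the target GC, then "cleaned" -
   every accidental run meeting the scan thresholds is disrupted by single
   substitutions, iterating until a scan of the background alone is empty;
2. planted features are inserted at uniformly sampled positions with at
   least dmax+1 bases of clearance between independent features, so no
   accidental compound loci arise;
3. a final repair pass rescans the full genome and disrupts any residual
   discrepancy (e.g. a background base accidentally extending a planted
   run), substituting only bases outside the planted spans, until the scan
   reproduces the truth byte-for-byte.

All sampling draws from one seeded numpy Generator (PCG64), so identical
seed + config give identical genomes.
"""

from __future__ import annotations

import math
from bisect import bisect_right, insort
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .compound import CSSRLocus, DEFAULT_DMAX, build_cssrs
from .errors import ConfigError
from .io import AnnotationIndex, GenomeRecord, ManifestEntry, make_genome_record
from .scan import (
    ScanParams,
    SSRLocus,
    has_minimal_period,
    scan_sequence,
    standardize_motif,
)

__all__ = [
    "PlantConfig",
    "CSSRPlan",
    "PlantedTruth",
    "DensityModel",
    "generate_genome",
    "generate_cohort",
    "write_genome_files",
    "write_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_SET = frozenset(b"ACGT")


@dataclass(frozen=True)
class CSSRPlan:
    """One compound-locus template: member motifs, copy numbers, gaps."""

    motifs: Tuple[str, ...]
    repeats: Tuple[int, ...]
    gaps: Tuple[int, ...]
    count: int = 1

    def __post_init__(self):
        if len(self.motifs) < 2:
            raise ConfigError("a compound plan needs >= 2 member motifs")
        if len(self.repeats) != len(self.motifs):
            raise ConfigError("repeats must match motifs in length")
        if len(self.gaps) != len(self.motifs) - 1:
            raise ConfigError("gaps must have one entry per adjacent member pair")


@dataclass(frozen=True)
class PlantConfig:
    """Specification of one synthetic genome."""

    genome_size: int
    gc_content: float
    seed: int
    genome_id: str = "synthetic"
    n_contigs: int = 1
    ssr_plan: Tuple[Tuple[str, int, int], ...] = ()  # (motif, repeats, count)
    cssr_plan: Tuple[CSSRPlan, ...] = ()
    dmax: int = DEFAULT_DMAX
    cds_fraction: Optional[float] = None
    subclade_label: Optional[str] = None

    def __post_init__(self):
        if self.genome_size < 100:
            raise ConfigError("genome_size must be >= 100")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigError("gc_content must be in (0, 1)")
        if self.n_contigs < 1 or self.n_contigs > self.genome_size // 100:
            raise ConfigError("invalid n_contigs")
        if self.cds_fraction is not None and not 0.0 < self.cds_fraction < 1.0:
            raise ConfigError("cds_fraction must be in (0, 1)")
        for plan in self.cssr_plan:
            if any(g < 0 or g > self.dmax for g in plan.gaps):
                raise ConfigError("compound gaps must satisfy 0 <= gap <= dmax")


@dataclass
class PlantedTruth:
    """Exact ground truth for a synthetic genome."""

    ssrs: List[SSRLocus]
    cssrs: List[CSSRLocus]
    ssr_regions: List[str]
    cssr_regions: List[str]
    background_gc: float
    cleaning_passes: int
    repair_passes: int


@dataclass(frozen=True)
class DensityModel:
    """Per-kb planting rates and composition used by generate_cohort.

    Defaults reflect a typical small cyanobacterial genome: ~2.6 SSRs/kb,
    ~0.085 compound loci/kb, compound complexity concentrated at 2 (mean
    about 2.06), dinucleotide repeats the most abundant type.
    """

    ssr_per_kb: float = 2.6
    cssr_per_kb: float = 0.085
    relative_noise: float = 0.05
    complexity_probs: Tuple[Tuple[int, float], ...] = (
        (2, 0.949), (3, 0.046), (4, 0.004), (5, 0.001),
    )
    type_weights: Tuple[Tuple[int, float], ...] = (
        (1, 0.25), (2, 0.45), (3, 0.28), (4, 0.012), (5, 0.005), (6, 0.003),
    )
    mono_tri_jitter: float = 0.06  # per-genome shift between mono and tri weight

    def __post_init__(self):
        if self.ssr_per_kb <= 0 or self.cssr_per_kb < 0:
            raise ConfigError("densities must be positive")
        if not 0 <= self.relative_noise < 1:
            raise ConfigError("relative_noise must be in [0, 1)")


# Motif pools per period, weighted toward the classes abundant in
# AT-skewed-but-GC-rich marine picocyanobacterial genomes.
_MOTIF_WEIGHTS: Dict[int, Tuple[Tuple[str, float], ...]] = {
    1: (("A", 0.7), ("C", 0.3)),
    2: (("AG", 0.40), ("AC", 0.30), ("CG", 0.25), ("AT", 0.05)),
    3: (
        ("AGC", 0.28), ("ACG", 0.18), ("ACC", 0.14), ("CCG", 0.14),
        ("AAC", 0.06), ("AAG", 0.06), ("AGG", 0.05), ("ACT", 0.04),
        ("ATC", 0.03), ("AAT", 0.02),
    ),
}


def _sample_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _substitute(
    arr: np.ndarray, pos: int, rng: np.random.Generator
) -> None:
    """Replace arr[pos] with a base differing from itself and its neighbours."""
    forbidden = {int(arr[pos])}
    if pos > 0:
        forbidden.add(int(arr[pos - 1]))
    if pos + 1 < arr.size:
        forbidden.add(int(arr[pos + 1]))
    choices = [b for b in _BASES if int(b) not in forbidden]
    arr[pos] = rng.choice(np.array(choices, dtype=np.uint8))


def _disrupt_span(
    arr: np.ndarray,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    protected: Optional[np.ndarray] = None,
) -> int:
    """Break periodicity on [lo, hi) by substituting every <= 5 bases.

    Only unprotected positions are touched.  Returns the number of
    substitutions made (0 when every base in the span is protected).
    """
    if protected is None:
        positions = list(range(lo, hi))
    else:
        positions = [p for p in range(lo, hi) if not protected[p]]
    if not positions:
        return 0
    if len(positions) > 4:
        # random phase: substituting a fixed phase of a periodic run can
        # recreate a perfect run with a rotated motif and cycle forever
        off = int(rng.integers(0, 5))
        chosen = positions[off::5]
    else:
        chosen = [positions[len(positions) // 2]]
    for p in chosen:
        _substitute(arr, p, rng)
    return len(chosen)


def _clean_background(
    arr: np.ndarray, params: ScanParams, rng: np.random.Generator, max_passes: int = 100
) -> int:
    """Disrupt accidental SSRs until a scan of the sequence is empty."""
    for n_pass in range(1, max_passes + 1):
        loci = scan_sequence(arr.tobytes().decode("ascii"), params)
        if not loci:
            return n_pass - 1
        for loc in loci:
            _disrupt_span(arr, loc.start - 1, loc.end, rng)
    raise RuntimeError("background cleaning did not converge")


def compose_compound(
    plan: CSSRPlan,
    rng: np.random.Generator,
    params: ScanParams,
    max_tries: int = 30,
) -> Tuple[str, List[Tuple[int, str, int]]]:
    """Render a compound plan as a sequence whose scan recovers its members.

    Returns the composed sequence and (0-based offset, motif, repeats) per
    member.  Gap bases are resampled until the scanner, run on the composed
    sequence alone, reports exactly the planned members; if no gap content
    can achieve this (e.g. abutting members whose junction extends a run),
    raises ConfigError: such a plan has no scanner-consistent realization.
    """
    offsets: List[Tuple[int, str, int]] = []
    pos = 0
    for i, (motif, reps) in enumerate(zip(plan.motifs, plan.repeats)):
        offsets.append((pos, motif, reps))
        pos += len(motif) * reps
        if i < len(plan.gaps):
            pos += plan.gaps[i]
    expected = {
        (off + 1, off + len(m) * r, m) for off, m, r in offsets
    }
    resamplable = any(g > 0 for g in plan.gaps)
    tries = max_tries if resamplable else 1
    for _ in range(tries):
        parts: List[str] = []
        for i, (motif, reps) in enumerate(zip(plan.motifs, plan.repeats)):
            parts.append(motif * reps)
            if i < len(plan.gaps):
                g = plan.gaps[i]
                parts.append(
                    "".join(chr(b) for b in rng.choice(_BASES, size=g))
                )
        seq = "".join(parts)
        got = {(l.start, l.end, l.motif) for l in scan_sequence(seq, params)}
        if got == expected:
            return seq, offsets
    raise ConfigError(
        f"compound plan {plan.motifs} with gaps {plan.gaps} has no "
        "scanner-consistent realization"
    )


def _validate_ssr_plan(
    plan: Sequence[Tuple[str, int, int]], params: ScanParams
) -> None:
    for motif, reps, count in plan:
        if not motif or not set(motif.encode()) <= _BASE_SET:
            raise ConfigError(f"invalid motif {motif!r}")
        if len(motif) > params.max_period:
            raise ConfigError(f"motif {motif!r} exceeds max period")
        if not has_minimal_period(motif):
            raise ConfigError(f"motif {motif!r} is not minimal-period")
        if reps < params.min_repeats[len(motif)]:
            raise ConfigError(
                f"({motif}){reps} is below the detection threshold and "
                "could never be recovered"
            )
        if count < 0:
            raise ConfigError("plan counts must be >= 0")


def _make_cds_track(
    rng: np.random.Generator, contig_len: int, fraction: float
) -> List[Tuple[int, int]]:
    """Alternating coding blocks covering ~fraction of the contig (1-based)."""
    intervals: List[Tuple[int, int]] = []
    pos = 1 + int(rng.integers(0, 200))
    while pos <= contig_len:
        coding = int(rng.integers(600, 1800))
        end = min(pos + coding - 1, contig_len)
        intervals.append((pos, end))
        gap = max(1, int(coding * (1 - fraction) / fraction))
        gap = max(1, int(gap * rng.uniform(0.5, 1.5)))
        pos = end + 1 + gap
    return intervals


def _overlaps_track(track: List[Tuple[int, int]], start: int, end: int) -> bool:
    # track is sorted and non-overlapping, so ends are increasing: the last
    # interval starting at or before `end` is the only overlap candidate
    if not track:
        return False
    i = bisect_right(track, (end, float("inf"))) - 1
    return i >= 0 and track[i][1] >= start


def generate_genome(
    config: PlantConfig, params: Optional[ScanParams] = None
) -> Tuple[GenomeRecord, Optional[AnnotationIndex], PlantedTruth]:
    """Generate one synthetic genome with planted SSRs/CSSRs and ground truth.

    The returned truth satisfies: scanning the genome with ``params``
    reproduces exactly the planted SSR loci, compound assembly with
    ``config.dmax`` reproduces exactly the planted compound loci, and the
    recorded region calls match classification against the emitted CDS
    track.
    """
    params = params or ScanParams()
    rng = np.random.default_rng(config.seed)
    _validate_ssr_plan(config.ssr_plan, params)

    # render features up front so feasibility is checked before any sampling
    features: List[Tuple[str, object]] = []  # (sequence, payload)
    for motif, reps, count in config.ssr_plan:
        for _ in range(count):
            features.append((motif * reps, ("ssr", motif, reps)))
    for plan in config.cssr_plan:
        for _ in range(count := plan.count):
            seq, offsets = compose_compound(plan, rng, params)
            features.append((seq, ("cssr", offsets)))

    clearance = config.dmax + 1
    need = sum(len(s) + clearance for s, _ in features) + clearance
    if need > config.genome_size:
        raise ConfigError(
            f"planted features need {need} bases with clearance; "
            f"genome_size is {config.genome_size}"
        )

    # contig sizes: even split, remainder to the first contig
    base = config.genome_size // config.n_contigs
    sizes = [base] * config.n_contigs
    sizes[0] += config.genome_size - base * config.n_contigs
    contig_ids = [f"contig_{i+1}" for i in range(config.n_contigs)]

    arrays = [_sample_background(rng, n, config.gc_content) for n in sizes]
    bg_gc = sum(
        int(np.sum((a == ord("G")) | (a == ord("C")))) for a in arrays
    ) / config.genome_size
    cleaning_passes = 0
    for a in arrays:
        cleaning_passes += _clean_background(a, params, rng)

    # placement: uniform positions with clearance, per-contig occupancy lists
    total = float(config.genome_size)
    contig_p = np.array([n / total for n in sizes])
    occupied: List[List[Tuple[int, int]]] = [[] for _ in sizes]

    def try_place(flen: int) -> Tuple[int, int]:
        for _ in range(2000):
            ci = int(rng.choice(len(sizes), p=contig_p))
            if sizes[ci] < flen:
                continue
            pos = int(rng.integers(0, sizes[ci] - flen + 1))
            lo, hi = pos - clearance, pos + flen + clearance
            occ = occupied[ci]
            i = bisect_right(occ, (lo, lo))
            ok = True
            for j in (i - 1, i):
                if 0 <= j < len(occ):
                    s, e = occ[j]
                    if s < hi and e > lo:
                        ok = False
                        break
            if ok:
                insort(occ, (pos, pos + flen))
                return ci, pos
        raise ConfigError("could not place all planted features; genome too dense")

    truth_ssrs: List[SSRLocus] = []
    truth_cssrs: List[CSSRLocus] = []
    for seq, payload in features:
        ci, pos = try_place(len(seq))
        arrays[ci][pos : pos + len(seq)] = np.frombuffer(
            seq.encode("ascii"), dtype=np.uint8
        )
        cid = contig_ids[ci]
        if payload[0] == "ssr":
            _, motif, reps = payload
            truth_ssrs.append(
                SSRLocus(
                    genome_id=config.genome_id,
                    contig_id=cid,
                    start=pos + 1,
                    end=pos + len(motif) * reps,
                    period=len(motif),
                    motif=motif,
                    standard_motif=standardize_motif(motif),
                    repeats=reps,
                )
            )
        else:
            _, offsets = payload
            members = tuple(
                SSRLocus(
                    genome_id=config.genome_id,
                    contig_id=cid,
                    start=pos + off + 1,
                    end=pos + off + len(m) * r,
                    period=len(m),
                    motif=m,
                    standard_motif=standardize_motif(m),
                    repeats=r,
                )
                for off, m, r in offsets
            )
            truth_ssrs.extend(members)
            truth_cssrs.append(
                CSSRLocus(
                    genome_id=config.genome_id,
                    contig_id=cid,
                    start=members[0].start,
                    end=members[-1].end,
                    members=members,
                    compound_motif="-".join(m.standard_motif for m in members),
                )
            )

    truth_ssrs.sort(key=lambda s: (s.contig_id, s.start))
    truth_cssrs.sort(key=lambda c: (c.contig_id, c.start))

    # final repair: rescan the full genome, disrupt any discrepancy outside
    # the planted spans, until the scan equals the truth exactly
    protected = {cid: np.zeros(n, dtype=bool) for cid, n in zip(contig_ids, sizes)}
    truth_keys = set()
    for s in truth_ssrs:
        protected[s.contig_id][s.start - 1 : s.end] = True
        truth_keys.add((s.contig_id, s.start, s.end, s.motif))

    repair_passes = 0
    for _ in range(100):
        scanned = []
        for cid, a in zip(contig_ids, arrays):
            scanned.extend(
                scan_sequence(
                    a.tobytes().decode("ascii"), params,
                    genome_id=config.genome_id, contig_id=cid,
                )
            )
        scanned_keys = {(l.contig_id, l.start, l.end, l.motif) for l in scanned}
        if scanned_keys == truth_keys:
            break
        spurious = [l for l in scanned if (l.contig_id, l.start, l.end, l.motif) not in truth_keys]
        if not spurious:
            raise RuntimeError(
                "planted loci missing from scan with no spurious locus to repair"
            )
        repair_passes += 1
        idx = {cid: i for i, cid in enumerate(contig_ids)}
        n_sub = 0
        for l in spurious:
            # a spurious locus wholly inside a planted span is the greedy
            # shadow of an upstream defect; it vanishes once that is fixed,
            # so only a pass with zero repairable loci is a real failure
            n_sub += _disrupt_span(
                arrays[idx[l.contig_id]], l.start - 1, l.end, rng,
                protected[l.contig_id],
            )
        if n_sub == 0:
            raise RuntimeError(
                "genome repair stalled: every spurious locus lies wholly "
                "inside planted spans"
            )
    else:
        raise RuntimeError("genome repair did not converge in 100 passes")

    contigs = [
        (cid, a.tobytes().decode("ascii")) for cid, a in zip(contig_ids, arrays)
    ]
    record = make_genome_record(config.genome_id, contigs, config.subclade_label)

    annotation: Optional[AnnotationIndex] = None
    ssr_regions = ["NA"] * len(truth_ssrs)
    cssr_regions = ["NA"] * len(truth_cssrs)
    if config.cds_fraction is not None:
        tracks = {
            cid: _make_cds_track(rng, n, config.cds_fraction)
            for cid, n in zip(contig_ids, sizes)
        }
        annotation = AnnotationIndex(
            genome_id=config.genome_id,
            cds_intervals={c: tuple(v) for c, v in tracks.items() if v},
        )
        ssr_regions = [
            "coding" if _overlaps_track(tracks[s.contig_id], s.start, s.end) else "noncoding"
            for s in truth_ssrs
        ]
        cssr_regions = [
            "coding" if _overlaps_track(tracks[c.contig_id], c.start, c.end) else "noncoding"
            for c in truth_cssrs
        ]

    truth = PlantedTruth(
        ssrs=truth_ssrs,
        cssrs=truth_cssrs,
        ssr_regions=ssr_regions,
        cssr_regions=cssr_regions,
        background_gc=bg_gc,
        cleaning_passes=cleaning_passes,
        repair_passes=repair_passes,
    )
    return record, annotation, truth


# --- cohort generation -------------------------------------------------------


def _weighted_choice(rng: np.random.Generator, items: Sequence, weights: Sequence[float]):
    w = np.asarray(weights, dtype=float)
    return items[int(rng.choice(len(items), p=w / w.sum()))]


def _sample_motif(rng: np.random.Generator, period: int) -> str:
    from .scan import enumerate_standard_motifs

    if period in _MOTIF_WEIGHTS:
        motifs, weights = zip(*_MOTIF_WEIGHTS[period])
        return _weighted_choice(rng, list(motifs), weights)
    pool = sorted(enumerate_standard_motifs(period))
    return pool[int(rng.integers(0, len(pool)))]


def _sample_repeats(rng: np.random.Generator, period: int, params: ScanParams) -> int:
    lo = params.min_repeats[period]
    extra = int(rng.geometric(0.6)) - 1
    cap = 9 if period == 1 else 5
    return lo + min(extra, cap)


def _sample_cssr_plan(
    rng: np.random.Generator,
    complexity: int,
    dmax: int,
    params: ScanParams,
    type_weights: Dict[int, float],
    max_tries: int = 50,
) -> CSSRPlan:
    """Draw a compound plan and keep resampling until it is scanner-consistent."""
    periods = sorted(type_weights)
    weights = [type_weights[p] for p in periods]
    for _ in range(max_tries):
        motifs: List[str] = []
        reps: List[int] = []
        for _ in range(complexity):
            p = _weighted_choice(rng, periods, weights)
            m = _sample_motif(rng, p)
            if motifs and standardize_motif(m) == standardize_motif(motifs[-1]):
                m = _sample_motif(rng, 1 if p != 1 else 2)
            motifs.append(m)
            reps.append(_sample_repeats(rng, len(m), params))
        gaps = [int(rng.integers(1, dmax + 1)) for _ in range(complexity - 1)]
        plan = CSSRPlan(tuple(motifs), tuple(reps), tuple(gaps))
        try:
            compose_compound(plan, rng, params)
            return plan
        except ConfigError:
            continue
    raise ConfigError("could not sample a scanner-consistent compound plan")


def generate_cohort(
    n: int = 54,
    size_range: Tuple[int, int] = (1_680_000, 3_310_000),
    gc_range: Tuple[float, float] = (0.5245, 0.6444),
    density_model: Optional[DensityModel] = None,
    seed: Optional[int] = None,
    dmax: int = DEFAULT_DMAX,
    cds_fraction: Optional[float] = 0.85,
    n_contigs: int = 1,
    params: Optional[ScanParams] = None,
) -> List[Tuple[GenomeRecord, Optional[AnnotationIndex], PlantedTruth]]:
    """Generate a cohort of synthetic genomes with planted ground truth.

    Defaults emulate the study conditions: 54 single-species genomes of
    1.68-3.31 Mb with GC 52.45-64.44%, planted SSR abundance proportional
    to genome size with the density model's relative noise.
    """
    if n < 3:
        raise ConfigError("a cohort needs at least 3 genomes")
    if size_range[0] > size_range[1] or size_range[0] < 1000:
        raise ConfigError(f"degenerate size_range {size_range}")
    if not 0 < gc_range[0] <= gc_range[1] < 1:
        raise ConfigError(f"degenerate gc_range {gc_range}")
    dm = density_model or DensityModel()
    params = params or ScanParams()
    master = np.random.default_rng(seed)

    complexities, cprobs = zip(*dm.complexity_probs)
    base_weights = dict(dm.type_weights)

    cohort = []
    for i in range(n):
        size = int(master.integers(size_range[0], size_range[1] + 1))
        gc = float(master.uniform(gc_range[0], gc_range[1]))
        kb = size / 1000.0

        noise = dm.relative_noise
        n_ssr = max(0, int(round(dm.ssr_per_kb * kb * (1 + noise * master.normal()))))
        n_cssr = max(0, int(round(dm.cssr_per_kb * kb * (1 + noise * master.normal()))))

        # per-genome jitter between mono and tri weight produces both of the
        # naturally occurring second-most-abundant-type patterns
        tw = dict(base_weights)
        delta = float(master.uniform(-dm.mono_tri_jitter, dm.mono_tri_jitter))
        tw[1] = max(0.01, tw[1] + delta)
        tw[3] = max(0.01, tw[3] - delta)

        cssr_plans: List[CSSRPlan] = []
        members_total = 0
        for _ in range(n_cssr):
            c = int(_weighted_choice(master, list(complexities), cprobs))
            plan = _sample_cssr_plan(master, c, dmax, params, tw)
            cssr_plans.append(plan)
            members_total += c

        n_single = max(0, n_ssr - members_total)
        periods = sorted(tw)
        weights = [tw[p] for p in periods]
        drawn_p = [
            int(_weighted_choice(master, periods, weights)) for _ in range(n_single)
        ]
        singles = Counter(
            (
                (m := _sample_motif(master, p)),
                _sample_repeats(master, len(m), params),
            )
            for p in drawn_p
        )
        ssr_plan = tuple(
            (motif, reps, count) for (motif, reps), count in sorted(singles.items())
        )

        config = PlantConfig(
            genome_size=size,
            gc_content=gc,
            seed=int(master.integers(0, 2**31 - 1)),
            genome_id=f"synth_{i+1:03d}",
            n_contigs=n_contigs,
            ssr_plan=ssr_plan,
            cssr_plan=tuple(cssr_plans),
            dmax=dmax,
            cds_fraction=cds_fraction,
        )
        cohort.append(generate_genome(config, params))
    return cohort


# --- file emission -----------------------------------------------------------


def write_genome_files(
    record: GenomeRecord,
    annotation: Optional[AnnotationIndex],
    truth: Optional[PlantedTruth],
    out_dir,
    line_width: int = 80,
) -> Dict[str, Path]:
    """Write one synthetic genome as FASTA (+ GFF3 and truth TSVs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    fasta = out_dir / f"{record.genome_id}.fasta"
    with open(fasta, "w") as fh:
        for cid, seq in record.contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    paths["fasta"] = fasta

    if annotation is not None:
        gff = out_dir / f"{record.genome_id}.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            k = 0
            for cid, intervals in sorted(annotation.cds_intervals.items()):
                for s, e in intervals:
                    k += 1
                    fh.write(
                        f"{cid}\tssrsurvey_sim\tCDS\t{s}\t{e}\t.\t+\t0\t"
                        f"ID=cds{k:06d}\n"
                    )
        paths["gff"] = gff

    if truth is not None:
        tssr = out_dir / f"{record.genome_id}.truth_ssr.tsv"
        with open(tssr, "w") as fh:
            fh.write(
                "genome_id\tcontig_id\tstart\tend\tperiod\tmotif\t"
                "standard_motif\trepeats\tregion\n"
            )
            for s, reg in zip(truth.ssrs, truth.ssr_regions):
                fh.write(
                    f"{s.genome_id}\t{s.contig_id}\t{s.start}\t{s.end}\t"
                    f"{s.period}\t{s.motif}\t{s.standard_motif}\t{s.repeats}\t{reg}\n"
                )
        paths["truth_ssr"] = tssr

        tcssr = out_dir / f"{record.genome_id}.truth_cssr.tsv"
        with open(tcssr, "w") as fh:
            fh.write(
                "genome_id\tcontig_id\tstart\tend\tcomplexity\t"
                "compound_motif\tspan_length\tregion\n"
            )
            for c, reg in zip(truth.cssrs, truth.cssr_regions):
                fh.write(
                    f"{c.genome_id}\t{c.contig_id}\t{c.start}\t{c.end}\t"
                    f"{c.complexity}\t{c.compound_motif}\t{c.span_length}\t{reg}\n"
                )
        paths["truth_cssr"] = tcssr
    return paths


def write_cohort(
    cohort: Sequence[Tuple[GenomeRecord, Optional[AnnotationIndex], PlantedTruth]],
    out_dir,
) -> Path:
    """Write a whole synthetic cohort plus a manifest usable by the CLI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        for record, annotation, truth in cohort:
            paths = write_genome_files(record, annotation, truth, out_dir)
            gff = paths["gff"].name if "gff" in paths else ""
            sub = record.subclade_label or ""
            fh.write(
                f"{record.genome_id}\t{paths['fasta'].name}\t{gff}\t{sub}\n"
            )
    return manifest
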