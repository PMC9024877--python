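"""The survey model: scan -> compound assembly -> placement -> statistics.

`MicrosatelliteSurvey` is built from genome records (or a cohort manifest)
plus the detection parameters; `fit()` runs the full pipeline over every
genome and returns a `SurveyResults` carrying all per-locus, per-genome and
cohort-level tables, a text `summary()`, and `save()` for the TSV/JSON
outputs.  Per-genome failures are isolated: the remaining genomes are still
surveyed and the failures reported on the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import annotate, cohort as cohort_mod, compound, io as io_mod, stats
from .compound import DEFAULT_DMAX
from .errors import SurveyError
from .scan import ScanParams, scan_ssrs

__all__ = ["MicrosatelliteSurvey", "SurveyResults"]

logger = logging.getLogger("ssrsurvey")


@dataclass
class _GenomeInput:
    record: io_mod.GenomeRecord
    annotation: Optional[io_mod.AnnotationIndex] = None


class MicrosatelliteSurvey:
    """Genome-wide SSR/CSSR survey over one or more assemblies.

    Parameters
    ----------
    genomes
        GenomeRecord objects (see :func:`ssrsurvey.io.read_fasta` or the
        synthetic generator).
    annotations
        Optional mapping genome_id -> AnnotationIndex; genomes without an
        entry get region "NA" (missing, not zero).
    scan_params
        Detection thresholds; defaults to 6 copies for mononucleotide
        repeats and 3 for periods 2-6.
    dmax
        Maximum gap (bases strictly between adjacent SSRs) for compound
        assembly; default 10.
    z_denominator
        "sqrt" (default, Poisson-like standardization) or "linear".
    pearson_pairs
        Variable pairs for the correlation table; defaults to nSSR and
        nCSSR against genome size, GC content and each other.
    """

    def __init__(
        self,
        genomes: Sequence[io_mod.GenomeRecord],
        annotations: Optional[Dict[str, io_mod.AnnotationIndex]] = None,
        scan_params: Optional[ScanParams] = None,
        dmax: int = DEFAULT_DMAX,
        z_denominator: str = "sqrt",
        pearson_pairs: Optional[Sequence[Tuple[str, str]]] = None,
    ):
        if not genomes:
            raise SurveyError("survey needs at least one genome")
        if z_denominator not in ("sqrt", "linear"):
            raise SurveyError(f"unknown z_denominator {z_denominator!r}")
        self.genomes = list(genomes)
        self.annotations = dict(annotations or {})
        self.scan_params = scan_params or ScanParams()
        self.dmax = int(dmax)
        self.z_denominator = z_denominator
        self.pearson_pairs = (
            tuple(pearson_pairs) if pearson_pairs is not None
            else cohort_mod.DEFAULT_PEARSON_PAIRS
        )

    @classmethod
    def from_manifest(cls, manifest_path, **kwargs) -> "MicrosatelliteSurvey":
        """Build a survey from a cohort manifest (TSV or YAML).

        Unreadable genomes raise immediately here; use `fit()`'s isolation
        only for per-genome analysis errors by loading records yourself.
        """
        entries = io_mod.read_manifest(manifest_path)
        genomes, annotations, failures = cls._load_entries(entries)
        if failures:
            raise SurveyError(
                "could not read: " + "; ".join(f"{g}: {e}" for g, e in failures)
            )
        return cls(genomes, annotations, **kwargs)

    @staticmethod
    def _load_entries(entries):
        genomes, annotations, failures = [], {}, []
        for entry in entries:
            try:
                rec = io_mod.read_fasta(
                    entry.fasta_path, entry.genome_id, entry.subclade_label
                )
                if entry.gff_path is not None:
                    annotations[entry.genome_id] = io_mod.read_gff_cds(
                        entry.gff_path, rec
                    )
                genomes.append(rec)
            except Exception as exc:  # noqa: BLE001 - isolation by design
                failures.append((entry.genome_id, str(exc)))
        return genomes, annotations, failures

    @classmethod
    def from_manifest_isolated(
        cls, manifest_path, **kwargs
    ) -> Tuple["MicrosatelliteSurvey", List[Tuple[str, str]]]:
        """Like from_manifest, but skips unreadable genomes and reports them."""
        entries = io_mod.read_manifest(manifest_path)
        genomes, annotations, failures = cls._load_entries(entries)
        if not genomes:
            raise SurveyError("no genome in the manifest could be read")
        return cls(genomes, annotations, **kwargs), failures

    def fit(self) -> "SurveyResults":
        """Run the survey; always returns, carrying per-genome failures."""
        ssr_rows: List[dict] = []
        cssr_rows: List[dict] = []
        summaries: List[stats.GenomeSummary] = []
        loci_by_genome: Dict[str, list] = {}
        cssrs_by_genome: Dict[str, list] = {}
        ok_genomes: List[io_mod.GenomeRecord] = []
        failures: List[Tuple[str, str]] = []

        for rec in self.genomes:
            try:
                logger.info("surveying %s (%d bp)", rec.genome_id, rec.total_length)
                ssrs = scan_ssrs(rec, self.scan_params)
                cssrs, in_cssr = compound.build_cssrs(ssrs, self.dmax)
                ann = self.annotations.get(rec.genome_id)
                ssr_regions = annotate.classify_regions(ssrs, ann)
                cssr_regions = annotate.classify_regions(cssrs, ann)
                summaries.append(
                    stats.summarize_genome(rec, ssrs, cssrs, ssr_regions, cssr_regions)
                )
                loci_by_genome[rec.genome_id] = ssrs
                cssrs_by_genome[rec.genome_id] = cssrs
                ok_genomes.append(rec)
                for s, reg, flag in zip(ssrs, ssr_regions, in_cssr):
                    ssr_rows.append(
                        {
                            "genome_id": s.genome_id, "contig_id": s.contig_id,
                            "start": s.start, "end": s.end, "period": s.period,
                            "motif": s.motif, "standard_motif": s.standard_motif,
                            "repeats": s.repeats, "length": s.length,
                            "region": reg, "in_cssr": flag,
                        }
                    )
                for c, reg in zip(cssrs, cssr_regions):
                    cssr_rows.append(
                        {
                            "genome_id": c.genome_id, "contig_id": c.contig_id,
                            "start": c.start, "end": c.end,
                            "complexity": c.complexity,
                            "compound_motif": c.compound_motif,
                            "span_length": c.span_length,
                            "member_count": c.complexity, "region": reg,
                        }
                    )
            except Exception as exc:  # noqa: BLE001 - per-genome isolation
                logger.error("genome %s failed: %s", rec.genome_id, exc)
                failures.append((rec.genome_id, str(exc)))

        if not summaries:
            raise SurveyError("every genome failed; nothing to report")

        ssr_loci = pd.DataFrame(ssr_rows, columns=io_mod.SSR_COLUMNS)
        cssr_loci = pd.DataFrame(cssr_rows, columns=io_mod.CSSR_COLUMNS)
        matrix = stats.motif_ra_matrix(ok_genomes, loci_by_genome)

        all_cssrs = [c for cs in cssrs_by_genome.values() for c in cs]
        cx_counts, cx_props = compound.complexity_spectrum(all_cssrs)
        uniq_counts, uniq_total = compound.unique_compound_motifs(cssrs_by_genome)

        any_cssr = any(s.nCSSR > 0 for s in summaries)
        if any_cssr:
            c_bar = cohort_mod.mean_complexity(summaries)
            z_table = cohort_mod.z_scores(summaries, c_bar, self.z_denominator)
        else:
            c_bar = float("nan")
            z_table = pd.DataFrame(
                columns=["genome_id", "ncSSR", "nCSSR_obs", "nCSSR_exp", "Z"]
            )
        if len(summaries) >= 3:
            correlations = cohort_mod.pearson_table(summaries, self.pearson_pairs)
        else:
            correlations = pd.DataFrame(columns=["pair", "rho", "p_value", "n"])

        pattern_tally: Dict[str, int] = {}
        for s in summaries:
            pattern_tally[s.pattern] = pattern_tally.get(s.pattern, 0) + 1

        cohort_result = cohort_mod.CohortResult(
            n=len(summaries),
            c_bar=c_bar,
            z_table=z_table,
            correlations=correlations,
            complexity_counts=cx_counts,
            complexity_proportions=cx_props,
            unique_motif_counts=uniq_counts,
            unique_motif_total=uniq_total,
            total_ssr=int(sum(s.nSSR for s in summaries)),
            total_cssr_loci=int(sum(s.nCSSR for s in summaries)),
            total_cssr_members=int(sum(s.ncSSR for s in summaries)),
            pattern_tally=pattern_tally,
        )
        return SurveyResults(
            model=self,
            summaries=summaries,
            ssr_loci=ssr_loci,
            cssr_loci=cssr_loci,
            motif_ra_matrix=matrix,
            cohort=cohort_result,
            failures=failures,
        )


def _fmt(x, nd=3):
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{nd}f}"


class SurveyResults:
    """Fitted survey: per-locus, per-genome and cohort tables.

    Attributes
    ----------
    ssr_loci, cssr_loci : pandas.DataFrame
        One row per locus with coordinates, motifs, region calls.
    genome_summary : pandas.DataFrame
        One row per genome (counts, RA/RD, cSSR%, pattern, coding
        fractions, nCSSR_exp, Z).
    motif_ra_matrix : pandas.DataFrame
        Standard motifs x genomes, relative abundance per kb.
    correlations, z_table, unique_motifs : pandas.DataFrame
    cohort : CohortResult
    failures : list of (genome_id, message)
    """

    def __init__(self, model, summaries, ssr_loci, cssr_loci, motif_ra_matrix,
                 cohort, failures):
        self.model = model
        self.summaries = summaries
        self.ssr_loci = ssr_loci
        self.cssr_loci = cssr_loci
        self.motif_ra_matrix = motif_ra_matrix
        self.cohort = cohort
        self.failures = failures

    # -- tabular views --------------------------------------------------------

    @property
    def genome_summary(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            row = {
                "genome_id": s.genome_id,
                "subclade": s.subclade_label if s.subclade_label is not None else "",
                "genome_size": s.genome_size,
                "gc_content": s.gc_content,
                "nSSR": s.nSSR,
                "nCSSR": s.nCSSR,
                "ncSSR": s.ncSSR,
                "cSSR_pct": s.cSSR_pct,
                "RA_ssr": s.RA_ssr,
                "RD_ssr": s.RD_ssr,
                "RA_cssr": s.RA_cssr,
                "RD_cssr": s.RD_cssr,
                "pattern": s.pattern,
                "pattern_tie": s.pattern_tie,
                "coding_fraction_ssr": s.coding_fraction_ssr,
                "coding_fraction_cssr": s.coding_fraction_cssr,
                "nCSSR_exp": s.nCSSR_exp,
                "Z": s.Z,
            }
            for p in range(1, 7):
                row[f"n_period_{p}"] = s.type_counts.get(p, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def correlations(self) -> pd.DataFrame:
        return self.cohort.correlations

    @property
    def z_table(self) -> pd.DataFrame:
        return self.cohort.z_table

    @property
    def unique_motifs(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.cohort.unique_motif_counts.items()),
            columns=["genome_id", "unique_compound_motifs"],
        )

    @property
    def c_bar(self) -> float:
        return self.cohort.c_bar

    # -- reporting ------------------------------------------------------------

    def run_manifest(self) -> dict:
        return {
            "package": "ssrsurvey",
            "version": _pkg_version,
            "n_genomes": self.cohort.n,
            "scan_params": self.model.scan_params.as_dict(),
            "dmax": self.model.dmax,
            "z_denominator": self.model.z_denominator,
            "pearson_pairs": [list(p) for p in self.model.pearson_pairs],
            "rng": "numpy PCG64 (simulation only)",
            "failures": [list(f) for f in self.failures],
        }

    def summary(self) -> str:
        c = self.cohort
        lines = [
            "Microsatellite survey",
            "=" * 60,
            f"genomes surveyed            {c.n}",
            f"total SSRs                  {c.total_ssr}",
            f"total compound loci (CSSR)  {c.total_cssr_loci}",
            f"total compound members      {c.total_cssr_members}",
            f"mean complexity C_bar       {_fmt(c.c_bar)}",
            "",
            "complexity spectrum:",
        ]
        for k, v in c.complexity_counts.items():
            lines.append(
                f"  C={k:<2d} {v:>8d}  ({100 * c.complexity_proportions[k]:.1f}%)"
            )
        lines.append("")
        lines.append("repeat-type pattern tally:")
        for pat, cnt in sorted(c.pattern_tally.items()):
            lines.append(f"  {pat:<18s} {cnt}")
        lines.append(f"unique compound motifs      {c.unique_motif_total}")
        if len(c.correlations):
            lines.append("")
            lines.append("Pearson correlations:")
            for _, r in c.correlations.iterrows():
                lines.append(
                    f"  {r['pair']:<22s} rho={_fmt(r['rho'])}  p={_fmt(r['p_value'], 4)}"
                )
        if self.failures:
            lines.append("")
            lines.append("failed genomes:")
            for gid, msg in self.failures:
                lines.append(f"  {gid}: {msg}")
        return "\n".join(lines)

    def save(self, out_dir) -> Dict[str, object]:
        """Write all result tables and the run manifest; see io.write_tables."""
        return io_mod.write_tables(self, out_dir)
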