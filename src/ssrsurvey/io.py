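"""Genome and annotation input, result-table output.

Coordinates are 1-based inclusive throughout (the GFF3 convention); any
internal half-open arithmetic converts at the boundary.  Soft-masked
(lowercase) sequence is uppercased and treated as ordinary sequence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import FormatError, GFFParseError

__all__ = [
    "GenomeRecord",
    "AnnotationIndex",
    "ManifestEntry",
    "read_fasta",
    "read_gff_cds",
    "read_manifest",
    "write_tables",
    "make_genome_record",
]

_IUPAC = set("ACGTUNRYSWKMBDHV")

SSR_COLUMNS = [
    "genome_id", "contig_id", "start", "end", "period", "motif",
    "standard_motif", "repeats", "length", "region", "in_cssr",
]
CSSR_COLUMNS = [
    "genome_id", "contig_id", "start", "end", "complexity",
    "compound_motif", "span_length", "member_count", "region",
]


@dataclass(frozen=True)
class GenomeRecord:
    """A genome assembly: ordered contigs plus basic composition statistics."""

    genome_id: str
    contigs: Tuple[Tuple[str, str], ...]
    total_length: int
    gc_content: float
    subclade_label: Optional[str] = None

    def contig_lengths(self) -> Dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs}


def make_genome_record(
    genome_id: str,
    contigs: Sequence[Tuple[str, str]],
    subclade_label: Optional[str] = None,
) -> GenomeRecord:
    """Build a GenomeRecord, computing total length and GC content.

    GC content is (#G + #C) / (#A + #C + #G + #T); ambiguity codes are
    excluded from the denominator.
    """
    seen = set()
    total = 0
    gc = 0
    acgt = 0
    norm_contigs = []
    for cid, seq in contigs:
        if cid in seen:
            raise FormatError(f"duplicate contig id {cid!r} in genome {genome_id!r}")
        seen.add(cid)
        seq = seq.upper().replace("U", "T")
        total += len(seq)
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
        norm_contigs.append((cid, seq))
    return GenomeRecord(
        genome_id=genome_id,
        contigs=tuple(norm_contigs),
        total_length=total,
        gc_content=(gc / acgt) if acgt else 0.0,
        subclade_label=subclade_label,
    )


@dataclass(frozen=True)
class AnnotationIndex:
    """Per-contig CDS intervals (1-based inclusive), strand ignored."""

    genome_id: str
    cds_intervals: Dict[str, Tuple[Tuple[int, int], ...]]

    def n_intervals(self) -> int:
        return sum(len(v) for v in self.cds_intervals.values())


@dataclass(frozen=True)
class ManifestEntry:
    genome_id: str
    fasta_path: Path
    gff_path: Optional[Path] = None
    subclade_label: Optional[str] = None


def read_fasta(path, genome_id: str, subclade_label: Optional[str] = None) -> GenomeRecord:
    """Read a (multi-)FASTA assembly into a GenomeRecord.

    Sequences are uppercased and U is mapped to T.  Raises FormatError for
    an empty file, duplicate contig ids, or records whose content is not
    dominated by nucleotide codes.
    """
    path = Path(path)
    contigs: List[Tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if seq:
            bad = sum(seq.count(ch) for ch in set(seq) if ch not in _IUPAC)
            if bad > 0.1 * len(seq):
                raise FormatError(
                    f"record {rec.id!r} in {path} is not nucleotide-dominant"
                )
        contigs.append((rec.id, seq))
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return make_genome_record(genome_id, contigs, subclade_label)


def read_gff_cds(path, genome: GenomeRecord) -> AnnotationIndex:
    """Extract CDS intervals from a GFF3 file into a per-contig sorted index.

    Features of type other than CDS are ignored; a CDS on a contig absent
    from the genome is skipped with a warning; intervals extending past a
    contig end are clipped with a warning.  A malformed feature line raises
    GFFParseError carrying the line number.
    """
    path = Path(path)
    lengths = genome.contig_lengths()
    by_contig: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                break  # embedded FASTA section ends the feature table
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(
                    f"expected 9 tab-separated columns, got {len(cols)}", lineno
                )
            if cols[2] != "CDS":
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise GFFParseError(
                    f"non-integer coordinates {cols[3]!r}/{cols[4]!r}", lineno
                ) from None
            if start < 1 or start > end:
                raise GFFParseError(f"invalid interval {start}..{end}", lineno)
            contig = cols[0]
            if contig not in lengths:
                warnings.warn(
                    f"{path}:{lineno}: CDS on unknown contig {contig!r}; skipped"
                )
                continue
            clen = lengths[contig]
            if start > clen:
                warnings.warn(
                    f"{path}:{lineno}: CDS {start}..{end} beyond contig end {clen}; skipped"
                )
                continue
            if end > clen:
                warnings.warn(
                    f"{path}:{lineno}: CDS {start}..{end} clipped to contig end {clen}"
                )
                end = clen
            by_contig.setdefault(contig, []).append((start, end))
    return AnnotationIndex(
        genome_id=genome.genome_id,
        cds_intervals={c: tuple(sorted(v)) for c, v in by_contig.items()},
    )


def read_manifest(path) -> List[ManifestEntry]:
    """Read a cohort manifest (TSV or YAML).

    TSV columns: genome_id, fasta_path[, gff_path[, subclade]]; empty gff
    cells mean "no annotation".  YAML form: a list of mappings with keys
    genome_id, fasta, optional gff and subclade.
    """
    path = Path(path)
    entries: List[ManifestEntry] = []
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, list):
            raise FormatError(f"YAML manifest {path} must be a list of mappings")
        for i, item in enumerate(data):
            try:
                entries.append(
                    ManifestEntry(
                        genome_id=str(item["genome_id"]),
                        fasta_path=path.parent / item["fasta"],
                        gff_path=(path.parent / item["gff"]) if item.get("gff") else None,
                        subclade_label=item.get("subclade"),
                    )
                )
            except KeyError as e:
                raise FormatError(f"manifest entry {i}: missing key {e}") from None
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: manifest rows need >= 2 columns"
                    )
                gff = cols[2] if len(cols) > 2 and cols[2] else None
                sub = cols[3] if len(cols) > 3 and cols[3] else None
                entries.append(
                    ManifestEntry(
                        genome_id=cols[0],
                        fasta_path=path.parent / cols[1],
                        gff_path=(path.parent / gff) if gff else None,
                        subclade_label=sub,
                    )
                )
    if not entries:
        raise FormatError(f"manifest {path} lists no genomes")
    return entries


def _to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def write_tables(results, out_dir) -> Dict[str, Path]:
    """Write all survey result tables and the JSON run manifest.

    Emits ssr_loci.tsv, cssr_loci.tsv, genome_summary.tsv,
    motif_ra_matrix.tsv, correlations.tsv, unique_motifs.tsv, z_scores.tsv
    and run_manifest.json with every parameter echoed.  Output is
    deterministic: identical inputs and configuration yield byte-identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    tables = {
        "ssr_loci": results.ssr_loci.loc[:, SSR_COLUMNS],
        "cssr_loci": results.cssr_loci.loc[:, CSSR_COLUMNS],
        "genome_summary": results.genome_summary,
        "motif_ra_matrix": results.motif_ra_matrix.reset_index(),
        "correlations": results.correlations,
        "unique_motifs": results.unique_motifs,
        "z_scores": results.z_table,
    }
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        _to_tsv(df, p)
        paths[name] = p

    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(
        json.dumps(results.run_manifest(), indent=2, sort_keys=True) + "\n"
    )
    paths["run_manifest"] = manifest_path
    return paths


def read_ssr_table(path) -> pd.DataFrame:
    """Read an ssr_loci.tsv back into a DataFrame with proper dtypes."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={
            "genome_id": str, "contig_id": str, "motif": str,
            "standard_motif": str, "region": str,
        },
    )
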