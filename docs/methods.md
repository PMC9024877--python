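# Methods

## Scope and model

`ssrsurvey` performs a genome-wide survey of perfect microsatellites (SSRs)
and compound microsatellites (CSSRs) over one or more assemblies, the kind
of descriptive repeat landscape used to compare closely related prokaryotic
genomes. The survey has four stages:

1. **Detection.** A perfect SSR is a tandem repetition of a 1–6 bp motif
   with at least `min_repeats(period)` complete copies; the defaults are
   6 copies for mononucleotide repeats and 3 copies for periods 2–6, the
   thresholds customary for small prokaryotic genomes. Runs never cross an
   ambiguity code or a contig boundary, and a reported motif always has
   minimal period (an (AC)n run is never additionally reported as period
   4 or 6).
2. **Compound assembly.** SSRs on one contig whose pairwise gap (bases
   strictly between them; 0 = abutting) is at most `dmax` (default 10 bp)
   are chained; maximal chains with ≥ 2 members are compound loci. Members
   keep their identity and still count in nSSR, so
   cSSR% = 100·ncSSR/nSSR ≤ 100.
3. **Placement.** A locus is *coding* when its 1-based inclusive span
   overlaps any CDS interval from the GFF3 annotation by ≥ 1 base;
   compound loci are classified by their full span. Genomes without
   annotation report missing (NA) coding fractions, never zero.
4. **Statistics.** Per genome: nSSR, nCSSR (compound loci), ncSSR (compound
   members), cSSR%, relative abundance RA (loci per kb, kb = 1000 bp
   exactly) and relative density RD (repeat bp per kb), repeat-type
   composition and its ordering pattern, coding fractions, and the
   per-standard-motif RA matrix. Per cohort: mean complexity
   C̄ = (1/n)Σ ncSSRᵢ/nCSSRᵢ, the Z index, unique compound-motif counts,
   the pooled complexity spectrum, and Pearson correlations.

### Motif standardization

Counting motifs literally fragments classes across strands and phases, so
each motif is mapped to its *standard motif*: the lexicographically smallest
string (A<C<G<T) among all cyclic rotations of the motif and of its reverse
complement. This collapses the 4 mononucleotides into the two classes A and
C, the 12 minimal dinucleotides into AC, AG, AT, CG, and the minimal motifs
of periods 3–6 into 10, 33, 102 and 350 classes respectively.

### The Z index

With C̄ the cohort mean of members-per-compound-locus, the expected number
of compound loci in genome *i* is nCSSR_exp = ncSSRᵢ/C̄, and

    Z = (nCSSR_obs − nCSSR_exp) / sqrt(nCSSR_exp)

a Poisson-like standardization: Z > 0 means the genome splits its compound
members into more, smaller loci than the cohort average. The square-root
denominator is the package default; a plain-ratio denominator
(`z_denominator="linear"`) is provided as a configuration switch because
both conventions circulate, and the choice is echoed into the run manifest.
Genomes with no compound loci have an undefined ratio and are excluded from
C̄ with a warning.

### Correlations

Pearson product-moment coefficients with two-sided p-values from the
t transform (n−2 df), via `scipy.stats.pearsonr`. Default pairs: nSSR and
nCSSR each against genome size, GC content and the other repeat counts. No
multiple-testing correction is applied — the table is descriptive, not a
screening procedure.

## Scanner algorithm and its oracle

Scanning is greedy left-to-right: at each position, periods are tried in
increasing order; the first qualifying maximal run is emitted, truncated to
whole motif copies, and scanning resumes immediately after it. This gives a
single canonical, non-overlapping decomposition per contig, matching the
common behaviour of MISA/Krait-style repeat finders. Because published
per-genome counts from such tools depend on this (undocumented) overlap
convention, counts from other scanners may deviate by a small margin; any
such discrepancy is a convention difference, not a detection difference.

The implementation precomputes, per period p, the boolean match array
`s[j] == s[j+p]` (numpy), enumerates candidate start positions from its
run-length encoding, and replays the greedy rule over candidates only. The
test suite holds it to *exact* locus-list agreement with an independent
character-by-character brute-force enumerator on hundreds of random
sequences at GC 0.3–0.65, with and without ambiguity codes.

## Synthetic genomes

The generator emulates the study conditions for small marine
picocyanobacterial assemblies and is the basis of all end-to-end testing:

* genome size 1.68–3.31 Mb and GC 52.45–64.44% (cohort defaults; any range
  can be requested);
* planted SSR abundance 2.6 loci/kb proportional to genome size with 5%
  relative noise — the centre of the observed 2.44–2.91/kb range;
* compound-locus abundance 0.085/kb with complexity distribution
  {2: 0.949, 3: 0.046, 4: 0.004, 5: 0.001}, giving a mean of ≈ 2.06
  members per locus;
* motif pools weighted toward the classes that dominate such genomes
  (A over C; AG, AC, CG among dinucleotides; AGC, ACG, ACC, CCG among
  trinucleotides), with copy numbers drawn from a truncated geometric above
  each detection threshold — values the survey literature reports only
  qualitatively, so fixed here once as realistic defaults;
* an optional CDS track covering ~85% of each genome (cyanobacteria-like
  coding density), emitted as GFF3.

**Exactness guarantee.** Background sequence is sampled base-by-base at the
target GC and then *cleaned*: every accidental run meeting the thresholds
is disrupted by substitutions (one per ≤ 5 bases of the run, at a random
phase — a fixed phase can rebuild a rotated periodic run and cycle), until
a scan of the background alone returns nothing. Features are placed
uniformly with ≥ dmax+1 clearance so no accidental compound loci form. A
final repair loop rescans the whole genome and disrupts any residual
discrepancy — typically a background base extending a planted run —
touching only bases outside planted spans, until the scan equals the truth
exactly. Compound templates are validated up front: gap bases are resampled
until the scanner, run on the composed feature alone, reproduces the
members; plans with no scanner-consistent realization (e.g. (A)₆ abutting
(AC)₃, where the junction A necessarily extends the first run) are rejected
as configuration errors. Cleaning and repair pass counts are recorded on
the truth object; both loops are bounded and raise if they stall.

**What the generator does not emulate**: real gene structure and codon
bias, phylogenetic relatedness between genomes, imperfect/interrupted
repeats, and mutation processes around repeat loci. Passing recovery tests
therefore demonstrates the correctness of detection, assembly, placement
and statistics on genomes whose repeat content is known exactly — not the
biological accuracy of any particular threshold choice on real data.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere (GFF3 convention); internal
  half-open arithmetic converts at the boundary.
* GC content excludes ambiguity codes from the denominator; RA/RD
  denominators use total assembly length *including* ambiguity bases.
* RD for compound loci counts the full span including interruptions — the
  compound locus is one genomic feature; the summed-member alternative is
  computable from the per-locus table.
* Compound-motif patterns join member standard motifs in genomic order
  ("A-AC-AGC"); a pattern and its reversal are *not* collapsed.
* Repeat-type pattern labels order mono/di/tri counts descending; ties are
  joined with "=" and flagged rather than broken arbitrarily.
* All tables are written with fixed column orders and fixed float
  formatting, so identical inputs and configuration give byte-identical
  outputs; every parameter is echoed into `run_manifest.json`.
* Per-genome analysis failures are isolated: the remaining genomes are
  surveyed and the failures listed (CLI exit status 2).

## Problem sizes used in validation

The test suite and the acceptance script exercise the pipeline at sizes
chosen to keep a full run fast while preserving every per-kb density:
scanner/oracle agreement on 200 × 2 kb sequences; exact planted recovery on
a 2 Mb genome with 500 individual SSRs and 50 compound loci; and a
54-genome cohort at 200–300 kb per genome with the full-scale defaults for
GC, abundance, complexity and coding density. Full-scale (1.68–3.31 Mb)
generation is supported and used by the `simulate` CLI defaults.

## Known limitations

* Only perfect repeats are detected; a single interruption splits a locus.
* The greedy decomposition is one of several defensible conventions;
  counts are comparable *within* a convention.
* The Z index's square-root standardization treats compound-locus counts as
  Poisson-like; for very small ncSSR the index is noisy.
* Correlation p-values assume independent genomes; phylogenetic
  non-independence in real cohorts is not modelled.
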