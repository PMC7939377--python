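# Methods

## Problem and scope

`ssrpanel` designs SSR (microsatellite) marker panels that fingerprint a
sub-population within a structured cohort. Given a reference genome, a
multi-sample VCF of SSR genotypes and a sample→sub-population table, it
(1) detects perfect tandem repeats de novo, (2) filters loci down to those
carrying a *private fixed allele* — an allele observed in exactly one
sub-population with every genotyped member homozygous for it — (3) scores
candidate loci with gene diversity (H) and polymorphism information
content (PIC), and (4) exports a named, genomically ordered panel with
flanking sequence for primer design. Read alignment, variant calling and
primer thermodynamics are upstream/downstream of this tool and out of
scope.

## Repeat model and scanner

A locus is a maximal run of a primitive 1–6 bp motif repeated perfectly
(no mismatches or indels; the final copy may be partial). "Primitive"
means the motif is not a whole-number power of a shorter unit, so `ATAT`
tracts are reported with motif `AT`. The scanner compares the sequence
with itself at each lag k and extracts maximal match runs, which is exact
for this model; tracts never cross an `N`.

Maximal tracts of different periods can overlap (a homopolymer run
abutting a dinucleotide tract, for example). Overlaps are resolved
deterministically: the longer tract wins, ties go to the shorter motif,
then to the leftmost start. The motif is reported in the phase of its
first occurrence, matching how published marker tables print structures
such as `GCG (12)`; canonical comparisons can use `primitive_motif`.

Defaults (all configurable): motif length 1–6 bp, tract length 10–500 bp,
at least 2 copies. The 10 bp floor reflects the smallest tracts that are
informative for length genotyping from short reads; the 500 bp ceiling is
the conventional upper bound for short-tandem-repeat callers. Whole-copy
counts are floors of tract length over motif length (`copies_whole`),
the figure printed in marker tables.

Coordinates are 1-based inclusive in all TSV/VCF-facing structures and
0-based half-open in BED, the respective conventions of those formats.

## Cohort model and presence scoring

Genotypes are diploid; half-calls are treated as missing, the conservative
choice compatible with the downstream complete-call requirement. The
presence matrix scores a locus 1 for a population when at least one of its
samples has a non-missing genotype (i.e. any reference or alternative
allele was observed); Venn sector counts are exact-subset counts over all
2^P population subsets plus the empty subset, and always sum to the number
of loci. Allele frequencies are chromosome counts over genotyped samples
only.

## Filtering cascade

Stage order (configurable; the independent predicates commute):

1. **allele count / call rate** — observed allele count within
   [2, 13] and no missing genotypes (a maximum missing fraction of 0,
   i.e. vcftools `--max-missing 1` semantics).
2. **doubleton** — keep loci with a private fixed allele: some allele a
   and population p with (i) a carried by ≥1 sample of p, (ii) a absent
   outside p, (iii) every genotyped sample of p homozygous a/a. This
   reproduces the merge-each-population-into-one-pseudo-individual
   doubleton semantics without physically merging files.
3. **length SD** — sample standard deviation (n−1) of the listed allele
   lengths (REF + ALTs, unweighted by frequency) strictly greater than
   7 bp. The unweighted choice follows from the computation being defined
   over the allele *lists*; n−1 matches the default of standard
   statistical software. Single-allele loci fail the stage.
4. **telomere margin** — the whole tract must lie within
   [margin+1, chrom_len−margin]; default margin 1 Mb.
5. **tract length and motif** — reference tract length within the closed
   window [13, 49] bp and primitive motif length ≥ 2 (homopolymers
   removed).

Boundary semantics are literal: SD retained iff > 7; lengths retained iff
13 ≤ L ≤ 49. The report telescopes (each stage's output is the next
stage's input) and annotates every survivor with its private population
and allele.

## Diversity statistics

H = 1 − Σ P_i² and PIC = H − Σ_{i<j} 2 P_i² P_j², with the pairwise sum
evaluated as (Σ P_i²)² − Σ P_i⁴ (an exact rearrangement). Frequencies are
computed over genotyped chromosomes, pooling all sub-populations, and only
observed alleles count toward l. Classes follow the conventional
thresholds — highly informative above PIC 0.5, reasonably informative
between 0.25 and 0.5, slightly informative below 0.25. The printed
thresholds leave the boundary values unassigned; this package assigns
boundaries downward (0.5 → reasonably, 0.25 → slightly).

## Panel naming and export

Markers sort by (chromosome order, start, end); chromosome order defaults
to FASTA sequence order. Ordinals are assigned per prefix starting at 1,
with the prefix chosen by the diagnostic population (e.g.
`margaritiferum → Xgma`) and a default (`Xunr`) otherwise. The
population-specific repeat structure of a doubleton locus is derived from
the private allele's length: floor(allele length / motif length) copies.
Exports are byte-stable: identical inputs give identical files. The
package ships the published six-marker margaritiferum panel
(`load_builtin_panel`) with its 40 bp primers as a reference fixture.

## Synthetic data generator

The generator stands in for a resequenced cohort: it emulates the
sub-population structure of the sorghum study (six races at sample sizes
4/29/19/3/16/4, 75 accessions) over a small multi-chromosome genome —
default 3 × 40 kb, a scale chosen so the full pipeline runs in seconds
while preserving every structural feature the filters act on. Planted
loci are perfect repeats whose flanks are *verified* repeat-free by
rejection-sampling the background against the scanner itself, so scanner
recovery is exact by construction. Alleles follow a stepwise mutation
model: lengths differ by whole motif units only.

Private fixed loci make one population homozygous for an allele absent
elsewhere; private segregating loci leave at least one member
heterozygous; shared loci draw from a common pool. The first sample of
every population is seeded heterozygous for two common alleles, which
structurally rules out *accidental* private fixed alleles — the recorded
truth table is therefore exact, and doubleton precision/recall against it
must be 1.0. An `admixture` knob leaks would-be private alleles into the
remaining populations; leak decisions are drawn once per locus before any
other randomness, so for a fixed seed the surviving doubleton count is
non-increasing in the admixture rate (mirroring how admixture between
sub-populations erodes fingerprinting power). Structural carriers are
protected from missingness masking so truth remains exact at any missing
rate.

What the generator does **not** emulate: read-level noise (stutter,
depth-dependent dropout), imperfect/compound repeats, linkage between
loci, and realistic genome composition (GC structure, transposable
elements). Passing tests therefore demonstrate correctness of the
genotype-level method, not robustness to raw-read artefacts.

Determinism: all randomness derives from `numpy.random.default_rng`
seeded from the design seed; identical seeds give byte-identical FASTA
and VCF output.

## Numerical and degenerate-input choices

- Frequency vectors must sum to 1 within 1e−9; computed frequencies sum
  to 1 within 1e−12.
- A VCF record with symbolic/breakend alleles is skipped with a warning
  count; a sample absent from the population table is a hard error.
- pysam cannot write ALT="." records, so exporting a single-allele locus
  raises; the simulator lists one unobserved stepwise-neighbour ALT at
  genotypically monomorphic sites instead, as merged call sets do.
- Flank extraction truncates at chromosome ends and flags the truncation
  rather than padding.

## Verification

Unit and property tests check the scanner against a brute-force
enumerate-and-resolve oracle (fixed-seed random and repeat-rich
sequences, plus hypothesis cases), H/PIC against naive double-loop
oracles with the PIC ≤ H ≤ 1 − 1/l bound, the doubleton filter against
an allele×population brute force and against planted truth over 50
seeded designs, cascade telescoping and stage commutation, and byte-level
round-trips of VCF and panel TSV. `scripts/acceptance.py` recomputes the
published Xgma1 whole-copy count from its printed repeat structure via
the scanner. Recomputing the published informativeness tally requires the
deposited per-accession genotype table (see `data/deposited/README.md`),
which is not redistributable with the package.
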