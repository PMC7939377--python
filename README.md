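# ssrpanel

De novo SSR (microsatellite) discovery, population-aware **doubleton
filtering**, and targeted-sequencing marker panel design.

`ssrpanel` is for plant geneticists and breeders who want a small set of
SSR markers that fingerprints one sub-population of a structured cohort —
for example the guinea working group *margaritiferum* within cultivated
sorghum — so that sub-population identity can be assayed with a cheap
targeted NGS panel instead of genome-wide SNPs. It takes a reference
genome (FASTA), a multi-sample VCF of SSR genotypes and a
sample→sub-population table, and produces a named, ordered panel with
diversity statistics and flanking sequence for primer design.

## Method

1. **Repeat scanner** — every maximal perfect tandem repeat of a
   primitive 1–6 bp motif (tract 10–500 bp, ≥2 copies by default), with
   deterministic overlap resolution (longest tract, then shortest motif,
   then leftmost).
2. **Doubleton filter** — the selective step. A locus is kept when some
   allele *a* and sub-population *p* satisfy: *a* occurs in *p*, nowhere
   else, and every genotyped member of *p* is homozygous *a/a* — a
   private fixed allele, equivalent to treating each sub-population as
   one merged diploid individual. Flanking stages require 2–13 observed
   alleles with complete calls, allele-length SD > 7 bp, distance > 1 Mb
   from chromosome ends, reference tract length in [13, 49] bp, and a
   non-homopolymer motif.
3. **Diversity statistics** — per locus, over allele frequencies P_i:

   H = 1 − Σ P_i²  and  PIC = 1 − Σ P_i² − Σ_{i<j} 2 P_i² P_j²

   with markers classed highly (PIC > 0.5), reasonably (0.25–0.5) or
   slightly (< 0.25) informative.
4. **Panel export** — markers named `X<tag><ordinal>` in genomic order
   (e.g. `Xgma1…Xgma6` for margaritiferum-diagnostic loci), written as
   TSV/BED with repeat structures, statistics and primers. The published
   six-marker sorghum panel ships with the package
   (`ssrpanel.load_builtin_panel()`).

A synthetic-data module (`ssrpanel.simdata`) generates small
multi-chromosome genomes with planted repeats and cohorts with known
private fixed alleles under a stepwise mutation model, giving exact
ground truth for every stage. See `docs/methods.md` for the full model
description and design choices.

## Worked example

Simulate a cohort (six sub-populations, 75 samples, 22 planted SSR loci,
six of them carrying margaritiferum-private fixed alleles), then run the
full pipeline:

```sh
ssrpanel simulate --seed 42 --outdir demo
ssrpanel run-all demo/genome.fa demo/cohort.vcf demo/populations.tsv \
    --telomere-margin 2000 --prefix margaritiferum=Xgma \
    --out-panel demo/panel.tsv --out-report demo/cascade.tsv
```

The cascade log shows each stage's telescoping counts:

```
stage allele_count in=22 out=20 removed=2
stage doubleton    in=20 out=6 removed=14
stage sd           in=6 out=6 removed=0
stage telomere     in=6 out=6 removed=0
stage length_motif in=6 out=6 removed=0
wrote 6-marker panel to demo/panel.tsv
```

The two loci removed at `allele_count` are monomorphic; `doubleton` keeps
exactly the six loci whose alleles are private to and fixed in
margaritiferum. The panel (selected columns of `demo/panel.tsv`):

```
name   chrom  start  end   ref_structure  pop_structure  H         PIC       private_population
Xgma1  1      2139   2171  GCC (11)       GCC (16)       0.694667  0.633463  margaritiferum
Xgma2  1      2429   2443  GGATG (3)      GGATG (7)      0.696444  0.635204  margaritiferum
Xgma3  2      2161   2188  CT (14)        CT (21)        0.696622  0.635427  margaritiferum
Xgma4  2      2518   2541  AT (12)        AT (19)        0.697867  0.636675  margaritiferum
Xgma5  3      2146   2190  AAG (15)       AAG (20)       0.698044  0.636848  margaritiferum
Xgma6  3      2558   2595  AG (19)        AG (26)        0.685956  0.625328  margaritiferum
```

`ref_structure` is the repeat in the reference genome (motif and
whole-copy count), `pop_structure` the diagnostic allele fixed in
margaritiferum — e.g. `Xgma1` carries 16 GCC copies in margaritiferum
against 11 in the reference. All six markers are highly informative
(PIC > 0.5) across the pooled cohort. Each pipeline step is also
available separately (`scan`, `presence`, `filter`, `stats`, `panel`) and
as library functions.

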