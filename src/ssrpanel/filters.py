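"""Filtering cascade selecting sub-population-diagnostic SSR loci.

The cascade mirrors a targeted-marker design workflow: an allele-count and
call-rate filter, the doubleton filter (the selective step that finds
private fixed alleles fingerprinting one sub-population), an allele-length
standard-deviation filter favouring length-diverse loci, a telomeric-margin
exclusion, a tract-length window compatible with short-read amplicons, and
removal of homopolymer motifs.

A *doubleton* locus carries an allele that (i) occurs in at least one
sample of exactly one sub-population, (ii) occurs in no sample outside that
sub-population, and (iii) is homozygous in every genotyped member of that
sub-population — i.e. a private fixed allele when each sub-population is
collapsed to a single diploid pseudo-individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .cohort import CohortGenotypes, LocusGenotypes, PopulationAssignment
from .repeats import SSRLocus, primitive_motif


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade.

    Boundary semantics are deliberate: loci are retained when the allele
    count lies in the closed interval [min_alleles, max_alleles], when the
    allele-length SD is strictly greater than ``sd_threshold`` bp, and when
    the tract length lies in the closed interval
    [tract_len_min, tract_len_max].
    """

    min_alleles: int = 2
    max_alleles: int = 13
    max_missing_fraction: float = 0.0
    sd_threshold: float = 7.0
    telomere_margin: int = 1_000_000
    tract_len_min: int = 13
    tract_len_max: int = 49
    motif_len_min: int = 2

    def __post_init__(self) -> None:
        if self.min_alleles > self.max_alleles:
            raise ValueError("min_alleles must not exceed max_alleles")
        for name in ("max_missing_fraction", "sd_threshold", "telomere_margin",
                     "tract_len_min", "tract_len_max", "motif_len_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class DoubletonHit(NamedTuple):
    allele_index: int
    allele: str
    population: str


class StageCount(NamedTuple):
    name: str
    n_in: int
    n_out: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


@dataclass
class CascadeReport:
    """Telescoping per-stage accounting plus the final locus list and the
    doubleton annotation (private population and allele) per survivor."""

    stages: list[StageCount]
    final: list[LocusGenotypes]
    doubletons: dict[tuple[str, int], list[DoubletonHit]]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "in": s.n_in, "out": s.n_out,
                 "removed": s.n_removed}
                for s in self.stages
            ],
            "final": [
                {
                    "chrom": l.chrom,
                    "pos": l.pos,
                    "private_population": self.doubletons[l.key][0].population
                    if self.doubletons.get(l.key) else None,
                }
                for l in self.final
            ],
        }

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tloci_in\tloci_out\tloci_removed\n")
            for s in self.stages:
                fh.write(f"{s.name}\t{s.n_in}\t{s.n_out}\t{s.n_removed}\n")


def allele_count_filter(
    loci: Sequence[LocusGenotypes], config: FilterConfig
) -> list[LocusGenotypes]:
    """Retain loci whose observed allele count (in genotypes, not the ALT
    list) lies within [min_alleles, max_alleles] and whose missing-genotype
    fraction does not exceed ``max_missing_fraction``."""
    out = []
    for loc in loci:
        n_obs = len(loc.observed_alleles())
        if not (config.min_alleles <= n_obs <= config.max_alleles):
            continue
        if loc.missing_fraction() > config.max_missing_fraction:
            continue
        out.append(loc)
    return out


def doubleton_hits(
    locus: LocusGenotypes, pops: PopulationAssignment, samples: Sequence[str]
) -> list[DoubletonHit]:
    """All (allele, population) pairs at a locus satisfying the private
    fixed-allele condition.  Populations with no genotyped sample at the
    locus cannot host a hit."""
    idx_by_pop: dict[str, list[int]] = {lab: [] for lab in pops.labels}
    for i, s in enumerate(samples):
        idx_by_pop[pops[s]].append(i)
    hits: list[DoubletonHit] = []
    for a in range(len(locus.alleles)):
        carriers = {
            pops[samples[i]]
            for i in range(len(samples))
            if not locus.is_missing(i) and a in locus.genotypes[i]
        }
        if len(carriers) != 1:
            continue
        (p,) = carriers
        called = [i for i in idx_by_pop[p] if not locus.is_missing(i)]
        if called and all(locus.genotypes[i] == (a, a) for i in called):
            hits.append(DoubletonHit(a, locus.alleles[a], p))
    return hits


def find_doubletons(
    cohort_or_loci, pops: PopulationAssignment, samples: Sequence[str] | None = None
) -> dict[tuple[str, int], list[DoubletonHit]]:
    """Map locus key -> doubleton hits, for loci with at least one private
    fixed allele.  Accepts a CohortGenotypes or a locus list plus samples."""
    if isinstance(cohort_or_loci, CohortGenotypes):
        loci, samples = cohort_or_loci.loci, cohort_or_loci.samples
    else:
        loci = cohort_or_loci
        if samples is None:
            raise ValueError("samples required when passing a locus list")
    if len(pops.labels) < 2:
        raise ValueError("doubleton analysis requires >= 2 sub-populations")
    out: dict[tuple[str, int], list[DoubletonHit]] = {}
    for loc in loci:
        hits = doubleton_hits(loc, pops, samples)
        if hits:
            out[loc.key] = hits
    return out


def allele_length_sd(locus: LocusGenotypes) -> float:
    """Sample standard deviation (n-1 denominator) of the lengths of the
    alleles listed at the locus (REF + ALTs), unweighted by frequency.

    A single-allele locus has no defined SD and automatically fails the SD
    stage.
    """
    lens = locus.allele_lens
    if len(lens) < 2:
        raise ValueError(
            f"SD undefined for single-allele locus {locus.chrom}:{locus.pos}"
        )
    return float(np.std(lens, ddof=1))


def sd_filter(
    loci: Sequence[LocusGenotypes], config: FilterConfig
) -> list[LocusGenotypes]:
    """Retain loci with allele-length SD strictly greater than the
    threshold; single-allele loci fail."""
    out = []
    for loc in loci:
        if len(loc.alleles) < 2:
            continue
        if allele_length_sd(loc) > config.sd_threshold:
            out.append(loc)
    return out


def positional_filter(
    loci: Sequence[LocusGenotypes],
    chrom_lengths: Mapping[str, int],
    margin: int,
) -> list[LocusGenotypes]:
    """Retain loci whose whole reference tract lies within
    [margin+1, chrom_len - margin] (1-based inclusive), excluding the
    telomere-proximal ends of each chromosome."""
    out = []
    for loc in loci:
        if loc.chrom not in chrom_lengths:
            raise KeyError(f"no length known for chromosome {loc.chrom!r}")
        L = chrom_lengths[loc.chrom]
        if loc.pos >= margin + 1 and loc.end <= L - margin:
            out.append(loc)
    return out


def _motif_of(loc: LocusGenotypes, scan_index: Mapping | None) -> str | None:
    if scan_index is not None and loc.key in scan_index:
        return scan_index[loc.key].motif
    return loc.motif


def tract_and_motif_filter(
    loci: Sequence[LocusGenotypes],
    config: FilterConfig,
    scan_index: Mapping[tuple[str, int], SSRLocus] | None = None,
) -> list[LocusGenotypes]:
    """Retain loci with reference tract length inside the closed window
    [tract_len_min, tract_len_max] and a primitive motif of at least
    ``motif_len_min`` bp (dropping homopolymers under the default of 2).

    The motif comes from the scanner annotation when available, else from
    the locus's own MOTIF annotation; a locus with no motif annotation is
    removed (its repeat structure cannot be verified).
    """
    out = []
    for loc in loci:
        tract_len = len(loc.alleles[0])
        if not (config.tract_len_min <= tract_len <= config.tract_len_max):
            continue
        motif = _motif_of(loc, scan_index)
        if motif is None or len(primitive_motif(motif)) < config.motif_len_min:
            continue
        out.append(loc)
    return out


DEFAULT_STAGE_ORDER = (
    "allele_count", "doubleton", "sd", "telomere", "length_motif"
)


def apply_cascade(
    cohort: CohortGenotypes,
    pops: PopulationAssignment,
    scan_loci: Iterable[SSRLocus] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    config: FilterConfig | None = None,
    stage_order: Sequence[str] = DEFAULT_STAGE_ORDER,
) -> CascadeReport:
    """Run the full cascade and return the telescoping report.

    ``scan_loci`` (from the repeat scanner) supply motif annotation keyed by
    (chrom, start); ``chrom_lengths`` enable the telomere stage, which is
    skipped with a zero-margin warning count when absent.
    """
    config = config or FilterConfig()
    scan_index = {l.key: l for l in scan_loci} if scan_loci is not None else None
    doubletons = find_doubletons(cohort, pops)

    def stage_allele_count(loci):
        return allele_count_filter(loci, config)

    def stage_doubleton(loci):
        return [l for l in loci if l.key in doubletons]

    def stage_sd(loci):
        return sd_filter(loci, config)

    def stage_telomere(loci):
        if chrom_lengths is None:
            return list(loci)
        return positional_filter(loci, chrom_lengths, config.telomere_margin)

    def stage_length_motif(loci):
        return tract_and_motif_filter(loci, config, scan_index)

    stages_fns: dict[str, Callable] = {
        "allele_count": stage_allele_count,
        "doubleton": stage_doubleton,
        "sd": stage_sd,
        "telomere": stage_telomere,
        "length_motif": stage_length_motif,
    }
    current = list(cohort.loci)
    counts: list[StageCount] = []
    for name in stage_order:
        if name not in stages_fns:
            raise ValueError(f"unknown cascade stage {name!r}")
        n_in = len(current)
        current = stages_fns[name](current)
        counts.append(StageCount(name, n_in, len(current)))
    current.sort(key=lambda l: (l.chrom, l.pos))
    return CascadeReport(
        stages=counts,
        final=current,
        doubletons={l.key: doubletons.get(l.key, []) for l in current},
    )
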