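"""Synthetic genome + cohort generator with exact ground truth.

The generator emulates the statistical structure of a resequenced crop
cohort with sub-population structure: a small multi-chromosome genome with
planted perfect tandem repeats in guaranteed repeat-free flanking sequence,
and a diploid cohort whose SSR alleles follow a stepwise length-mutation
model (allele lengths differ by whole motif units).  Planted loci carry one
of three allele configurations:

``private_fixed``
    one sub-population is homozygous for an allele found nowhere else —
    the doubleton configuration the filtering cascade is designed to find;
``private_segregating``
    an allele private to one sub-population but heterozygous in at least
    one member, so it must *not* be called a doubleton;
``shared``
    alleles distributed across sub-populations (including monomorphic
    reference-only sites when no alternative allele is planted).

An ``admixture`` knob leaks a fraction of would-be private fixed alleles
into the other sub-populations, converting them to shared loci; leak
decisions are drawn once per locus before any other randomness so that the
count of surviving doubletons is non-increasing in the admixture rate for
a fixed seed.

Every sample except the structurally required carriers can be masked
missing at ``missing_rate``; the first sample of each sub-population and
the members of a private allele's population are never masked, so the
recorded truth is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortGenotypes, LocusGenotypes, MISSING, PopulationAssignment, write_cohort
from .repeats import ScanConfig, SSRLocus, primitive_motif, scan_sequence, write_bed

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PRIVATE_FIXED = "private_fixed"
PRIVATE_SEGREGATING = "private_segregating"
SHARED = "shared"

#: sub-population sample sizes of the sorghum cohort the generator emulates
STUDY_POPULATIONS: dict[str, int] = {
    "bicolor": 4,
    "caudatum": 29,
    "durra": 19,
    "guinea": 3,
    "kafir": 16,
    "margaritiferum": 4,
}


@dataclass(frozen=True)
class PlantedLocus:
    """A repeat tract planted in the synthetic genome, with its cohort
    allele model (offsets are in whole motif units relative to the
    reference copy number)."""

    chrom: str
    start: int  # 1-based first tract base
    motif: str
    copies_ref: int
    kind: str = SHARED
    pop: str | None = None
    common_offsets: tuple[int, ...] = ()
    private_offset: int | None = None

    def __post_init__(self) -> None:
        if primitive_motif(self.motif) != self.motif:
            raise ValueError(f"planted motif {self.motif!r} is not primitive")
        if self.kind not in (PRIVATE_FIXED, PRIVATE_SEGREGATING, SHARED):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind != SHARED:
            if self.pop is None or self.private_offset is None:
                raise ValueError(f"{self.kind} locus needs pop and private_offset")
            if self.private_offset in (0, *self.common_offsets):
                raise ValueError("private_offset must be distinct")
        offs = set(self.common_offsets)
        if 0 in offs or len(offs) != len(self.common_offsets):
            raise ValueError("common_offsets must be distinct and non-zero")
        for off in (*self.common_offsets,
                    *( () if self.private_offset is None else (self.private_offset,) )):
            if self.copies_ref + off < 1:
                raise ValueError("allele copy number would drop below 1")

    @property
    def tract_len(self) -> int:
        return len(self.motif) * self.copies_ref

    @property
    def end(self) -> int:
        return self.start + self.tract_len - 1

    @property
    def ref_allele(self) -> str:
        return self.motif * self.copies_ref

    def as_ssr_locus(self) -> SSRLocus:
        return SSRLocus(chrom=self.chrom, start=self.start, end=self.end,
                        motif=self.motif)


@dataclass(frozen=True)
class SimDesign:
    seed: int
    chrom_lengths: Mapping[str, int]
    planted: Sequence[PlantedLocus]
    populations: Mapping[str, int]
    missing_rate: float = 0.0
    admixture: float = 0.0

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[PlantedLocus]] = {}
        for p in self.planted:
            if p.chrom not in self.chrom_lengths:
                raise ValueError(f"planted locus on unknown chromosome {p.chrom}")
            if p.start < 1 or p.end > self.chrom_lengths[p.chrom]:
                raise ValueError(f"planted locus out of bounds: {p}")
            by_chrom.setdefault(p.chrom, []).append(p)
        for chrom, loci in by_chrom.items():
            loci = sorted(loci, key=lambda l: l.start)
            for a, b in zip(loci, loci[1:]):
                if b.start <= a.end + 1:
                    raise ValueError(
                        f"planted loci overlap or touch on {chrom}: {a} / {b}"
                    )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.admixture <= 1.0:
            raise ValueError("admixture must be in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return [
            f"{lab}_{i:02d}"
            for lab, n in self.populations.items()
            for i in range(n)
        ]

    def assignment(self) -> PopulationAssignment:
        return PopulationAssignment(
            {f"{lab}_{i:02d}": lab
             for lab, n in self.populations.items()
             for i in range(n)}
        )


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def generate_genome(
    design: SimDesign,
    scan_config: ScanConfig | None = None,
    fasta_path=None,
    bed_path=None,
    max_iter: int = 300,
) -> dict[str, str]:
    """Build the synthetic genome: planted tracts spliced into random
    background that is then repaired (by re-randomising offending windows
    against the scanner itself) until a scan recovers exactly the planted
    loci with exact coordinates.
    """
    scan_config = scan_config or ScanConfig()
    rng = np.random.default_rng([design.seed % (2**31), 17])
    genome: dict[str, str] = {}
    for chrom, length in design.chrom_lengths.items():
        planted = sorted(
            (p for p in design.planted if p.chrom == chrom),
            key=lambda p: p.start,
        )
        arr = _random_dna(rng, length)
        protected = np.zeros(length, dtype=bool)
        for p in planted:
            tract = np.frombuffer(p.ref_allele.encode(), dtype=np.uint8)
            arr[p.start - 1 : p.end] = tract
            protected[p.start - 1 : p.end] = True
        want = {(p.start, p.end, p.motif) for p in planted}
        for _ in range(max_iter):
            found = scan_sequence(arr.tobytes().decode(), chrom, scan_config)
            got = {(l.start, l.end, l.motif) for l in found}
            if got == want:
                break
            offending = np.zeros(length, dtype=bool)
            for l in found:
                if (l.start, l.end, l.motif) not in want:
                    offending[l.start - 1 : l.end] = True
            offending &= ~protected
            if not offending.any():
                # a planted locus was shadowed or extended purely inside
                # protected sequence; redraw its immediate junctions
                for p in planted:
                    for j in (p.start - 2, p.end):
                        if 0 <= j < length and not protected[j]:
                            offending[j] = True
            idx = np.flatnonzero(offending)
            arr[idx] = _random_dna(rng, idx.size)
        else:
            raise RuntimeError(
                f"could not build repeat-free background for {chrom} "
                f"after {max_iter} iterations"
            )
        genome[chrom] = arr.tobytes().decode()
    if fasta_path is not None:
        write_fasta(genome, fasta_path)
    if bed_path is not None:
        order = {c: i for i, c in enumerate(design.chrom_lengths)}
        in_genomic_order = sorted(
            design.planted, key=lambda p: (order[p.chrom], p.start)
        )
        write_bed([p.as_ssr_locus() for p in in_genomic_order], bed_path)
    return genome


def embed_in_neutral_flanks(
    motif: str,
    copies: int,
    flank_len: int = 30,
    seed: int = 0,
    scan_config: ScanConfig | None = None,
    max_iter: int = 1000,
) -> tuple[str, int]:
    """Place a perfect ``motif * copies`` tract between random flanks that
    neither contain a repeat nor extend the tract across the junctions,
    verified against the scanner itself.

    Returns (sequence, 1-based tract start).  Deterministic per seed; used
    to reconstruct published single-marker tracts for validation.
    """
    cfg = scan_config or ScanConfig()
    if primitive_motif(motif) != motif:
        raise ValueError(f"motif {motif!r} is not primitive")
    tract = motif * copies
    rng = np.random.default_rng([seed % (2**31), 3])
    for _ in range(max_iter):
        left = _random_dna(rng, flank_len).tobytes().decode()
        right = _random_dna(rng, flank_len).tobytes().decode()
        seq = left + tract + right
        found = scan_sequence(seq, "_", cfg)
        if len(found) == 1 and (found[0].start, found[0].end, found[0].motif) == (
            flank_len + 1, flank_len + len(tract), motif
        ):
            return seq, flank_len + 1
    raise RuntimeError(
        f"no neutral flanks found for {motif} x {copies} in {max_iter} tries"
    )


def write_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class CohortTruth:
    """Ground truth accompanying a generated cohort."""

    cohort: CohortGenotypes
    doubletons: pd.DataFrame  # chrom, pos, population, allele
    leaked: list[tuple[str, int]]  # private_fixed loci converted by admixture


def _assign_common(
    rng: np.random.Generator,
    genotypes: list,
    pop_indices: Mapping[str, list[int]],
    pool: Sequence[int],
) -> None:
    """Fill genotypes for the given populations from the common allele pool.

    The first sample of every population is seeded heterozygous for the
    first two pool alleles, which structurally rules out accidental private
    fixed alleles in these populations; remaining chromosomes are drawn
    i.i.d. uniform from the pool.
    """
    for lab, idx in pop_indices.items():
        if not idx:
            continue
        if len(pool) >= 2:
            genotypes[idx[0]] = (pool[0], pool[1])
            rest = idx[1:]
        else:
            rest = idx
        for i in rest:
            draw = rng.integers(0, len(pool), size=2)
            genotypes[i] = (pool[int(draw[0])], pool[int(draw[1])])


def generate_cohort(
    design: SimDesign,
    genome: Mapping[str, str] | None = None,
    vcf_path=None,
    truth_path=None,
) -> CohortTruth:
    """Generate the diploid cohort VCF model honouring the planted allele
    configurations, plus the exact doubleton truth table."""
    if genome is not None:
        for p in design.planted:
            ref = genome[p.chrom][p.start - 1 : p.end]
            if ref != p.ref_allele:
                raise ValueError(
                    f"genome/design mismatch at {p.chrom}:{p.start}: "
                    f"{ref!r} != {p.ref_allele!r}"
                )
    rng = np.random.default_rng([design.seed % (2**31), 29])
    planted = sorted(design.planted, key=lambda p: (p.chrom, p.start))
    # leak decisions first, in a fixed order, so that raising `admixture`
    # only ever converts additional private loci and never rescues one
    leak_u = rng.random(len(planted))
    samples = design.samples
    pops = design.assignment()
    pop_indices: dict[str, list[int]] = {lab: [] for lab in design.populations}
    for i, s in enumerate(samples):
        pop_indices[pops[s]].append(i)

    loci: list[LocusGenotypes] = []
    truth_rows = []
    leaked: list[tuple[str, int]] = []
    protected_idx: set[tuple[int, int]] = set()  # (locus_no, sample_no)
    for li, p in enumerate(planted):
        alleles = [p.ref_allele]
        alleles += [p.motif * (p.copies_ref + o) for o in p.common_offsets]
        common_pool = list(range(len(alleles)))
        if not p.common_offsets and p.kind == SHARED:
            # genotypically monomorphic site: list one stepwise-neighbour
            # ALT that no sample carries, as merged call sets do
            alleles.append(p.motif * (p.copies_ref + 1))
        priv = None
        if p.kind != SHARED:
            alleles.append(p.motif * (p.copies_ref + p.private_offset))
            priv = len(alleles) - 1
        genotypes: list = [MISSING] * len(samples)
        is_leaked = p.kind == PRIVATE_FIXED and leak_u[li] < design.admixture
        if p.kind == PRIVATE_FIXED and not is_leaked:
            for i in pop_indices[p.pop]:
                genotypes[i] = (priv, priv)
                protected_idx.add((li, i))
            others = {lab: idx for lab, idx in pop_indices.items()
                      if lab != p.pop}
            _assign_common(rng, genotypes, others, common_pool)
            truth_rows.append(
                {"chrom": p.chrom, "pos": p.start, "population": p.pop,
                 "allele": alleles[priv]}
            )
        elif p.kind == PRIVATE_FIXED and is_leaked:
            _assign_common(rng, genotypes, pop_indices, common_pool + [priv])
            leaked.append((p.chrom, p.start))
        elif p.kind == PRIVATE_SEGREGATING:
            first = pop_indices[p.pop][0]
            _assign_common(rng, genotypes, pop_indices, common_pool)
            genotypes[first] = (priv, common_pool[0])
            protected_idx.add((li, first))
        else:
            _assign_common(rng, genotypes, pop_indices, common_pool)
        for lab, idx in pop_indices.items():
            if idx:
                protected_idx.add((li, idx[0]))
        loci.append(
            LocusGenotypes(
                chrom=p.chrom, pos=p.start, alleles=tuple(alleles),
                genotypes=genotypes, motif=p.motif,
                ref_copies=float(p.copies_ref),
            )
        )
    if design.missing_rate > 0:
        for li, loc in enumerate(loci):
            mask = rng.random(len(samples)) < design.missing_rate
            for i in np.flatnonzero(mask):
                if (li, int(i)) not in protected_idx:
                    loc.genotypes[int(i)] = MISSING
    cohort = CohortGenotypes(samples=list(samples), loci=loci)
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "population", "allele"]
    )
    if vcf_path is not None:
        write_cohort(cohort, vcf_path, contig_lengths=dict(design.chrom_lengths))
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return CohortTruth(cohort=cohort, doubletons=truth, leaked=leaked)


_MOTIF_POOL = ("AT", "AG", "CT", "GCG", "GCC", "ACT", "AAG",
               "AGAT", "GGATG", "CCACGC")


def study_design(
    seed: int,
    *,
    chrom_lengths: Mapping[str, int] | None = None,
    populations: Mapping[str, int] | None = None,
    n_private_fixed: int = 6,
    private_pop: str = "margaritiferum",
    n_private_seg: int = 4,
    n_shared: int = 10,
    n_monomorphic: int = 2,
    admixture: float = 0.0,
    missing_rate: float = 0.0,
    interior_margin: int = 2_100,
    spacing: int = 250,
) -> SimDesign:
    """A ready-made design emulating the study cohort: six sub-populations
    at their published sample sizes, with a handful of private fixed
    (doubleton) loci in one sub-population against a background of
    segregating-private, shared and monomorphic repeats.

    Planted alleles are spread widely enough in length (>= three length
    classes spanning >= 15 bp) that polymorphic loci exceed the 7 bp SD
    threshold of the default cascade; loci are kept ``interior_margin`` bp
    clear of chromosome ends.
    """
    rng = np.random.default_rng([seed % (2**31), 7])
    chrom_lengths = dict(chrom_lengths or {"1": 40_000, "2": 40_000, "3": 40_000})
    populations = dict(populations or STUDY_POPULATIONS)
    if private_pop not in populations:
        raise ValueError(f"{private_pop!r} not among populations")
    chroms = list(chrom_lengths)
    cursors = {c: interior_margin for c in chrom_lengths}
    kinds = (
        [PRIVATE_FIXED] * n_private_fixed
        + [PRIVATE_SEGREGATING] * n_private_seg
        + [SHARED] * n_shared
        + ["monomorphic"] * n_monomorphic
    )
    planted: list[PlantedLocus] = []
    for i, kind in enumerate(kinds):
        chrom = chroms[i % len(chroms)]
        motif = _MOTIF_POOL[int(rng.integers(0, len(_MOTIF_POOL)))]
        k = len(motif)
        c_lo = max(2, -(-13 // k), -(-6 // k) + 1)
        c_hi = 49 // k
        copies = int(rng.integers(c_lo, c_hi + 1))
        if kind == "monomorphic":
            common, priv, kind_, pop = (), None, SHARED, None
        else:
            o_pos = -(-9 // k)  # ceil: at least +9 bp
            o_neg = -min(copies - 1, -(-6 // k))  # at least -6 bp
            common = (o_pos, o_neg)
            priv = o_pos + 2 if kind != SHARED else None
            kind_ = kind
            pop = private_pop if kind != SHARED else None
        start = cursors[chrom] + int(rng.integers(0, 120))
        locus = PlantedLocus(
            chrom=chrom, start=start, motif=motif, copies_ref=copies,
            kind=kind_, pop=pop, common_offsets=common, private_offset=priv,
        )
        if locus.end > chrom_lengths[chrom] - interior_margin:
            raise ValueError(
                f"design does not fit on chromosome {chrom}; "
                "increase chrom_lengths or reduce locus counts"
            )
        cursors[chrom] = locus.end + spacing
        planted.append(locus)
    return SimDesign(
        seed=seed,
        chrom_lengths=chrom_lengths,
        planted=tuple(planted),
        populations=populations,
        missing_rate=missing_rate,
        admixture=admixture,
    )


def simulate(design: SimDesign, outdir) -> dict[str, Path]:
    """Generate and write the full synthetic data set: genome FASTA, truth
    BED, cohort VCF, doubleton truth TSV and population assignment TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "bed": outdir / "truth_loci.bed",
        "vcf": outdir / "cohort.vcf",
        "truth": outdir / "truth_doubletons.tsv",
        "pops": outdir / "populations.tsv",
    }
    genome = generate_genome(design, fasta_path=paths["fasta"], bed_path=paths["bed"])
    generate_cohort(design, genome, vcf_path=paths["vcf"], truth_path=paths["truth"])
    design.assignment().to_tsv(paths["pops"])
    return paths
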