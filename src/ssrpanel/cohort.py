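"""Multi-sample SSR genotype model: VCF ingest/export, sub-population
assignment, allele frequencies, and per-population presence (Venn) scoring.

Genotypes are diploid; a half-called genotype (one missing allele) is
treated as missing, which is the conservative reading compatible with the
complete-call requirement applied downstream.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

MISSING: tuple[None, None] = (None, None)

Genotype = tuple  # (int, int) or (None, None)


@dataclass
class LocusGenotypes:
    """One SSR site: allele sequences (REF first) and diploid calls for
    every cohort sample, in cohort sample order."""

    chrom: str
    pos: int  # 1-based position of the first tract base
    alleles: tuple[str, ...]
    genotypes: list[Genotype]
    motif: str | None = None
    ref_copies: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"duplicate alleles at {self.chrom}:{self.pos}")
        for gt in self.genotypes:
            for a in gt:
                if a is not None and not (0 <= a < len(self.alleles)):
                    raise ValueError(
                        f"allele index {a} out of range at {self.chrom}:{self.pos}"
                    )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def allele_lens(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.alleles)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference tract."""
        return self.pos + len(self.alleles[0]) - 1

    def is_missing(self, i: int) -> bool:
        a, b = self.genotypes[i]
        return a is None or b is None

    def called_indices(self) -> list[int]:
        return [i for i in range(len(self.genotypes)) if not self.is_missing(i)]

    def observed_alleles(self, sample_idx: Iterable[int] | None = None) -> set[int]:
        idx = range(len(self.genotypes)) if sample_idx is None else sample_idx
        out: set[int] = set()
        for i in idx:
            if not self.is_missing(i):
                out.update(self.genotypes[i])
        return out

    def missing_fraction(self) -> float:
        n = len(self.genotypes)
        return sum(self.is_missing(i) for i in range(n)) / n if n else 0.0


@dataclass
class CohortGenotypes:
    samples: list[str]
    loci: list[LocusGenotypes]
    n_skipped: int = 0  # symbolic/breakend records dropped on read

    def __post_init__(self) -> None:
        for loc in self.loci:
            if len(loc.genotypes) != len(self.samples):
                raise ValueError(
                    f"locus {loc.chrom}:{loc.pos} has {len(loc.genotypes)} "
                    f"genotypes for {len(self.samples)} samples"
                )

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}

    def locus(self, chrom: str, pos: int) -> LocusGenotypes:
        for loc in self.loci:
            if loc.key == (chrom, pos):
                return loc
        raise KeyError(f"no locus at {chrom}:{pos}")


@dataclass(frozen=True)
class PopulationAssignment:
    """Mapping of sample id to sub-population label (e.g. the sorghum races
    bicolor, caudatum, durra, guinea, kafir and the guinea working group
    margaritiferum)."""

    assignment: Mapping[str, str]

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.assignment.values():
            if lab not in seen:
                seen.append(lab)
        return seen

    def members(self, label: str) -> list[str]:
        return [s for s, l in self.assignment.items() if l == label]

    def __getitem__(self, sample: str) -> str:
        return self.assignment[sample]

    def __len__(self) -> int:
        return len(self.assignment)

    @classmethod
    def from_tsv(cls, path) -> "PopulationAssignment":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["sample_id", "population"],
            dtype=str, comment="#",
        )
        return cls(dict(zip(df["sample_id"], df["population"])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, l in self.assignment.items():
                fh.write(f"{s}\t{l}\n")


def _is_symbolic(allele: str) -> bool:
    return any(c in allele for c in "<>[].*") or allele == ""


def read_cohort(path) -> CohortGenotypes:
    """Read a VCF 4.x with sequence-resolved alleles into the cohort model.

    Records with symbolic or breakend ALTs are skipped and counted in
    ``n_skipped``.  MOTIF / REFCOPIES INFO keys, when present, populate the
    SSR annotation; unknown INFO keys are ignored.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        loci: list[LocusGenotypes] = []
        skipped = 0
        for rec in vf:
            alleles = tuple(rec.alleles or ())
            if not alleles or any(_is_symbolic(a) for a in alleles):
                skipped += 1
                continue
            gts: list[Genotype] = []
            for s in samples:
                gt = rec.samples[s].get("GT", MISSING)
                if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                    gts.append(MISSING)
                else:
                    gts.append((int(gt[0]), int(gt[1])))
            try:
                motif = rec.info.get("MOTIF")
                ref_copies = rec.info.get("REFCOPIES")
            except (KeyError, ValueError):  # INFO keys absent from header
                motif = ref_copies = None
            if isinstance(motif, (tuple, list)):
                motif = motif[0]
            if isinstance(ref_copies, (tuple, list)):
                ref_copies = ref_copies[0]
            loci.append(
                LocusGenotypes(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    alleles=alleles,
                    genotypes=gts,
                    motif=str(motif) if motif is not None else None,
                    ref_copies=float(ref_copies) if ref_copies is not None else None,
                )
            )
    if skipped:
        warnings.warn(f"skipped {skipped} symbolic/breakend record(s)")
    loci.sort(key=lambda l: (l.chrom, l.pos))
    return CohortGenotypes(samples=samples, loci=loci, n_skipped=skipped)


def write_cohort(
    cohort: CohortGenotypes, path, contig_lengths: Mapping[str, int] | None = None
) -> None:
    """Write the cohort back to an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("INFO", items=[("ID", "MOTIF"), ("Number", "1"),
                                   ("Type", "String"),
                                   ("Description", "SSR repeat unit")])
    header.add_meta("INFO", items=[("ID", "REFCOPIES"), ("Number", "1"),
                                   ("Type", "Float"),
                                   ("Description",
                                    "Motif copies in the reference tract")])
    contigs: dict[str, int | None] = {}
    for loc in cohort.loci:
        contigs.setdefault(loc.chrom, None)
    if contig_lengths:
        contigs.update(contig_lengths)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for s in cohort.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for loc in sorted(cohort.loci, key=lambda l: (l.chrom, l.pos)):
            if len(loc.alleles) < 2:
                raise ValueError(
                    f"cannot export single-allele locus {loc.chrom}:{loc.pos}; "
                    "VCF records need at least one ALT allele"
                )
            rec = out.new_record(
                contig=loc.chrom, start=loc.pos - 1,
                stop=loc.pos - 1 + len(loc.alleles[0]),
                alleles=loc.alleles,
            )
            if loc.motif is not None:
                rec.info["MOTIF"] = loc.motif
            if loc.ref_copies is not None:
                rec.info["REFCOPIES"] = loc.ref_copies
            for s, gt in zip(cohort.samples, loc.genotypes):
                rec.samples[s]["GT"] = None if gt == MISSING else gt
            out.write(rec)


def locus_label(loc: LocusGenotypes) -> str:
    return f"{loc.chrom}:{loc.pos}"


def presence_matrix(
    cohort: CohortGenotypes, pops: PopulationAssignment
) -> pd.DataFrame:
    """Loci x populations binary table: 1 where at least one sample of the
    population carries a non-missing reference or alternative allele.

    Rows of all zeros mark sites seen only in the reference genome.
    """
    missing = [s for s in cohort.samples if s not in pops.assignment]
    if missing:
        raise ValueError(
            "samples missing from the population assignment: "
            + ", ".join(missing)
        )
    labels = pops.labels
    idx_by_pop = {
        lab: [i for i, s in enumerate(cohort.samples) if pops[s] == lab]
        for lab in labels
    }
    data = np.zeros((len(cohort.loci), len(labels)), dtype=np.int8)
    for r, loc in enumerate(cohort.loci):
        for c, lab in enumerate(labels):
            if any(not loc.is_missing(i) for i in idx_by_pop[lab]):
                data[r, c] = 1
    return pd.DataFrame(
        data, index=[locus_label(l) for l in cohort.loci], columns=labels
    )


def venn_counts(matrix: pd.DataFrame) -> dict[frozenset, int]:
    """Count loci per exact population subset (the sectors of a Venn
    diagram), over all 2^P subsets including the empty one.  Counts sum to
    the number of loci."""
    labels = list(matrix.columns)
    if not labels:
        raise ValueError("at least one population required")
    counts: dict[frozenset, int] = {
        frozenset(c): 0
        for r in range(len(labels) + 1)
        for c in itertools.combinations(labels, r)
    }
    for _, row in matrix.iterrows():
        present = frozenset(lab for lab in labels if row[lab] == 1)
        counts[present] += 1
    return counts


def allele_frequencies(
    locus: LocusGenotypes, sample_idx: Sequence[int] | None = None
) -> np.ndarray:
    """Allele frequencies over the chromosomes of genotyped samples in the
    subset (2 per called diploid sample).  Missing genotypes are excluded;
    an all-missing subset is an error."""
    idx = range(len(locus.genotypes)) if sample_idx is None else sample_idx
    counts = np.zeros(len(locus.alleles), dtype=float)
    for i in idx:
        if not locus.is_missing(i):
            a, b = locus.genotypes[i]
            counts[a] += 1
            counts[b] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"no called genotypes at {locus.chrom}:{locus.pos} in subset"
        )
    return counts / total


def write_presence_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="locus")
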