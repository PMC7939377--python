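"""De novo detection of perfect short tandem repeats (SSRs/microsatellites).

A perfect tandem repeat is a run of a 1-6 bp motif repeated at least twice
with no internal mismatches or indels; the final copy may be partial.  The
scanner reports every maximal such tract that satisfies the configured
length bounds, resolving overlaps between tracts of different periods with
a deterministic rule (longest tract, then shortest motif, then leftmost).

Coordinates in :class:`SSRLocus` are 1-based inclusive, the convention of
VCF and of marker tables in the plant-genetics literature; BED output is
0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

_VALID = frozenset("ACGTN")


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,T,N}."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid character {char!r} at position {position} (0-based); "
            "only A, C, G, T and N are accepted"
        )


def primitive_motif(motif: str) -> str:
    """Return the shortest unit ``u`` such that ``motif == u * k``.

    ``"ATAT"`` reduces to ``"AT"``; a primitive motif such as ``"CCACGC"``
    is returned unchanged.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif[:p] * (n // p) == motif:
            return motif[:p]
    return motif


@dataclass(frozen=True)
class SSRLocus:
    """A perfect tandem-repeat tract on a chromosome.

    ``start``/``end`` are 1-based inclusive.  ``motif`` is the repeat unit
    in the phase of its first occurrence in the reference (e.g. the tract
    ``GCGGCG...`` reports motif ``GCG`` even though ``CGG`` is a rotation).
    ``copies_whole`` is the copy number rounded down to a whole repeat, the
    figure conventionally printed in marker tables.
    """

    chrom: str
    start: int
    end: int
    motif: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if primitive_motif(self.motif) != self.motif:
            raise ValueError(f"motif {self.motif!r} is not primitive")

    @property
    def tract_len(self) -> int:
        return self.end - self.start + 1

    @property
    def copies_exact(self) -> float:
        return self.tract_len / len(self.motif)

    @property
    def copies_whole(self) -> int:
        return self.tract_len // len(self.motif)

    @property
    def key(self) -> tuple[str, int]:
        """(chrom, start) — the join key against VCF records."""
        return (self.chrom, self.start)

    def sequence(self) -> str:
        """The tract sequence implied by motif and length."""
        n = len(self.motif)
        whole, part = divmod(self.tract_len, n)
        return self.motif * whole + self.motif[:part]


@dataclass(frozen=True)
class ScanConfig:
    """Bounds for the tandem-repeat scanner.

    Defaults bracket the length range of SSRs usable in short-read targeted
    sequencing: tracts of 10-500 bp with motifs of 1-6 bp and at least two
    copies of the unit.
    """

    motif_min_len: int = 1
    motif_max_len: int = 6
    min_tract_len: int = 10
    max_tract_len: int = 500
    min_copies: float = 2.0
    flank_len: int = 40

    def __post_init__(self) -> None:
        if self.motif_min_len < 1:
            raise ValueError("motif_min_len must be >= 1")
        if self.motif_max_len > self.min_tract_len:
            raise ValueError("motif_max_len must not exceed min_tract_len")
        if self.min_tract_len > self.max_tract_len:
            raise ValueError("min_tract_len must not exceed max_tract_len")


def _validate(seq: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        for i, c in enumerate(seq):
            if c in bad:
                raise InvalidSequenceError(c, i)


def _maximal_runs(eq: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (start, length) of maximal runs of True in a boolean vector."""
    if eq.size == 0:
        return
    padded = np.concatenate(([False], eq, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for a, b in zip(starts, ends):
        yield int(a), int(b - a)


def resolve_overlaps(candidates: Sequence[SSRLocus]) -> list[SSRLocus]:
    """Greedy overlap resolution: longer tract wins, ties go to the shorter
    motif, remaining ties to the leftmost tract.  Returns loci sorted by
    start."""
    ordered = sorted(
        candidates, key=lambda c: (-c.tract_len, len(c.motif), c.start)
    )
    kept: list[SSRLocus] = []
    for cand in ordered:
        if all(cand.end < k.start or cand.start > k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.start)
    return kept


def scan_sequence(
    seq: str, chrom: str, config: ScanConfig | None = None
) -> list[SSRLocus]:
    """Find all perfect tandem repeats in ``seq`` satisfying ``config``.

    Tracts are never called across an N.  The returned list is sorted by
    start, contains no overlapping loci, and every motif is primitive.
    """
    config = config or ScanConfig()
    seq = seq.upper()
    _validate(seq)
    n = len(seq)
    if n < config.min_tract_len:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    not_n = arr != ord("N")
    candidates: list[SSRLocus] = []
    for k in range(config.motif_min_len, config.motif_max_len + 1):
        if n < k + 1:
            break
        eq = (arr[k:] == arr[:-k]) & not_n[k:] & not_n[:-k]
        min_len = max(config.min_tract_len, math.ceil(k * config.min_copies))
        for a, m in _maximal_runs(eq):
            tract_len = m + k
            if tract_len < min_len or tract_len > config.max_tract_len:
                continue
            motif = seq[a : a + k]
            if "N" in motif or primitive_motif(motif) != motif:
                continue
            candidates.append(
                SSRLocus(chrom=chrom, start=a + 1, end=a + tract_len, motif=motif)
            )
    return resolve_overlaps(candidates)


def scan_genome(
    sequences: dict[str, str] | "object", config: ScanConfig | None = None
) -> list[SSRLocus]:
    """Scan every sequence of a genome (dict or pyfaidx.Fasta-like mapping),
    preserving the order in which chromosomes are given."""
    loci: list[SSRLocus] = []
    keys = sequences.keys() if hasattr(sequences, "keys") else [r.name for r in sequences]
    for name in keys:
        loci.extend(scan_sequence(str(sequences[name][:]), name, config))
    return loci


class Flanks(NamedTuple):
    upstream: str
    downstream: str
    upstream_truncated: bool
    downstream_truncated: bool


def extract_flanks(genome, locus: SSRLocus, flank_len: int) -> Flanks:
    """Extract up to ``flank_len`` bp immediately flanking a tract.

    ``genome`` is a mapping chrom -> indexable sequence (a plain dict of
    strings or a ``pyfaidx.Fasta``).  Flanks are truncated at chromosome
    ends; truncation is flagged rather than padded.
    """
    try:
        seq = genome[locus.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {locus.chrom!r} not present in genome") from exc
    chrom_len = len(seq)
    if locus.end > chrom_len:
        raise ValueError(
            f"locus {locus.chrom}:{locus.start}-{locus.end} exceeds "
            f"chromosome length {chrom_len}"
        )
    up_start = max(0, locus.start - 1 - flank_len)
    upstream = str(seq[up_start : locus.start - 1])
    down_end = min(chrom_len, locus.end + flank_len)
    downstream = str(seq[locus.end : down_end])
    return Flanks(
        upstream=upstream,
        downstream=downstream,
        upstream_truncated=len(upstream) < flank_len,
        downstream_truncated=len(downstream) < flank_len,
    )


def write_bed(loci: Iterable[SSRLocus], path) -> None:
    """BED6 export; name field is ``motif x copies_whole``, score the tract
    length, strand ``+`` (tracts are reported on the reference strand)."""
    with open(path, "w") as fh:
        for loc in loci:
            name = f"{loc.motif}x{loc.copies_whole}"
            fh.write(
                f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{name}\t"
                f"{loc.tract_len}\t+\n"
            )


def write_locus_table(loci: Iterable[SSRLocus], path) -> None:
    """TSV export with 1-based inclusive coordinates and the repeat
    structure in the conventional ``MOTIF (copies)`` form."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tmotif\tcopies_whole\trepeat_structure\n")
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.motif}\t"
                f"{loc.copies_whole}\t{loc.motif} ({loc.copies_whole})\n"
            )
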