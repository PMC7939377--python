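"""Per-locus diversity statistics for SSR markers.

Gene diversity (expected heterozygosity)::

    H = 1 - sum_i P_i^2

Polymorphism information content::

    PIC = 1 - sum_i P_i^2 - sum_{i<j} 2 P_i^2 P_j^2

where P_i are the allele frequencies at a locus with l alleles.  The
informativeness classes follow the conventional thresholds: a marker is
highly informative above PIC 0.5, reasonably informative between 0.25 and
0.5, and slightly informative at or below 0.25.  The printed thresholds
leave the exact boundary values unassigned; boundaries here go to the lower
class (PIC = 0.5 is "reasonably", PIC = 0.25 is "slightly").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortGenotypes, allele_frequencies, locus_label

HIGHLY = "highly"
REASONABLY = "reasonably"
SLIGHTLY = "slightly"

_SUM_TOL = 1e-9


def _check_freqs(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("frequency vector must be 1-D and non-empty")
    if np.any(p < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"frequencies sum to {p.sum()!r}, not 1")
    return p


def heterozygosity(freqs: Sequence[float]) -> float:
    """H = 1 - sum of squared allele frequencies."""
    p = _check_freqs(freqs)
    return float(1.0 - np.sum(p * p))


def pic(freqs: Sequence[float]) -> float:
    """PIC = H - sum over allele pairs of 2 P_i^2 P_j^2.

    The pairwise sum is computed as ((sum P_i^2)^2 - sum P_i^4), an exact
    rearrangement of the double loop.
    """
    p = _check_freqs(freqs)
    s2 = float(np.sum(p * p))
    s4 = float(np.sum(p ** 4))
    return 1.0 - s2 - (s2 * s2 - s4)


def classify_pic(value: float) -> str:
    if not (0.0 <= value < 1.0):
        raise ValueError(f"PIC must lie in [0, 1), got {value}")
    if value > 0.5:
        return HIGHLY
    if value > 0.25:
        return REASONABLY
    return SLIGHTLY


@dataclass(frozen=True)
class LocusStats:
    locus: str
    n_alleles: int
    H: float
    PIC: float
    pic_class: str


def cohort_stats(
    cohort: CohortGenotypes, sample_idx: Sequence[int] | None = None
) -> pd.DataFrame:
    """Per-locus H, PIC and class over the genotyped chromosomes of the
    cohort (all sub-populations pooled), as a DataFrame mirroring a
    marker-statistics supplementary table."""
    rows = []
    for loc in cohort.loci:
        freqs = allele_frequencies(loc, sample_idx)
        observed = freqs[freqs > 0]
        observed = observed / observed.sum()
        h = heterozygosity(observed)
        p = pic(observed)
        rows.append(
            LocusStats(
                locus=locus_label(loc),
                n_alleles=int(observed.size),
                H=h,
                PIC=p,
                pic_class=classify_pic(p),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def write_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format="%.6f")
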