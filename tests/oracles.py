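"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package: naive enumeration and
double loops only.
"""

from __future__ import annotations

import itertools


def brute_smallest_period(s: str) -> str:
    """Shortest u with s == u * k (whole powers only: "ACA" is primitive)."""
    n = len(s)
    for p in range(1, n + 1):
        if n % p == 0 and s[:p] * (n // p) == s:
            return s[:p]
    return s


def brute_scan(seq, min_tract=10, max_tract=500, min_copies=2.0,
               kmin=1, kmax=6):
    """Enumerate every (start, motif length) maximal perfect extension and
    apply the longest/shortest-motif/leftmost overlap resolution.

    Returns a sorted list of (start0, end0_exclusive, motif) in 0-based
    half-open coordinates.
    """
    n = len(seq)
    cands = []
    for k in range(kmin, kmax + 1):
        for i in range(n):
            if i + k > n:
                break
            motif = seq[i : i + k]
            if any(c == "N" for c in motif):
                continue
            if brute_smallest_period(motif) != motif:
                continue
            # extend right while the period holds and no N enters
            j = i + k
            while j < n and seq[j] != "N" and seq[j] == seq[j - k]:
                j += 1
            L = j - i
            # left-maximal: predecessor must not continue the same period
            if i > 0 and seq[i - 1] != "N" and i - 1 + k < n and \
                    seq[i - 1] == seq[i - 1 + k]:
                continue
            if L < min_tract or L > max_tract:
                continue
            if L / k < min_copies:
                continue
            cands.append((i, i + L, motif))
    cands.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    kept = []
    for c in cands:
        if all(c[1] <= k[0] or c[0] >= k[1] for k in kept):
            kept.append(c)
    kept.sort()
    return kept


def brute_pic(freqs) -> float:
    s = 1.0 - sum(p * p for p in freqs)
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            s -= 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    return s


def brute_heterozygosity(freqs) -> float:
    return 1.0 - sum(p * p for p in freqs)


def brute_presence(loci_genotypes, samples, assignment):
    """Per-population any() over non-missing genotypes.

    loci_genotypes: list of per-locus genotype lists aligned to samples.
    Returns list of dicts population -> 0/1.
    """
    pops = []
    for lab in dict.fromkeys(assignment.values()):
        pops.append(lab)
    rows = []
    for gts in loci_genotypes:
        row = {}
        for lab in pops:
            row[lab] = int(
                any(
                    gts[i][0] is not None and gts[i][1] is not None
                    for i, s in enumerate(samples)
                    if assignment[s] == lab
                )
            )
        rows.append(row)
    return rows


def brute_doubletons(alleles_per_locus, genotypes_per_locus, samples,
                     assignment):
    """Loop over (locus, allele, population) checking the private fixed
    condition directly.  Returns {locus_index: [(allele_index, pop), ...]}."""
    pops = list(dict.fromkeys(assignment.values()))
    out = {}
    for li, (alleles, gts) in enumerate(
        zip(alleles_per_locus, genotypes_per_locus)
    ):
        hits = []
        for a in range(len(alleles)):
            for p in pops:
                inside = [i for i, s in enumerate(samples)
                          if assignment[s] == p]
                outside = [i for i, s in enumerate(samples)
                           if assignment[s] != p]
                called = lambda i: gts[i][0] is not None and gts[i][1] is not None
                carried_in = any(called(i) and a in gts[i] for i in inside)
                carried_out = any(called(i) and a in gts[i] for i in outside)
                genotyped_in = [i for i in inside if called(i)]
                fixed = bool(genotyped_in) and all(
                    gts[i] == (a, a) for i in genotyped_in
                )
                if carried_in and not carried_out and fixed:
                    hits.append((a, p))
        if hits:
            out[li] = hits
    return out


def brute_venn(rows, labels):
    """Exact-subset counts from presence rows (dicts label -> 0/1)."""
    counts = {}
    for r in range(len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            counts[frozenset(combo)] = 0
    for row in rows:
        key = frozenset(l for l in labels if row[l])
        counts[key] += 1
    return counts
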