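"""Naming, ordering and export of the final SSR marker panel.

Markers are named with an "X" prefix (the convention marking SSR loci),
a population tag (e.g. ``Xgma`` for markers diagnostic of the guinea
working group margaritiferum, ``Xunr`` otherwise), and an ordinal assigned
in order of chromosomal and genomic location — from the first base of the
first chromosome to the last base of the last.

The shipped table :func:`load_builtin_panel` carries the six published
margaritiferum-diagnostic sorghum markers Xgma1-Xgma6 with their primers.
"""

from __future__ import annotations

import importlib.resources
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .repeats import SSRLocus

_PRIMER_ALPHABET = frozenset("ACGT")

TSV_COLUMNS = [
    "name", "chrom", "start", "end", "ref_structure", "pop_structure",
    "fwd_primer", "rev_primer", "H", "PIC", "pic_class",
    "private_population",
]


def repeat_structure(motif: str, copies_whole: int) -> str:
    """Format a repeat structure as ``MOTIF (copies)``, e.g. ``GCG (12)``."""
    return f"{motif} ({copies_whole})"


def parse_structure(text: str) -> tuple[str, int]:
    m = re.fullmatch(r"\s*([ACGT]+)\s*\((\d+)\)\s*", text)
    if not m:
        raise ValueError(f"cannot parse repeat structure {text!r}")
    return m.group(1), int(m.group(2))


@dataclass
class PanelRecord:
    """One candidate or validated marker in the panel."""

    locus: SSRLocus
    name: str | None = None
    pop_structure: str | None = None
    fwd_primer: str | None = None
    rev_primer: str | None = None
    H: float | None = None
    PIC: float | None = None
    pic_class: str | None = None
    private_population: str | None = None

    @property
    def ref_structure(self) -> str:
        return repeat_structure(self.locus.motif, self.locus.copies_whole)


def population_structure(locus: SSRLocus, allele_len: int) -> str:
    """Repeat structure of the sub-population-diagnostic allele, with the
    whole-copy count derived from the allele's tract length."""
    return repeat_structure(locus.motif, allele_len // len(locus.motif))


def name_panel(
    records: Sequence[PanelRecord],
    prefix_for: Mapping[str, str] | None = None,
    default_prefix: str = "Xunr",
    chrom_order: Sequence[str] | None = None,
) -> list[PanelRecord]:
    """Assign marker names: stable sort by (chromosome order, start, end),
    then per-prefix ordinals starting at 1.

    ``chrom_order`` defaults to the order of first appearance (FASTA
    sequence order when records come from a genome scan).  Records sharing
    coordinates are tie-broken by end then by name of motif, with a
    warning.
    """
    prefix_for = prefix_for or {}
    if chrom_order is None:
        chrom_order = []
        for r in records:
            if r.locus.chrom not in chrom_order:
                chrom_order.append(r.locus.chrom)
    rank = {c: i for i, c in enumerate(chrom_order)}
    for r in records:
        if r.locus.chrom not in rank:
            raise KeyError(f"chromosome {r.locus.chrom!r} not in chrom_order")
    coords = [(rank[r.locus.chrom], r.locus.start) for r in records]
    if len(set(coords)) < len(coords):
        warnings.warn("duplicate coordinates in panel; tie-breaking by end")
    ordered = sorted(
        records,
        key=lambda r: (rank[r.locus.chrom], r.locus.start, r.locus.end,
                       len(r.locus.motif), r.locus.motif),
    )
    counters: dict[str, int] = {}
    out: list[PanelRecord] = []
    for r in ordered:
        prefix = prefix_for.get(r.private_population or "", default_prefix)
        counters[prefix] = counters.get(prefix, 0) + 1
        out.append(replace(r, name=f"{prefix}{counters[prefix]}"))
    names = [r.name for r in out]
    assert len(set(names)) == len(names)
    return out


def _fmt(x) -> str:
    if x is None:
        return "."
    if isinstance(x, float):
        return f"{x:.6f}"
    return str(x)


def export_panel(records: Sequence[PanelRecord], path, fmt: str = "tsv") -> None:
    """Write the named panel as a marker TSV (1-based inclusive
    coordinates) or BED6 (0-based half-open).  Output is byte-identical
    across runs for identical input."""
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for r in records:
                fh.write(
                    "\t".join(
                        [
                            _fmt(r.name), r.locus.chrom, str(r.locus.start),
                            str(r.locus.end), r.ref_structure,
                            _fmt(r.pop_structure), _fmt(r.fwd_primer),
                            _fmt(r.rev_primer), _fmt(r.H), _fmt(r.PIC),
                            _fmt(r.pic_class), _fmt(r.private_population),
                        ]
                    )
                    + "\n"
                )
    elif fmt == "bed":
        with open(path, "w") as fh:
            for r in records:
                fh.write(
                    f"{r.locus.chrom}\t{r.locus.start - 1}\t{r.locus.end}\t"
                    f"{_fmt(r.name)}\t{r.locus.tract_len}\t+\n"
                )
    else:
        raise ValueError(f"unsupported export format {fmt!r}")


def _parse_opt(x: str):
    return None if x == "." else x


def read_panel(path) -> list[PanelRecord]:
    """Read a marker TSV written by :func:`export_panel` (or laid out the
    same way, as published marker tables are)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel table lacks columns: {missing}")
    records: list[PanelRecord] = []
    for _, row in df.iterrows():
        motif, _copies = parse_structure(row["ref_structure"])
        locus = SSRLocus(
            chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
            motif=motif,
        )
        records.append(
            PanelRecord(
                locus=locus,
                name=_parse_opt(row["name"]),
                pop_structure=_parse_opt(row["pop_structure"]),
                fwd_primer=_parse_opt(row["fwd_primer"]),
                rev_primer=_parse_opt(row["rev_primer"]),
                H=None if row["H"] == "." else float(row["H"]),
                PIC=None if row["PIC"] == "." else float(row["PIC"]),
                pic_class=_parse_opt(row["pic_class"]),
                private_population=_parse_opt(row["private_population"]),
            )
        )
    return records


def read_primer_table(
    path,
    panel: Sequence[PanelRecord],
    expected_len: int | None = None,
) -> tuple[list[PanelRecord], list[tuple[str, str]]]:
    """Merge externally designed primers (TSV in the marker-table layout)
    into the panel by marker name.

    Returns the updated panel and a rejects report of (name, reason) for
    rows whose marker name is unknown, whose primers contain characters
    outside {A,C,G,T}, or whose length differs from ``expected_len`` when
    one is configured.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    by_name = {r.name: i for i, r in enumerate(panel) if r.name}
    out = list(panel)
    rejects: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        name = row["name"]
        if name not in by_name:
            rejects.append((name, "marker name not in panel"))
            continue
        fwd, rev = row["fwd_primer"], row["rev_primer"]
        bad = [p for p in (fwd, rev) if set(p) - _PRIMER_ALPHABET]
        if bad:
            rejects.append((name, f"non-ACGT characters in primer {bad[0]!r}"))
            continue
        if expected_len is not None and (
            len(fwd) != expected_len or len(rev) != expected_len
        ):
            rejects.append(
                (name,
                 f"primer length {len(fwd)}/{len(rev)} != {expected_len}")
            )
            continue
        out[by_name[name]] = replace(
            out[by_name[name]], fwd_primer=fwd, rev_primer=rev
        )
    return out, rejects


def load_builtin_panel() -> list[PanelRecord]:
    """The published margaritiferum-diagnostic sorghum panel (Xgma1-Xgma6)
    shipped with the package: genomic locations on the sorghum reference,
    reference and margaritiferum repeat structures, and 40 bp primers."""
    ref = importlib.resources.files("ssrpanel") / "data" / "sorghum_margaritiferum_panel.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_panel(p)
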