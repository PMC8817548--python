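"""Codon counting and GC-content indices.

GC1/GC2/GC3 are the G+C fractions at the three codon positions over sense
codons (the terminal stop is excluded; ATG and TGG are included, matching
codonW). GC3s restricts the third position to codons of amino acids with
two or more synonymous codons, i.e. it additionally drops ATG and TGG.

The 5'→3' GC3 gradient summarises how third-position composition changes
along genes. Two readings of "divided into 100 groups" are supported:

* ``positional`` (default): each gene's sense codons are cut into 100
  contiguous segments; bin *b* pools third-position G+C over segment *b*
  of every gene — a true 5'→3' profile.
* ``ranked``: genes are sorted by gene-level GC3 and cut into 100
  equal-size groups; bin = group mean GC3 — a quantile profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .cds_io import CdsRecord
from .genetic_code import (
    ALL_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    GeneticCode,
    standard_code,
)

logger = logging.getLogger(__name__)

_GC = frozenset("GC")


@dataclass
class CodonCountTable:
    """Occurrence counts over all 64 codons for a gene or a pooled species.

    Sense codons and the terminal stop are both recorded; downstream
    statistics decide which subset they consume.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in ALL_CODONS}
    )
    scope: str = ""

    @property
    def total_sense(self) -> int:
        return sum(self.counts[c] for c in SENSE_CODONS)

    @property
    def total_stops(self) -> int:
        return sum(self.counts[c] for c in STOP_CODONS)


@dataclass(frozen=True)
class CompositionProfile:
    """GC indices in percent for one gene or pool."""

    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    n_codons: int


@dataclass(frozen=True)
class GradientVector:
    """Mean third-position G+C fraction per 5'→3' bin for one species."""

    species: str
    bins: tuple[float, ...]
    mode: Literal["positional", "ranked"]

    def __post_init__(self) -> None:
        if any(not (0.0 <= b <= 1.0) for b in self.bins):
            raise ValueError("gradient bins must be fractions in [0, 1]")


def count_codons(record: CdsRecord) -> CodonCountTable:
    """Count frame-0 codons of one record (terminal stop kept in STOP slots)."""
    if record.length % 3 != 0:
        raise ValueError(
            f"{record.id}: length {record.length} not divisible by 3"
        )
    table = CodonCountTable(scope=record.id)
    for codon in record.codons():
        table.counts[codon] += 1
    return table


def pool_counts(
    tables: Sequence[CodonCountTable], scope: str = "pooled"
) -> CodonCountTable:
    """Elementwise sum of count tables (species-level pooling)."""
    if not tables:
        raise ValueError("cannot pool an empty list of count tables")
    pooled = CodonCountTable(scope=scope)
    for t in tables:
        for codon, n in t.counts.items():
            pooled.counts[codon] += n
    return pooled


def gc_profile(
    counts: CodonCountTable, code: GeneticCode | None = None
) -> CompositionProfile:
    """GC, GC1–GC3 and GC3s (all percent) from a codon count table."""
    code = code or standard_code()
    n_sense = counts.total_sense
    if n_sense == 0:
        raise ValueError(f"{counts.scope or 'table'}: no sense codons")
    gc_pos = [0, 0, 0]
    gc3s_num = 0
    n_syn = 0
    for codon in SENSE_CODONS:
        n = counts.counts[codon]
        if n == 0:
            continue
        for pos in range(3):
            if codon[pos] in _GC:
                gc_pos[pos] += n
        if len(code.families[code.codon_to_aa[codon]]) >= 2:
            n_syn += n
            if codon[2] in _GC:
                gc3s_num += n
    gc1, gc2, gc3 = (100.0 * g / n_sense for g in gc_pos)
    return CompositionProfile(
        gc=(gc1 + gc2 + gc3) / 3.0,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc3s=100.0 * gc3s_num / n_syn if n_syn else 0.0,
        n_codons=n_sense,
    )


def gc3_fraction(record: CdsRecord) -> float:
    """Gene-level third-position G+C fraction over sense codons."""
    cods = record.sense_codons()
    if not cods:
        raise ValueError(f"{record.id}: no sense codons")
    return sum(1 for c in cods if c[2] in _GC) / len(cods)


def gc3_gradient(
    records: Iterable[CdsRecord],
    n_bins: int = 100,
    mode: Literal["positional", "ranked"] = "positional",
    species: str = "",
) -> GradientVector:
    """5'→3' GC3 gradient over a gene set (see module docstring for modes).

    In positional mode genes with fewer than ``n_bins`` sense codons cannot
    fill every segment and are skipped (count logged).
    """
    records = list(records)
    if mode == "positional":
        num = np.zeros(n_bins, dtype=np.int64)
        den = np.zeros(n_bins, dtype=np.int64)
        skipped = 0
        for rec in records:
            cods = rec.sense_codons()
            L = len(cods)
            if L < n_bins:
                skipped += 1
                continue
            third_gc = np.fromiter(
                (c[2] in _GC for c in cods), dtype=np.int64, count=L
            )
            edges = (np.arange(n_bins + 1) * L) // n_bins
            np.add.at(num, np.arange(n_bins), np.add.reduceat(third_gc, edges[:-1]))
            den += np.diff(edges)
        if skipped:
            logger.info(
                "gc3_gradient: skipped %d gene(s) shorter than %d sense codons",
                skipped,
                n_bins,
            )
        if not den.any():
            raise ValueError("no gene long enough for the positional gradient")
        bins = tuple((num / den).tolist())
    elif mode == "ranked":
        if not records:
            raise ValueError("no genes for ranked gradient")
        vals = np.sort(np.array([gc3_fraction(r) for r in records]))
        groups = np.array_split(vals, n_bins)
        if any(len(g) == 0 for g in groups):
            raise ValueError(
                f"need at least {n_bins} genes for a {n_bins}-bin ranked gradient"
            )
        bins = tuple(float(g.mean()) for g in groups)
    else:
        raise ValueError(f"unknown gradient mode: {mode!r}")
    return GradientVector(species=species, bins=bins, mode=mode)


def composition_table(records: Sequence[CdsRecord]) -> "list[tuple[str, CompositionProfile]]":
    """Per-gene composition profiles, order preserved."""
    return [(r.id, gc_profile(count_codons(r))) for r in records]


def write_composition_tsv(
    rows: Sequence[tuple[str, CompositionProfile]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_codons\tGC\tGC1\tGC2\tGC3\tGC3s\n")
        for gene_id, p in rows:
            fh.write(
                f"{gene_id}\t{p.n_codons}\t{p.gc:.4f}\t{p.gc1:.4f}\t"
                f"{p.gc2:.4f}\t{p.gc3:.4f}\t{p.gc3s:.4f}\n"
            )


def write_gradient_tsv(grad: GradientVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin\tmean_gc3\n")
        for i, v in enumerate(grad.bins, start=1):
            fh.write(f"{i}\t{v:.6f}\n")
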