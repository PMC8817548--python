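"""Codon-pair statistics: junction dinucleotides and RSCPU.

A codon pair is two adjacent in-frame sense codons; pairs overlap
((c1,c2), (c2,c3), ...) so one gene with L sense codons contributes L-1
pairs. Pairs never involve the terminal stop codon.

The junction table classifies every pair by the dinucleotide straddling
the codon boundary — third base of the first codon plus first base of the
second (the XY of nnXYnn) — into 16 percentages summing to 100.

RSCPU lifts the Sharp-Li RSCU form to pairs: the synonymous family of a
pair is all pairs encoding the same ordered amino-acid dipeptide; within
a family of size m with observed total T, RSCPU = m * count / T.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .cds_io import CdsRecord
from .genetic_code import BASES, GeneticCode, standard_code

#: The 16 junction categories in fixed row order (nnAAnn ... nnTTnn).
JUNCTION_CATEGORIES = tuple(x + y for x in BASES for y in BASES)


@dataclass
class PairCountTable:
    """Occurrence counts of ordered sense-codon pairs, pooled over genes."""

    counts: Counter = field(default_factory=Counter)
    scope: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class JunctionTable:
    """Percentages of codon pairs per junction dinucleotide category."""

    percentages: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"junction percentages sum to {total}, not 100")


def codon_pair_counts(records: Iterable[CdsRecord], scope: str = "") -> PairCountTable:
    """Count overlapping adjacent sense-codon pairs pooled across genes."""
    table = PairCountTable(scope=scope)
    for rec in records:
        cods = rec.sense_codons()
        for i in range(len(cods) - 1):
            table.counts[(cods[i], cods[i + 1])] += 1
    return table


def junction_table(pairs: PairCountTable) -> JunctionTable:
    """16-category nnXYnn percentages from a pair count table."""
    if pairs.total == 0:
        raise ValueError("no codon pairs to classify")
    cat = Counter()
    for (c1, c2), n in pairs.counts.items():
        cat[c1[2] + c2[0]] += n
    total = pairs.total
    return JunctionTable(
        percentages={xy: 100.0 * cat[xy] / total for xy in JUNCTION_CATEGORIES}
    )


def _dipeptide_families(
    pairs: PairCountTable, code: GeneticCode
) -> dict[tuple[str, str], list[tuple[str, str]]]:
    """Observed pairs grouped by ordered amino-acid dipeptide."""
    fams: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for c1, c2 in pairs.counts:
        key = (code.codon_to_aa[c1], code.codon_to_aa[c2])
        fams.setdefault(key, []).append((c1, c2))
    return fams


def rscpu(
    pairs: PairCountTable, code: GeneticCode | None = None
) -> dict[tuple[str, str], float]:
    """RSCPU per observed pair over dipeptide families.

    The family *size* m counts all m1*m2 codon-pair combinations encoding
    the dipeptide, observed or not; only observed pairs appear as keys
    (unobserved pairs of an observed family have RSCPU 0 implicitly, and
    families with zero total are undefined, hence absent).
    """
    code = code or standard_code()
    if pairs.total == 0:
        raise ValueError("empty pair count table")
    out: dict[tuple[str, str], float] = {}
    for (aa1, aa2), members in _dipeptide_families(pairs, code).items():
        m = len(code.families[aa1]) * len(code.families[aa2])
        t = sum(pairs.counts[p] for p in members)
        for p in members:
            out[p] = m * pairs.counts[p] / t
    return out


def pair_family_shares(
    pairs: PairCountTable, code: GeneticCode | None = None
) -> dict[tuple[str, str], float]:
    """Within-dipeptide-family share of each observed pair."""
    code = code or standard_code()
    out: dict[tuple[str, str], float] = {}
    for members in _dipeptide_families(pairs, code).values():
        t = sum(pairs.counts[p] for p in members)
        for p in members:
            out[p] = pairs.counts[p] / t
    return out


def high_frequency_pairs(
    rscpu_table: Mapping[tuple[str, str], float],
    pairs: PairCountTable,
    code: GeneticCode | None = None,
    rscpu_threshold: float = 1.5,
    share_threshold: float = 0.60,
) -> set[tuple[str, str]]:
    """Pairs with RSCPU > 1.5 or within-family share > 60% (both strict)."""
    shares = pair_family_shares(pairs, code)
    return {
        p
        for p, v in rscpu_table.items()
        if v > rscpu_threshold or shares[p] > share_threshold
    }


def write_junction_tsv(
    tables: Mapping[str, JunctionTable], path: str | Path
) -> None:
    """Junction TSV shaped like the cross-species comparison table:
    16 nnXYnn rows, one column per species."""
    species = list(tables)
    with open(path, "w") as fh:
        fh.write("codon_pair\t" + "\t".join(species) + "\n")
        for xy in JUNCTION_CATEGORIES:
            row = "\t".join(f"{tables[s].percentages[xy]:.4f}" for s in species)
            fh.write(f"nn{xy}nn\t{row}\n")


def write_rscpu_tsv(
    pairs: PairCountTable,
    path: str | Path,
    code: GeneticCode | None = None,
) -> None:
    code = code or standard_code()
    table = rscpu(pairs, code)
    shares = pair_family_shares(pairs, code)
    high = high_frequency_pairs(table, pairs, code)
    with open(path, "w") as fh:
        # family=dipeptide: pairs are grouped by ordered amino-acid dipeptide
        fh.write("# family=dipeptide\n")
        fh.write("pair\tdipeptide\tcount\tshare\tRSCPU\tis_high_frequency\n")
        for (c1, c2) in sorted(table):
            dip = code.codon_to_aa[c1] + code.codon_to_aa[c2]
            fh.write(
                f"{c1}-{c2}\t{dip}\t{pairs.counts[(c1, c2)]}\t"
                f"{shares[(c1, c2)]:.6f}\t{table[(c1, c2)]:.6f}\t"
                f"{int((c1, c2) in high)}\n"
            )
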