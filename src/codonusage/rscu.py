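"""Relative synonymous codon usage (RSCU) and derived statistics.

RSCU follows Sharp & Li: for codon *j* of a synonymous family *i* with
``n_i`` members and observed family total ``T_i``,

    RSCU_ij = n_i * x_ij / T_i

so 1.0 means no bias and the values of an observed family sum to ``n_i``.
Families never observed yield *missing* (None) rather than 0 — a zero
would fake extreme bias.

High-frequency codons use the strict rules RSCU > 1.5 or within-family
relative frequency > 60%; single-codon families (Met, Trp) and stops are
never eligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .composition import CodonCountTable
from .genetic_code import STOP, STOP_CODONS, GeneticCode, standard_code

#: The four-codon motif families used for dinucleotide-suppression scans.
MOTIF_PATTERNS = {
    "NCG": ("ACG", "CCG", "GCG", "TCG"),
    "NTA": ("ATA", "CTA", "GTA", "TTA"),
    "XCG": ("ACG", "CCG", "GCG", "TCG"),
    "XCC": ("ACC", "CCC", "GCC", "TCC"),
}


@dataclass
class RscuTable:
    """RSCU and within-family relative frequency per codon.

    ``values[codon] is None`` marks a codon of a family with zero observed
    counts (undefined RSCU).
    """

    values: dict[str, float | None] = field(default_factory=dict)
    rel_freq: dict[str, float | None] = field(default_factory=dict)
    scope: str = ""


def rscu(
    counts: CodonCountTable,
    code: GeneticCode | None = None,
    include_stops: bool = True,
) -> RscuTable:
    """Sharp–Li RSCU per codon; stops form one 3-member family if included."""
    code = code or standard_code()
    if counts.total_sense + counts.total_stops == 0:
        raise ValueError("empty codon count table")
    table = RscuTable(scope=counts.scope)
    for aa, fam in code.families.items():
        if aa == STOP and not include_stops:
            continue
        n_i = len(fam)
        total = sum(counts.counts[c] for c in fam)
        for c in fam:
            if total == 0:
                table.values[c] = None
                table.rel_freq[c] = None
            else:
                table.values[c] = n_i * counts.counts[c] / total
                table.rel_freq[c] = counts.counts[c] / total
    return table


def high_frequency_codons(
    table: RscuTable,
    code: GeneticCode | None = None,
    rscu_threshold: float = 1.5,
    freq_threshold: float = 0.60,
) -> set[str]:
    """Codons with RSCU > 1.5 or relative frequency > 60% (both strict)."""
    code = code or standard_code()
    out: set[str] = set()
    for codon, val in table.values.items():
        if val is None or codon in STOP_CODONS:
            continue
        aa = code.codon_to_aa[codon]
        if len(code.families[aa]) < 2:
            continue
        rf = table.rel_freq[codon]
        if val > rscu_threshold or (rf is not None and rf > freq_threshold):
            out.add(codon)
    return out


def stop_codon_rscu(counts: CodonCountTable) -> dict[str, float]:
    """RSCU over the three-member stop family: 3 * x_s / T_stop."""
    total = counts.total_stops
    if total == 0:
        raise ValueError("no stop codons counted")
    return {s: 3 * counts.counts[s] / total for s in STOP_CODONS}


def motif_rscu(table: RscuTable, pattern: str) -> dict[str, float | None]:
    """RSCU of the four codons matching ``pattern`` (NCG, NTA, XCG or XCC)."""
    try:
        codons = MOTIF_PATTERNS[pattern.upper()]
    except KeyError:
        raise ValueError(
            f"unknown motif pattern {pattern!r}; expected one of "
            f"{sorted(MOTIF_PATTERNS)}"
        ) from None
    return {c: table.values[c] for c in codons}


def xcg_xcc_ratio(table: RscuTable) -> float:
    """Sum of XCG RSCUs over sum of XCC RSCUs (CpG-suppression index).

    Ratios below 1 indicate CG-dinucleotide avoidance at codon positions
    2–3 relative to the CC baseline.
    """
    xcg = [table.values[c] for c in MOTIF_PATTERNS["XCG"]]
    xcc = [table.values[c] for c in MOTIF_PATTERNS["XCC"]]
    if any(v is None for v in xcg + xcc):
        raise ValueError("XCG/XCC ratio undefined: some family unobserved")
    denom = sum(xcc)  # type: ignore[arg-type]
    if denom == 0:
        raise ZeroDivisionError("XCG/XCC ratio undefined: sum RSCU(XCC) = 0")
    return sum(xcg) / denom  # type: ignore[arg-type]


def write_rscu_tsv(
    table: RscuTable,
    counts: CodonCountTable,
    path: str | Path,
    code: GeneticCode | None = None,
) -> None:
    """Long-format RSCU TSV: codon, amino acid, count, rel freq, RSCU, flag."""
    code = code or standard_code()
    high = high_frequency_codons(table, code)
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tcount\trel_freq\tRSCU\tis_high_frequency\n")
        for codon in sorted(table.values):
            aa = code.codon_to_aa[codon]
            val = table.values[codon]
            rf = table.rel_freq[codon]
            fh.write(
                f"{codon}\t{aa}\t{counts.counts[codon]}\t"
                f"{'' if rf is None else f'{rf:.6f}'}\t"
                f"{'' if val is None else f'{val:.6f}'}\t"
                f"{int(codon in high)}\n"
            )


def species_rscu(
    gene_counts: "list[CodonCountTable]",
    scope: str,
    code: GeneticCode | None = None,
) -> tuple[CodonCountTable, RscuTable]:
    """Pool per-gene counts and compute genome-wide RSCU at species scope."""
    from .composition import pool_counts

    pooled = pool_counts(gene_counts, scope=f"pooled:{scope}")
    return pooled, rscu(pooled, code)
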