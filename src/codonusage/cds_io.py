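"""FASTA I/O for coding sequences and the quality filter.

A usable CDS must start with ATG, end with a single stop codon, be longer
than 300 nt, have a length divisible by three, contain only {A,C,G,T} and
no in-frame internal stop. Each rejected record is attributed to its first
failing rule so the counts in the report always add up to the input size.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Rule evaluation order; a record is counted under its first failing rule.
FILTER_RULES = (
    "not_triplet",
    "too_short",
    "ambiguous_base",
    "bad_start",
    "bad_stop",
    "internal_stop",
)

_VALID_BASES = frozenset("ACGT")
_STOPS = frozenset({"TAA", "TAG", "TGA"})


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence: identifier plus uppercase nucleotide string."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def codons(self) -> list[str]:
        """Frame-0 codons, including the terminal stop if present."""
        return [self.seq[i : i + 3] for i in range(0, len(self.seq) - 2, 3)]

    def sense_codons(self) -> list[str]:
        """Frame-0 codons with a single terminal stop codon stripped."""
        cods = self.codons()
        if cods and cods[-1] in _STOPS:
            cods.pop()
        return cods


@dataclass
class FilterReport:
    """Per-rule rejection counts for one filtering pass."""

    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in FILTER_RULES}
    )
    kept: int = 0
    total: int = 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reason\tcount\n")
            for reason in FILTER_RULES:
                fh.write(f"{reason}\t{self.counts[reason]}\n")
            fh.write(f"kept\t{self.kept}\n")
            fh.write(f"total\t{self.total}\n")


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[CdsRecord]:
    """Read a (possibly gzip-compressed) multi-FASTA file of CDSs.

    Sequences are uppercased; record order follows the file. An empty file
    yields an empty list with a warning. Sequence data appearing before the
    first header raises :class:`FastaParseError` with the line number.
    """
    with _open_maybe_gzip(path) as fh:
        first_data_line = None
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: sequence data before first FASTA header at line {lineno}"
            )
        first_data_line = lineno
        break
    if first_data_line is None:
        logger.warning("%s: empty FASTA file", path)
        return []
    records = []
    # Re-parse with Biopython for robust header/sequence handling.
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(CdsRecord(id=rec.id, seq=str(rec.seq).upper()))
    return records


def write_fasta(records: Sequence[CdsRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA (gzip if the path ends in .gz); round-trip safe."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    seqrecords = (
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    )
    with _open_maybe_gzip(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def _first_failing_rule(seq: str, min_len: int) -> str | None:
    if len(seq) % 3 != 0:
        return "not_triplet"
    if len(seq) <= min_len:
        return "too_short"
    if not _VALID_BASES.issuperset(seq):
        return "ambiguous_base"
    if not seq.startswith("ATG"):
        return "bad_start"
    if seq[-3:] not in _STOPS:
        return "bad_stop"
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in _STOPS:
            return "internal_stop"
    return None


def filter_cds(
    records: Iterable[CdsRecord], min_len: int = 300
) -> tuple[list[CdsRecord], FilterReport]:
    """Apply the CDS quality filter; keep length > ``min_len`` nt.

    Rules are checked in the fixed order of :data:`FILTER_RULES`; each
    rejected record increments exactly one reason, so
    ``kept + sum(rejections) == total``. Filtering is idempotent.
    """
    report = FilterReport()
    kept: list[CdsRecord] = []
    for rec in records:
        report.total += 1
        reason = _first_failing_rule(rec.seq, min_len)
        if reason is None:
            kept.append(rec)
            report.kept += 1
        else:
            report.counts[reason] += 1
    return kept, report
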