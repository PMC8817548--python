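"""Standard nuclear genetic code: synonymous families and degeneracy classes.

Every downstream statistic (RSCU, ENc, GC3s, codon pairs) consults this
single immutable table. Codons are DNA-alphabet (T, not U), uppercase.
Only the standard code is supported; organellar variants are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from types import MappingProxyType
from typing import Mapping

STOP = "*"

BASES = "ACGT"

#: All 64 trinucleotides in lexicographic order.
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

# Standard code, one-letter amino-acid symbols, '*' for stop.
_CODON_TO_AA = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP, "TAG": STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": STOP, "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if _CODON_TO_AA[c] != STOP
)


class InvalidCodonError(ValueError):
    """Raised when a string is not one of the 64 {A,C,G,T} trinucleotides."""


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code with its synonymous-family structure.

    Attributes
    ----------
    codon_to_aa
        Map of the 64 codons to one-letter amino-acid symbols ('*' = stop).
    families
        Amino acid -> ordered tuple of synonymous codons (lexicographic).
        Includes a '*' family of the three stop codons.
    degeneracy_classes
        Family size k in {1, 2, 3, 4, 6} -> frozenset of amino acids whose
        synonymous family has exactly k members (stops excluded).
    """

    codon_to_aa: Mapping[str, str] = field(
        default_factory=lambda: MappingProxyType(dict(_CODON_TO_AA))
    )

    def __post_init__(self) -> None:
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        object.__setattr__(
            self,
            "families",
            MappingProxyType({aa: tuple(cods) for aa, cods in fams.items()}),
        )
        classes: dict[int, set[str]] = {}
        for aa, cods in self.families.items():
            if aa == STOP:
                continue
            classes.setdefault(len(cods), set()).add(aa)
        object.__setattr__(
            self,
            "degeneracy_classes",
            MappingProxyType({k: frozenset(v) for k, v in classes.items()}),
        )

    families: Mapping[str, tuple[str, ...]] = field(init=False)
    degeneracy_classes: Mapping[int, frozenset[str]] = field(init=False)

    def translate(self, codon: str) -> str:
        """Amino-acid symbol for ``codon`` ('*' for stop)."""
        try:
            return self.codon_to_aa[codon.upper()]
        except KeyError:
            raise InvalidCodonError(f"not a valid codon: {codon!r}") from None


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """Return the (cached, immutable) standard nuclear genetic code."""
    return GeneticCode()


def family_of(code: GeneticCode, codon: str) -> tuple[str, tuple[str, ...], int]:
    """Return ``(amino_acid, family_codons, family_size)`` for ``codon``.

    Raises
    ------
    InvalidCodonError
        If ``codon`` is not one of the 64 valid trinucleotides.
    """
    aa = code.translate(codon)
    fam = code.families[aa]
    return aa, fam, len(fam)
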