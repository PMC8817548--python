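"""Shared fixtures: the genetic code and reusable synthetic gene sets."""

from __future__ import annotations

import pytest

import codonusage as cu
from codonusage.cds_io import CdsRecord
from codonusage.genetic_code import STOP


@pytest.fixture(scope="session")
def code():
    return cu.standard_code()


@pytest.fixture(scope="session")
def one_codon_per_family_gene(code) -> CdsRecord:
    """A CDS using exactly one synonymous codon per amino acid, every
    degenerate family present twice — Wright's ENc is exactly 20."""
    body = []
    for aa, fam in sorted(code.families.items()):
        if aa == STOP or len(fam) < 2:
            continue
        body.extend([fam[0], fam[0]])
    return CdsRecord(id="one_per_family", seq="ATG" + "".join(body) + "TAA")


@pytest.fixture(scope="session")
def uniform_usage_counts(code) -> cu.CodonCountTable:
    """Every codon of every family (stops included) at an equal count of
    1000 — equal synonymous usage at scale."""
    t = cu.CodonCountTable(scope="uniform")
    for codon in t.counts:
        t.counts[codon] = 1000
    return t


@pytest.fixture(scope="session")
def mutation_only_records() -> list[CdsRecord]:
    """500 genes x 300 sense codons under the mutation-only model at
    theta = 0.5 — the null gene set used by the ENc-plot checks."""
    spec = cu.SyntheticSpec(
        n_genes=500,
        codon_length_range=(300, 300),
        model=cu.MutationOnly(0.5),
        seed=1,
    )
    return cu.generate(spec, label="null")


@pytest.fixture(scope="session")
def small_random_records() -> list[CdsRecord]:
    """100 modest genes with biased codon weights, for oracle recounts."""
    weights = {}
    codeobj = cu.standard_code()
    for aa, fam in codeobj.families.items():
        for i, c in enumerate(fam):
            weights[c] = float(i + 1)
    spec = cu.SyntheticSpec(
        n_genes=100,
        codon_length_range=(101, 160),
        model=cu.Weighted(weights),
        seed=42,
    )
    return cu.generate(spec, label="rand")
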