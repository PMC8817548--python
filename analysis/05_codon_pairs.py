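#!/usr/bin/env python
"""Codon-pair analysis: junction dinucleotide spectrum and RSCPU.

Classifies every adjacent sense-codon pair by the dinucleotide straddling
the codon junction (nnXYnn) and computes relative synonymous codon-pair
usage over dipeptide families. With CpG suppression in the generator the
nnCGnn share drops below its unsuppressed expectation. Writes the
cross-species junction table and per-species RSCPU tables under
results/profile/.
"""

from pathlib import Path

from codonusage.cds_io import read_fasta
from codonusage.codon_pairs import (
    codon_pair_counts,
    high_frequency_pairs,
    junction_table,
    rscpu,
    write_junction_tsv,
    write_rscpu_tsv,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fastas = sorted((ROOT / "filtered").glob("*.filtered.fa"))
    if not fastas:
        raise SystemExit("run 02_filter_cds.py first")
    out = ROOT / "profile"
    out.mkdir(parents=True, exist_ok=True)
    junctions = {}
    print(f"{'species':<16} {'top junction':>12} {'nnCGnn%':>8} {'high-freq pairs':>15}")
    for fasta in fastas:
        label = fasta.name.split(".")[0]
        pairs = codon_pair_counts(read_fasta(fasta), scope=label)
        j = junction_table(pairs)
        junctions[label] = j
        write_rscpu_tsv(pairs, out / f"{label}.rscpu.tsv")
        top = max(j.percentages, key=j.percentages.get)
        n_high = len(high_frequency_pairs(rscpu(pairs), pairs))
        print(
            f"{label:<16} {'nn' + top + 'nn':>12} {j.percentages['CG']:8.2f} "
            f"{n_high:15d}"
        )
    write_junction_tsv(junctions, out / "junction_comparison.tsv")


if __name__ == "__main__":
    main()
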