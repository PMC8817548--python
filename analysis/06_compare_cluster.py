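#!/usr/bin/env python
"""Cross-species comparison: GC3-gradient distances and RSCU biclustering.

Computes each species' 100-bin 5'->3' GC3 gradient, the pairwise
Euclidean distance matrix over those gradients, and the complete-linkage
biclustering of the species x 59-codon RSCU matrix. Species generated at
nearby GC3 should sit at small gradient distances; the dendrogram's
structure reflects overall codon-usage similarity. Writes the distance
matrix, RSCU matrix, merge lists and Newick dendrograms under
results/compare/.
"""

from pathlib import Path

from codonusage.cds_io import read_fasta
from codonusage.comparative import (
    bicluster,
    build_rscu_matrix,
    gradient_distance_matrix,
    write_distance_tsv,
    write_merge_tsv,
    write_rscu_matrix_tsv,
)
from codonusage.composition import count_codons, gc3_gradient, pool_counts
from codonusage.rscu import rscu

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fastas = sorted((ROOT / "filtered").glob("*.filtered.fa"))
    if len(fastas) < 2:
        raise SystemExit("run 02_filter_cds.py first (need >= 2 species)")
    out = ROOT / "compare"
    out.mkdir(parents=True, exist_ok=True)

    gradients, tables = [], []
    for fasta in fastas:
        label = fasta.name.split(".")[0]
        records = read_fasta(fasta)
        gradients.append(gc3_gradient(records, n_bins=100, species=label))
        pooled = pool_counts([count_codons(r) for r in records], scope=label)
        tables.append((label, rscu(pooled)))

    dm = gradient_distance_matrix(gradients)
    write_distance_tsv(dm, out / "gc3_gradient_distances.tsv")
    off_diag = dm.d[dm.d > 0]
    print(
        f"gradient distances over {len(dm.labels)} species: "
        f"{off_diag.min():.3f} - {off_diag.max():.3f}"
    )

    matrix = build_rscu_matrix(tables)
    write_rscu_matrix_tsv(matrix, out / "rscu_matrix.tsv")
    row_d, col_d, row_order, col_order = bicluster(matrix)
    (out / "species_dendrogram.nwk").write_text(row_d.to_newick() + "\n")
    (out / "codon_dendrogram.nwk").write_text(col_d.to_newick() + "\n")
    write_merge_tsv(row_d, out / "species_merges.tsv")
    write_merge_tsv(col_d, out / "codon_merges.tsv")
    print(f"species leaf order: {', '.join(row_order)}")
    print(f"59-codon matrix clustered; outputs in {out}")


if __name__ == "__main__":
    main()
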