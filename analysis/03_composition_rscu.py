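#!/usr/bin/env python
"""Per-species composition and RSCU: GC indices, high-frequency codons,
stop-codon preference and the XCG/XCC CpG-suppression ratio.

Prints one summary line per species and writes the per-gene composition
and long-format RSCU tables under results/profile/.
"""

from pathlib import Path

from codonusage.cds_io import read_fasta
from codonusage.composition import (
    composition_table,
    count_codons,
    gc_profile,
    pool_counts,
    write_composition_tsv,
)
from codonusage.rscu import (
    high_frequency_codons,
    rscu,
    stop_codon_rscu,
    write_rscu_tsv,
    xcg_xcc_ratio,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fastas = sorted((ROOT / "filtered").glob("*.filtered.fa"))
    if not fastas:
        raise SystemExit("run 02_filter_cds.py first")
    out = ROOT / "profile"
    out.mkdir(parents=True, exist_ok=True)
    print(
        f"{'species':<16} {'GC%':>6} {'GC3%':>6} {'GC3s%':>6} "
        f"{'high-freq codons':<28} {'XCG/XCC':>8}"
    )
    for fasta in fastas:
        label = fasta.name.split(".")[0]
        records = read_fasta(fasta)
        gene_counts = [count_codons(r) for r in records]
        pooled = pool_counts(gene_counts, scope=label)
        prof = gc_profile(pooled)
        table = rscu(pooled)
        high = sorted(high_frequency_codons(table))
        write_composition_tsv(composition_table(records), out / f"{label}.composition.tsv")
        write_rscu_tsv(table, pooled, out / f"{label}.rscu.tsv")
        stops = stop_codon_rscu(pooled)
        fav_stop = max(stops, key=stops.get)
        print(
            f"{label:<16} {prof.gc:6.2f} {prof.gc3:6.2f} {prof.gc3s:6.2f} "
            f"{','.join(high) or '-':<28} {xcg_xcc_ratio(table):8.3f}"
            f"   stop pref {fav_stop} ({stops[fav_stop]:.2f})"
        )


if __name__ == "__main__":
    main()
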