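#!/usr/bin/env python
"""ENc-plot and neutrality-plot analysis of the panel.

For each species: per-gene observed ENc (Wright) vs the mutation-only
expectation from GC3s, the binned (ENCexp-ENCobs)/ENCexp distribution,
and the GC12-on-GC3 regression. Mutation-only species should hug the
expected curve (most deviations in [-0.1, 0.1)) and the coupled species
should show a significantly positive slope near its generating value.
Writes ENc tables, deviation histograms and neutrality fits under
results/profile/.
"""

from pathlib import Path

from codonusage.cds_io import read_fasta
from codonusage.composition import composition_table
from codonusage.enc_neutrality import (
    enc_table,
    neutrality_fit,
    write_enc_tsv,
    write_histogram_tsv,
    write_neutrality_tsv,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fastas = sorted((ROOT / "filtered").glob("*.filtered.fa"))
    if not fastas:
        raise SystemExit("run 02_filter_cds.py first")
    out = ROOT / "profile"
    out.mkdir(parents=True, exist_ok=True)
    fits = []
    print(
        f"{'species':<16} {'mean dev':>9} {'% in [-0.1,0.1)':>16} "
        f"{'slope':>7} {'R2':>6} {'p':>9}"
    )
    for fasta in fastas:
        label = fasta.name.split(".")[0]
        records = read_fasta(fasta)
        enc_records, hist = enc_table(records)
        write_enc_tsv(enc_records, out / f"{label}.enc.tsv")
        write_histogram_tsv(hist, out / f"{label}.enc_deviation_hist.tsv")
        comp = composition_table(records)
        fit = neutrality_fit(
            [(p.gc1 + p.gc2) / 2 for _, p in comp], [p.gc3 for _, p in comp]
        )
        fits.append((label, fit))
        mean_dev = sum(r.deviation for r in enc_records) / len(enc_records)
        mid = hist.percentages[1] + hist.percentages[2]  # [-0.1,0) + [0,0.1)
        print(
            f"{label:<16} {mean_dev:9.4f} {mid:16.1f} "
            f"{fit.slope:7.3f} {fit.r2:6.3f} {fit.p_value:9.2e}"
        )
    write_neutrality_tsv(fits, out / "neutrality.tsv")


if __name__ == "__main__":
    main()
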