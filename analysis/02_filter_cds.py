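#!/usr/bin/env python
"""Apply the CDS quality filter to the panel and report per-rule rejections.

Synthetic panels are valid by construction, so every species should come
through with zero rejections — this step is where real downloaded CDS
sets would lose entries (non-ATG starts, internal stops, ambiguity
codes, length <= 300 nt). Output: filtered FASTA + filter report TSV per
species under results/filtered/.
"""

from pathlib import Path

from codonusage.pipeline import RunConfig, run_filter

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = sorted((ROOT / "panel").glob("*.fa"))
    if not panel:
        raise SystemExit("run 01_simulate_panel.py first")
    config = RunConfig(species=[(p.stem, str(p)) for p in panel])
    run_filter(config, ROOT / "filtered")
    for p in panel:
        report = (ROOT / "filtered" / f"{p.stem}.filter_report.tsv").read_text()
        rows = dict(line.split("\t") for line in report.splitlines()[1:])
        rejected = int(rows["total"]) - int(rows["kept"])
        print(f"{p.stem}: kept {rows['kept']}/{rows['total']} ({rejected} rejected)")


if __name__ == "__main__":
    main()
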