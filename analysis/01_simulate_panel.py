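#!/usr/bin/env python
"""Generate the synthetic seven-species panel used by the downstream steps.

The panel emulates a clade of plant genomes whose codon usage differs
mainly through third-position mutation pressure: five species under the
mutation-only model at varied GC3 (0.39-0.48, the spread of typical
dicot genomes), one with a 5'->3' GC3 gradient, and one with GC12-GC3
coupling. All species carry mild CpG suppression. Output: one FASTA plus
a JSON sidecar per species under results/panel/.
"""

from pathlib import Path

from codonusage.pipeline import RunConfig, run_simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"

SPECIES = {
    "jujube_like": {"kind": "mutation_only", "theta": 0.39},
    "strawberry_like": {"kind": "mutation_only", "theta": 0.41},
    "apple_like": {"kind": "mutation_only", "theta": 0.42},
    "apricot_like": {"kind": "mutation_only", "theta": 0.40},
    "pear_like": {"kind": "mutation_only", "theta": 0.44},
    "mulberry_like": {"kind": "gradient", "theta_start": 0.40, "theta_end": 0.48},
    "peach_like": {
        "kind": "coupled",
        "slope": 0.20,
        "intercept": 0.45,
        "sigma": 0.015,
        "gc3_center": 0.42,
    },
}


def main() -> None:
    config = RunConfig(
        seed=20240301,
        simulate={
            label: {
                "n_genes": 120,
                "codon_length_range": [120, 400],
                "model": model,
                "cg_suppression": 0.7,
            }
            for label, model in SPECIES.items()
        },
    )
    paths = run_simulate(config, OUT)
    print(f"wrote {len(paths)} species FASTA files to {OUT}")
    for label, path in paths.items():
        print(f"  {label}: {path.name}")


if __name__ == "__main__":
    main()
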